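"""Tests for landmark edits, VP diffusion and the audit utilities."""

import numpy as np
import pytest
from skimage.transform import resize

from geospine import phantom
from geospine.counterfactual import (CounterfactualEdit, DiffusionModel, EditCapError,
                                     VPSchedule, class_probability, edit_landmarks,
                                     monotonicity_audit, realism_comparison, sample,
                                     train_denoiser, vp_forward)
from geospine.geometry import compute_all_indices
from geospine.phantom import CLASSES


@pytest.fixture(scope="module")
def pathology_samples():
    rng = np.random.default_rng(2)
    return {cls: phantom.make_sample(phantom.sample_config(cls, rng))
            for cls in ("spondylolisthesis", "infection", "spondyloarthropathy",
                        "normal_lumbar")}


class TestEditLandmarks:
    def test_identity_edit(self, pathology_samples):
        s = pathology_samples["normal_lumbar"]
        out = edit_landmarks(s.landmarks, CounterfactualEdit("slip_ratio", 0.0))
        assert np.array_equal(out.centroids, s.landmarks.centroids)

    @pytest.mark.parametrize("index_id,delta", [
        ("slip_ratio", 0.1), ("slip_ratio", -0.03),
        ("disc_asymmetry", 0.05), ("disc_asymmetry", -0.04),
        ("si_symmetry", 1.5), ("si_symmetry", -0.2),
        ("cobb_angle", 4.0), ("cobb_angle", -1.5),
    ])
    def test_targeted_index_changes_by_exactly_delta(self, pathology_samples,
                                                     index_id, delta):
        s = pathology_samples["spondylolisthesis"]
        before = compute_all_indices(s.landmarks)
        out = edit_landmarks(s.landmarks, CounterfactualEdit(index_id, delta))
        after = compute_all_indices(out)
        if index_id in ("slip_ratio", "disc_asymmetry"):
            lvl = int(np.argmax(getattr(before, index_id)))  # default edit target
            change = getattr(after, index_id)[lvl] - getattr(before, index_id)[lvl]
        else:
            change = getattr(after, index_id) - getattr(before, index_id)
        assert change == pytest.approx(delta, abs=1e-6)

    def test_slip_edit_preserves_all_other_stored_indices(self, pathology_samples):
        s = pathology_samples["spondylolisthesis"]
        before = compute_all_indices(s.landmarks)
        out = edit_landmarks(s.landmarks, CounterfactualEdit("slip_ratio", 0.08))
        after = compute_all_indices(out)
        lvl = int(np.argmax(before.slip_ratio))
        keep = np.delete(np.arange(len(before.slip_ratio)), lvl)
        assert np.allclose(after.slip_ratio[keep], before.slip_ratio[keep], atol=1e-9)
        assert np.allclose(after.disc_asymmetry, before.disc_asymmetry, atol=1e-9)
        assert after.si_symmetry == pytest.approx(before.si_symmetry, abs=1e-9)

    def test_disc_and_si_edits_touch_nothing_else(self, pathology_samples):
        s = pathology_samples["infection"]
        before = compute_all_indices(s.landmarks)
        for index_id, delta in (("disc_asymmetry", -0.05), ("si_symmetry", 0.7)):
            after = compute_all_indices(
                edit_landmarks(s.landmarks, CounterfactualEdit(index_id, delta)))
            assert np.allclose(after.slip_ratio, before.slip_ratio, atol=1e-9)
            assert after.cobb_angle == pytest.approx(before.cobb_angle, abs=1e-9)

    def test_cobb_edit_preserves_disc_and_si(self, pathology_samples):
        s = pathology_samples["normal_lumbar"]
        before = compute_all_indices(s.landmarks)
        after = compute_all_indices(
            edit_landmarks(s.landmarks, CounterfactualEdit("cobb_angle", 5.0)))
        assert np.allclose(after.disc_asymmetry, before.disc_asymmetry, atol=1e-12)
        assert after.si_symmetry == pytest.approx(before.si_symmetry, abs=1e-12)

    def test_slip_cap_rejected(self):
        with pytest.raises(EditCapError, match="0.2"):
            CounterfactualEdit("slip_ratio", 0.25)

    def test_disc_height_cap_rejected(self, pathology_samples):
        s = pathology_samples["normal_lumbar"]
        asym = compute_all_indices(s.landmarks).disc_asymmetry
        j = int(np.argmax(asym))
        # driving asymmetry up by 0.9 implies >30 % height change on a margin
        with pytest.raises(EditCapError, match="30"):
            edit_landmarks(s.landmarks, CounterfactualEdit("disc_asymmetry", 0.9, level=j))

    def test_infeasible_negative_slip_rejected(self, pathology_samples):
        s = pathology_samples["normal_lumbar"]
        with pytest.raises(ValueError, match="negative"):
            edit_landmarks(s.landmarks, CounterfactualEdit("slip_ratio", -0.2))


class TestVPForward:
    def test_t0_is_identity(self):
        sched = VPSchedule(T=100)
        x0 = np.random.default_rng(0).normal(size=(8, 8))
        assert np.array_equal(vp_forward(x0, 0, sched, np.zeros((8, 8))), x0)

    def test_unit_variance_preserved_at_all_t(self):
        sched = VPSchedule(T=50)
        rng = np.random.default_rng(1)
        n = 10_000
        x0 = rng.normal(size=n)
        for t in (1, 10, 25, 50):
            xt = vp_forward(x0, t, sched, rng.normal(size=n))
            assert xt.var() == pytest.approx(1.0, abs=0.05)

    def test_alpha_bar_is_running_product(self):
        sched = VPSchedule(T=1000)
        prod = np.concatenate([[1.0], np.cumprod(1.0 - sched.beta_t)])
        assert np.max(np.abs(sched.alpha_bar - prod)) < 1e-12

    def test_t_out_of_range(self):
        with pytest.raises(ValueError):
            vp_forward(np.zeros(4), 101, VPSchedule(T=100), np.zeros(4))


class TestDenoiserTraining:
    @pytest.fixture(scope="module")
    def trained(self):
        samples = phantom.generate_samples(n=60, seed=3, image_size=(96, 96))
        imgs = np.stack([resize(s.image, (16, 16), anti_aliasing=True) for s in samples])
        labels = np.array([CLASSES.index(s.class_label) for s in samples])
        deltas = np.random.default_rng(0).uniform(-0.2, 0.2, len(samples))
        sched = VPSchedule(T=200)
        model, losses = train_denoiser(imgs, labels, deltas, sched, n_steps=200, seed=4)
        return model, losses, sched, (imgs, labels, deltas)

    def test_loss_decreases(self, trained):
        _, losses, _, _ = trained
        assert np.mean(losses[-20:]) < np.mean(losses[:20])

    def test_output_shape_matches_input(self, trained):
        model, _, _, _ = trained
        out = model.denoise(np.random.default_rng(0).normal(size=(16, 16)), 10, 2, 0.05)
        assert out.shape == (16, 16)

    def test_training_deterministic(self, trained):
        _, losses, sched, (imgs, labels, deltas) = trained
        _, losses2 = train_denoiser(imgs, labels, deltas, sched, n_steps=200, seed=4)
        assert np.array_equal(losses, losses2)

    def test_sampling_deterministic_and_clipped(self, trained):
        model, _, sched, _ = trained
        edit = CounterfactualEdit("slip_ratio", 0.1)
        a = sample(model, 0, edit, seed=9, schedule=sched)
        b = sample(model, 0, edit, seed=9, schedule=sched)
        assert np.array_equal(a, b)
        assert a.min() >= 0.0 and a.max() <= 1.0


class TestSamplerClosedForm:
    def test_point_mass_posterior_mean(self):
        """With the analytic denoiser for a point-mass data distribution at m,
        ancestral sampling must concentrate at m."""
        m = 0.7  # in model space [-1, 1] after the affine intensity map: 2m-1
        target = 2 * m - 1.0
        sched = VPSchedule(T=100)

        class Oracle:
            image_shape = (1, 1)

            def denoise(self, x, t, y, dg):
                ab = sched.alpha_bar[t]
                return (x - np.sqrt(ab) * target) / np.sqrt(1.0 - ab)

        xs = [sample(Oracle(), 0, None, seed=s, schedule=sched)[0, 0] for s in range(200)]
        assert np.mean(xs) == pytest.approx(m, abs=0.02)
        assert np.std(xs) < 0.05


class TestAudits:
    def test_monotone_classifier_flagged_true(self, pathology_samples):
        s = pathology_samples["spondylolisthesis"]

        def fn(image, landmarks):
            slip = compute_all_indices(landmarks).summary()[0]
            p = min(0.95, 0.2 + slip)
            out = np.full(6, (1 - p) / 5)
            out[0] = p
            return out

        rec = monotonicity_audit(fn, s, "slip_ratio", "spondylolisthesis",
                                 [0, 0.05, 0.10, 0.15, 0.20])
        assert rec["monotone"] is True
        assert len(rec["probabilities"]) >= 4

    def test_alternating_classifier_flagged_false(self, pathology_samples):
        s = pathology_samples["spondylolisthesis"]
        state = {"k": 0}

        def fn(image, landmarks):
            state["k"] += 1
            p = 0.2 if state["k"] % 2 else 0.8
            out = np.full(6, (1 - p) / 5)
            out[0] = p
            return out

        rec = monotonicity_audit(fn, s, "slip_ratio", "spondylolisthesis",
                                 [0, 0.05, 0.10, 0.15])
        assert rec["monotone"] is False

    def test_grid_beyond_cap_is_skipped(self, pathology_samples):
        s = pathology_samples["normal_lumbar"]

        def fn(image, landmarks):
            return np.full(6, 1 / 6)

        rec = monotonicity_audit(fn, s, "slip_ratio", "spondylolisthesis",
                                 [0, 0.1, 0.2, 0.25])
        assert 0.25 not in rec["grid"]  # cap honored: infeasible point skipped

    def test_abnormal_probability_pools_pathologies(self):
        probs = np.array([0.1, 0.2, 0.3, 0.15, 0.15, 0.1])
        assert class_probability(probs, "abnormal") == pytest.approx(0.6)


class TestRealismComparison:
    def test_identical_groups(self, small_samples):
        out = realism_comparison(small_samples, small_samples)
        for rec in out.values():
            assert rec["cohens_d"] == pytest.approx(0.0, abs=1e-12)
            assert rec["ks_p"] == pytest.approx(1.0)

    def test_unit_mean_shift_effect_size(self):
        rng = np.random.default_rng(0)

        class Fake:
            def __init__(self, v):
                self._v = v

            def summary(self):
                return np.array([self._v, 0.1, 1.0, 5.0])

        a = [Fake(v) for v in rng.normal(0, 1, 200)]
        b = [Fake(v) for v in rng.normal(1, 1, 200)]
        out = realism_comparison(a, b)
        assert out["slip_ratio"]["cohens_d"] == pytest.approx(1.0, abs=0.2)
        assert out["slip_ratio"]["p_value"] < 1e-6

    def test_report_fields_follow_method_comparison_format(self, small_samples):
        out = realism_comparison(small_samples[:10], small_samples[10:20])
        for rec in out.values():
            for key in ("real_mean", "real_sd", "cf_mean", "cf_sd", "p_value",
                        "cohens_d", "ks_p", "frac_within_95"):
                assert key in rec

    def test_too_few_samples_rejected(self, small_samples):
        with pytest.raises(ValueError):
            realism_comparison(small_samples[:1], small_samples[:5])
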