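"""Weakly supervised keypoint discovery with geometric priors.

A small heatmap network predicts one spatial map per keypoint slot; soft
(argmax-free) decoding yields sub-pixel centroid estimates plus a visibility
score.  Training mixes three signals:

* direct coordinate regression on the sparsely annotated subset (<= 15 % of
  images carry landmarks),
* four differentiable geometric priors on *all* images — vertebrae are
  ordered along the spine axis, consecutive spacing is smooth, centroids stay
  near the least-squares spinal axis, and curvature varies smoothly
  (third-order differences),
* an EMA teacher-student consistency term: the teacher (exponential moving
  average of the student) sees weakly augmented images and its heatmaps,
  mapped back into the student frame, supervise the student's heatmaps on
  strongly augmented views.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from . import _autograd as ag
from ._autograd import Tensor
from .nn import MLP, AdamW, Module

logger = logging.getLogger(__name__)

__all__ = [
    "HeatmapSet",
    "PriorWeights",
    "TeacherState",
    "soft_argmax",
    "supervised_keypoint_loss",
    "prior_losses",
    "ema_update",
    "consistency_loss",
    "KeypointNet",
    "train_keypoint_model",
    "keypoint_error",
]


@dataclass
class HeatmapSet:
    """Per-keypoint nonnegative maps with decoded coordinates and visibility."""

    maps: np.ndarray       # (K, H, W), >= 0
    keypoints: np.ndarray  # (K, 2) decoded (x, y)
    visibility: np.ndarray  # (K,) in [0, 1]


@dataclass
class PriorWeights:
    """Nonnegative weights of the four geometric priors."""

    w_order: float = 1.0
    w_spacing: float = 1.0
    w_symmetry: float = 1.0
    w_curvature: float = 1.0

    def __post_init__(self):
        if min(self.w_order, self.w_spacing, self.w_symmetry, self.w_curvature) < 0:
            raise ValueError("prior weights must be >= 0")


@dataclass
class TeacherState:
    """EMA copy of the student parameters."""

    params: list
    decay: float = 0.99

    def __post_init__(self):
        if not (0.0 <= self.decay <= 1.0):
            raise ValueError("EMA decay must lie in [0, 1]")


def soft_argmax(heatmap, temperature: float = 1.0):
    """Spatial expectation under softmax(heatmap / T); returns ((x, y), visibility).

    Fully differentiable when given a Tensor.  Visibility is the maximum
    softmax probability mass inside any 5x5 window (computed on detached
    values).  As T -> 0 the decode approaches the hard argmax cell center.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    t = ag.as_tensor(heatmap)
    data = t.data
    if not np.any(np.isfinite(data)):
        raise ValueError("heatmap has no finite entries")
    h, w = data.shape
    p = ag.softmax((t * (1.0 / temperature)).reshape(-1), axis=-1).reshape(h, w)
    cols = Tensor(np.arange(w, dtype=float)[None, :])
    rows = Tensor(np.arange(h, dtype=float)[:, None])
    x = (p * cols).sum()
    y = (p * rows).sum()
    mass = ndimage.uniform_filter(p.data, size=5, mode="constant") * 25.0
    visibility = float(np.clip(mass.max(), 0.0, 1.0))
    return (x, y), visibility


def supervised_keypoint_loss(decoded, annotated: np.ndarray,
                             visible: np.ndarray | None = None):
    """Mean squared decoded-vs-annotated coordinate error (pixels^2).

    ``decoded``: (K, 2) Tensor or array; ``annotated``: (N, 2) array matched
    to the first N slots by index.  Averaged over visible keypoints; with no
    annotated keypoints contributes 0 (logged).
    """
    annotated = np.asarray(annotated, dtype=float).reshape(-1, 2)
    n = len(annotated)
    if n == 0:
        logger.warning("supervised_keypoint_loss: no annotated keypoints; contributing 0")
        return Tensor(0.0)
    dec = ag.as_tensor(decoded)
    if visible is None:
        visible = np.ones(n, dtype=bool)
    idx = np.nonzero(visible[:n])[0]
    if len(idx) == 0:
        logger.warning("supervised_keypoint_loss: no visible keypoints; contributing 0")
        return Tensor(0.0)
    diff = dec[idx] - Tensor(annotated[idx])
    return (diff * diff).sum(axis=-1).mean()


def prior_losses(decoded, weights: PriorWeights, margin: float = 1.0,
                 symmetry_tol: float = 2.0) -> dict:
    """The four geometric priors on decoded keypoints; all differentiable.

    ordering   : sum_i max(0, y_i - y_{i+1} + margin)^2  (superior->inferior)
    spacing    : population variance of consecutive gap lengths
    symmetry   : mean squared lateral deviation from the least-squares spinal
                 axis beyond a tolerance band
    curvature  : mean squared norm of third-order centroid differences

    Returns {"ordering", "spacing", "symmetry", "curvature", "total"}.
    """
    p = ag.as_tensor(decoded)
    k = p.shape[0]
    if k < 3:
        raise ValueError("priors need at least 3 decoded keypoints")
    x, y = p[:, 0], p[:, 1]

    viol = (y[:-1] - y[1:] + margin).relu()
    ordering = (viol * viol).sum()

    d = p[1:] - p[:-1]
    gaps = ((d * d).sum(axis=-1) + 1e-12) ** 0.5
    mu = gaps.mean()
    spacing = ((gaps - mu) * (gaps - mu)).mean()

    # least-squares spinal axis x = a + b*y (closed-form 2x2 solve)
    ym, xm = y.mean(), x.mean()
    yc, xc = y - ym, x - xm
    b = (yc * xc).sum() / ((yc * yc).sum() + 1e-9)
    dev = xc - b * yc
    excess = (ag.smooth_abs(dev, 1e-6) - symmetry_tol).relu()
    symmetry = (excess * excess).mean()

    if k >= 4:
        d3 = p[3:] - p[2:-1] * 3.0 + p[1:-2] * 3.0 - p[:-3]
        curvature = (d3 * d3).sum(axis=-1).mean()
    else:
        logger.warning("prior_losses: < 4 keypoints, curvature prior skipped")
        curvature = Tensor(0.0)

    total = (weights.w_order * ordering + weights.w_spacing * spacing
             + weights.w_symmetry * symmetry + weights.w_curvature * curvature)
    return {"ordering": ordering, "spacing": spacing, "symmetry": symmetry,
            "curvature": curvature, "total": total}


def ema_update(teacher: TeacherState, student_params: list) -> TeacherState:
    """theta_T <- beta*theta_T + (1-beta)*theta_S, elementwise."""
    student = [p.data if isinstance(p, Tensor) else np.asarray(p, dtype=float)
               for p in student_params]
    if len(student) != len(teacher.params):
        raise ValueError("teacher/student parameter counts differ")
    new = []
    for t, s in zip(teacher.params, student):
        if t.shape != s.shape:
            raise ValueError(f"teacher/student shape mismatch {t.shape} vs {s.shape}")
        new.append(teacher.decay * t + (1.0 - teacher.decay) * s)
    return TeacherState(new, teacher.decay)


def consistency_loss(student_maps, teacher_maps: np.ndarray,
                     keypoint_mask: np.ndarray | None = None):
    """Mean squared difference of sum-normalized heatmaps, averaged over keypoints.

    Teacher maps are constants (no gradient).  ``keypoint_mask`` optionally
    gates which slots contribute (teacher-confidence gating).
    """
    s = ag.as_tensor(student_maps)
    t = np.asarray(teacher_maps, dtype=float)
    if s.shape != t.shape:
        raise ValueError(f"heatmap grids differ: {s.shape} vs {t.shape}")
    k = s.shape[0]
    mask = np.ones(k, dtype=bool) if keypoint_mask is None else np.asarray(keypoint_mask)
    if not mask.any():
        return Tensor(0.0)
    sflat = s.reshape(k, -1)
    snorm = sflat / (sflat.sum(axis=-1, keepdims=True) + 1e-12)
    tflat = t.reshape(k, -1)
    tnorm = tflat / (tflat.sum(axis=-1, keepdims=True) + 1e-12)
    diff = snorm[np.nonzero(mask)[0]] - Tensor(tnorm[mask])
    return (diff * diff).mean()


# ---------------------------------------------------------------------------
# heatmap network
# ---------------------------------------------------------------------------

class KeypointNet(Module):
    """Tiny heatmap model: downsampled image -> MLP -> K maps on a G x G grid.

    Decoding scales grid cells back to image pixels; slots beyond the visible
    chain simply produce low-confidence maps.
    """

    def __init__(self, n_keypoints: int = 10, in_grid: int = 32, heat_grid: int = 16,
                 hidden: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_keypoints = n_keypoints
        self.in_grid = in_grid
        self.heat_grid = heat_grid
        self.net = MLP([in_grid * in_grid, hidden, n_keypoints * heat_grid ** 2], rng)

    def heatmaps(self, image: np.ndarray) -> Tensor:
        feat = _sk_resize(image, (self.in_grid, self.in_grid), anti_aliasing=True)
        out = self.net(Tensor(feat.reshape(1, -1)))
        return out.reshape(self.n_keypoints, self.heat_grid, self.heat_grid)

    def decode(self, image: np.ndarray, temperature: float = 1.0):
        """Returns (decoded (K,2) Tensor in image pixels, visibility (K,), maps)."""
        h, w = image.shape
        maps = self.heatmaps(image)
        sy, sx = h / self.heat_grid, w / self.heat_grid
        coords, vis = [], []
        for k in range(self.n_keypoints):
            (x, y), v = soft_argmax(maps[k], temperature)
            coords.append(ag.stack([x * sx + sx / 2.0, y * sy + sy / 2.0]))
            vis.append(v)
        return ag.stack(coords, axis=0), np.array(vis), maps

    def predict(self, image: np.ndarray) -> HeatmapSet:
        decoded, vis, maps = self.decode(image)
        m = maps.data
        m = m - m.min(axis=(1, 2), keepdims=True)
        return HeatmapSet(m, decoded.data, vis)


def keypoint_error(model: KeypointNet, samples) -> float:
    """Mean distance (px) between decoded slots and true centroids."""
    errs = []
    for s in samples:
        decoded, _, _ = model.decode(s.image)
        n = s.landmarks.n_vertebrae
        d = decoded.data[:n] - s.landmarks.centroids
        errs.append(np.sqrt((d ** 2).sum(axis=1)).mean())
    return float(np.mean(errs))


def export_predictions(model: KeypointNet, image: np.ndarray, path,
                       n_vertebrae: int, roi_size: float = 16.0) -> None:
    """Write decoded keypoints in the landmark CSV schema plus a sidecar JSON
    with per-keypoint visibility and ROI bounding boxes (x, y, w, h)."""
    import json
    from pathlib import Path

    from .geometry import LandmarkSet
    from .io import write_landmarks

    pred = model.predict(image)
    pts = pred.keypoints[:n_vertebrae]
    order = np.argsort(pts[:, 1], kind="stable")
    pts = pts[order]
    # enforce strictly increasing y for schema validity
    for i in range(1, len(pts)):
        if pts[i, 1] <= pts[i - 1, 1]:
            pts[i, 1] = pts[i - 1, 1] + 1e-6
    n = len(pts)
    lm = LandmarkSet(pts, np.full(n, roi_size), np.full((n - 1, 2), roi_size / 2.0),
                     np.array([0.0, 0.0]), visibility=pred.visibility[:n][order])
    write_landmarks(lm, path)
    sidecar = {
        "visibility": [float(v) for v in pred.visibility[:n][order]],
        "roi_boxes": [[float(x - roi_size / 2), float(y - roi_size / 2),
                       roi_size, roi_size] for x, y in pts],
    }
    Path(path).with_suffix(".rois.json").write_text(json.dumps(sidecar, indent=1))


def _augment(image: np.ndarray, rng: np.random.Generator, strong: bool):
    """Training augmentations; returns (image, transform record for alignment)."""
    record = {"flip": False, "angle": 0.0}
    out = image
    scale = 1.0 + rng.uniform(-0.1, 0.1)          # intensity +-10 %
    out = np.clip(out * scale, 0.0, 1.0)
    if strong:
        if rng.random() < 0.5:
            out = out[:, ::-1].copy()
            record["flip"] = True
        angle = rng.uniform(-5.0, 5.0)             # mild rotation
        out = ndimage.rotate(out, angle, reshape=False, order=1, mode="nearest")
        record["angle"] = angle
        out = np.clip(out + rng.normal(0.0, 0.02, out.shape), 0.0, 1.0)
    return out, record


def _align_teacher_maps(maps: np.ndarray, record: dict) -> np.ndarray:
    """Map teacher heatmaps (weak view) into the student's strong-view frame."""
    out = maps
    if record["flip"]:
        out = out[:, :, ::-1]
    if record["angle"]:
        out = np.stack([
            ndimage.rotate(m, record["angle"], reshape=False, order=1, mode="nearest")
            for m in out
        ])
    return np.clip(out, 0.0, None)


def train_keypoint_model(samples, annotated_mask, n_keypoints: int = 10,
                         weights: PriorWeights | None = None, epochs: int = 30,
                         lr: float = 3e-3, seed: int = 0, use_priors: bool = True,
                         use_consistency: bool = False, ema_decay: float = 0.95,
                         prior_scale: float = 0.01) -> tuple:
    """Train the keypoint model under sparse supervision.

    Supervised coordinate regression runs on annotated samples only; the
    geometric priors (and optionally EMA teacher-student consistency) run on
    every sample.  Returns (model, history dict of per-epoch loss terms).
    """
    weights = weights or PriorWeights()
    rng = np.random.default_rng(seed)
    model = KeypointNet(n_keypoints=n_keypoints, seed=seed)
    opt = AdamW(model.parameters(), lr=lr, weight_decay=1e-4)
    teacher = TeacherState([p.copy() for p in model.state()], ema_decay)
    history = {"supervised": [], "prior": [], "consistency": []}
    annotated_mask = np.asarray(annotated_mask, dtype=bool)

    for _ in range(epochs):
        order = rng.permutation(len(samples))
        sums = {"supervised": 0.0, "prior": 0.0, "consistency": 0.0}
        for i in order:
            s = samples[i]
            model.zero_grad()
            loss = Tensor(0.0)
            decoded, _, _ = model.decode(s.image)
            n = s.landmarks.n_vertebrae
            if annotated_mask[i]:
                sup = supervised_keypoint_loss(decoded[np.arange(n)], s.landmarks.centroids)
                loss = loss + sup
                sums["supervised"] += sup.item()
            if use_priors:
                pri = prior_losses(decoded[np.arange(n)], weights)["total"] * prior_scale
                loss = loss + pri
                sums["prior"] += pri.item()
            if use_consistency:
                weak, _ = _augment(s.image, rng, strong=False)
                strong, record = _augment(s.image, rng, strong=True)
                tmodel = KeypointNet(n_keypoints=n_keypoints, seed=seed)
                tmodel.load_state(teacher.params)
                tmaps = tmodel.heatmaps(weak).data
                tmaps = tmaps - tmaps.min(axis=(1, 2), keepdims=True)
                aligned = _align_teacher_maps(tmaps, record)
                vis = np.array([
                    float(ndimage.uniform_filter(
                        np.exp(m - m.max()) / np.exp(m - m.max()).sum(),
                        size=5, mode="constant").max() * 25.0)
                    for m in tmaps
                ])
                gate = vis > 0.5
                smaps = model.heatmaps(strong)
                cons = consistency_loss(smaps.relu(), aligned, gate) * 100.0
                loss = loss + cons
                sums["consistency"] += cons.item()
            if loss.requires_grad:
                loss.backward()
                opt.step()
            teacher = ema_update(teacher, model.parameters())
        for k in history:
            history[k].append(sums[k] / len(samples))
    return model, history
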