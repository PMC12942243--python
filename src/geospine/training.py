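"""Multi-objective training of the spine-graph classifier, plus ablations.

The training objective is a weighted sum of six terms:

    L = λ1·Lcls + λ2·Lreg + λ3·Lgeom + λ4·Lconcept + λ5·LNS + λ6·LCF

Lcls   class-weighted cross-entropy over the six diagnostic categories,
Lreg   MSE between the regression head and the (normalized) geometry-index
       summary of each image,
Lgeom  the spacing-smoothness + symmetry geometric priors evaluated on the
       landmark chain (recorded for monitoring; it drives learning only when
       a keypoint model is trained jointly, since here landmarks are inputs),
Lconcept  supervised-contrastive alignment of pooled embeddings with concept
       tiers derived from binned slip/curvature severity,
LNS    the relaxed log-barrier over monotonicity-constraint slopes estimated
       by counterfactual landmark edits,
LCF    a hinge on counterfactual logit shifts: edits that should raise a
       class logit must not lower it.

Optimization is AdamW with linear warm-up and cosine decay, early stopping on
validation loss.  ``run_ablation`` trains the full model and the four
standard ablation variants (w/o geometry indices, w/o symbolic constraints,
w/o counterfactual consistency, CNN baseline only) under identical splits.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _autograd as ag
from ._autograd import Tensor
from .constraints import (BarrierConfig, Constraint, DEFAULT_CONSTRAINTS,
                          PHANTOM_CONSTRAINTS, log_barrier)
from .counterfactual import CounterfactualEdit, EditCapError, edit_landmarks
from .geometry import compute_all_indices
from .keypoints import PriorWeights, prior_losses
from .metrics import agreement_metrics, classification_metrics
from .nn import AdamW, Linear, MLP, Module, warmup_cosine_lr
from .phantom import CLASSES, rasterize
from .spine_graph import (INDEX_SCALE, ImageEncoder, SpineGraphModel,
                          TransformerConfig, build_graph)

logger = logging.getLogger(__name__)

__all__ = [
    "LossWeights",
    "TrainConfig",
    "total_loss",
    "concept_alignment_loss",
    "concept_tiers",
    "counterfactual_consistency_loss",
    "train",
    "evaluate",
    "run_ablation",
    "predict_fn_factory",
    "ABLATION_VARIANTS",
]


@dataclass
class LossWeights:
    """Weights λ1..λ6 of the six loss terms (clinical-scale defaults)."""

    cls: float = 1.0
    reg: float = 0.5
    geom: float = 0.3
    concept: float = 0.3
    ns: float = 0.2
    cf: float = 0.2

    def __post_init__(self):
        if min(self.cls, self.reg, self.geom, self.concept, self.ns, self.cf) < 0:
            raise ValueError("loss weights must be >= 0")

    def as_dict(self) -> dict:
        return {"cls": self.cls, "reg": self.reg, "geom": self.geom,
                "concept": self.concept, "ns": self.ns, "cf": self.cf}


@dataclass
class TrainConfig:
    """Optimizer, schedule and ablation switches for one training run."""

    lr: float = 2e-2
    weight_decay: float = 1e-2
    warmup_epochs: int = 2
    epochs: int = 25
    batch_size: int = 32
    patience: int = 20
    val_fraction: float = 0.15
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    barrier: BarrierConfig = field(default_factory=BarrierConfig)
    constraints: tuple = PHANTOM_CONSTRAINTS
    n_constraint_samples: int = 24
    cf_step: float = 0.08
    disable_geometry: bool = False
    disable_constraints: bool = False
    disable_counterfactual: bool = False
    cnn_only: bool = False

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be > 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def total_loss(components: dict, weights: LossWeights):
    """Σ λi·Li over the six named components; errors on NaN naming the term."""
    wd = weights.as_dict()
    out = None
    for name, w in wd.items():
        c = components[name]
        val = c.item() if isinstance(c, Tensor) else float(c)
        if not np.isfinite(val):
            raise ValueError(f"loss component {name!r} is not finite ({val})")
        term = c * w if isinstance(c, Tensor) else Tensor(float(c) * w)
        out = term if out is None else out + term
    return out


def concept_tiers(index_summaries: np.ndarray) -> np.ndarray:
    """Concept tier labels from binned severity: slip {<0.25, 0.25–0.5, >=0.5}
    crossed with Cobb {<10°, 10–25°, >=25°} (9 tiers)."""
    s = np.asarray(index_summaries)
    slip_bin = np.digitize(s[:, 0], [0.25, 0.5])
    cobb_bin = np.digitize(s[:, 3], [10.0, 25.0])
    return slip_bin * 3 + cobb_bin


def concept_alignment_loss(embeddings, tiers: np.ndarray, temperature: float = 0.1):
    """Supervised-contrastive loss over temperature-scaled cosine similarities.

    Same-tier pairs are attracted, cross-tier pairs repelled; batches with a
    single tier contribute 0 (warned).
    """
    z = ag.as_tensor(embeddings)
    tiers = np.asarray(tiers)
    n = z.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if len(np.unique(tiers)) < 2:
        logger.warning("concept_alignment_loss: single tier in batch; contributing 0")
        return Tensor(0.0)
    norm = ((z * z).sum(axis=-1, keepdims=True) + 1e-12) ** 0.5
    zn = z / norm
    sim = ag.matmul(zn, zn.transpose(1, 0)) * (1.0 / temperature)
    eye = np.eye(n, dtype=bool)
    sim = ag.where_mask(eye, Tensor(np.full((n, n), -1e30)), sim)
    logz = ag.logsumexp(sim, axis=-1, keepdims=True)
    logp = sim - logz
    pos = (tiers[:, None] == tiers[None, :]) & ~eye
    counts = pos.sum(axis=1)
    anchors = counts > 0
    if not anchors.any():
        return Tensor(0.0)
    masked = logp * Tensor(pos.astype(float))
    per_anchor = masked.sum(axis=-1)[np.nonzero(anchors)[0]] * Tensor(
        1.0 / counts[anchors].astype(float))
    return -(per_anchor.mean())


def counterfactual_consistency_loss(logits_before: Tensor, logits_after: Tensor,
                                    class_idx: np.ndarray, directions: np.ndarray):
    """Hinge on counterfactual logit shifts: mean max(0, −dir·(after − before)).

    Zero iff every edit moves its target-class logit in the required
    direction; linear in the size of each violation.
    """
    rows = np.arange(len(class_idx))
    lb = logits_before[rows, class_idx]
    la = logits_after[rows, class_idx]
    d = Tensor(np.asarray(directions, dtype=float))
    viol = (-(la - lb) * d).relu()
    return viol.mean()


# ---------------------------------------------------------------------------
# CNN-only baseline
# ---------------------------------------------------------------------------

class CnnOnlyModel(Module):
    """Global image encoder + linear heads; no graph, no geometry features."""

    def __init__(self, d_global: int = 32, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.encoder = ImageEncoder(out_dim=d_global, hidden=64, rng=rng)
        self.cls = Linear(d_global, len(CLASSES), rng)
        self.reg = Linear(d_global, 4, rng)
        self.use_index_features = False

    def forward_batch(self, batch: dict, return_pooled: bool = False):
        h = self.encoder(batch["global_feats"]).relu()
        out = (self.cls(h), self.reg(h))
        return (*out, h) if return_pooled else out

    def prepare_batch(self, images, graphs, index_summaries) -> dict:
        feats = np.stack([self.encoder.downsample(img) for img in images])
        return {"global_feats": feats}

    def predict_proba(self, images, graphs, index_summaries) -> np.ndarray:
        logits, _ = self.forward_batch(self.prepare_batch(images, graphs, index_summaries))
        return ag.softmax(logits, axis=-1).data


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _sample_features(samples):
    graphs = [build_graph(s.landmarks) for s in samples]
    summaries = np.stack([s.true_indices.summary() for s in samples])
    labels = np.array([CLASSES.index(s.class_label) for s in samples])
    return graphs, summaries, labels


def _geom_value(samples) -> float:
    """Spacing + symmetry priors on the landmark chains (monitoring value)."""
    w = PriorWeights(w_order=0.0, w_spacing=1.0, w_symmetry=1.0, w_curvature=0.0)
    vals = []
    for s in samples[:32]:
        pri = prior_losses(Tensor(s.landmarks.centroids), w)
        vals.append(pri["total"].item())
    return float(np.mean(vals)) if vals else 0.0


def _build_counterfactual_bank(samples, constraints, step, rng, n_subset):
    """Pre-rasterized (original, edited) pairs for the NS and CF terms.

    Pairs are drawn across all classes: the monotone rules are global (a
    rising index must raise the target-class probability on any spine), and
    cross-class coverage is what generalizes the constraint to held-out
    audits.
    """
    idx = rng.choice(len(samples), size=min(n_subset, len(samples)), replace=False)
    bank = []
    for i in idx:
        s = samples[i]
        for c in constraints:
            try:
                lm = edit_landmarks(s.landmarks, CounterfactualEdit(c.index_id, step))
                img = rasterize(lm, s.image.shape)
            except (ValueError, EditCapError) as e:
                logger.info("training counterfactual skipped (%s)", e)
                continue
            bank.append({
                "orig": s, "edited_image": img, "edited_landmarks": lm,
                "edited_summary": compute_all_indices(lm).summary(),
                "constraint": c,
            })
    return bank


def _class_prob_tensor(logits: Tensor, target: str):
    p = ag.softmax(logits, axis=-1)
    if target == "abnormal":
        return p[:, :3].sum(axis=-1)
    return p[:, CLASSES.index(target)]


def train(dataset, model_spec: dict | None = None, config: TrainConfig | None = None):
    """Train a spine-graph classifier on phantoms; returns (model, history).

    ``dataset`` is a list of PhantomSample.  ``model_spec`` sets the
    desk-scale architecture (d_local, d_global, n_heads, n_layers).  History
    records every loss component per epoch; training is deterministic for a
    fixed config seed and aborts on divergence.
    """
    config = config or TrainConfig()
    spec = {"d_local": 16, "d_global": 16, "n_heads": 4, "n_layers": 1}
    spec.update(model_spec or {})
    rng = np.random.default_rng(config.seed)

    # stratified train/val split
    labels_all = np.array([CLASSES.index(s.class_label) for s in dataset])
    val_idx = []
    for c in np.unique(labels_all):
        members = np.nonzero(labels_all == c)[0]
        k = max(1, int(round(config.val_fraction * len(members))))
        val_idx.extend(rng.choice(members, size=k, replace=False))
    val_mask = np.zeros(len(dataset), dtype=bool)
    val_mask[np.array(val_idx)] = True
    train_set = [s for s, m in zip(dataset, val_mask) if not m]
    val_set = [s for s, m in zip(dataset, val_mask) if m]

    if config.cnn_only:
        model = CnnOnlyModel(seed=config.seed)
    else:
        cfg = TransformerConfig(node_dim=spec["d_local"] + spec["d_global"],
                                n_heads=spec["n_heads"], n_layers=spec["n_layers"])
        model = SpineGraphModel(cfg, spec["d_local"], spec["d_global"], seed=config.seed,
                                use_index_features=not config.disable_geometry)
    opt = AdamW(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)

    graphs, summaries, labels = _sample_features(train_set)
    vgraphs, vsummaries, vlabels = _sample_features(val_set)
    tiers = concept_tiers(summaries)
    freq = np.bincount(labels, minlength=len(CLASSES)).astype(float)
    class_w = np.where(freq > 0, freq.sum() / np.maximum(freq, 1) / len(CLASSES), 0.0)

    w = config.weights
    use_ns = w.ns > 0 and not config.disable_constraints and not config.cnn_only
    use_cf = w.cf > 0 and not config.disable_counterfactual and not config.cnn_only
    bank = []
    if use_ns or use_cf:
        bank = _build_counterfactual_bank(train_set, config.constraints,
                                          config.cf_step, rng,
                                          config.n_constraint_samples)
    geom_value = _geom_value(train_set)

    n = len(train_set)
    steps_per_epoch = max(1, int(np.ceil(n / config.batch_size)))
    total_steps = steps_per_epoch * config.epochs
    warmup_steps = steps_per_epoch * config.warmup_epochs

    def weighted_ce(logits, y):
        logz = ag.logsumexp(logits, axis=-1, keepdims=True)
        logp = logits - logz
        rows = np.arange(len(y))
        nll = -(logp[rows, y])
        cw = class_w[y]
        return (nll * Tensor(cw)).sum() * (1.0 / cw.sum())

    def forward_loss(idx_batch):
        imgs = [train_set[i].image for i in idx_batch]
        gs = [graphs[i] for i in idx_batch]
        summ = summaries[idx_batch]
        y = labels[idx_batch]
        batch = model.prepare_batch(imgs, gs, summ)
        logits, reg, pooled = model.forward_batch(batch, return_pooled=True)
        comp = {}
        comp["cls"] = weighted_ce(logits, y)
        target = Tensor(summ / INDEX_SCALE)
        diff = reg - target
        comp["reg"] = (diff * diff).mean()
        comp["geom"] = Tensor(geom_value)
        comp["concept"] = (concept_alignment_loss(pooled, tiers[idx_batch])
                           if not config.cnn_only else Tensor(0.0))
        return comp, logits

    def ns_cf_terms():
        comp = {"ns": Tensor(0.0), "cf": Tensor(0.0)}
        if not bank:
            return comp
        imgs = [e["orig"].image for e in bank] + [e["edited_image"] for e in bank]
        gs = ([build_graph(e["orig"].landmarks) for e in bank]
              + [build_graph(e["edited_landmarks"]) for e in bank])
        summ = np.stack([e["orig"].true_indices.summary() for e in bank]
                        + [e["edited_summary"] for e in bank])
        batch = model.prepare_batch(imgs, gs, summ)
        logits, _ = model.forward_batch(batch)
        m = len(bank)
        before, after = logits[np.arange(m)], logits[np.arange(m, 2 * m)]
        if use_ns:
            gvals = []
            for k, e in enumerate(bank):
                c = e["constraint"]
                pb = _class_prob_tensor(before[k].reshape(1, -1), c.target_class)
                pa = _class_prob_tensor(after[k].reshape(1, -1), c.target_class)
                gvals.append(((pa - pb) * (c.direction / config.cf_step)).reshape(1))
            g = ag.concatenate(gvals)
            comp["ns"] = log_barrier(g, config.barrier) * (1.0 / len(bank))
        if use_cf:
            cls_idx, dirs = [], []
            for e in bank:
                c = e["constraint"]
                cls_idx.append(0 if c.target_class == "abnormal"
                               else CLASSES.index(c.target_class))
                dirs.append(c.direction)
            comp["cf"] = counterfactual_consistency_loss(
                before, after, np.array(cls_idx), np.array(dirs))
        return comp

    history = []
    best_val, best_state, since_best = np.inf, model.state(), 0
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        sizes = np.array([graphs[i].n_nodes for i in order])
        order = order[np.argsort(sizes, kind="stable")]  # bucket by graph size
        batches = [order[k:k + config.batch_size] for k in range(0, n, config.batch_size)]
        epoch_comp = {k: 0.0 for k in ("cls", "reg", "geom", "concept", "ns", "cf")}
        for bi, idx_batch in enumerate(batches):
            lr = warmup_cosine_lr(step, total_steps, config.lr, warmup_steps)
            comp, _ = forward_loss(idx_batch)
            if bi == 0:
                extra = ns_cf_terms()
            else:
                extra = {"ns": Tensor(0.0), "cf": Tensor(0.0)}
            comp.update(extra)
            loss = total_loss(comp, w)
            if loss.item() > 1e6:
                raise RuntimeError(f"training diverged at epoch {epoch} (loss {loss.item():.3g})")
            model.zero_grad()
            loss.backward()
            opt.step(lr=lr)
            step += 1
            for k in epoch_comp:
                epoch_comp[k] += comp[k].item() if isinstance(comp[k], Tensor) else float(comp[k])
        for k in epoch_comp:
            epoch_comp[k] /= len(batches)
        # effective contribution of switched-off terms is exactly 0
        if not use_ns:
            epoch_comp["ns"] = 0.0
        if not use_cf:
            epoch_comp["cf"] = 0.0

        vloss = _validation_loss(model, val_set, vgraphs, vsummaries, vlabels,
                                 class_w, w, geom_value, config)
        row = {"epoch": epoch, "lr": warmup_cosine_lr(step - 1, total_steps, config.lr,
                                                      warmup_steps),
               "val_loss": vloss}
        row.update({f"loss_{k}": v for k, v in epoch_comp.items()})
        history.append(row)
        if vloss < best_val - 1e-9:
            best_val, best_state, since_best = vloss, model.state(), 0
        else:
            since_best += 1
            if since_best >= config.patience:
                logger.info("early stopping at epoch %d", epoch)
                break
    model.load_state(best_state)
    return model, pd.DataFrame(history)


def _validation_loss(model, val_set, graphs, summaries, labels, class_w, w,
                     geom_value, config) -> float:
    if not val_set:
        return 0.0
    batch = model.prepare_batch([s.image for s in val_set], graphs, summaries)
    logits, reg = model.forward_batch(batch)
    logz = ag.logsumexp(logits, axis=-1, keepdims=True)
    logp = (logits - logz).data
    rows = np.arange(len(labels))
    cw = class_w[labels]
    ce = float((-logp[rows, labels] * cw).sum() / cw.sum())
    mse = float(((reg.data - summaries / INDEX_SCALE) ** 2).mean())
    return w.cls * ce + w.reg * mse + w.geom * geom_value


def evaluate(model, samples) -> dict:
    """Classification metrics plus per-index agreement of the regression head."""
    graphs, summaries, labels = _sample_features(samples)
    probs = model.predict_proba([s.image for s in samples], graphs, summaries)
    out = classification_metrics(labels, probs)
    batch = model.prepare_batch([s.image for s in samples], graphs, summaries)
    _, reg = model.forward_batch(batch)
    pred = reg.data * INDEX_SCALE
    names = ("slip_ratio", "disc_asymmetry", "si_symmetry", "cobb_angle")
    out["agreement"] = {
        name: agreement_metrics(pred[:, k], summaries[:, k]) for k, name in enumerate(names)
    }
    return out


def predict_fn_factory(model):
    """(image, landmarks) -> class probabilities, recomputing geometry features."""

    def predict_fn(image, landmarks):
        graph = build_graph(landmarks)
        summary = compute_all_indices(landmarks).summary()
        return model.predict_proba([image], [graph], summary[None])[0]

    return predict_fn


ABLATION_VARIANTS = ("full", "wo_geometry", "wo_constraints", "wo_counterfactual", "cnn_only")


def run_ablation(train_samples, test_samples, config: TrainConfig | None = None,
                 model_spec: dict | None = None, trained_full=None,
                 return_models: bool = False):
    """Train the full model and the four standard variants on identical splits.

    Returns a table with one row per variant (accuracy, macro-F1, AUROC and
    the shared test-split hash); with ``return_models`` also a dict of the
    trained variant models.  A variant failure is recorded without aborting
    the others.  ``trained_full`` optionally reuses an already trained full
    model for the "full" row.
    """
    config = config or TrainConfig()
    split_hash = hashlib.sha256(
        ("|".join(s.sample_id for s in test_samples)).encode()).hexdigest()[:12]
    switches = {
        "full": {},
        "wo_geometry": {"disable_geometry": True},
        "wo_constraints": {"disable_constraints": True},
        "wo_counterfactual": {"disable_counterfactual": True},
        "cnn_only": {"cnn_only": True},
    }
    rows, models = [], {}
    for variant in ABLATION_VARIANTS:
        try:
            if variant == "full" and trained_full is not None:
                model = trained_full
            else:
                model, _ = train(train_samples, model_spec,
                                 replace(config, **switches[variant]))
            models[variant] = model
            m = evaluate(model, test_samples)
            rows.append({"variant": variant, "accuracy": m["accuracy"],
                         "macro_f1": m["macro_f1"], "auroc": m["auroc"],
                         "test_split_hash": split_hash, "error": ""})
        except Exception as e:  # record failure, continue others
            logger.exception("ablation variant %s failed", variant)
            rows.append({"variant": variant, "accuracy": np.nan, "macro_f1": np.nan,
                         "auroc": np.nan, "test_split_hash": split_hash, "error": str(e)})
    table = pd.DataFrame(rows)
    return (table, models) if return_models else table
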