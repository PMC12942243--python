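"""Neuro-symbolic monotonicity constraints with a log-barrier penalty.

Clinical priors of the form "probability of diagnosis D rises with geometry
index g" are encoded as inequality constraints g_j >= 0, where g_j is the
directional finite-difference slope of the model's target-class probability
under a landmark-space counterfactual edit of the index.  Violations are
penalized with a relaxed log-barrier

    L = -mu * sum_j log(g_j)            for g_j >= delta,

continued below ``delta`` by its second-order Taylor expansion so the penalty
stays finite, strongly increasing for violated constraints, and C^1 at the
junction.

``directional_consistency`` is the corresponding audit metric: the fraction
of samples whose target-class probability strictly increases when the index
is increased by a fixed step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import _autograd as ag
from ._autograd import Tensor
from .counterfactual import CounterfactualEdit, EditCapError, class_probability, edit_landmarks
from .phantom import CLASSES, rasterize

logger = logging.getLogger(__name__)

__all__ = [
    "Constraint",
    "BarrierConfig",
    "DEFAULT_CONSTRAINTS",
    "evaluate_constraint",
    "log_barrier",
    "directional_consistency",
    "load_constraints",
    "save_constraints",
]

_INDEX_IDS = ("slip_ratio", "disc_asymmetry", "si_symmetry", "cobb_angle")


@dataclass
class Constraint:
    """One monotonicity rule: direction * d P(target_class) / d index >= 0."""

    name: str
    index_id: str
    target_class: str
    direction: int = 1

    def __post_init__(self):
        if self.index_id not in _INDEX_IDS:
            raise ValueError(f"unknown index_id {self.index_id!r}")
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")
        if self.target_class not in CLASSES and self.target_class != "abnormal":
            raise ValueError(f"unknown target class {self.target_class!r}")


#: the three canonical clinical index->diagnosis relations.  The six-class
#: scheme has no dedicated curvature-abnormality class, so the Cobb rule
#: targets the pooled pathology ("abnormal") probability.
DEFAULT_CONSTRAINTS = (
    Constraint("slip_to_spondylolisthesis", "slip_ratio", "spondylolisthesis", 1),
    Constraint("si_to_spondyloarthropathy", "si_symmetry", "spondyloarthropathy", 1),
    Constraint("cobb_to_abnormal", "cobb_angle", "abnormal", 1),
)

#: constraints that hold in the synthetic phantom domain, used as the training
#: default: on phantoms the high-curvature spines are the normal thoracic and
#: cervical regions, so the clinical Cobb->abnormal rule is false there and
#: enforcing it would regularize the model toward a relation the data
#: contradicts.
PHANTOM_CONSTRAINTS = DEFAULT_CONSTRAINTS[:2]


@dataclass
class BarrierConfig:
    """Log-barrier parameters.

    mu          : barrier strength (> 0)
    relax_delta : junction below which the quadratic extension replaces -log
    fd_step     : finite-difference step (index units) for slope estimation
    """

    mu: float = 1.0
    relax_delta: float = 0.05
    fd_step: float = 0.02

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if not (0 < self.relax_delta < 1):
            raise ValueError("relax_delta must lie in (0, 1)")
        if self.fd_step <= 0:
            raise ValueError("fd_step must be > 0")


def evaluate_constraint(constraint: Constraint, predict_fn, sample_,
                        cfg: BarrierConfig | None = None) -> float:
    """Directional finite-difference slope g of the target-class probability.

    g = direction * [f(edit(sample, +step)) - f(sample)] / step, where the
    edit is a landmark-space counterfactual of the constraint's index and f
    the target-class probability.  Positive g = constraint satisfied.  If the
    step is infeasible (cap or geometry), it is halved once before failing.
    """
    cfg = cfg or BarrierConfig()
    image_size = sample_.image.shape
    step = cfg.fd_step
    base = class_probability(predict_fn(sample_.image, sample_.landmarks),
                             constraint.target_class)
    for attempt in range(2):
        try:
            lm = edit_landmarks(sample_.landmarks,
                                CounterfactualEdit(constraint.index_id, step))
            img = rasterize(lm, image_size)
            bumped = class_probability(predict_fn(img, lm), constraint.target_class)
            return constraint.direction * (bumped - base) / step
        except (ValueError, EditCapError) as e:
            if attempt == 0:
                logger.info("constraint %s: step %.3f infeasible (%s); halving",
                            constraint.name, step, e)
                step /= 2.0
            else:
                raise ValueError(
                    f"constraint {constraint.name}: edit infeasible even after "
                    f"halving the step ({e})"
                ) from e


def log_barrier(g_values, cfg: BarrierConfig | None = None):
    """Relaxed log-barrier penalty of the constraint slopes.

    For g >= delta the exact -mu*log(g); below delta the C^1 quadratic
    continuation -mu*[log(delta) + (g-delta)/delta - (g-delta)^2/(2 delta^2)],
    which keeps violated constraints (g <= 0) finite and strongly penalized.
    Accepts numpy arrays (reported values) or tensors (training path).
    """
    cfg = cfg or BarrierConfig()
    mu, d = cfg.mu, cfg.relax_delta
    if isinstance(g_values, Tensor):
        g = g_values
        mask = g.data >= d
        safe = ag.where_mask(mask, g, Tensor(np.full(g.data.shape, d)))
        exact = safe.log() * (-mu)
        u = g - d
        ext = (Tensor(np.full(g.data.shape, math.log(d))) + u * (1.0 / d)
               - (u * u) * (1.0 / (2 * d * d))) * (-mu)
        return ag.where_mask(mask, exact, ext).sum()
    g = np.asarray(g_values, dtype=float)
    if np.any(~np.isfinite(g)):
        raise ValueError("constraint values must be finite")
    out = np.empty_like(g)
    hi = g >= d
    out[hi] = -mu * np.log(g[hi])
    u = g[~hi] - d
    out[~hi] = -mu * (math.log(d) + u / d - u ** 2 / (2 * d * d))
    return float(out.sum())


def directional_consistency(predict_fn, index_id: str, target_class: str,
                            samples, step: float = 0.05) -> float:
    """Fraction of samples whose target-class probability strictly rises when
    the index is increased by ``step`` via a landmark edit."""
    if len(samples) == 0:
        raise ValueError("need at least one sample")
    hits, used = 0, 0
    for s in samples:
        try:
            lm = edit_landmarks(s.landmarks, CounterfactualEdit(index_id, step))
            img = rasterize(lm, s.image.shape)
        except (ValueError, EditCapError) as e:
            logger.info("directional_consistency: sample skipped (%s)", e)
            continue
        p0 = class_probability(predict_fn(s.image, s.landmarks), target_class)
        p1 = class_probability(predict_fn(img, lm), target_class)
        hits += int(p1 > p0)
        used += 1
    if used == 0:
        raise ValueError("all edits infeasible; cannot measure consistency")
    return hits / used


# ---------------------------------------------------------------------------
# YAML registry
# ---------------------------------------------------------------------------

def save_constraints(constraints, path):
    payload = [{"name": c.name, "index": c.index_id, "class": c.target_class,
                "direction": c.direction} for c in constraints]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_constraints(path) -> list[Constraint]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return [Constraint(e["name"], e["index"], e["class"], int(e.get("direction", 1)))
            for e in payload]
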