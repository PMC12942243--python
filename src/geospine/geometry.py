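"""Differentiable radiographic geometry: the four clinical spine indices.

Given an ordered chain of vertebral centroids (superior to inferior, pixel
coordinates, origin top-left, y increasing downward) with per-vertebra widths,
per-disc left/right heights and sacroiliac left/right distances, this module
computes

* slip ratio per level  — |x_i − x_{i−1}| / w_i  (anterolisthesis proxy,
  normalized by the width of the lower vertebra of the pair),
* disc-height asymmetry per disc — |h_left − h_right| / mean height,
* sacroiliac spacing symmetry — |d_left − d_right| (pixels),
* a Cobb-like curvature angle — the angle between tangents of a least-squares
  polynomial fit x(y) through the centroids, evaluated at chosen end levels.

Every index is implemented twice through one code path: on plain numpy arrays
the exact formulas are used (reported values), on autodiff tensors smooth
surrogates replace |·| and the arccos argument is clamped away from ±1 so the
whole pipeline carries usable gradients.  ``gradient_check`` verifies the
analytic gradients against central finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor

__all__ = [
    "LandmarkSet",
    "GeometryIndices",
    "EdgeAttributes",
    "SmoothingConfig",
    "slip_ratio",
    "disc_asymmetry",
    "si_symmetry",
    "cobb_angle",
    "compute_all_indices",
    "edge_attributes",
    "gradient_check",
]


@dataclass
class SmoothingConfig:
    """Numerical-smoothness knobs for the differentiable pipeline.

    abs_epsilon : ε of the |u| ≈ sqrt(u²+ε²)−ε surrogate (0 ⇒ exact |u|).
    acos_clamp  : margin keeping the arccos argument away from ±1 so its
                  gradient stays finite.
    spline_degree : degree of the least-squares centroid fit x(y).
    """

    abs_epsilon: float = 1e-6
    acos_clamp: float = 1e-7
    spline_degree: int = 3

    def __post_init__(self):
        if self.abs_epsilon < 0:
            raise ValueError("abs_epsilon must be >= 0")
        if not (0 < self.acos_clamp < 1e-3):
            raise ValueError("acos_clamp must lie in (0, 1e-3)")


@dataclass
class LandmarkSet:
    """Ordered spine landmarks for one radiograph.

    centroids : (N, 2) array of (x, y) pixel coordinates, strictly increasing y.
    widths : (N,) vertebral widths in pixels, > 0.
    disc_heights : (N-1, 2) left/right disc heights in pixels, >= 0.
    si_distances : (2,) left/right sacrum-to-ilium distances in pixels.
    visibility : (N,) per-landmark confidence in [0, 1].
    """

    centroids: np.ndarray
    widths: np.ndarray
    disc_heights: np.ndarray
    si_distances: np.ndarray
    visibility: np.ndarray = None

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        self.widths = np.asarray(self.widths, dtype=float).reshape(-1)
        self.disc_heights = np.asarray(self.disc_heights, dtype=float).reshape(-1, 2)
        self.si_distances = np.asarray(self.si_distances, dtype=float).reshape(2)
        n = len(self.centroids)
        if self.visibility is None:
            self.visibility = np.ones(n)
        self.visibility = np.asarray(self.visibility, dtype=float).reshape(-1)
        if len(self.widths) != n or len(self.visibility) != n:
            raise ValueError("widths/visibility length must match number of vertebrae")
        if n > 0 and len(self.disc_heights) != n - 1:
            raise ValueError(f"expected {n - 1} discs for {n} vertebrae, got {len(self.disc_heights)}")
        if n > 1 and not np.all(np.diff(self.centroids[:, 1]) > 0):
            raise ValueError("centroid y-coordinates must be strictly increasing (superior to inferior)")
        if np.any(self.widths <= 0):
            raise ValueError("vertebral widths must be positive")
        if np.any(self.disc_heights < 0):
            raise ValueError("disc heights must be non-negative")

    @property
    def n_vertebrae(self) -> int:
        return len(self.centroids)

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(
            self.centroids.copy(), self.widths.copy(), self.disc_heights.copy(),
            self.si_distances.copy(), self.visibility.copy(),
        )


@dataclass
class GeometryIndices:
    """The four clinical indices of one radiograph."""

    slip_ratio: np.ndarray      # (N-1,) level i value = |x_i - x_{i-1}| / w_i
    disc_asymmetry: np.ndarray  # (N-1,)
    si_symmetry: float          # pixels
    cobb_angle: float           # degrees in [0, 180]

    def summary(self) -> np.ndarray:
        """Per-image 4-vector: (max slip, max disc asymmetry, SI, Cobb)."""
        smax = float(np.max(self.slip_ratio)) if len(self.slip_ratio) else 0.0
        amax = float(np.max(self.disc_asymmetry)) if len(self.disc_asymmetry) else 0.0
        return np.array([smax, amax, self.si_symmetry, self.cobb_angle])

    def as_dict(self) -> dict:
        return {
            "slip_ratio": [float(v) for v in self.slip_ratio],
            "disc_asymmetry": [float(v) for v in self.disc_asymmetry],
            "si_symmetry": float(self.si_symmetry),
            "cobb_angle": float(self.cobb_angle),
        }


@dataclass
class EdgeAttributes:
    """Geometric attributes of one spine-graph edge."""

    distance: float     # ‖p_i − p_j‖₂, pixels
    orientation: float  # atan2(Δy, Δx) ∈ (−π, π], radians, y-down frame
    curvature: float    # 1/pixels, 0 at chain ends

    def as_array(self) -> np.ndarray:
        return np.array([self.distance, self.orientation, self.curvature])


def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _abs(u, eps: float):
    if isinstance(u, Tensor):
        return ag.smooth_abs(u, eps)
    return np.abs(u)


# ---------------------------------------------------------------------------
# the four indices
# ---------------------------------------------------------------------------

def slip_ratio(landmarks: LandmarkSet = None, *, x=None, widths=None,
               cfg: SmoothingConfig | None = None):
    """Per-level slip ratio |x_i − x_{i−1}| / w_i for levels i = 2..N.

    Accepts either a LandmarkSet (exact numpy path) or raw ``x``/``widths``
    vectors which may be autodiff tensors (smooth path).
    """
    cfg = cfg or SmoothingConfig()
    if landmarks is not None:
        x = landmarks.centroids[:, 0]
        widths = landmarks.widths
    n = len(x.data) if isinstance(x, Tensor) else len(x)
    if n < 2:
        return np.zeros(0) if not _is_tensor(x) else Tensor(np.zeros(0))
    wlow = widths[1:]
    wcheck = wlow.data if isinstance(wlow, Tensor) else np.asarray(wlow)
    if np.any(wcheck == 0):
        raise ValueError("zero vertebral width in slip-ratio denominator")
    dx = x[1:] - x[:-1]
    eps = cfg.abs_epsilon if _is_tensor(x) else 0.0
    return _abs(dx, eps) / wlow


def disc_asymmetry(landmarks: LandmarkSet = None, *, heights=None,
                   cfg: SmoothingConfig | None = None):
    """Per-disc |h_left − h_right| / mean(h_left, h_right)."""
    cfg = cfg or SmoothingConfig()
    if landmarks is not None:
        heights = landmarks.disc_heights
    h = heights
    hdata = h.data if isinstance(h, Tensor) else np.asarray(h)
    if hdata.shape[0] == 0:
        return np.zeros(0) if not _is_tensor(h) else Tensor(np.zeros(0))
    mean = (hdata[:, 0] + hdata[:, 1]) / 2.0
    bad = np.nonzero(mean == 0)[0]
    if len(bad):
        raise ValueError(f"disc {int(bad[0])} has zero mean height (division by zero)")
    hl, hr = h[:, 0], h[:, 1]
    eps = cfg.abs_epsilon if _is_tensor(h) else 0.0
    return _abs(hl - hr, eps) / ((hl + hr) * 0.5)


def si_symmetry(landmarks: LandmarkSet = None, *, distances=None,
                cfg: SmoothingConfig | None = None):
    """|d_left − d_right| of the sacroiliac distances, in input length units."""
    cfg = cfg or SmoothingConfig()
    if landmarks is not None:
        distances = landmarks.si_distances
    d = distances
    ddata = d.data if isinstance(d, Tensor) else np.asarray(d)
    if ddata.shape[-1] != 2 or np.any(~np.isfinite(ddata)):
        raise ValueError("both SI distances must be present and finite")
    eps = cfg.abs_epsilon if _is_tensor(d) else 0.0
    out = _abs(d[0] - d[1], eps)
    return out if isinstance(out, Tensor) else float(out)


def _polyfit_tangents(x, y, end_levels, degree: int, clamp: float):
    """LS polynomial fit x(t), t = normalized y; returns slopes dx/dy at the ends."""
    tensor = _is_tensor(x, y)
    n = len(x.data) if isinstance(x, Tensor) else len(x)
    deg = min(degree, n - 1)
    i0, i1 = end_levels
    # differentiable normalization of y for conditioning
    mid = (y[i0] + y[i1]) * 0.5
    half = (y[i1] - y[i0]) * 0.5
    t = (y - mid) / half
    if tensor:
        cols = [Tensor(np.ones(n))] + [t ** k for k in range(1, deg + 1)]
        V = ag.stack(cols, axis=1)
        G = ag.matmul(V.transpose(1, 0), V)
        b = ag.matmul(V.transpose(1, 0), x)
        coeffs = ag.solve(G, b)
        slopes = []
        for i in (i0, i1):
            ti = t[i]
            s = Tensor(np.zeros(()))
            for k in range(1, deg + 1):
                s = s + coeffs[k] * float(k) * ti ** (k - 1)
            slopes.append(s / half)
    else:
        V = np.vander(t, deg + 1, increasing=True)
        coeffs, *_ = np.linalg.lstsq(V, x, rcond=None)
        slopes = []
        for i in (i0, i1):
            s = sum(coeffs[k] * k * t[i] ** (k - 1) for k in range(1, deg + 1))
            slopes.append(s / half)
    return slopes


def cobb_angle(landmarks: LandmarkSet = None, end_levels=None,
               cfg: SmoothingConfig | None = None, *, x=None, y=None):
    """Cobb-like angle (degrees) between end-level tangents of the centroid fit.

    The centroid chain is fit with a least-squares polynomial x(y) (a linear
    solve, hence differentiable); tangent vectors v = (dx/dy, 1) at the two end
    levels give  θ = arccos(v_u·v_l / ‖v_u‖‖v_l‖).  On the exact (numpy) path
    the arccos argument is clipped to [−1, 1]; on the tensor path it is clamped
    inside (−1, 1) so the gradient stays finite.
    """
    cfg = cfg or SmoothingConfig()
    if landmarks is not None:
        x = landmarks.centroids[:, 0]
        y = landmarks.centroids[:, 1]
    n = len(x.data) if isinstance(x, Tensor) else len(x)
    if n < 3:
        raise ValueError("Cobb angle needs at least 3 vertebrae")
    if end_levels is None:
        end_levels = (0, n - 1)
    i0, i1 = end_levels
    if not (0 <= i0 < n and 0 <= i1 < n and i0 != i1):
        raise ValueError(f"invalid end levels {end_levels} for chain of {n}")
    su, sl = _polyfit_tangents(x, y, (i0, i1), cfg.spline_degree, cfg.acos_clamp)
    if _is_tensor(x, y):
        dot = su * sl + 1.0
        norm = ((su * su + 1.0) * (sl * sl + 1.0)).sqrt()
        cosv = dot / norm
        theta = ag.arccos_clamped(cosv, cfg.acos_clamp)
        return theta * (180.0 / np.pi)
    dot = su * sl + 1.0
    norm = np.sqrt((su ** 2 + 1.0) * (sl ** 2 + 1.0))
    if norm == 0:
        raise ValueError("degenerate zero-length tangent")
    cosv = np.clip(dot / norm, -1.0, 1.0)
    return float(np.degrees(np.arccos(cosv)))


def compute_all_indices(landmarks: LandmarkSet,
                        cfg: SmoothingConfig | None = None) -> GeometryIndices:
    """Bundle the four indices (exact numpy path). Pure function of landmarks.

    Cobb is reported as 0 for chains with fewer than 3 vertebrae (no curvature
    is measurable).
    """
    cfg = cfg or SmoothingConfig()
    try:
        slips = np.asarray(slip_ratio(landmarks, cfg=cfg))
    except ValueError as e:
        raise ValueError(f"slip_ratio: {e}") from e
    try:
        asym = np.asarray(disc_asymmetry(landmarks, cfg=cfg))
    except ValueError as e:
        raise ValueError(f"disc_asymmetry: {e}") from e
    si = si_symmetry(landmarks, cfg=cfg)
    cobb = cobb_angle(landmarks, cfg=cfg) if landmarks.n_vertebrae >= 3 else 0.0
    return GeometryIndices(slips, asym, float(si), float(cobb))


# ---------------------------------------------------------------------------
# edge attributes (spine-graph geometry)
# ---------------------------------------------------------------------------

def _menger_curvature(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Reciprocal circumradius of the triangle (a, b, c); 0 for collinear points."""
    ab, bc, ac = b - a, c - b, c - a
    cross = ab[0] * bc[1] - ab[1] * bc[0]
    denom = np.linalg.norm(ab) * np.linalg.norm(bc) * np.linalg.norm(ac)
    if denom == 0:
        return 0.0
    return float(2.0 * abs(cross) / denom)


def edge_attributes(p_i, p_j, chain: np.ndarray | None = None,
                    edge: tuple[int, int] | None = None) -> EdgeAttributes:
    """Distance, orientation and local curvature for the edge (p_i, p_j).

    ``chain`` is the ordered (M, 2) array of node positions the edge belongs
    to and ``edge`` the node indices; curvature is the mean second-order
    (Menger) curvature at the edge's interior endpoints, 0 where an endpoint
    is a chain end.  Coincident points get distance 0 and, by convention,
    orientation 0.
    """
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    d = p_j - p_i
    dist = float(np.linalg.norm(d))
    orientation = 0.0 if dist == 0 else float(np.arctan2(d[1], d[0]))
    curvature = 0.0
    if chain is not None and edge is not None:
        chain = np.asarray(chain, dtype=float)
        m = len(chain)
        vals = []
        for k in edge:
            if 1 <= k <= m - 2:
                vals.append(_menger_curvature(chain[k - 1], chain[k], chain[k + 1]))
        if vals:
            curvature = float(np.mean(vals))
    return EdgeAttributes(dist, orientation, curvature)


# ---------------------------------------------------------------------------
# gradient verification harness
# ---------------------------------------------------------------------------

_INDEX_OPS = ("slip_ratio", "disc_asymmetry", "si_symmetry", "cobb_angle")


def _op_scalar(op: str, cx: Tensor, cy: Tensor, heights: Tensor, si: Tensor,
               widths: np.ndarray, cfg: SmoothingConfig) -> Tensor:
    if op == "slip_ratio":
        return slip_ratio(x=cx, widths=Tensor(widths), cfg=cfg).sum()
    if op == "disc_asymmetry":
        return disc_asymmetry(heights=heights, cfg=cfg).sum()
    if op == "si_symmetry":
        v = si_symmetry(distances=si, cfg=cfg)
        # make it depend (trivially, with zero gradient) on the centroids so the
        # harness can assert functional independence
        return v + (cx.sum() + cy.sum()) * 0.0
    if op == "cobb_angle":
        return cobb_angle(x=cx, y=cy, cfg=cfg)
    raise ValueError(f"unknown index op {op!r}; expected one of {_INDEX_OPS}")


def gradient_check(index_op: str, landmarks: LandmarkSet,
                   cfg: SmoothingConfig | None = None, fd_step: float = 1e-4) -> float:
    """Max relative error between autodiff and central-FD gradients of one index.

    The scalar under test is the sum of the index's values; gradients are taken
    w.r.t. every centroid coordinate, disc height and SI distance.  Both sides
    evaluate the *smooth* (tensor) pipeline so the comparison is exact up to
    finite-difference truncation.  Relative error uses |a − f| / (|a| + |f| + 1e-8).
    """
    cfg = cfg or SmoothingConfig()
    base = {
        "cx": landmarks.centroids[:, 0].copy(),
        "cy": landmarks.centroids[:, 1].copy(),
        "heights": landmarks.disc_heights.copy(),
        "si": landmarks.si_distances.copy(),
    }
    widths = landmarks.widths

    def evaluate(vals, want_grads=False):
        cx = Tensor(vals["cx"], requires_grad=want_grads)
        cy = Tensor(vals["cy"], requires_grad=want_grads)
        heights = Tensor(vals["heights"], requires_grad=want_grads)
        si = Tensor(vals["si"], requires_grad=want_grads)
        out = _op_scalar(index_op, cx, cy, heights, si, widths, cfg)
        if not want_grads:
            return float(out.data)
        out.backward()
        grads = {
            "cx": np.zeros_like(vals["cx"]) if cx.grad is None else cx.grad,
            "cy": np.zeros_like(vals["cy"]) if cy.grad is None else cy.grad,
            "heights": np.zeros_like(vals["heights"]) if heights.grad is None else heights.grad,
            "si": np.zeros_like(vals["si"]) if si.grad is None else si.grad,
        }
        return float(out.data), grads

    _, analytic = evaluate(base, want_grads=True)
    max_err = 0.0
    for key in base:
        flat = base[key].reshape(-1)
        for i in range(flat.size):
            pert = {k: v.copy() for k, v in base.items()}
            pert[key].reshape(-1)[i] = flat[i] + fd_step
            up = evaluate(pert)
            pert[key].reshape(-1)[i] = flat[i] - fd_step
            down = evaluate(pert)
            fd = (up - down) / (2.0 * fd_step)
            a = analytic[key].reshape(-1)[i]
            if not (np.isfinite(fd) and np.isfinite(a)):
                return float("nan")
            err = abs(a - fd) / (abs(a) + abs(fd) + 1e-8)
            max_err = max(max_err, err)
    return max_err
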