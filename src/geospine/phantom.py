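"""Synthetic spine phantoms with exactly controllable geometry indices.

A phantom is an ordered chain of vertebral bodies along a curved spine axis,
rendered into a grayscale pseudo-radiograph.  The generator *inverts* the four
geometry indices: given requested per-level slip ratios, per-disc asymmetries,
a sacroiliac spacing difference and a Cobb-like angle, it constructs landmarks
whose recomputed indices equal the request exactly (jitter 0).

Construction sketch
-------------------
* Horizontal steps Δx_i = σ_i · s_i · w_i realize the slip targets for any
  sign pattern σ; a C-shaped pattern (signs flip mid-chain) is used when a
  nonzero Cobb angle is requested.
* With x fixed, the fitted-tangent Cobb angle is a function of the vertical
  scale c of the chain alone (the least-squares polynomial fit is invariant
  under reparameterization, so end slopes scale as 1/c).  The requested angle
  therefore reduces to a quadratic equation in c, solved in closed form; a
  bracketing root-finder is the fallback for unusual slope patterns.
* Uniform rescaling of (x, y, widths) normalizes chain height into the image
  without touching any index (slip and Cobb are scale-invariant by
  construction; disc and SI values are stored explicitly).

Six diagnostic classes with geometry-driven signatures emulate the clinical
class mix: spondylolisthesis (one high-slip level), infection (one asymmetric,
collapsed disc), spondyloarthropathy (SI spacing difference), and three
normal regions (cervical/thoracic/lumbar) distinguished by vertebra count,
relative width and curvature band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq
from skimage.draw import polygon as _sk_polygon

from .geometry import GeometryIndices, LandmarkSet, compute_all_indices

__all__ = [
    "CLASSES",
    "TABLE1_COUNTS",
    "class_mix_clinical",
    "PhantomConfig",
    "PhantomSample",
    "DegradationSpec",
    "InfeasibleTargetError",
    "generate_landmarks",
    "rasterize",
    "degrade",
    "sample_config",
    "generate_samples",
    "make_dataset",
    "sparse_annotation_mask",
]

CLASSES = (
    "spondylolisthesis",
    "infection",
    "spondyloarthropathy",
    "normal_cervical",
    "normal_thoracic",
    "normal_lumbar",
)

#: clinical class frequencies (counts out of 1613) used for the default mix
TABLE1_COUNTS = {
    "spondylolisthesis": 496,
    "infection": 322,
    "spondyloarthropathy": 275,
    "normal_cervical": 192,
    "normal_thoracic": 70,
    "normal_lumbar": 258,
}


def class_mix_clinical() -> dict[str, float]:
    total = sum(TABLE1_COUNTS.values())
    return {k: v / total for k, v in TABLE1_COUNTS.items()}


class InfeasibleTargetError(ValueError):
    """Raised when requested targets cannot be realized as a valid phantom."""


@dataclass
class PhantomConfig:
    """Generative controls for a single phantom.

    target_slip / target_disc_asymmetry are per-level / per-disc arrays of
    length ``n_vertebrae - 1``; target_si is in pixels, target_cobb in degrees.
    ``widths`` are *relative* vertebral widths (rescaled with the chain);
    ``disc_frac`` sets each disc's mean height as a fraction of the local
    centroid gap.
    """

    n_vertebrae: int = 5
    image_size: tuple[int, int] = (128, 128)
    class_label: str | None = None
    target_slip: np.ndarray = None
    target_disc_asymmetry: np.ndarray = None
    target_si: float = 0.0
    target_cobb: float = 0.0
    jitter_scale: float = 0.0
    seed: int = 0
    widths: np.ndarray = None
    disc_frac: np.ndarray = None
    si_base: float = 3.0
    height_frac: float = 0.72

    def __post_init__(self):
        n = self.n_vertebrae
        if n < 2:
            raise ValueError("n_vertebrae must be >= 2")
        if self.image_size[0] < 64 or self.image_size[1] < 64:
            raise ValueError("image_size must be at least (64, 64)")
        if self.class_label is not None and self.class_label not in CLASSES:
            raise ValueError(f"unknown class {self.class_label!r}")
        self.target_slip = (
            np.zeros(n - 1) if self.target_slip is None
            else np.asarray(self.target_slip, dtype=float).reshape(n - 1)
        )
        self.target_disc_asymmetry = (
            np.zeros(n - 1) if self.target_disc_asymmetry is None
            else np.asarray(self.target_disc_asymmetry, dtype=float).reshape(n - 1)
        )
        self.widths = (
            np.full(n, 30.0) if self.widths is None
            else np.asarray(self.widths, dtype=float).reshape(n)
        )
        self.disc_frac = (
            np.full(n - 1, 0.35) if self.disc_frac is None
            else np.asarray(self.disc_frac, dtype=float).reshape(n - 1)
        )
        if np.any(self.target_slip < 0):
            raise ValueError("target slip ratios must be >= 0")
        if np.any(self.target_disc_asymmetry < 0) or np.any(self.target_disc_asymmetry >= 2):
            raise ValueError("target disc asymmetries must lie in [0, 2)")
        if not (0.0 <= self.target_cobb < 90.0):
            raise ValueError("target Cobb angle must lie in [0, 90) degrees")
        if self.target_si < 0:
            raise ValueError("target SI difference must be >= 0")
        if self.jitter_scale < 0:
            raise ValueError("jitter_scale must be >= 0")


@dataclass
class PhantomSample:
    """One synthetic radiograph with full ground truth."""

    landmarks: LandmarkSet
    image: np.ndarray
    class_label: str | None
    true_indices: GeometryIndices
    annotated: bool = False
    sample_id: str = ""

    def __post_init__(self):
        h, w = self.image.shape
        c = self.landmarks.centroids
        if len(c) and (np.any(c[:, 0] < 0) or np.any(c[:, 0] >= w)
                       or np.any(c[:, 1] < 0) or np.any(c[:, 1] >= h)):
            raise ValueError("landmark coordinates outside image bounds")


@dataclass
class DegradationSpec:
    """Image degradations: Gaussian noise, Gaussian blur, directional blur."""

    noise_sigma: float = 0.0
    blur_sigma: float = 0.0
    motion_length: float = 0.0
    motion_angle: float = 0.0

    def __post_init__(self):
        if min(self.noise_sigma, self.blur_sigma, self.motion_length) < 0:
            raise ValueError("degradation parameters must be >= 0")


# ---------------------------------------------------------------------------
# landmark generation (index inversion)
# ---------------------------------------------------------------------------

def _fit_end_slopes(x: np.ndarray, u: np.ndarray) -> tuple[float, float]:
    """End slopes dx/du of the least-squares cubic fit x(u)."""
    n = len(x)
    deg = min(3, n - 1)
    mid = (u[0] + u[-1]) / 2.0
    half = (u[-1] - u[0]) / 2.0
    t = (u - mid) / half
    V = np.vander(t, deg + 1, increasing=True)
    coeffs, *_ = np.linalg.lstsq(V, x, rcond=None)
    slopes = []
    for ti in (t[0], t[-1]):
        slopes.append(sum(coeffs[k] * k * ti ** (k - 1) for k in range(1, deg + 1)) / half)
    return slopes[0], slopes[-1]


def _solve_chain_scale(x: np.ndarray, theta_deg: float) -> float:
    """Vertical scale c such that the fitted-tangent angle of (x, c·u) is theta."""
    n = len(x)
    u = np.arange(n, dtype=float)
    tu, tl = _fit_end_slopes(x, u)
    T = math.tan(math.radians(theta_deg))
    D = tl - tu
    prod = tu * tl
    c = None
    if abs(D) > 1e-12 and T > 0:
        if prod < 0:  # opposite end slopes: angle spans (0, 180) monotonically
            P = -prod
            c = (abs(D) + math.sqrt(D * D + 4.0 * T * T * P)) / (2.0 * T)
        else:
            disc = D * D - 4.0 * T * T * prod
            if disc >= 0:
                c = (abs(D) + math.sqrt(disc)) / (2.0 * T)
    if c is not None and c > 0:
        return c
    # fallback: bracketed root-find on the angle-vs-scale curve
    from .geometry import cobb_angle

    def angle_at(cc):
        return cobb_angle(x=x, y=cc * u) - theta_deg

    scales = np.geomspace(1e-3, 1e6, 60)
    vals = [angle_at(s) for s in scales]
    for a, b, fa, fb in zip(scales[:-1], scales[1:], vals[:-1], vals[1:]):
        if fa == 0:
            return a
        if fa * fb < 0:
            return brentq(angle_at, a, b, xtol=1e-12, rtol=1e-15)
    raise InfeasibleTargetError(
        f"Cobb target {theta_deg:.3f} deg is unreachable for the requested slip pattern"
    )


def generate_landmarks(config: PhantomConfig) -> LandmarkSet:
    """Build landmarks whose recomputed indices equal the config targets.

    With ``jitter_scale == 0`` the inversion is exact (machine precision);
    jitter adds isotropic Gaussian noise to the centroids afterwards, and the
    realized indices then differ from the targets accordingly.  Deterministic
    for a fixed seed.  Raises :class:`InfeasibleTargetError` for target
    combinations the construction cannot realize.
    """
    n = config.n_vertebrae
    s = config.target_slip
    w = config.widths
    theta = config.target_cobb
    img_h, img_w = config.image_size

    if theta > 0:
        flip = (n - 1) // 2
        signs = np.where(np.arange(n - 1) < flip, -1.0, 1.0)
    else:
        signs = np.ones(n - 1)
    dx = signs * s * w[1:]
    x = np.concatenate([[0.0], np.cumsum(dx)])

    H = config.height_frac * img_h
    if theta == 0.0:
        # a collinear chain can be constructed directly in pixel units: widths
        # are free when slips are zero (slip = 0/w) or proportional (spacing
        # follows |Δx|), so the width-to-gap aspect is chosen anatomically and
        # capped to the image width
        w_unit = w / np.mean(w)
        if np.all(s == 0):
            gap = H / (n - 1)
            w_scaled = w_unit * min(1.7 * gap, 0.35 * img_w)
            y = gap * np.arange(n, dtype=float)
            x = np.zeros(n)
        elif np.all(s > 0):
            m_width = min(1.7 * H / (n - 1),
                          0.35 * img_w / float(np.sum(s * w_unit[1:])))
            w_scaled = w_unit * m_width
            dx = signs * s * w_scaled[1:]
            y = np.concatenate([[0.0], np.cumsum(np.abs(dx) * (H / np.sum(np.abs(dx))))])
            x = np.concatenate([[0.0], np.cumsum(dx)])
        else:
            raise InfeasibleTargetError(
                "Cobb target 0 requires slip targets that are all zero or all positive "
                "(mixed patterns cannot form a collinear chain)"
            )
    else:
        if n < 3:
            raise InfeasibleTargetError("a nonzero Cobb target needs at least 3 vertebrae")
        if np.all(dx == 0):
            raise InfeasibleTargetError(
                "Cobb target > 0 is unreachable with all-zero slip targets "
                "(a straight vertical chain has zero curvature)"
            )
        c = _solve_chain_scale(x, theta)
        y = c * np.arange(n, dtype=float)
        # uniform rescale into the image (index-preserving)
        k = H / (y[-1] - y[0])
        x, y, w_scaled = x * k, y * k, w * k

    x = x - x.mean() + img_w / 2.0
    y = y - y[0] + (1.0 - config.height_frac) * img_h / 2.0

    half_w = w_scaled / 2.0
    if np.any(x - half_w < 1) or np.any(x + half_w > img_w - 1):
        worst = int(np.argmax(np.maximum(half_w - x, x + half_w - img_w)))
        raise InfeasibleTargetError(
            f"vertebra {worst} exceeds image width (slip targets too large for {img_w} px)"
        )

    centroids = np.stack([x, y], axis=1)
    if config.jitter_scale > 0:
        rng = np.random.default_rng(config.seed)
        centroids = centroids + rng.normal(0.0, config.jitter_scale, size=centroids.shape)
        centroids[:, 1] = np.sort(centroids[:, 1])
        if np.any(np.diff(centroids[:, 1]) <= 0):
            centroids[:, 1] += np.arange(n) * 1e-6
        centroids[:, 0] = np.clip(centroids[:, 0], half_w + 1, img_w - 1 - half_w)
        centroids[:, 1] = np.clip(centroids[:, 1], 1, img_h - 2)

    gaps = np.diff(centroids[:, 1])
    mean_h = config.disc_frac * gaps
    a = config.target_disc_asymmetry
    disc_heights = np.stack([mean_h * (1 + a / 2.0), mean_h * (1 - a / 2.0)], axis=1)
    si = np.array([config.si_base + config.target_si, config.si_base])
    return LandmarkSet(centroids, w_scaled, disc_heights, si)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def rasterize(landmarks: LandmarkSet, image_size: tuple[int, int],
              background: float = 0.12, body_intensity: float = 0.85,
              return_labels: bool = False):
    """Render landmarks as a grayscale pseudo-radiograph in [0, 1].

    Vertebral bodies are bright quadrilaterals whose facing edges are tilted so
    the visible inter-body gap equals the stored left/right disc heights; the
    sacroiliac region is drawn as a sacral block plus two lateral iliac marks
    whose vertical offsets encode d_left/d_right.  ``return_labels`` also
    returns an integer map assigning pixels to vertebra indices (0 = none).
    """
    img_h, img_w = image_size
    img = np.full((img_h, img_w), background)
    labels = np.zeros((img_h, img_w), dtype=int)
    c = landmarks.centroids
    n = len(c)
    if n == 0:
        return (img, labels) if return_labels else img
    if (np.any(c[:, 0] < 0) or np.any(c[:, 0] >= img_w)
            or np.any(c[:, 1] < 0) or np.any(c[:, 1] >= img_h)):
        bad = int(np.argmax((c[:, 0] < 0) | (c[:, 0] >= img_w) | (c[:, 1] < 0) | (c[:, 1] >= img_h)))
        raise ValueError(f"landmark {bad} at {tuple(c[bad])} is outside the image")

    x, y, w = c[:, 0], c[:, 1], landmarks.widths
    gaps = np.diff(y)
    h = landmarks.disc_heights
    body_share = 0.65

    for i in range(n):
        if i > 0:
            m = (y[i - 1] + y[i]) / 2.0
            ytl, ytr = m + h[i - 1, 0] / 2.0, m + h[i - 1, 1] / 2.0
        else:
            cap = gaps[0] * body_share / 2.0 if n > 1 else w[0] * 0.35
            ytl = ytr = y[0] - cap
        if i < n - 1:
            m = (y[i] + y[i + 1]) / 2.0
            ybl, ybr = m - h[i, 0] / 2.0, m - h[i, 1] / 2.0
        else:
            cap = gaps[-1] * body_share / 2.0 if n > 1 else w[-1] * 0.35
            ybl = ybr = y[-1] + cap
        cols = np.array([x[i] - w[i] / 2.0, x[i] + w[i] / 2.0, x[i] + w[i] / 2.0, x[i] - w[i] / 2.0])
        rows = np.array([ytl, ytr, ybr, ybl])
        rr, cc = _sk_polygon(rows, cols, shape=img.shape)
        img[rr, cc] = body_intensity
        labels[rr, cc] = i + 1

    # sacroiliac region: sacral block + two iliac marks at d_left / d_right
    d_left, d_right = landmarks.si_distances
    sac_top = min(y[-1] + gaps[-1] * body_share / 2.0 + 1.0, img_h - 2.0) if n > 1 else y[-1] + w[-1] * 0.4
    sac_w = w[-1] * 1.05
    rr, cc = _sk_polygon(
        np.array([sac_top, sac_top, sac_top + 6.0, sac_top + 6.0]),
        np.array([x[-1] - sac_w / 2, x[-1] + sac_w / 2, x[-1] + sac_w / 2, x[-1] - sac_w / 2]),
        shape=img.shape,
    )
    img[rr, cc] = 0.75
    for side, d in ((-1.0, d_left), (1.0, d_right)):
        cx0 = x[-1] + side * (sac_w / 2 + 4.0)
        cy0 = sac_top + 3.0 + d
        rr, cc = _sk_polygon(
            np.array([cy0 - 2, cy0 - 2, cy0 + 2, cy0 + 2]),
            np.array([cx0 - 2, cx0 + 2, cx0 + 2, cx0 - 2]),
            shape=img.shape,
        )
        img[rr, cc] = 0.7
    img = np.clip(img, 0.0, 1.0)
    return (img, labels) if return_labels else img


def degrade(image: np.ndarray, spec: DegradationSpec, seed: int = 0) -> np.ndarray:
    """Apply noise → Gaussian blur → motion blur, then clip to [0, 1]."""
    if np.any(image < 0) or np.any(image > 1):
        raise ValueError("input image intensities must lie in [0, 1]")
    out = np.asarray(image, dtype=float)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, spec.noise_sigma, size=out.shape)
    if spec.blur_sigma > 0:
        out = ndimage.gaussian_filter(out, spec.blur_sigma, mode="nearest")
    if spec.motion_length >= 1:
        L = int(round(spec.motion_length))
        size = L if L % 2 == 1 else L + 1
        kernel = np.zeros((size, size))
        ang = math.radians(spec.motion_angle)
        c0 = size // 2
        for t in np.linspace(-L / 2.0, L / 2.0, 4 * size):
            r = int(round(c0 + t * math.sin(ang)))
            col = int(round(c0 + t * math.cos(ang)))
            if 0 <= r < size and 0 <= col < size:
                kernel[r, col] = 1.0
        kernel /= kernel.sum()
        out = ndimage.convolve(out, kernel, mode="nearest")
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# class-conditional sampling and datasets
# ---------------------------------------------------------------------------

def sample_config(class_label: str, rng: np.random.Generator,
                  image_size: tuple[int, int] = (128, 128),
                  jitter_scale: float = 0.0) -> PhantomConfig:
    """Draw a class-consistent PhantomConfig.

    Geometry signatures: spondylolisthesis = one level with slip in [0.1, 0.5];
    infection = one disc with asymmetry in [0.15, 0.6] and collapsed mean
    height; spondyloarthropathy = SI difference in [2, 6] px; the three normal
    regions differ by vertebra count, relative width and Cobb band
    (lumbar 2–8°, cervical 10–18°, thoracic 22–38°).
    """
    if class_label not in CLASSES:
        raise ValueError(f"unknown class {class_label!r}")
    region = {
        "spondylolisthesis": "lumbar", "infection": "lumbar",
        "spondyloarthropathy": "lumbar", "normal_lumbar": "lumbar",
        "normal_cervical": "cervical", "normal_thoracic": "thoracic",
    }[class_label]
    n = {"lumbar": 5, "cervical": 7, "thoracic": 10}[region]
    ratio = {"lumbar": rng.uniform(1.5, 2.0), "cervical": rng.uniform(1.2, 1.7),
             "thoracic": rng.uniform(1.3, 1.8)}[region]
    cobb_band = {"lumbar": (2.0, 8.0), "cervical": (10.0, 18.0), "thoracic": (22.0, 38.0)}[region]
    cobb = rng.uniform(*cobb_band)

    # base slips consistent with the target curve: a C-curve with end-tangent
    # angle theta over n-1 unit gaps has per-level |Δx| ≈ tan(θ/2)·|2u/U − 1|,
    # and slip = |Δx| / width with width = ratio · gap
    u = n - 1
    mid_slopes = np.abs((2 * np.arange(u) + 1.0) / u - 1.0) * math.tan(math.radians(cobb) / 2.0)
    slips = mid_slopes / ratio * rng.uniform(0.85, 1.15, size=u) + rng.uniform(0.003, 0.012, size=u)
    widths = ratio * rng.uniform(0.95, 1.05, size=n)

    asym = rng.uniform(0.0, 0.10, size=n - 1)
    si = rng.uniform(0.0, 0.5)
    disc_frac = np.full(n - 1, 0.35)

    if class_label == "spondylolisthesis":
        level = rng.integers(0, n - 1)
        slips[level] = rng.uniform(0.1, 0.5)
    elif class_label == "infection":
        disc = rng.integers(0, n - 1)
        asym[disc] = rng.uniform(0.15, 0.6)
        disc_frac[disc] = 0.15
    elif class_label == "spondyloarthropathy":
        si = rng.uniform(2.0, 6.0)

    return PhantomConfig(
        n_vertebrae=n, image_size=image_size, class_label=class_label,
        target_slip=slips, target_disc_asymmetry=asym, target_si=si,
        target_cobb=cobb, jitter_scale=jitter_scale,
        seed=int(rng.integers(0, 2 ** 31 - 1)), widths=widths, disc_frac=disc_frac,
    )


def make_sample(config: PhantomConfig, sample_id: str = "") -> PhantomSample:
    """Generate landmarks, rasterize, and record recomputed ground-truth indices."""
    landmarks = generate_landmarks(config)
    image = rasterize(landmarks, config.image_size)
    indices = compute_all_indices(landmarks)
    return PhantomSample(landmarks, image, config.class_label, indices, sample_id=sample_id)


def _class_counts(n=None, class_mix=None, n_per_class=None) -> dict[str, int]:
    if n_per_class is not None:
        counts = {c: int(n_per_class) for c in CLASSES}
    elif class_mix is not None:
        total = sum(class_mix.values())
        counts = {c: int(round(class_mix[c] / total * n)) for c in class_mix}
    else:
        base, rem = divmod(int(n), len(CLASSES))
        counts = {c: base + (1 if i < rem else 0) for i, c in enumerate(CLASSES)}
    for c in counts:
        if c not in CLASSES:
            raise ValueError(f"unknown class {c!r}")
        if counts[c] < 0:
            raise ValueError("negative class count")
    return counts


def generate_samples(n=None, class_mix=None, n_per_class=None, seed: int = 0,
                     image_size=(128, 128), jitter_scale: float = 0.0) -> list[PhantomSample]:
    """In-memory stratified phantom dataset (deterministic for a fixed seed)."""
    counts = _class_counts(n, class_mix, n_per_class)
    rng = np.random.default_rng(seed)
    samples = []
    for cls in CLASSES:
        for i in range(counts.get(cls, 0)):
            for _attempt in range(20):
                cfg = sample_config(cls, rng, image_size=image_size, jitter_scale=jitter_scale)
                try:
                    samples.append(make_sample(cfg, sample_id=f"{cls}_{i:04d}"))
                    break
                except InfeasibleTargetError:
                    continue
            else:
                raise InfeasibleTargetError(f"could not draw a feasible {cls} phantom")
    order = rng.permutation(len(samples))
    return [samples[i] for i in order]


def sparse_annotation_mask(dataset: list[PhantomSample], fraction: float,
                           seed: int = 0) -> np.ndarray:
    """Mark floor(fraction·N) samples annotated, stratified by class.

    Per-class counts follow largest-remainder allocation, so each differs from
    exact proportionality by at most one.
    """
    if not (0 < fraction <= 1):
        raise ValueError("annotation fraction must lie in (0, 1]")
    n = len(dataset)
    total = int(math.floor(fraction * n))
    labels = [s.class_label for s in dataset]
    classes = sorted(set(labels), key=lambda c: CLASSES.index(c) if c in CLASSES else 99)
    per = {c: labels.count(c) for c in classes}
    quota = {c: per[c] * total / n for c in classes}
    counts = {c: int(math.floor(quota[c])) for c in classes}
    rest = total - sum(counts.values())
    for c in sorted(classes, key=lambda c: quota[c] - counts[c], reverse=True)[:rest]:
        counts[c] += 1
    rng = np.random.default_rng(seed)
    mask = np.zeros(n, dtype=bool)
    for c in classes:
        idx = np.array([i for i, lab in enumerate(labels) if lab == c])
        chosen = rng.choice(idx, size=min(counts[c], len(idx)), replace=False)
        mask[chosen] = True
    for s, m in zip(dataset, mask):
        s.annotated = bool(m)
    return mask


def make_dataset(out_dir, n=None, class_mix=None, n_per_class=None, seed: int = 0,
                 image_size=(128, 128), jitter_scale: float = 0.0,
                 annotated_fraction: float = 0.15):
    """Write a phantom dataset to disk: PNGs, landmark CSVs and a manifest CSV."""
    import pandas as pd
    from pathlib import Path
    from PIL import Image

    from .io import write_landmarks

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "landmarks").mkdir(parents=True, exist_ok=True)
    samples = generate_samples(n, class_mix, n_per_class, seed=seed,
                               image_size=image_size, jitter_scale=jitter_scale)
    sparse_annotation_mask(samples, annotated_fraction, seed=seed + 1)
    rows = []
    for s in samples:
        img_path = out / "images" / f"{s.sample_id}.png"
        lm_path = out / "landmarks" / f"{s.sample_id}.csv"
        Image.fromarray((s.image * 255).round().astype(np.uint8)).save(img_path)
        write_landmarks(s.landmarks, lm_path)
        summ = s.true_indices.summary()
        rows.append({
            "path": str(img_path.relative_to(out)),
            "landmark_path": str(lm_path.relative_to(out)),
            "class": s.class_label,
            "slip_max": summ[0], "disc_asymmetry_max": summ[1],
            "si_symmetry": summ[2], "cobb_angle": summ[3],
            "annotated": s.annotated,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return samples, manifest
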