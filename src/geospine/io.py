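"""On-disk formats: landmark files, datasets, experiment configs, run manifests.

Landmark schema (CSV): one row per vertebra with 0-based pixel coordinates
(origin top-left, y down)::

    index, cx, cy, width, disc_h_left, disc_h_right

where the disc columns describe the disc *below* the vertebra (blank on the
last row), followed by one trailer row with ``index = "si"`` carrying the
sacroiliac left/right distances in the disc columns.  The JSON dialect
mirrors the same keys.  Round-tripping preserves values to full precision.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import GeometryIndices, LandmarkSet

__all__ = [
    "write_landmarks",
    "read_landmarks",
    "load_dataset",
    "ExperimentConfig",
    "load_config",
    "save_config",
    "RunManifest",
    "derive_seed",
]

_COLUMNS = ["index", "cx", "cy", "width", "disc_h_left", "disc_h_right"]


class LandmarkSchemaError(ValueError):
    pass


def _fmt(v: float) -> str:
    return format(float(v), ".17g")


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    path = Path(path)
    n = landmarks.n_vertebrae
    if path.suffix.lower() == ".json":
        payload = {
            "vertebrae": [
                {
                    "index": i,
                    "cx": landmarks.centroids[i, 0],
                    "cy": landmarks.centroids[i, 1],
                    "width": landmarks.widths[i],
                    "disc_h_left": landmarks.disc_heights[i, 0] if i < n - 1 else None,
                    "disc_h_right": landmarks.disc_heights[i, 1] if i < n - 1 else None,
                }
                for i in range(n)
            ],
            "si": {"d_left": landmarks.si_distances[0], "d_right": landmarks.si_distances[1]},
        }
        path.write_text(json.dumps(payload, indent=1))
        return
    lines = [",".join(_COLUMNS)]
    for i in range(n):
        disc = (
            (_fmt(landmarks.disc_heights[i, 0]), _fmt(landmarks.disc_heights[i, 1]))
            if i < n - 1 else ("", "")
        )
        lines.append(",".join([
            str(i), _fmt(landmarks.centroids[i, 0]), _fmt(landmarks.centroids[i, 1]),
            _fmt(landmarks.widths[i]), *disc,
        ]))
    lines.append(",".join(["si", "", "", "", _fmt(landmarks.si_distances[0]),
                           _fmt(landmarks.si_distances[1])]))
    path.write_text("\n".join(lines) + "\n")


def _build_landmarks(rows: list[dict], si: tuple, origin: str) -> LandmarkSet:
    if not rows:
        raise LandmarkSchemaError(f"{origin}: no vertebra rows")
    centroids, widths, discs = [], [], []
    for k, r in enumerate(rows):
        for fieldname in ("cx", "cy", "width"):
            if r[fieldname] is None or (isinstance(r[fieldname], float) and np.isnan(r[fieldname])):
                raise LandmarkSchemaError(f"{origin}: row {k} missing field {fieldname!r}")
        if float(r["width"]) <= 0:
            raise LandmarkSchemaError(f"{origin}: row {k} has non-positive width")
        centroids.append((float(r["cx"]), float(r["cy"])))
        widths.append(float(r["width"]))
        if k < len(rows) - 1:
            hl, hr = r.get("disc_h_left"), r.get("disc_h_right")
            if hl is None or hr is None or (isinstance(hl, float) and np.isnan(hl)):
                raise LandmarkSchemaError(f"{origin}: row {k} missing disc heights")
            discs.append((float(hl), float(hr)))
    centroids = np.asarray(centroids)
    bad = np.nonzero(np.diff(centroids[:, 1]) <= 0)[0]
    if len(bad):
        raise LandmarkSchemaError(
            f"{origin}: row {bad[0] + 1} breaks the superior-to-inferior y ordering"
        )
    return LandmarkSet(centroids, np.asarray(widths), np.asarray(discs).reshape(-1, 2),
                       np.asarray(si, dtype=float))


def read_landmarks(path) -> LandmarkSet:
    """Read a landmark file (dialect auto-detected from the extension)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        for key in ("vertebrae", "si"):
            if key not in payload:
                raise LandmarkSchemaError(f"{path.name}: missing top-level key {key!r}")
        si = (payload["si"]["d_left"], payload["si"]["d_right"])
        return _build_landmarks(payload["vertebrae"], si, path.name)
    df = pd.read_csv(path, dtype={"index": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise LandmarkSchemaError(f"{path.name}: missing column(s) {missing}")
    trailer = df[df["index"] == "si"]
    if len(trailer) != 1:
        raise LandmarkSchemaError(f"{path.name}: expected exactly one 'si' trailer row")
    si = (float(trailer.iloc[0]["disc_h_left"]), float(trailer.iloc[0]["disc_h_right"]))
    body = df[df["index"] != "si"]
    rows = body.to_dict("records")
    return _build_landmarks(rows, si, path.name)


def load_dataset(root):
    """Load a dataset written by :func:`geospine.phantom.make_dataset`."""
    from PIL import Image

    from .geometry import compute_all_indices
    from .phantom import PhantomSample

    root = Path(root)
    manifest = pd.read_csv(root / "manifest.csv")
    samples = []
    for _, row in manifest.iterrows():
        img = np.asarray(Image.open(root / row["path"]), dtype=float) / 255.0
        lm = read_landmarks(root / row["landmark_path"])
        samples.append(PhantomSample(lm, img, row["class"], compute_all_indices(lm),
                                     annotated=bool(row["annotated"]),
                                     sample_id=Path(row["path"]).stem))
    return samples, manifest


# ---------------------------------------------------------------------------
# experiment configuration
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {"phantom", "model", "loss_weights", "train", "constraints_path",
                "output_dir", "seed"}


@dataclass
class ExperimentConfig:
    """Validated experiment configuration (YAML-backed)."""

    phantom: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    loss_weights: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    constraints_path: str | None = None
    output_dir: str = "runs"
    seed: int = 0

    def as_dict(self) -> dict:
        return {
            "phantom": self.phantom, "model": self.model,
            "loss_weights": self.loss_weights, "train": self.train,
            "constraints_path": self.constraints_path,
            "output_dir": self.output_dir, "seed": self.seed,
        }


def load_config(path) -> ExperimentConfig:
    payload = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(payload) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return ExperimentConfig(**payload)


def save_config(config: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.as_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# run manifests and seeding
# ---------------------------------------------------------------------------

def derive_seed(global_seed: int, name: str) -> int:
    """Stable per-module child seed below 2^31."""
    h = hashlib.sha256(f"{global_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written before and finalized after a CLI run."""

    command: str
    config: dict
    seed: int
    path: Path = None
    inputs: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    status: str = "running"

    def __post_init__(self):
        from . import __version__

        self.config_hash = hashlib.sha256(
            json.dumps(self.config, sort_keys=True, default=str).encode()).hexdigest()[:16]
        self.version = __version__

    def add_input(self, path):
        p = Path(path)
        if p.is_file():
            self.inputs[str(p)] = _sha256(p)

    def add_output(self, path):
        self.outputs.append(str(path))

    def write(self):
        payload = {
            "command": self.command, "config": self.config,
            "config_hash": self.config_hash, "version": self.version,
            "seed": self.seed, "inputs": self.inputs, "outputs": self.outputs,
            "status": self.status, "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        Path(self.path).write_text(json.dumps(payload, indent=1, default=str))

    def finalize(self, status: str = "complete"):
        self.status = status
        self.write()
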