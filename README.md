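# geospine

Geometry-grounded analysis of spinal radiographs on synthetic phantoms:
differentiable radiographic indices, an edge-aware spine-graph transformer,
neuro-symbolic monotonicity constraints, and counterfactual geometry editing
with a desk-scale conditional diffusion model.

## Who this is for

Researchers prototyping *anatomically grounded* spine-imaging models: instead
of treating a radiograph as an opaque texture, the package represents each
spine as an ordered chain of vertebral landmarks and derives the clinical
measurements radiologists actually use — as differentiable functions, so they
can participate in training objectives, symbolic constraints and
counterfactual audits.  Because real spinal radiographs are rarely shareable,
everything runs on a synthetic phantom generator whose ground-truth geometry
is controllable *exactly*.

## The four indices

For centroids (xᵢ, yᵢ) ordered superior→inferior with vertebral widths wᵢ,
disc heights (hⱼˡ, hⱼʳ), and sacroiliac distances (d_left, d_right):

* **Slip ratio** (spondylolisthesis proxy): `SlipRatioᵢ = |xᵢ − xᵢ₋₁| / wᵢ`
* **Disc asymmetry** (infection/degeneration): `Asymmetryⱼ = |hⱼˡ − hⱼʳ| / h̄ⱼ`
* **SI spacing symmetry** (spondyloarthropathy): `|d_left − d_right|`
* **Cobb-like angle** (curvature): angle between tangents of a least-squares
  polynomial fit x(y) at the end vertebrae,
  `θ = arccos(v_u·v_l / ‖v_u‖‖v_l‖)`

All four carry gradients (smooth |·| surrogate, clamped arccos), verified
against central finite differences to < 1e-5 relative error.

Downstream, a chain graph over vertebra and disc nodes is processed by a
graph transformer whose attention is modulated by geometric edge attributes
(distance, orientation, curvature):
`score(i,j) = (qᵢ + φ(aᵢⱼ))ᵀ kⱼ / √d_k`, softmax over neighbors.  A
log-barrier layer penalizes violations of clinical monotonicity rules (e.g.
"P(spondylolisthesis) rises with slip ratio"), and a counterfactual editor
changes one index by an exact Δg for constraint evaluation and model audits.

## Worked example

```python
import numpy as np
from geospine import phantom
from geospine.geometry import compute_all_indices
from geospine.counterfactual import CounterfactualEdit, edit_landmarks

cfg = phantom.sample_config("spondylolisthesis", np.random.default_rng(0))
sample = phantom.make_sample(cfg)
idx = compute_all_indices(sample.landmarks)
print("slip per level:", np.round(idx.slip_ratio, 3))
print("cobb angle (deg): %.3f" % idx.cobb_angle)

edited = edit_landmarks(sample.landmarks, CounterfactualEdit("slip_ratio", 0.10))
print("slip after +0.10 edit:", np.round(compute_all_indices(edited).slip_ratio, 3))
```

prints

```
slip per level: [0.359 0.014 0.013 0.011]
cobb angle (deg): 2.099
slip after +0.10 edit: [0.459 0.014 0.013 0.011]
```

The phantom was drawn from the spondylolisthesis class, so one level carries
a pathological slip (0.359) over a small-curvature lumbar chain; the
counterfactual edit moves exactly that level by exactly +0.10 and leaves
every other level untouched.

A full desk-scale study (600 training / 200 test phantoms, six diagnostic
classes in clinically realistic proportions) trains in well under a minute on
one CPU:

```bash
geospine generate --out runs/ds --n 60 --seed 7     # PNGs + landmark CSVs
geospine train    --out runs/m  --n 600 --seed 7    # model + loss history
geospine evaluate --model runs/m/model.npz --out runs/eval --seed 7
geospine audit    --model runs/m/model.npz --out runs/audit --seed 7
geospine ablate   --out runs/abl --seed 7           # variant comparison table
```

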