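# Methods

## Overview

The package studies geometry-grounded classification of spinal radiographs
under conditions where the raw clinical images cannot be shared.  Every
component therefore operates on *synthetic spine phantoms*: parametric
landmark chains rendered into grayscale pseudo-radiographs, whose ground
truth geometry is exact by construction.  The pipeline is: phantom generation
→ differentiable geometry indices → spine-graph transformer classification →
symbolic monotonicity constraints → counterfactual editing and audits.

## Phantom generator

A phantom is an ordered chain of N vertebral centroids with per-vertebra
widths, per-disc left/right heights, and two sacroiliac distances.  The
generator *inverts* the four geometry indices: given requested per-level slip
ratios s, per-disc asymmetries a, an SI difference δ and a Cobb-like angle θ,
it constructs a landmark set whose recomputed indices equal the request to
machine precision (observed worst error ≈ 4·10⁻¹³ over thousands of draws).

The inversion exploits three facts:

1. Horizontal steps Δxᵢ = σᵢ·sᵢ·wᵢ realize any slip vector for any sign
   pattern σ; a C-shaped pattern (sign flip mid-chain) is used when θ > 0.
2. With x fixed, the least-squares polynomial fit x(y) is invariant under
   reparameterization of y, so the end-tangent slopes scale exactly as 1/c in
   the chain's vertical scale c.  The requested angle then reduces to a
   quadratic equation in c — solved in closed form, with a bracketed
   root-finder as fallback for unusual slope patterns.
3. Uniform rescaling of (x, y, widths) is index-preserving, which normalizes
   the chain into the image.  For θ = 0 the chain is built collinear directly
   in pixel units (the width/gap aspect is then a free anatomical choice,
   capped to the image width).  θ = 0 with a mix of zero and nonzero slip
   targets is rejected as infeasible: such a chain cannot be collinear.

Disc heights are stored explicitly (mean height a fixed fraction of the local
centroid gap, 0.35 by default; 0.15 for a "collapsed" disc), so disc and SI
targets are trivially exact.

**Class signatures.**  Six diagnostic classes map to geometry:
spondylolisthesis = one level with slip drawn from [0.1, 0.5]; infection =
one disc with asymmetry in [0.15, 0.6] and collapsed mean height;
spondyloarthropathy = SI difference in [2, 6] px; three normal regions
(lumbar N=5 / cervical N=7 / thoracic N=10) distinguished by vertebra count,
width-to-gap aspect and curvature band (2–8° / 10–18° / 22–38°).  Base
per-level slips are *derived from the target curve* (a C-curve with
end-tangent angle θ implies per-level |Δx| ≈ tan(θ/2)·|2u/U − 1|·gap), which
keeps slip and curvature targets jointly consistent — a strongly curved chain
with near-zero per-level displacement is geometrically impossible.  The
default class mix follows the clinical prevalence of the six categories
(30.7 / 20.0 / 17.0 / 11.9 / 4.3 / 16.0 %).

**Rendering.**  Vertebral bodies are bright quadrilaterals whose facing edges
tilt so the visible inter-body gap equals the stored left/right disc heights;
a sacral block and two lateral marks encode the SI distances.  The intensity
model is deliberately simple (flat brightness, optional Gaussian
noise/blur/motion degradations): the indices depend only on geometry, and the
rendering exists so that image-stream encoders can see class-relevant
structure.  What the phantoms do **not** emulate: projective geometry,
exposure/scatter physics, soft tissue, osteophytes, patient positioning
variation.  Passing tests therefore demonstrate correctness of the
*machinery* (indices, constraints, audits, training dynamics), not clinical
performance on real radiographs.

## Differentiable geometry

Reported index values use exact formulas.  Inside differentiable pipelines,
|u| is replaced by √(u² + ε²) − ε with ε = 10⁻⁶, and the arccos argument is
clamped to ±(1 − 10⁻⁷) so gradients stay finite; the exact path clips to
[−1, 1] instead, so a collinear chain reports exactly 0°.  The curvature fit
is a least-squares polynomial of degree min(3, N−1) in a normalized ordinate
(a linear solve, hence differentiable end to end).  A verification harness
compares autodiff gradients of each index with central finite differences
(step 10⁻⁴ px) over all coordinates; worst observed relative error ≈ 5·10⁻⁸.

Edge attributes for the spine graph are (distance, orientation, curvature).
Curvature uses the Menger form (reciprocal circumradius of consecutive node
triples, averaged over an edge's interior endpoints, 0 at chain ends): unlike
a raw second difference it is exactly zero for collinear but unevenly spaced
points, which the attribute contract requires.

All neural and differentiable components run on a minimal reverse-mode
autodiff core over numpy written for this package (`geospine._autograd`),
with a small layer/optimizer library on top; at desk scale this is fast
enough for the full study on one CPU.

## Spine-graph transformer

Nodes alternate vertebra/disc along the chain (2N−1 nodes, 2N−2 edges).
Node embeddings concatenate a local stream (MLP over 16×16 ROI crops) and a
global stream (MLP over the 24×24-downsampled image).  Attention scores are
`(qᵢ + φ(aᵢⱼ))ᵀkⱼ/√d_k` with φ a shared ReLU MLP mapping edge attributes to
per-head query-space vectors; a softmax over the neighborhood (self-attention
fallback for isolated nodes) makes rows stochastic, and each layer applies
residual + layer-norm and a feedforward block — standard transformer
stabilizers adopted as design choices.  Mean-pooled embeddings feed a 6-class
head and a 4-vector index-regression head.  When geometry features are
enabled, the per-image index summary (max slip, max disc asymmetry, SI
difference, Cobb angle — normalized and gain-scaled to match the
layer-normed embedding scale) is appended to the pooled vector; the
"without geometry indices" ablation removes exactly this.

Published-scale settings (node dim 256, 4 heads, 3 layers) remain the config
defaults; the desk-scale study uses node dim 32 (16+16), 4 heads, 1 layer,
which trains to convergence in ~20 s per run.

## Weakly supervised keypoints

A small heatmap network (downsampled image → MLP → one 16×16 map per
keypoint slot) is decoded by soft-argmax: spatial expectation under
softmax(heatmap/T), treating maps as logits (softmax of a quadratic logit
blob is a proper Gaussian, so the decode of such a blob is exact).
Visibility is the maximum 5×5-window probability mass.  Training combines
coordinate MSE on the annotated ≤15 % subset with four differentiable priors
on every image — ordering (hinge² on y-order violations with 1 px margin),
spacing (population variance of gap lengths), symmetry (squared lateral
deviation from the least-squares spinal axis beyond a 2 px band), and
curvature (squared third differences) — and, optionally, EMA teacher-student
consistency: the teacher (decay 0.95) sees weak (intensity-only) views, its
heatmaps are flipped/rotated into the student's strong-view frame, and slots
gate on teacher visibility > 0.5.  On held-out phantoms, adding the priors
to 15 %-supervised training reduced mean keypoint error in every seed tested
(the property suite re-measures this over 5 seeds).

## Constraints and counterfactuals

A constraint is (index, target class, direction); the clinical registry
ships slip→spondylolisthesis, SI difference→spondyloarthropathy, and
Cobb→pooled abnormal probability (the six-class scheme has no dedicated
curvature class).  The *training* default uses only the first two: on
phantoms the high-curvature spines are the normal thoracic and cervical
regions, so the Cobb rule is false in the modeled domain and enforcing it
would regularize the model toward a relation the data contradicts.
Because a classifier consumes images rather than indices, the constrained
derivative is realized as a finite difference along a *landmark-space
counterfactual edit* (default step 0.02–0.08 in index units) followed by
re-rasterization.  Violations are penalized by a relaxed log-barrier:
−μ·log g above the junction δ (μ = 1, δ = 0.05), continued below δ by its
second-order Taylor expansion so the penalty is finite, strictly decreasing
and C¹ everywhere — a pure −log g would be undefined for violated
constraints encountered mid-training.

Edits are exact by construction: slip edits rigidly shift the targeted
vertebra and everything inferior (all other slip levels, disc and SI values
are unchanged; the fitted Cobb angle necessarily moves); disc edits rescale
one disc's margins at fixed mean; SI edits move the wider side; Cobb edits
rotate the inferior half-chain about the mid-chain centroid with the angle
solved so the recomputed fitted-tangent angle lands exactly on target (slips
are exempt from the no-touch guarantee in that one case, as rotation and
lateral displacement are coupled).  Clinical caps are enforced: |Δslip| ≤
0.2 and per-margin disc-height changes ≤ 30 %.

The generative path is a desk-scale class- and Δg-conditional diffusion
model: a linear-β variance-preserving schedule (β from 10⁻⁴ to 2·10⁻²,
T = 1000 by default, 100–200 in tests), an MLP denoiser on 16×16 images with
sinusoidal time embedding, learned class embedding and scalar Δg
conditioning, trained on noise-prediction MSE and sampled by ancestral
reversal.  It demonstrates the conditional-generation mechanism; the *exact*
landmark-edit path is what constraint evaluation and audits use, since those
require a guaranteed Δg.

## Training objective

L = λ₁·L_cls + λ₂·L_reg + λ₃·L_geom + λ₄·L_concept + λ₅·L_NS + λ₆·L_CF with
λ = (1.0, 0.5, 0.3, 0.3, 0.2, 0.2).  L_cls is inverse-frequency-weighted
cross-entropy (weighting chosen over resampling for determinism); L_reg is
MSE between the regression head and the normalized index summary; L_geom
applies the spacing + symmetry priors to the landmark chains — with
ground-truth landmarks as inputs it is a recorded monitoring value and only
drives learning when a keypoint model is trained jointly; L_concept is a
supervised-contrastive loss over concept tiers built by crossing slip bins
{<0.25, 0.25–0.5, ≥0.5} with Cobb bins {<10°, 10–25°, ≥25°}; L_NS is the
log-barrier over probability slopes estimated on a fixed bank of
pre-rasterized counterfactual pairs (24 samples across all classes per
rule, rebuilt per run, evaluated once per epoch — cross-class coverage is
what generalizes the monotone rule to held-out audits); L_CF is a hinge on
counterfactual logit shifts over the same bank.

A finding worth knowing: on this synthetic task the constraint machinery has
little measurable headroom.  Because the geometry-index features feed the
classifier directly, the monotone slip-probability coupling is learnable
from classification alone — a fully unconstrained model already shows
0.96–0.99 held-out directional consistency, and constrained variants land
in the same band (differences of one to three samples in two hundred).  The
constraint layer's value is therefore expected to materialize on harder
data where unconstrained models violate clinical monotonicity appreciably;
here the tests verify the *mechanism* (barrier algebra, slope estimation,
audit plumbing), not a performance gap.  Stronger enforcement (barrier
strength μ ≥ 2) was observed to destabilize training occasionally and is
not the default.

Optimization is AdamW (desk-scale: lr 2·10⁻², weight decay 10⁻², 25 epochs,
batch 32, 2 warm-up epochs then cosine decay, early stopping on validation
loss with patience 20; the published-scale schedule — lr 10⁻⁴, 150 epochs,
batch 16 — is impractical and unnecessary at this problem size).  Batches
are bucketed by graph size to minimize padding.  All randomness flows from
one seed; identical seeds give bit-identical histories.

## Evaluation

Classification: accuracy, macro-F1, one-vs-rest macro AUROC (scikit-learn).
Index agreement: MAE, Lin's CCC, R² about the identity line, Bland–Altman
bias ± 1.96 SD, Deming regression with unit error-variance ratio
(hand-coded; cross-checked against brute-force formula evaluations).
Directional consistency: the fraction of held-out samples whose target-class
probability strictly rises when the index is edited up by 0.05.  The
degradation protocol re-evaluates a trained model on test images with
additive Gaussian noise σ ∈ {0.05, 0.10, 0.15}, blur, or motion blur.
Because the classifier's geometry features come from landmarks rather than
the degraded pixels, accuracy degrades only mildly under noise — the
protocol exercises the image streams, which is the honest behavior of this
architecture and is reported as such.

## Study sizes

The end-to-end study uses 600 training / 200 test phantoms (128×128 px,
16×16 ROIs) per seed and five seeds for the stochastic properties; the
keypoint-prior comparison uses 48/24 phantoms at 96×96 over five seeds; the
diffusion demonstration trains 200 steps on 16×16 images.  These sizes give
stable results while keeping the full suite comfortably within a desktop
CPU budget.

## Known limitations

* Phantom realism is intentionally minimal (see above); no claim transfers
  to real radiographs without re-validation.
* The keypoint model and classifier are trained separately; the joint
  pipeline (predicted landmarks feeding the graph) is supported by the APIs
  but the desk-scale study uses ground-truth landmarks.
* Constraints are global monotone rules; context-conditional or non-monotone
  clinical logic is out of scope.
* Cobb edits interact with slip values (rigid rotation moves x
  coordinates); audits that need both fixed should edit slip last.
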