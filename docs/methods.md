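# Methods

## Scope and model chain

`pjaplan` models one structure: the intervertebral disc immediately
cephalad to the upper instrumented vertebra (UIV) of a fused scoliotic
spine. The chain is

    disc geometry → FEM stress fields (pre & post) → Δσ subregion features
    → neural risk model → 1-D angle optimization,

with a packaged 12-patient clinical table and a synthetic-cohort generator
supplying the data. Vertebrae, instrumentation, contact and time-dependent
tissue behaviour are outside the model.

## Disc geometry and meshing

The disc is an elliptic cylinder: lateral semi-axis 20 mm, anterior–
posterior semi-axis 14 mm, height 8 mm — typical adult lumbar-disc
dimensions, since patient imaging is not an input. The nucleus pulposus
occupies a scaled inner ellipse (default scale 0.6, i.e. 36 % of the
cross-section) whose centre may be offset in-plane; the offset is the
package's handle on anatomical asymmetry and must leave the nucleus inside
the annulus.

Coordinates: +x patient-left, +y anterior, +z cephalad, origin at the
inferior-face centroid, so the eight subregion labels
({F, N} × {A, P} × {L, R}) are sign tests on element centroids; centroids
exactly on a dividing plane go to the non-negative side.

Meshing is deterministic and self-contained: the cross-section is
triangulated (fan around the centre plus ring quads), extruded into
prisms layer by layer, and each prism is cut into three tetrahedra with the
smallest-global-vertex rule for quad-face diagonals, which makes every
shared face agree between neighbours (a conforming mesh) and never produces
an inverted element. Default resolution 5 rings × 16 sectors × 4 layers
(1 728 tets, 405 nodes) keeps the cross-section polygon within 2.6 % of the
ellipse area; the volume error is purely cross-sectional, so axial
refinement leaves it unchanged while circumferential refinement shrinks it.
One caveat inherited from the diagonal rule: the tet pattern is not
mirror-symmetric, so discrete stress fields on a symmetric disc are only
approximately left/right symmetric (tests budget 5 % for this).

## Finite-element model

Both tissues are linear elastic, homogeneous, isotropic (Hooke's law):
nucleus E = 1.0 MPa, ν = 0.49 (nearly incompressible gel); annulus
E = 3.4 MPa, ν = 0.45. Elements are 4-node constant-strain tetrahedra in a
consistent mm–N–MPa system. The inferior face is fixed in all degrees of
freedom; the load `F = G cos α` (G = body weight above the UIV × 9.81 ×
`uiv_fraction`, default 0.5 with a per-UIV-level override table in the run
configuration) acts along −z, lumped over superior-face nodes in proportion
to tributary area — the consistent lumping of a uniform traction, so only
the magnitude, never the distribution, depends on the angle. Constraints
are eliminated (reduced system) and the SPD system solved by direct sparse
factorization; element stress is recovered as `σ = D B u` and scalarized as
von Mises stress, chosen because it is rotation-invariant and standard for
soft-tissue stress summaries.

Verification: the ν = 0 patch test (uniform pressure on a fixed-base block)
reproduces the homogeneous stress state to machine precision; reactions
balance the applied load; the solution scales exactly linearly with the
load, which the feature pipeline exploits.

## Features

Each subregion contributes its maximum and volume-weighted average element
von Mises stress (volume weighting makes the average mesh-density
independent). Features are the 16 signed differences post − pre (the sign
carries whether a region is loaded or unloaded by the correction), then age
in years and gender encoded M = 0 / F = 1: 18 inputs in a fixed, documented
order. Pre- and post-operative states are simulated on the same disc model,
so differences isolate the angle effect; summaries from different
geometries refuse to subtract. Features are z-scored with training-fold
statistics only — the held-out patient of a cross-validation fold never
contributes to the standardization.

## Risk model and training

One hidden tanh layer (default width 8) and a sigmoid output unit map the
18 features to a risk in (0, 1). Training minimizes the mean squared error
against the binary PJK label (honouring the L2-norm objective literally,
rather than substituting cross-entropy) with full-batch Adam: learning rate
0.01, β₁ 0.9, β₂ 0.999, ε 1e-8, 2 000 epochs, Xavier-uniform
initialization. All draws flow from one seed, so training is
bit-reproducible. Backpropagation is analytic for both the weights and the
inputs; the input gradient feeds the angle optimizer. Classification uses
the 0.5 threshold. Evaluation is leave-one-out cross-validation (each fold
re-standardizes and re-trains from scratch) with accuracy and rank-based
(Mann–Whitney, ties as ½) AUC.

## Feature ranking and sensitivity

DX score: squared class-mean difference over the sum of sample (n−1) class
variances, guarded by ε = 1e-12 for constant features; ranking descends,
ties break by feature order; the impact of a subset is its share of the
total score in percent. Sensitivity multiplies each selected feature by
(1 + δ) on an 11-point symmetric grid spanning the requested range
(default ±5 %) for every patient and reports the maximum relative change of
the predicted risk in percent; exactly-zero entries are shifted additively
by δ times the feature's cohort standard deviation instead ("output
variance" is read as change magnitude, the conservative interpretation).

## Angle optimization

Because the FEM is linear in the load, the stress summary at any angle is
the unit-load summary times `G cos α`; one unit-load solve therefore gives
the exact risk-versus-angle curve (the dual-path tests confirm equality
with full re-solves to solver precision). The optimizer scans a 0.1° grid
over the bounds (default 0°–45°, which covers every clinically applied
angle in the packaged cohort with margin), refines from the best grid point
with Adam using the analytic dg/dα, and never returns anything worse than
the best sampled point. Candidates within `risk_tolerance` (default 1e-3)
of the minimum tie-break toward the patient's pre-operative angle: blindly
minimizing the PJA is not clinically sensible, so among equally low-risk
angles the status quo wins. A flat curve (constant model) is flagged in the
diagnostics and returns the pre-operative angle. Pre- and post-operative G
are equal (body weight does not change at surgery).

## Synthetic cohorts

The generator emulates the published cohort's envelope: weight uniform on
32.5–71 kg, age uniform integers 13–20, 8:4 female:male ratio, pre-
operative PJA truncated-normal N(7°, 5°) on [0°, 20°], post-operative PJA =
pre + N(2°, 3°) clipped to [0°, 30°], prevalence target ≈ 25 % (3 of 12 in
the packaged table). Each virtual patient receives its own disc anatomy —
dimension jitter (relative SD 0.05, clipped at 2 SD), nucleus size uniform
on scale 0.5–0.7, nucleus-centre offset uniform over a scaled elliptic
slack region — because with one shared symmetric geometry all 16 stress
features are exact multiples of the common factor `G(cos α_post −
cos α_pre)` and no univariate statistic could distinguish them. The risk
mechanism acts through one designated feature (default: the max-stress
change in the right-anterior nucleus): P(PJK) = sigmoid(β₀ + β₁ z) on the
cohort-standardized feature, with Bernoulli labels by default (β₀ = −1.1,
β₁ = 4).

Two documented presets support parameter-recovery testing:

* **`strong_recovery`** — deterministic threshold labels (PJK iff
  β₀ + β₁z > 0, β₁ = 6) with a boundary margin of 2 logit units (the
  generator oversamples 1.6× and avoids candidates inside the margin),
  narrow weight (48–52 kg) and angle-change (5° ± 0.25°) spreads, no
  dimension jitter but strong nucleus asymmetry (offset fraction 0.8), and
  a finer mesh (8 rings × 24 sectors). These choices make the mechanism
  identifiable: the labels are a noiseless, margin-separated function of
  one anatomy-driven feature, so leave-one-out accuracy and AUC ≥ 0.9 and
  a first-place DX rank for the mechanism feature are properties of the
  method, not of label luck. With the full cohort-envelope nuisance variation the
  shared load factor correlates all stress features above 0.99 and no
  ranking method could single one out.
* **`null_mechanism`** — β₁ = 0: labels are intercept-only Bernoulli draws,
  independent of every feature; the pipeline should score near chance.

What the generator does **not** emulate: real disc shapes from CT,
nonlinear or anisotropic tissue, vertebral deformation, instrumentation,
and any non-biomechanical risk pathway. Passing recovery tests therefore
demonstrates that the pipeline can learn and invert a stress-mediated
mechanism when one exists — not that PJK in patients is so mediated.

## The packaged clinical table

The 12-patient table (9 non-PJK / 3 PJK, weights 32.5–71 kg, ages 13–20,
8 F / 4 M, with each patient's pre-operative PJA, applied post-operative
PJA, the original study's predicted risk and recommended angle) is included
verbatim as in-repo data and checksummed in the tests. Its published prose
summary of pre-operative PJA by group (8.4° ± 2.9° PJK; 6.7° non-PJK) is
inconsistent with the table itself (table-derived: 8.07° ± 3.50° and
6.81°); the package follows the table and reports table-derived values.
The original study's real-data metrics (83.3 % LOOCV accuracy, 0.889 AUC,
74.3 % top-5 impact, 2.10–4.66 % sensitivities) depended on per-patient CT
geometry that is not publicly available and are deliberately not
reproduction targets.

## Numerical choices and limitations

* Direct sparse factorization; systems are a few thousand DOF, seconds per
  solve at default resolution.
* Sigmoid evaluated in the numerically stable split form; Adam bias
  correction per step; losses recorded per epoch (first entry =
  at-initialization loss).
* Degenerate inputs fail loudly: inverted tets, empty subregions,
  unconstrained meshes, single-class training sets (warning) and
  single-class AUC (error), mismatched geometries in Δσ.
* Problem sizes in tests and the acceptance script (n = 60 cohorts,
  default or 8×24×4 meshes, 2 000-epoch training) were chosen so the whole
  pipeline — including ~100 per-patient FEM solves — completes in minutes
  on one CPU while keeping every verification meaningful.
* The linear-elastic, isotropic disc without vertebrae is a deliberate
  simplification; anisotropic annulus fibre structure, disc–vertebra
  interaction and time-dependent degeneration are out of scope.
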