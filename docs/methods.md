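# Methods

`cranioplan` is a desk-scale re-creation of a surrogate-modelling pipeline
for spring-assisted cranioplasty (SAC): instead of hours-long patient-specific
finite-element runs, a regression model is trained on a corpus of simulated
surgeries and then predicts a post-operative head shape in milliseconds.
Because no patient imaging is deposited anywhere, every stage that would
normally consume CT scans or 3D photographs is replaced by a parametric,
fully seeded synthetic stand-in.  This note records the models, the
parameters that matter, and the design decisions taken where the problem
was genuinely open.

## Synthetic anatomy

The neurocranium is the upper half of an ellipsoid in a fixed anatomical
frame (x lateral, y anteroposterior with posterior negative, z superior;
base cut at z = 0, the nasion–tragion analogue).  The mesh is a structured
polar grid (default 50 × 40, ≈ 2000 vertices), so **every patient at one
resolution shares the template topology** and point correspondence holds by
construction — the property the statistical shape model needs.  Faces are
labelled frontal / parietal / occipital plus 2 mm coronal and lambdoid
suture bands placed at configurable fractions (defaults 0.30 and 0.85) of
the anteroposterior extent.

Patient parameters are drawn from truncated normals, deterministic in the
seed:

| parameter | distribution | source/rationale |
|---|---|---|
| skull thickness t_skull | N(2.02, 0.33) mm, > 0.5 | published cohort statistic |
| skin thickness t_skin | N(3.42, 0.51) mm, > 1 | published cohort statistic |
| age at surgery | N(174, 35) days in [90, 300] | published cohort (5.8 ± 1.15 months) |
| common size factor | N(1, 0.05) | overall cranial size spread |
| per-axis shape residual | N(1, 0.025) per axis | inter-patient shape-ratio spread |
| elongation (severity) | N(1.15, 0.02), ≥ 1 | scaphocephalic narrowing |

Severity is volume-preserving: the anteroposterior semi-axis is multiplied
by the elongation e, the other two divided by √e, which divides the cranial
index (CI) by e^1.5 without changing intracranial volume.  A small (1.5%)
lateral *parietal-eminence bulge* peaking at 35% of the skull height makes
the widest cranial section sit above the base ring, as in real heads; on a
pure half-ellipsoid the maximum width would lie exactly on the
(simulator-fixed) base and no surgery could ever change the extent-based CI.

The size/shape split matters downstream: the pipeline removes the common
size factor by volume normalisation (below), and the residual spreads were
chosen so that after that normalisation the outcome-shape spectrum balances
anatomical and surgical variance — with much larger anatomical spreads the
94% variance rule would discard the surgical-deformation modes entirely and
the surrogate's inputs and outputs would carry no surgical signal.  The
synthetic anatomy is intrinsically low-rank (after volume normalisation it
is essentially two-dimensional, because elongation lies inside the
volume-preserving axis-ratio plane); real cohorts are far richer, so
passing tests here demonstrate the pipeline's mechanics, not clinical
coverage.

The osteotomy is laid out in surface coordinates measured from the centre
of the coronal suture: anterior notch pair at A·L, posterior pair at AP·L
along the midline arc, half-width LAT·L/2 to each side, with
L the midline arc length from the reference point to the lambdoid suture
and (A, AP, LAT) ratios bounded to [0.18, 0.30], [0.47, 0.63],
[0.10, 0.25].  Arc length (surgical tape-measure practice), not chord, is
used throughout.  The rectangle is marked, not removed: the simulator
softens it.  Four 5 mm notch marks sit at its corners.

## Spring-distraction simulator

The Ansys viscoelastic FEM of the original workflow is deliberately
replaced by a deterministic quasi-static shell solve that preserves its
interface (springs as stiffness + free length, fixed base, bonded regions)
and produces a smooth shape-to-shape map in ~50 ms:

minimise E(u) = ½ uᵀ K u − fᵀ u,  K = α(L_w + b·L_w²) + βI, u = 0 on the base ring,

where L_w is the edge-weighted graph Laplacian of the skull mesh (the three
coordinates decouple), the squared term is plate bending, and edge weights
soften the suture bands (1/10 of bone) and the excised osteotomy strip
(1/50).  The bending term is essential, not cosmetic: a pure membrane
Laplacian has a log-singular point-load response, so all displacement piles
onto the loaded vertex and the vault never widens.  With bending the
response is plate-like — each parietal side rotates outward about the
base/suture hinges.

Springs are Hookean and push-only: F = k·(L0 − x) for opening x < L0, zero
beyond (the clinical distractors have a 60 mm free opening).  Forces act as
equal-and-opposite pairs at the bone vertices lateral of the cut (the strip
itself is excised and carries no load), directed along the initial lateral
separation.  Spring force and opening are coupled by a damped fixed-point
iteration (relaxation 0.3, tolerance 1e-4 mm, ≤ 100 iterations); the inner
problem is linear with a cached sparse factorisation, so each extra
iteration is three triangular solves.

Numerical defaults: α = 0.023 N/mm at the reference age (174 days), scaled
linearly with age (older = stiffer — the form is invented, the sign follows
the reported error–age correlation), bending b = 100, Tikhonov anchor
β = 1e-3.  α was set so the condensed tissue stiffness seen by a spring
pair is ≈ 1 N/mm, giving openings of roughly 28–54 mm across the catalogue
— the clinically observed range — and a deformation spread the shape model
can retain.  The spring catalogue (k ∈ {0.5, 1.0, 1.5} N/mm, L0 = 60 mm)
is a **placeholder**: the per-model constants of the clinical springs are
not published.

Contracts verified in tests: displacement exactly zero on the base ring,
relative solve residual < 1e-8, zero-force limit, linearity of the inner
solve, equality of reported opening and post-hoc notch distance, agreement
of the condensed scalar system with the closed form x* = kL0/(k+c), CI
strictly increasing for every valid configuration and non-decreasing in
spring stiffness.

## Design of experiments

Per patient, round(N(80, 2.5)) clipped to [75, 85] configurations:
osteotomy ratios from truncated normals centred mid-range with
SD = range/4 (≈ 95% of the untruncated mass in-bounds), spring model per
site uniform over the catalogue, configurations with AP ≤ A redrawn.  A
Latin-hypercube option exists for space-filling coverage.  Everything is
deterministic given the seed; per-patient seeds are derived from the master
seed so a corpus can be extended without reshuffling existing patients.

## Correspondence

Meshes from the synthetic pipeline share topology, so correspondence is
the identity.  For external meshes the package provides rigid ICP
(Kabsch/Umeyama updates with a safeguarded point-to-plane step — accepted
only when it lowers the RMS residual, which keeps the recorded residual
sequence monotone while escaping the tangential-sliding stalls
point-to-point ICP suffers on smooth head-like surfaces) followed by
Amberg-style non-rigid ICP (per-vertex affine transforms, decreasing
stiffness schedule, default {10, 2, 0.5, 0.1, 0.02} × 20 inner
iterations).  The NRICP result always has the template's exact vertex and
face count.  No landmarks are used.

## Statistical shape modelling

Shapes are vectorised as (x1, y1, z1, …) and modelled as m = m̄ + Φb with
orthonormal modes Φ from the eigendecomposition of the sample covariance
(divisor n − 1), computed via thin SVD of the deviation matrix — with
n ≪ 3N this is the only sane route, and it is verified against the dense
covariance eigendecomposition in tests.  Mode signs are fixed by making
each mode's largest-magnitude entry positive.  The retained mode count is
the smallest k whose cumulative explained variance reaches the threshold
(default 0.94 for both the pre-operative and the outcome model).  Separate
models are fitted to the 30 pre-operative shapes and to all simulated
outcome shapes.

Before modelling, every shape is **volume-normalised** to the
population-mean skull volume (per-patient factor, shared between a
patient's pre-operative and simulated shapes, inverted at prediction
time).  This applies the pipeline's own unchanged-volume assumption — the
same one used to rescale follow-up scans — systematically: without it the
overall-size mode swamps the spectrum and the 94% rule retains nothing
else.  An optional generalised-Procrustes step exists but is off by
default (the synthetic shapes are construction-aligned).

## Surrogate regression

One row per simulated surgery: age (days), A, AP, LAT, anterior and
posterior spring stiffness and free length (8 features), plus the
pre-operative mode coefficients b_in; targets are the outcome mode
coefficients b_out.  With eleven retained modes on each side this is the
published 30-column layout; on the synthetic corpus the retained counts
are smaller (typically 2 and 3) because the anatomy family is low-rank.
Rows are split 0.33 to test; features **and targets** are standardised
with train-set statistics only, so the reported MSE/MAE are on the
standardised mode scale (whether the original figures are on that scale is
not stated anywhere; this choice is documented, not asserted).  Constant
columns (the shared 60 mm free length) are left centred and flagged.

Seven families are supported — linear regression (baseline), decision
tree, random forest, XGBoost, SVR, gradient boosting, AdaBoost — with
per-output wrapping where a learner is not natively multi-output.
Screening discards families below the baseline's mean 5-fold CV R² or with
fold-to-fold SD above 0.10.  Hyperparameter tuning is sequential
model-based (Bayesian) optimisation at a fixed budget of 50 evaluations ×
5 seeded folds: a seeded random warm-up, then a Gaussian-process surrogate
of the mean CV R² (Matérn 5/2 + white noise on [0,1]-scaled numerics and
one-hot categoricals) proposing each next configuration by expected
improvement over random candidate draws.  Guidance matters here: the SVR
space puts ε uniform on [0, 5] while useful configurations need ε near
zero, so pure random search (available via ``method="random"``) rarely
lands in the good region within the budget.  The XGBoost space drops the
`sampling_method` knob (its non-default value requires GPU training) and
keeps booster/eta/gamma/max_depth.

## Prediction and validation

For a new head mesh: inward offset by t_skin to a synthetic skull →
template correspondence (identity or NRICP) → volume normalisation →
projection to b_in → feature assembly and scaling → surrogate → b_out →
reconstruction → inverse volume scale → outward offset by t_skin.
Validation compares surfaces after volume-matching the reference
(isotropic rescale to equal volume — removing growth under the
unchanged-volume assumption) using exact point-to-triangle distances in
both directions; correlation analysis reports Pearson r (with two-sided p,
unthresholded) of per-case mean error against age, pre-operative CI and
spring stiffnesses.

The clinical validation numbers of the original study (2.70 ± 0.58 mm
against follow-up 3D photographs, and the associated correlations) depend
on undeposited patient data and are **not** reproducible here; validation
is simulator-held-out instead.

## Problem sizes and determinism

The default study is 30 patients × ~80 configurations (≈ 2400 simulations)
at ≈ 2000-vertex meshes — about 2.5 minutes for corpus generation and
under a minute for tuning on one CPU.  The determinism contract (identical
master seed ⇒ byte-identical dataset CSV and identical report JSON) is
exercised at a 3-patient smoke scale, since it is scale-independent.  All
randomness flows from explicit seeds through `numpy.random.default_rng`;
no global state is touched.

## Known limitations

- The simulator is a calibrated caricature: linear, quasi-static, no
  viscoelastic creep over the distraction weeks, no suture tearing, no
  brain/dura loading, placeholder spring constants.
- The anatomy family has no frontal bossing, fontanelles or basicranium,
  and its low rank makes shape-model mode counts smaller than on real
  cohorts.
- Extent-based CI is sensitive only to the widest section; simulated CI
  gains (tenths of a point) are far smaller than clinical corrections.
- Extrapolation outside the spring catalogue (e.g. the zero-force limit)
  carries ~1 mm error — the design of experiments contains nothing softer
  than 0.5 N/mm, and no regressor can recover a saturating force law from
  three design points.
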