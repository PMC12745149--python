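# Methods

This note documents the models and procedures implemented in `lvatlas`, the
assumptions behind them, the synthetic data they are exercised on, and the
numerical conventions that matter for reproducing results.

## Shape representation and derived measures

An exam is an `LVShape`: `P` template-corresponding 3D points (mm) at
end-diastole (ED) and end-systole (ES), a shared triangulation of the
endocardial and epicardial surfaces each closed by a basal cap fan, and two
landmarks (endocardial apex point; ordered mitral-ring point set). All
statistical machinery operates on the flattened shape vector, the ED block
concatenated with the ES block (length `2·P·3`). Endocardial point `i`
corresponds to epicardial point `i + P/2`, so per-point wall thickness is the
distance between the pair; this relies on template correspondence and avoids
the ambiguities of normal-ray thickness measures.

Derived measures are computed entirely from the mesh and are pose-invariant:

* **EDV, ESV** — closed-endocardial-surface volumes by the divergence theorem
  (signed tetrahedron sum; the surface must be watertight and consistently
  oriented, otherwise the offending edge is named in the error).
* **mass** — 1.05 g/mL × ED myocardial shell volume (epi minus endo). The
  density is the standard CMR convention.
* **EF** = 100·(EDV−ESV)/EDV and **MVR** = mass/EDV hold exactly as algebraic
  identities of the returned values.
* **L** — apex to mitral-centroid distance, per frame; **LS** =
  100·(L_ED−L_ES)/L_ED.
* **SphVi** — cavity volume divided by the volume of the sphere whose
  diameter is L, per frame. The name denotes a volume-based sphericity index;
  this concrete formula is our choice, exposed per frame.
* **RWT (ED)** — 2 × mean inferolateral wall thickness / mid-cavity internal
  diameter (twice the mean radial distance of mid-third endocardial points
  from the long axis), an echo-convention analogue defined at ED.
* **AHA-17 map** — long-axis thirds (basal/mid/apical, 6/6/4 circumferential
  sectors) plus an apical cap (segment 17, lowest 12% of the axis). The
  circumferential zero is the template's septal reference: mitral-ring point
  0, with handedness fixed by the ring ordering, so the assignment is
  invariant under rigid motion of points and landmarks together. Sector
  boundaries are nudged by 1e-6 degrees so grid points lying exactly on a
  boundary bin identically under rigid motion despite roundoff.
* **Regional thickening** — 100·(WT_ES−WT_ED)/WT_ED per segment, from
  segment-mean wall thicknesses of the endocardial points' segments.

## Template

The synthetic template is a truncated prolate spheroid: endocardial ellipsoid
(semi-axes 26, 26, 52 mm), epicardial surface offset by an 8 mm wall, both
truncated by the basal plane at half the long semi-axis and closed by cap
fans; the ES frame contracts the cavity (radial ×0.66, long-axis ×0.87) and
thickens the wall ×1.35. Defaults give EDV ≈ 123 mL, EF ≈ 62%, mass ≈ 114 g,
LS ≈ 13%, mean thickening ≈ 35% — a healthy mid-range LV. The default
resolution is 781 points per surface (1562 total); doubling the resolution
changes volumes by <1%, so reduced-resolution templates (301/surface) are
used in simulations where runtime matters, a choice recorded alongside each
study size below.

## Alignment

Generalized Procrustes analysis is rigid by default (a similarity option
exists, but size is a remodeling signal and is deliberately not factored
out). Alignment is always driven by the ED frame and the same transform is
applied to ES, so contraction-related ED/ES differences survive alignment.
The GPA loop re-estimates the mean until it moves <1e-6 mm RMS (max 100
iterations); the objective (sum of squared distances to the mean) is
non-increasing, which the tests assert.

## Protocol bias correction

The baseline exam is GRE, the follow-up SSFP; SSFP systematically shows a
larger cavity and smaller mass. From same-session GRE/SSFP pairs: GPA on the
GRE shapes; PCA on the aligned GRE vectors keeping the smallest basis
covering `variance_keep` (default 0.95) of variance; each SSFP shape inherits
its pair's GRE transform; both protocols are scored in the GRE basis, *each
about its own training mean*; PLSR (rank chosen by internal leave-one-out
over 2..min(20, K) unless fixed) maps GRE scores to SSFP scores.

Correcting a new GRE shape aligns it to the model reference, maps its scores,
reconstructs about the SSFP training mean, and adds back the residual
orthogonal to the basis. Two consequences, both deliberate: the mean
protocol offset is applied in full (including its component outside the PCA
basis — scoring both protocols about the GRE mean would silently truncate
it, leaving a zero-noise constant bias uncorrectable), and subject-specific
detail outside the basis is never edited. A protocol flag guards against
double correction. ED/ES frame-timing harmonization between protocols is out
of scope; synthetic data has exact frames.

## Trajectories, transport, atlas

A remodeling trajectory is the follow-up minus (bias-corrected) baseline
shape vector, computed after GPA-aligning all baselines; each follow-up
inherits its subject's baseline transform, so pose never pollutes the
difference — this assumes both exams share a subject coordinate frame, which
the generator reproduces by posing both exams identically. Transport to the
common reference is linear shift — plain vector addition onto the mean
baseline shape — valid when shapes are close enough to share a tangent
space; no curved-manifold machinery is used. Transport makes the trajectory
scores exactly independent of baseline inter-subject variance when baseline
variation does not re-rotate the GPA alignment (pure size variation is the
exact case; the acceptance check scales baseline variance ×10 and asserts
z-scores change by <1e-6).

The atlas is PCA of the transported shapes: components sorted by decreasing
variance, numerically-null trailing components dropped (explained variance
below 1e-10 of the leading one — their near-zero score SDs would amplify
roundoff into meaningless z-scores). Component signs are fixed by requiring a
positive dot product with a fixed seeded random reference vector; a
largest-loading-positive rule was tried first and flips under roundoff on
rotationally symmetric templates where loading magnitudes tie. Scores are
z-scored by the training-score SDs, so the training cohort has mean 0, SD 1
per component; downstream consumers truncate at a variance fraction (0.99 by
convention).

## Risk labels and model comparison

Seven binary factors: obesity (BMI > 30), high cholesterol (total > 240 or
LDL > 160 or HDL < 40 or triglycerides > 150 — the thresholds chain with
"or" by default since requiring all four simultaneously is clinically
implausible; an "all" toggle exists), hypertension (diagnosis, or SBP > 140
and DBP > 90; "or" toggle for the blood-pressure clause), smoking at
follow-up, diabetes (diagnosis or impaired fasting glucose), hypertension
medication, statins. A subject is positive if the factor is present at
follow-up, negative if absent at both exams, excluded otherwise (remitted
cases fit neither definition); missing fields exclude a subject for that
factor only.

The comparison trains, per response (each factor, plus sex adjusted for age
only), two elastic-net logistic regressions — Atlas scores vs
ΔEDV/ΔESV/Δmass/ΔEF, both plus sex and baseline age — on ten stratified
80/20 shuffle splits ("ten-fold cross validation at 80/20" is not standard
k-fold; shuffle splits match the stated design literally). Fold seeds are
shared between models, so accuracies are paired. Hyperparameters (mixing
parameter on {0, 0.1, …, 1.0}; regularization strength log-uniform over
[1e-4, 1e2], i.e. C in [1e-2, 1e4]) are tuned by 50-draw randomized search
in an inner stratified 5-fold CV maximizing balanced accuracy; features are
standardized inside each training split only. Balanced accuracy is the mean
of per-class recalls (implemented directly; cross-checked against
scikit-learn). Models are compared by a paired two-sided t-test over the ten
fold-wise differences, Bonferroni-corrected across the responses tested; a
degenerate test (zero-variance differences) reports p = 1 for identical
models and p = 0 for a constant nonzero gap. Factors with fewer than 40
labeled subjects or fewer than 10 per class are skipped with a logged reason.

## Remodeling modes

Each retained score component is regressed by OLS on a shared design:
baseline age, BSA change, SBP, DBP, BMI, HDL, LDL (continuous, taken at
baseline, standardized so coefficients are per-SD effects), race/ethnicity
dummies (white reference), sex, and the binary factors (follow-up presence
indicators). The OLS is vectorized across components; standard errors come
from the shared `(XᵀX)⁻¹` and per-component residual variance (cross-checked
against statsmodels). A rank-deficient design raises with the collinear
columns named.

Factor f's remodeling mode is `Δs = delta · Σ_m β_fm σ_m v_m` — the
coefficient row propagated back through the atlas, all other predictors at
reference. This equals the difference of model-predicted transported shapes
at factor = 1 vs 0 (asserted as an oracle test). Binary factors are reported
at delta = 1 (present vs absent), continuous ones at +1 SD; output headers
state the contrast. Global summaries apply the mean trajectory with and
without the mode to the mean baseline shape and report measure differences
as percent of the baseline value; regional summaries report per-segment
thickening differences in percentage points. Entries with |value| ≤ SEM
(per-measure SD of subject-level percent changes / √n) are masked,
mirroring the convention of reporting only above-SEM effects. Displacements
are exactly linear in delta; measure deltas are first-order linear (small
deformations).

## Synthetic cohort

The generator emulates the data structure the analysis assumes, with planted
truth retained for parameter recovery:

* **Baseline variation** — four global modes (size SD 4%, long-axis length
  SD 3%, wall thickness SD 0.8 mm, sphericity SD 2%), giving EDV spreads in
  the ±15–20% range of population cohorts.
* **Aging drift** — mild concentric remodeling per decade (endo scaled in
  1.35%, epi 0.55%): EDV ≈ −4%, mass ≈ +1% over 10 years.
* **Risk effects** — per-factor displacement fields scaled so each factor's
  global deltas sit at the few-percent decade scale of adjusted longitudinal
  risk analyses (e.g., obesity mass +3%, smoking EDV −4.8%). Effects enter as
  `effect_f · x_if` with `x_if` the follow-up label indicator; the cohort
  mean change is therefore drift plus prevalence-weighted effects (EDV ≈ −6
  to −8%, mass ≈ +5%), somewhat stronger than the drift alone — matching
  both the per-factor effect scale and the marginal means simultaneously
  would require centering the effect terms, which the simulate contract does
  not do.
* **Noise** — spatially smooth random fields: 60 unit-RMS low-order Fourier
  fields over the surface parameters, with coefficients scaled so the
  per-coordinate noise SD is `noise_sd` (default 0.5 mm). Smoothness is the
  realistic feature: segmentation/model-fitting errors are spatially
  correlated, and they give the shape PCA the decaying spectrum on which the
  "components covering 99% of variance" rule yields a compact feature set.
  An iid option exists for null/property tests.
* **Protocol bias** — optional constant field (endo outward 1 mm, epi inward
  0.6 mm: SSFP-vs-GRE direction) subtracted from observed baselines, which
  are then labeled GRE; plus smooth bias noise.
* **Covariates** — distributions and exam-to-exam transitions matching a
  large multi-ethnic cohort: age 59.6 ± 9.4 at baseline (+10 at follow-up),
  54.3% female, four race/ethnicity groups, BMI 27.7 ± 4.8 (obesity ≈ 0.3),
  smoking 10.5% → 7.1%, hypertension diagnosis 37.8% → 57.1%, statins
  13.4% → 35.1%, treated/untreated diabetes ≈ 17% at follow-up, and so on.
  Transitions are one-step Bernoulli draws; no within-decade dynamics.
* **Pose** — one random rigid pose per subject (≤5° rotation, ≤5 mm
  translation) applied to both exams; the exam interval is fixed at 10 years.

Everything is reproducible from `(config, seed)` via spawned generator
streams; the truth bundle stores mode coefficients, planted fields, labels
and the seed.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: image acquisition and segmentation, real
anatomical shape statistics (the template is an idealized spheroid and its
rotational symmetry is atypical), nonlinear or regionally heterogeneous
protocol bias, covariate-shape confounding beyond the planted linear
effects, attrition, and frame-timing variability between protocols.

## Validation study sizes

The acceptance checks (tests and `scripts/acceptance.py`) run at the sizes
their claims require while keeping the template at 301 points/surface (the
<1% resolution-stability result above justifies this as a pure runtime
choice): transport identities at n = 60; atlas recovery at n = 500 (the
planted-field cosine is computed in the template frame, since GPA leaves an
atlas in an arbitrary mean orientation that would rigidly rotate components
against the planted field); bias leave-one-out at n = 100 pairs; association
at n = 500 planted / n = 400 null with the full 50-draw search; mode
recovery at n = 500 with each planted field scaled to the displacement-noise
norm (SNR 1, defined as field norm over expected noise-difference norm). The
volume-neutral effect used in the association check is a cos(2θ) endocardial
pattern whose second-order EDV/ESV/mass residuals are removed exactly by a
three-knob Newton solve, so the Mass-Volume feature set is uninformative by
construction.

## Known limitations

* Linear-shift transport and linear mode reconstruction assume small
  deformations; strongly remodeled ventricles (e.g., overt heart failure)
  violate the shared-tangent-space premise.
* The bias correction is only as representative as its paired training set;
  it edits the modeled subspace plus the mean offset and cannot fix biases
  that appear only in directions absent from training variation.
* Wall thickness by corresponding-point distance depends on template
  correspondence quality; it is exact on synthetic data but an approximation
  on fitted models.
* The AHA-17 circumferential reference is the mitral-ring point ordering, a
  template convention standing in for anatomical RV-insertion landmarks.
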