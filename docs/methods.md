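# Methods

`glauprog` analyses the longitudinal structure–function relationship in
glaucoma: how progressive thinning of the circumpapillary retinal nerve
fiber layer (cpRNFL, measured by OCT circle scans) relates to progressive
loss of visual-field sensitivity (standard automated perimetry, 24-2).
This note documents the models, the conventions and numerical choices, and
what the synthetic cohort does and does not emulate.

## Data model

A cohort is a set of patients, each contributing one or two eyes; each eye
contributes four or more paired visits.  A visual-field exam carries the 52
non-blind-spot 24-2 thresholds and total deviations (dB), summary indices
(MD, PSD) and reliability proportions.  An OCT record carries 768 thickness
samples (µm) along the 3.46 mm circle, plus the signed fovea–optic-nerve-
head-centre angle.  All angular quantities use one canonical frame: 0° at
the temporal meridian, increasing through superior, right-eye orientation;
sample *k* is centred at (k + 0.5)·360/768°.  Left-eye data are mirrored
into this frame (field x negated; profile order reversed about the temporal
meridian; the fovea–ONH angle keeps its sign, being defined against the
horizontal in either eye).

## Sector maps

A structure–function map pairs a partition of the 52 field points into
named field sectors with a partition of the circle into half-open disc
arcs, plus a correspondence linking each field sector to the disc sector
its nerve fibers enter (field and retina are inverted in both axes, so the
inferior–nasal field corresponds to the superotemporal disc).  Maps ship as
editable CSV files:

* `spectralis6` — the instrument's standard six disc sectors
  (T 315–45°, TS 45–90°, NS 90–135°, N 135–225°, NI 225–270°, TI 270–315°),
  no field partition;
* `garway_heath` — six field sectors with the classic arcs (temporal
  311–40°, 40/80/120/230/270/311° boundaries).  The per-point grouping is
  reconstructed from the map's anatomical logic; because the original
  figure is not reproducible in open form the file is explicitly editable,
  and correcting a point's sector requires no code change;
* `nakanishi` — a map whose arc boundaries rotate per eye by
  (fovea–ONH angle − reference), reference −7° by default.  The shipped
  point grouping is a synthetic placeholder with the published map's
  structure.

Sector values are arithmetic means: of the µm samples inside an arc (plus
a `global` mean over all 768), and of the field values inside a field
sector.  Field averaging has two modes, because it is genuinely contested
whether perimetric values should be averaged on the logarithmic scale:
`geometric_db` (arithmetic mean of dB, i.e. a geometric mean of linear
sensitivities — the conventional summary) and `arith_antilog` (convert each
point to 1/Lambert via 1/L = 10^(dB/10), average, report in dB).  By the
AM–GM inequality the antilog mean always weakly dominates the conventional
one.  Ties at arc boundaries are resolved by the half-open convention.

## Scale transforms

Sensitivity: dB = 10·log₁₀(1/L).  Thickness: LogRNFLT = 10·log₁₀(µm).
Thickness below 1 µm is clamped (with a warning) before the logarithm:
pathological sectors can reach single-digit µm and a segmentation zero must
not produce −∞.  Both conversions are strict monotone bijections with
round-trip error ≤ 1e-12 relative.

## The longitudinal model

Each outcome series (one sector, scale, averaging mode) is fitted with a
linear mixed model with random intercepts and slopes at two nested levels,

    Y_ijt = β₀ + β₁·t + ζ₀j + ζ₁j·t + ζ₀i|j + ζ₁i|j·t + ε_ijt,

subject *j*, eye *i|j*, time *t* in years since the eye's first exam.  No
further covariates enter.  Estimation is REML by default (ML available),
through statsmodels MixedLM: subject-level 2×2 covariance unstructured
(optionally diagonal), eye-level intercept and slope variances as
independent components (an unstructured eye-level block is not expressible
there; the practical effect on fixed effects is in the second decimal).
Per-eye baselines and rates are best linear unbiased predictors,
β + subject effect + eye effect.

Numerical choices, each exact or conservative:

* **Response standardization.**  The response is centred/scaled before
  optimization and results are mapped back; (RE)ML is exactly equivariant
  under this affine map.  The reported criterion includes the Jacobian
  correction.
* **Time centring.**  Random effects are parametrized at the mean
  follow-up time, where intercept and slope estimates are orthogonal for
  balanced designs, and mapped back to the baseline origin afterwards.
  For the unstructured covariance this is an exact reparametrization.  The
  diagonal constraint is *imposed in the centred parametrization*: imposing
  independence at t = 0 would make the model depend on the arbitrary time
  origin, and in the centred frame the familiar shrinkage ordering (each
  BLUP slope weakly between β₁ and the eye's own least-squares slope,
  balanced single-eye designs) holds exactly, which it provably does not at
  an uncentred origin.
* **Starting values and optimizers.**  Method-of-moments starts from the
  per-eye OLS coefficient covariance; BFGS first, then L-BFGS and CG, then
  a diagonal fallback, logging any fallback.  Without good starts the
  quasi-Newton optimizers occasionally report convergence at a poor local
  optimum.
* **Degenerate input.**  If the pooled per-eye OLS residual is numerically
  zero (relative 1e-10), the exact σ²→0 limit is returned directly: BLUPs
  equal the per-eye OLS lines, fixed effects are means of subject-mean
  coefficients, covariances are the empirical moments.  Boundary
  optimization in this regime is ill-posed and only approaches this limit.

## Correlation analysis

For each map, value kind (threshold / total deviation), averaging mode,
field scale (dB or 1/L) and thickness scale (µm or LogRNFLT) — the 4 × 2
variant grid — and separately for baselines and slopes, per-eye BLUPs are
correlated across modalities cell by cell (field sector × disc sector,
Pearson).  Cells with a constant vector are *undefined* (NaN), never 0, so
they cannot bias rank tests.  Strength labels: |r| < 0.4 weak, < 0.7
moderate, else strong (configurable).

Corresponding vs non-corresponding cells are compared with a Wilcoxon
signed-rank test, pairing each field sector's corresponding-cell r against
the mean of its non-corresponding cells (a pooled rank-sum alternative is
provided, since the pairing is a genuine design choice).  The signed-rank
null distribution is exact for n ≤ 25 — a subset-sum dynamic program over
doubled midranks, so tied magnitudes are handled exactly — and a
tie-corrected normal approximation beyond.  Variant-grid contrasts
(antilog vs conventional averaging; nonlinear vs linear scales) use the
same test two-sided over matched cells.  No multiplicity correction is
applied across the grid.

## Synthetic cohorts

The generator emulates a progression cohort at a realistic scale: 100
patients with 31% contributing both eyes (≈131 eyes), follow-up ≈3.7 ± 0.95
years, visits every ≈0.5 years (at least four per eye), baseline MD
−6.20 ± 4.34 dB, baseline global cpRNFL 68.5 ± 11.6 µm, rates
−0.30 ± 0.40 dB/y and −0.95 ± 1.0 µm/y, fovea–ONH angle −7.63 ± 4.04°.

Latents are hierarchical Gaussians: each baseline/slope is a subject-level
plus eye-level component, 30% of variance at the eye level by default.
Structural and functional latents are correlated (ρ = 0.6 default) at both
levels, so the total per-eye structure–function correlation equals ρ; the
same ρ couples the baselines.  Focal progression is emulated by per-sector
slope deviations (0.5 µm/y and 0.15 dB/y SD by default), correlated ρ
within corresponding sector pairs — this is what makes corresponding cells
correlate more strongly than non-corresponding ones downstream.

Profiles are a smooth two-harmonic TSNIT base curve (double hump, nasal
trough; coefficients frozen to reproduce the relative sector pattern of a
moderate glaucoma cohort) scaled to the eye's baseline global thickness,
declining linearly in time, with optional wedge-shaped defects (off by
default so sector trajectories stay exactly linear).  Observation noise is
one Gaussian per visit per standard arc, shared across the arc's samples,
so any sector mean carries the configured noise SD (2 µm).  Thickness is
clamped to [1, 299] µm.

Visual fields are linked to structure on the linear-sensitivity scale:
at baseline, each field sector's 1/L equals a·max(T − b, 0) for the
corresponding disc sector's thickness T, gain a = 6.5 (1/L)/µm and floor
b = 30 µm (the glial/vascular remnant; thickness never falls below ≈30 µm
even in absolute field loss).  A closed-form per-eye dB offset calibrates
the implied mean deviation to the eye's drawn baseline MD, preserving the
structural coupling while honouring the configured MD moments.  Sensitivity
then declines linearly *in dB* at the eye's functional slope — a
thickness-linear drive would make the dB trajectory convex and bias naïve
slope recovery by ≈0.05 dB/y over 3.7 years, whereas the observed MD decay
over such windows is adequately linear.  The latent "functional thickness"
(the inverse link of the sector's dB trajectory) is stored per eye, so the
link identity holds exactly at every visit.  Per-point Gaussian noise
(1.8 dB) is added and negative sensitivities clamp to 0 dB; total deviation
uses a flat 30 dB age-normal reference.

What the generator does **not** emulate — hence what green tests do not
show about real data: instrument segmentation error and media opacity,
perimetric learning and fatigue effects, non-Gaussian and
eccentricity-dependent perimetric noise, treatment-induced slope changes,
the cpRNFL floor effect as a nonlinearity in time (the floor enters only
through the static link), spatially smooth point-level field loss within a
sector, and visit-time correlation between the two modalities beyond
shared scheduling.

## Pipeline

`run_pipeline` chains simulate/load → sectorize → transform → fit →
correlate → report.  Reading applies the reliability rule (fixation loss
< 20%, false-negative < 33%, false-positive bound configurable, default
< 33% since the printed rule is ambiguous about whether the false-positive
bound shares the 33% threshold) and drops eyes with fewer than four
surviving exams; exclusion counts satisfy rows_in = rows_used +
rows_excluded in the machine-readable run log.  1536-sample profiles are
accepted and pair-averaged to 768.  An optional `is_first_lifetime_test`
flag supports removing a subject's first-ever field test (learning
effect); it is off by default because lifetime history is usually absent.
All randomness flows from one seed; reruns are byte-identical except the
run-log timestamp.

Problem sizes in the test suite (chosen to keep the full suite in the
tens of minutes on one core): study-scale checks use 100-subject cohorts;
replicate-based checks use 200 replicates for coverage/bias of β₁ and 100
replicates for slope-correlation recovery against a 1000-rep Monte-Carlo
oracle; exhaustive checks (arc rotation, signed-rank enumeration) run at
their natural full size.

## Known limitations

* The eye-level random-effect covariance is diagonal (library constraint);
  subject-level off-diagonals absorb most of the difference.
* The Garway-Heath point grouping and the entire Nakanishi grouping are
  reconstructions shipped as editable data, not verbatim reprints of the
  source figures.
* The generator's functional channel shares one slope per field sector;
  point-level spatial structure within sectors is absent.
* Confidence intervals are Wald-type (normal); coverage is validated by
  simulation at study scale but small-cohort inference should prefer
  profile or bootstrap intervals.
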