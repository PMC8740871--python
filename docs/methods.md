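# Methods

`morphodim` implements a 2D landmark geometric-morphometrics pipeline for
quantifying facial and body sexual dimorphism, together with a calibrated
synthetic-cohort generator that stands in for the unpublished field data
(305 Maasai adults, 185 men and 120 women, aged 17–90). This note records
the models, the parameter choices, and the design decisions that were
genuinely open.

## Landmark scheme and coordinate conventions

A face is an ordered configuration of 71 points: 37 fixed anatomical
landmarks and 34 semilandmarks covering the facial outline, the eyebrows
and the lip vermillion borders. The bundled scheme
(`data/default_scheme.yaml`) names the classical soft-tissue points
(glabella Gl, nasion N, subnasale Sn, labiale superius/inferius Ls/Li,
stomion Sto, gnathion Gn; paired zygion Zy, gonion Go, cheilion Ch, alare
Al, exo-/endocanthion Ex/En, palpebrale superius/inferius Ps/Pi, and
eyebrow/philtrum anchors) and declares, for every point, its bilateral
pair or midline membership and — for semilandmarks — the neighbor triple
that defines its sliding tangent.

The exact 71-point template geometry is **a stand-in, not a
reconstruction**: no coordinate template is published for the original
configuration. The bundled template is laid out so that the twelve index
ratios match the published young-adult male means wherever those are
mutually consistent (the mandibular index is over-determined by the
fWHR/cheekbone constraints and comes out 2.49 instead of 2.55).

Raw digitized coordinates are image pixels (y down); on read they are
multiplied by the record's SCALE (cm per pixel) and y-flipped, so all
downstream geometry is y-up in cm. Missing SCALE records are an error
unless an explicit fallback is supplied — index ratios are
scale-invariant, but centroid size is reported in cm and needs true
scale.

## Superimposition

Generalized Procrustes analysis: configurations are centered, scaled to
unit centroid size, and iteratively rotated onto an evolving consensus
until the consensus moves less than 1e-8 (root summed squared
displacement). Centroid size CS = sqrt(Σᵢ ‖xᵢ − x̄‖²) is recorded in cm
before scale removal. The final consensus is put into a canonical
orientation (principal axis vertical, third-moment sign rule), which
makes GPA output strictly invariant — not merely invariant up to rotation
— under similarity transforms of any input.

**Sliding semilandmarks.** Each semilandmark may move only along the unit
chord between its slider neighbors. The sliding amounts minimize the
thin-plate-spline bending energy of the deviation from the consensus
restricted to those tangent directions — a linear least-squares problem
per configuration, using the bending-energy matrix (the upper-left block
of the inverse TPS system matrix of the consensus; kernel U(r) = r² log
r²). Sliding is interleaved with GPA iterations, at most 5 rounds,
stopping early when the total energy change falls below 1e-8. The chord
tangent (rather than a spline tangent) is the simplest standard choice.
Total bending energy never increases: the zero-slide vector is always
feasible.

**Symmetrization.** Head pitch/yaw in 2D projections masquerades as
asymmetric shape variation, so configurations are symmetrized before
inference: reflect across the y axis, swap left/right labels, superimpose
the mirrored copy onto the original (reflection allowed — here it is the
point), and average. The average is then rotated so the midline
regression line is vertical and mirrored once more in that frame, making
paired points exactly symmetric and midline points exactly on the axis
(1e-9). The operation is idempotent. Whether the original analysis slid
before or after symmetrizing is unstated; the default order here is
GPA+slide → symmetrize → re-GPA, and both orders are available.

## Inference on shape

**Sequential PERMANOVA.** Shape dimorphism is tested with a sequential
(Type I) permutational MANOVA on the flattened aligned coordinates with
Euclidean distances. For a Euclidean response the distance-based
decomposition equals the projection decomposition, so each term's SS is
computed from an orthonormal basis of its design-matrix increment;
R² = SS/SS_total; pseudo-F uses the residual mean square of the full
model; p = (#{F* ≥ F} + 1)/(n_perm + 1) over permutations of the raw
observation rows (n_perm = 10 000 by default, seeded). This matches
`vegan::adonis2(..., method="euclidean", by="terms")`, which is verified
directly in a test. Term order matters and reproduces the study's models:
age before sex in the whole sample, BMI before sex per cohort.

**Repeatability.** Digitization agreement is the among-individual
variance fraction r = σ²_among / (σ²_among + σ²_error) from a one-way
multivariate variance decomposition over individual identity on jointly
superimposed replicate digitizations (balanced k per individual;
σ²_among = (MS_among − MS_within)/k).

**Allometry.** Shape-on-size regression per sex with size as natural log
centroid size (or body height), BMI optionally entered first, assessed by
the same sequential PERMANOVA machinery.

## Facial indices

Twelve dimensionless ratios computed from named landmarks of the
superimposed coordinates: four upper-fWHR variants (|Zy-Zy| over
|N-Sto|, |Gl-Sto|, |N-Ls|, |Gl-Ls|), total fWHR (|N-Gn|), lower fWHR
(|Sn-Gn|), cheekbone prominence (|Zy-Zy|/|Go-Go|), mandibular index
(|Go-Go|/|Sto-Gn|), nasal index (|Al-Al|/|N-Sn|), mouth shape
(|Ls-Li|/|Ch-Ch|), mouth-face index (|Ch-Ch|/|Zy-Zy|), and the mean
left/right eye height-to-width ratio (|Ps-Pi|/|Ex-En|). All distances
are Euclidean point distances, not axis projections (heights measured on
a tilted face would otherwise depend on orientation); this was an open
choice and is switch-free by design. Gl and N fall back to their
defining midpoints (medial-eyebrow midpoint; upper-eyelid midpoint) in
schemes that do not digitize them. Zero denominators yield NaN with an
explicit warning. Exactly 12 variables feed the Bonferroni correction in
the MANCOVA stages.

## Body statistics

* Sex contrasts: Student's t gated on Levene's test (mean-centered) at
  α = 0.05 — pooled-variance t with df = n₁+n₂−2 when variances are
  compatible, Welch/Satterthwaite otherwise. Effect size is Hedges' g =
  (x̄_m − x̄_f)/s_pooled · J, J = 1 − 3/(4df − 1): male minus female, so
  g < 0 whenever women exceed men.
* ANCOVA/MANCOVA: dv ~ BMI + trait with Type III SS for the trait;
  partial η² = SS_trait/(SS_trait + SS_res). With one covariate and one
  factor, Type III is stated explicitly because sequential SS would
  differ.
* Stepwise logistic (sex classifier): forward selection by Rao score
  test (p_enter = 0.05), removal by Wald p (p_remove = 0.10) — the
  "forward Wald" algorithm of the originating statistics package.
  Reported: coefficients, Wald p, likelihood-ratio model p, Nagelkerke
  (as "R²") and Cox–Snell pseudo-R², and apparent accuracy at the 0.5
  cutoff (in-sample, matching the published "predicts sex with 88%"
  reading).
* Stepwise linear (handgrip strength): forward F-to-enter, ties broken
  by larger F then input column order; deterministic given column order.
* Age trends: cubic least squares y ~ age + age² + age³ with the
  overall-model F p-value.
* Missing data: complete-case per analysis (this is why degrees of
  freedom differ between rows of the published tables).

## Synthetic cohort generator

The generator defines the study conditions; every quantitative check in
the package is a planted-vs-recovered experiment against it.

* **Design.** 305 subjects split 185:120 across three cohorts — young
  17–29 (72 M / 46 F), mid 30–50 (70/46), elderly 51–90 (43/28). The
  published figures give cohort totals (118/116/71) but not per-sex
  splits; the overall sex ratio is applied within cohorts. One figure
  labels the elderly cohort "51–65" while the sample extends to 90; the
  bounds are parameters, defaulting to 51–90.
* **Faces.** landmarks = template + sex shift + linear age trajectory +
  within-group BMI displacement + isotropic noise (sd 0.004 shape units
  per coordinate — a typical within-population Procrustes dispersion for
  faces; effect magnitudes are calibrated *relative* to it, so recovery
  results are insensitive to the exact value), scaled to the subject's
  facial centroid size and rigidly jittered. The sex axis encodes the
  published male pattern (narrower, vertically prolonged face, wider
  nose, lower brows, wider mouth, higher hairline); age and BMI axes are
  orthogonalized against it and against the similarity tangent space so
  superimposition cannot absorb planted signal.
* **Calibration oracle.** For a two-group shift m along a unit direction
  in isotropic noise, E[SS_between] = n₁n₂/n·m² and E[SS_total] =
  ΣSS_effects + (n−1)σ²·d_eff, with d_eff = 2k−4 = 138 because
  superimposition removes four similarity degrees of freedom from the
  noise. Each analysis-model degree of freedom additionally absorbs
  σ²·d_eff of noise SS into its sequential term; the planted magnitudes
  solve the joint system so every term's *expected sequential R²* equals
  its target (whole sample: sex 1.8%, age 6%; per-cohort sex 2/3/4%).
  Continuous effects use E[SS] = β²Sxx with realized Sxx. The oracle is
  validated against direct Monte-Carlo simulation in the tests.
* **BMI.** The planted BMI axis is driven by each subject's BMI
  *deviation from their sex-by-cohort mean*: the facial correlate of the
  between-sex BMI difference is part of the sex term, keeping the
  planted decomposition interpretable under the study's model orders.
* **Bodies.** Per-sex, per-cohort normals at the published means/SDs for
  height, BMI, handgrip, wrist diameter, circumferences, triceps
  skinfold and facial centroid size; weight is derived as
  BMI·(height/100)², which reproduces the published weight means to
  ≤0.2 kg in all four printed sex×cohort cells while keeping the BMI
  identity exact. Elderly body rows are not published; the mid-adult
  moments are reused. Parameters are independent within sex by default
  (no covariances are published); a correlation structure can be
  injected for stress tests.
* **Observer copies.** Two digitizations per face with isotropic noise
  whose variance is set from the realized among-individual shape
  variance so the population ratio equals the target repeatability
  (0.91), again budgeting for the 4 similarity dof the joint
  superimposition removes.

## What recovery runs do (and do not) show

Recovery experiments (`morphodim.experiments`, `scripts/acceptance.py`,
`analysis/07_recovery_experiments.py`) superimpose with **GPA only — no
sliding, no symmetrization**: the calibration oracle fixes the variance
decomposition of the coordinates handed to PERMANOVA, and sliding would
delete the tangential noise component of the 34 semilandmarks (and
symmetrization the asymmetric component), inflating recovered R² above
the planted value. The full reporting pipeline (`run_full`, the analysis
scripts) slides and symmetrizes as the original analysis did; on
synthetic data its R² values accordingly sit somewhat above the planted
raw-coordinate fractions, which is expected and not an error.

Replicate sizes: 50 replicates at n_perm = 999 for the PERMANOVA
recoveries, 200 for repeatability, 500 for the height effect size, 100
for the classifier — enough that replicate-mean standard errors are an
order of magnitude below the comparison tolerances.

Because body parameters are independent within sex, the synthetic
classifier is *more* accurate (~95%) than the published 88% (real
anthropometrics are positively correlated, which lowers joint
information); the published figure is treated as a lower benchmark. For
the same reason the default design plants no shape–size allometry and no
handgrip–body structure, so the allometry and handgrip stages of the
analysis scripts return null results on default synthetic data; the
allometry estimator itself is validated separately with an explicitly
planted 6% log-CS gradient at n = 136. None of the synthetic checks
speak to properties the generator does not emulate: real landmark noise
is anisotropic and spatially correlated, real faces have
integration/modularity structure, and real covariates are mutually
correlated.

## Numerical choices

* Iterative tolerances 1e-8 (GPA movement, sliding-energy change),
  overridable.
* Sliding systems are solved exactly; a singular system falls back to a
  ridge-regularized solve (logged), and energy non-increase is enforced.
* Permutation exceedance uses a 1e-9 relative slack so exact ties (e.g.
  complementary relabelings) count as exceedances despite float
  round-off.
* Reflections are disallowed in OPA (nearest proper rotation, flagged)
  except inside symmetrization, where reflection is the point.
* Stepwise ties break on larger statistic, then input column order.
* Degenerate inputs raise: all-coincident configurations (centroid
  size), duplicated TPS source points, constant predictors, zero pooled
  SD, single-observer repeatability, empty groups.
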