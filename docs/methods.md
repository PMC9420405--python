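# Methods

This note documents the statistical models implemented in `craniomorph`,
the conventions and numerical choices that were genuinely open, what the
synthetic-data generator does and does not emulate, and the package's
known limitations.

## Data model and preprocessing

A specimen is six strictly positive distances in mm — GOL, XCB, BBH for
the neurocranium and BPL, NPH, ZYB for the splanchnocranium — plus taxon,
group and age-class labels and optional body mass (kg), endocranial
volume (cm³) and geological age. Specimens missing any of the six
measurements are excluded from multivariate analyses rather than imputed;
complete-case analysis is likewise used for the BM/ECV associations.

All analyses work on base-10 logarithms. Two matrices are derived:

* the **log-raw matrix** `log10(x)`, input to the factor model;
* the **shape matrix** `log10(x / GM(x))`, the Mosimann log-shape
  variables with one geometric mean per cranium taken over all six
  variables jointly (not per block), so both modules are scaled to the
  size of the same specimen and remain comparable. Implemented as
  row-centering of the log matrix, which is algebraically identical and
  makes the row-sum-zero invariant exact to rounding (≤ 1e−10 in tests).

The fixed variable order is (GOL, BBH, XCB, NPH, BPL, ZYB) so loading
tables are comparable across runs. No within-group (pooled) centering is
applied anywhere: ordinations are fitted over all specimens jointly.

## Two-block PLS

The between-block association matrix is computed over column-centered
block data — cross-correlations by default, cross-covariances as an
option — and decomposed by SVD. The default is the correlation mode
because the magnitude of the leading singular value of a 3×3
cross-correlation matrix (bounded by 3) matches the scale on which such
analyses are conventionally reported, and because it makes block scores
unit-free; the covariance mode is retained for sensitivity analysis. In
correlation mode block data are column-standardized before scoring.
Scores of new specimens (fossils placed into a fitted space, perturbed
replicates) always use the *training* means and SDs.

Sign convention: SVD loadings are sign-indeterminate, so each dimension
is oriented to make the neurocranial loadings sum positive, flipping the
paired splanchnocranial vector with it. The between-block geometry
(including the sign of the score correlation) is therefore data-driven;
on two-module craniometric data the splanchnocranial loadings of
dimension 1 come out negative — a large face means a relatively small
braincase.

## Factor model

Eigendecomposition of the 6×6 Pearson correlation matrix of the log-raw
measurements (the eigenvalues then sum to 6, which is also how the model
is validated), with loadings `eigenvector · √eigenvalue` and factor
scores standardized to unit variance so loadings are variable–factor
correlations and communalities are bounded by 1. Factors are unrotated.

Orientation: factor I is signed so the neurocranial variables load
positively (high score = relatively large neurocranium); every other
factor is signed so its loadings sum positive (for the size factor:
bigger crania score higher).

The **isometry diagnostic** maps the unit isometric direction
(1,…,1)/√6 of log-measurement space into the factor plane with the
scoring transformation (standardize by training SDs, multiply by the
scoring-coefficient matrix `eigenvector/√eigenvalue`) and reports the
angle of the image to each factor axis, folded to [0°, 90°]. With two
retained factors the two angles sum to 90°. A small angle to one factor
certifies it as the size axis; the mapping through the scoring
coefficients (rather than the loadings) is our choice of convention and
is the one under which the angles behave as a partition of 90°.

## RMA trajectories and contrasts

Trajectory fits regress the **shape factor (I) on the size factor (II)**:
the RMA slope is the shape change per unit size along an ontogenetic or
evolutionary series. This orientation is what makes the two printed
summaries of a trajectory mutually consistent — the slope of the fitted
line and the juvenile→adult centroid angle measured from the +factor-I
axis (folded to [0°, 180°]), which relate by angle = 180° − atan(1/|slope|)
when the centroid vector runs along the line.

* Slope: `sign(r)·s_y/s_x`; a sample with r exactly 0 takes positive sign
  with a warning (unreachable on real data).
* Slope CI (default): the analytic interval
  `slope·(√(B+1) ∓ √B)`, `B = (1−r²)·F(0.95; 1, n−2)/(n−2)`.
  A seeded BCa bootstrap (2000 resamples, scipy's implementation) is the
  alternative and is the **default for intercept CIs**, where the
  sampling distribution is markedly asymmetric whenever |r| is small.
* Significance of r: two-sided t-test with n−2 df.
* **Slope contrast**: T = |ln|b₁| − ln|b₂|| / √(s₁² + s₂²) with
  s_i² = (1−r_i²)/n_i (the asymptotic variance of the log RMA slope) and
  effective degrees of freedom
  df = (s₁²+s₂²)² / (s₁⁴/(n₁−2) + s₂⁴/(n₂−2)), two-sided p from
  Student's t. Slopes of opposite sign are refused — the log-slope
  contrast is undefined across signs and the qualitative difference is
  the finding. The test's empirical size is verified by simulation in
  the suite: 2000 replicate pairs with equal true slopes at n = 50 give
  a rejection rate within [0.035, 0.065] at α = 0.05.
* Intercept comparison is by overlap of the 95% intervals — conservative,
  but it is the form in which such contrasts are conventionally reported.

## Heterochrony decomposition

Given a reference trajectory (an RMA fit plus its ontogenetic polarity,
the juvenile→adult direction along the line), a target centroid is
decomposed by orthogonal projection into

* `along` — signed displacement along the line from the reference
  centroid: beyond the reference adult state ⇒ **peramorphic**, short of
  it ⇒ **paedomorphic**, within a dead-band (default 0.1 score units) ⇒
  no call. The dead-band exists because these labels are qualitative in
  origin; making them threshold-based makes them testable, and the
  threshold is configurable and always reported.
* `offset` — signed perpendicular displacement: **transposed** when
  |offset| exceeds the reference line's 95% prediction-band half-width at
  the target's along-coordinate,
  h(t) = t₀.₉₇₅,ₙ₋₂ · s⊥ · √(1 + 1/n + t²/((n−1)·v∥)), where s⊥ and v∥
  are the perpendicular residual SD and along-line variance of the
  reference sample (exact functions of s_x, s_y, r for an RMA line
  through the centroid). An absolute threshold can be supplied instead.

`along² + offset² = ‖target − centroid‖²` exactly, and the decomposition
is equivariant under rotation of the score plane.

## Encephalization quotient

EQ = ECV / (a·BM^b), defaults a = 1.77, b = 0.76 — a widely used primate
brain–body scaling with mass in kg and volume in cm³. Published EQ values
depend entirely on this convention, so the constants are explicit
arguments, are recorded on every result, and must match the source of the
BM/ECV estimates being analysed. Partial correlations use the standard
first-order formula with a t-test on n−3 df; the implementation is
cross-checked in the suite against both the residual-regression identity
and an independent library.

## Measurement-error robustness

Each replicate multiplies every measurement of a specimen by an
independent draw from Uniform(1−e, 1+e) — the most direct encoding of
"inaccuracies of up to e" — or optionally from a Gaussian with SD e/2
truncated at ±e. The perturbed specimen is passed through the model's own
preprocessing and scored in the fixed (unrefitted) ordination. Summaries:
centroid shift (cloud centroid to unperturbed score) and dispersion (RMS
radius about the cloud centroid). A single integer seed makes clouds
bit-reproducible, and with paired seeds dispersion is monotone in e.

## Synthetic data

The generator draws, per specimen, a latent log-size s (Gaussian within
group and stage; juveniles default to 0.18 log units below their species'
adults) and sets log10 measurements to `c_g + s·b + ε`:

* `b` (allometric coefficients, mean exactly 1 so s is the log geometric
  mean): defaults ≈ (0.26, 0.14, 0.20, 1.94, 1.85, 1.62) — the braincase
  close to adult size across the sampled juvenile range while the face
  roughly doubles relative to it, with ZYB nearest to isometry;
* `c_g` — the lateral transpositions: a scalar shift along the contrast
  (+1,+1,+1,−1,−1,−1) per group, plus a small within-block "facial
  reorganization" vector that differs between the ape-like and
  hominin-like clades. The latter matters: a transposition exactly
  proportional to the contrast slides *along* the leading PLS dimension,
  so it is the within-block heterogeneity that separates the ape and
  hominin lines in the PLS plane, as in real crania where basion- and
  nasion-prosthion reduce more than zygomatic breadth;
* `ε` — Gaussian log-scale noise, SD 0.015 (≈3.5% multiplicative), in the
  middle of the 2–5% disagreement typical between measurement sources;
* optional BM/ECV log-linear in s (the australopithecine-like group uses
  a zero ECV–size slope, the Homo-like group a positive one and a
  positive shape–size trend, reproducing the contrast between an
  uncoordinated and a coordinated clade), and an optional geological-age
  covariate affine in s.

The study-scale configuration fixes group sizes at the real sample's
composition (Pongo 14+10, Gorilla 29+5, Pan 54+10, H. sapiens 142+9
adults+juveniles; 10 australopithecine and 21 extinct-Homo adults). The
small fixture (~68 specimens) keeps the same parameters at reduced n; its
factory verifies the advertised construction guarantees (leading PLS
dimension > 90%, within-species centroid angles in (90°, 180°)) on each
draw and deterministically re-derives a sub-seed for the rare draws at
this size where the near-tied size and shape eigenvalues swap factor
order.

**What passing tests on synthetic data do and do not show.** The
generator reproduces the qualitative architecture — a dominant
between-module covariation axis, a shape factor leading a near-isometric
size factor, parallel negative within-species trajectories with angles in
(90°, 180°), hominins transposed off the ape line with disjoint intercept
CIs at study scale, a coordinated shape–size–ECV trend only in the
Homo-like group. It does not target the printed magnitudes of any real
analysis: its trajectories are steeper in the size direction than real
hominid ontogenies (centroid angles ≈ 122° rather than ≈ 160°, slope
magnitudes below 1 rather than ≈ 3), within-group score correlations are
stronger than real static allometries because the only within-group shape
scatter is measurement noise, and real asymmetric, taphonomically biased
fossil samples have no synthetic counterpart. Tests on this data
therefore validate the estimators and their calibration, not any
empirical claim about hominids; empirical reproduction runs only when the
study's measurement tables are supplied (see `tests/test_acceptance.py`).

## Numerical choices and degenerate inputs

Constant columns, blocks with fewer than 4 specimens, factor models with
n ≤ p, near-zero retained eigenvalues, zero-variance RMA inputs,
zero-length polarity vectors and collinear partial-correlation controls
all raise typed errors naming the offending column or quantity rather
than propagating NaNs. Angles are computed with atan2 and folded
([0°, 90°] for isometry angles, [0°, 180°] for trajectory angles).
Probabilities are clipped to [0, 1]. All Monte-Carlo machinery
(bootstraps, perturbations, the generator) runs on named NumPy
generators seeded from a single integer.

## Limitations

* The pipeline is strictly two-module, three-variables-per-module; it
  does not generalize to other block structures without changes to the
  domain types.
* Heterochrony labels depend on configurable thresholds (dead-band,
  prediction band) that have no canonical values; conclusions near the
  thresholds should be checked for sensitivity.
* The slope-contrast variance `(1−r²)/n` is asymptotic; at very small n
  with weak correlations the test is approximate (its size is verified at
  n = 50).
* EQ results are only as meaningful as the (a, b) constants and the
  provenance of the BM/ECV estimates.
* No phylogenetic comparative correction is applied anywhere; groups are
  treated as fixed strata, as in the analysis the package implements.
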