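# craniomorph

Allometry and heterochrony analysis of two-module craniometric data.

The hominid cranium is built from two modules that grow at different
rates: the neurocranium (braincase) and the splanchnocranium (face). In
great apes and humans alike the braincase is close to adult size early in
ontogeny while the face keeps growing, so the relative size of the
neurocranium falls as the cranium grows — a shared negative ontogenetic
allometry. Against that conserved trajectory, evolutionary differences
between species decompose into two independent kinds of heterochronic
change: **ontogenetic scaling** (truncating or extending the ancestral
trajectory, giving paedomorphic or peramorphic adults) and **lateral
transposition** (a parallel trajectory starting from a different shape at
a given size). `craniomorph` implements the complete statistical pipeline
for this decomposition from six classical anthropometric variables — GOL,
XCB, BBH (neurocranium) and BPL, NPH, ZYB (splanchnocranium), in mm — for
anyone analysing hominid or other two-module metric cranial data.

## Methods at its core

* **Size-scaled two-block PLS.** Each specimen's log10 measurements are
  scaled by their geometric mean (Mosimann log-shape variables, row sums
  exactly zero), and the 3×3 between-block association matrix is
  decomposed by SVD. Dimension *i* carries
  100·σᵢ²/Σσⱼ² of the squared covariation; block scores and their
  correlation quantify morphological integration of face and braincase.
* **Factor (size/shape) model.** PCA of the 6×6 correlation matrix of the
  raw log measurements, rescaled to factor loadings
  L = eigenvector·√eigenvalue so each loading is a variable–factor
  correlation and communalities h² = ΣL² are bounded by 1. The isometric
  direction (1,…,1)/√6 is mapped through the scoring transformation; its
  angle to each factor identifies the size axis (factor II here) and the
  shape axis (factor I, relative neurocranium size).
* **RMA trajectories.** Reduced major axis lines
  (slope = sign(r)·s_y/s_x) of the shape factor on the size factor per
  species or group, with analytic slope CIs
  slope·(√(B+1) ∓ √B), B = (1−r²)F₀.₉₅(1, n−2)/(n−2), seeded BCa
  bootstrap intercept CIs, Clarke's test for slope differences on the log
  slopes with an effective-df correction, and juvenile→adult centroid
  angles measured from the +factor-I axis.
* **Heterochrony decomposition.** A target group's centroid is split into
  a signed displacement *along* a reference ontogenetic trajectory
  (paedomorphic/peramorphic) and a perpendicular *offset* (transposed
  when outside the reference line's 95% prediction band).
* **Encephalization associations.** Pearson and first-order partial
  correlations among factor scores, log body mass, log endocranial volume
  and EQ = ECV/(a·BMᵇ) (defaults a = 1.77, b = 0.76).
* **Robustness.** Specimens are perturbed by multiplicative measurement
  error (uniform within ±e per variable) and re-scored in the *fixed*
  ordination, summarizing positional stability.

A synthetic-data generator (`craniomorph.simulate`) draws datasets with
exactly this structure — shared log-linear allometries, group
transpositions, stage-specific size distributions, lognormal noise,
optional BM/ECV/geological age — so the whole pipeline is testable
without any external data.

## Worked example

```bash
python analysis/01_simulate_study_data.py --seed 1
python analysis/02_ordinations.py
python analysis/03_allometric_trajectories.py
```

prints, for the seed-1 study-scale synthetic sample (304 crania):

```
2B-PLS: dimension 1 carries 100.00% of the squared covariation (singular value 2.946); block-score correlation 1.000.
Factor model: eigenvalues 3.279 / 2.659 (54.66% + 44.31% of variance).
Isometric direction: 10.2 deg from factor II, 79.8 deg from factor I — factor II is the
size axis, factor I the relative-neurocranium shape axis.
Within-species trajectories (shape factor on size factor):
  Pongo          slope  -0.641  r -0.997  n 24
  Gorilla        slope  -0.641  r -0.988  n 34
  Pan            slope  -0.632  r -0.975  n 64
  Homo_sapiens   slope  -0.641  r -0.974  n 151
Juvenile-to-adult centroid angles from the +factor-I axis:
  Pongo           122.3 deg
  Gorilla         122.5 deg
  Pan             122.5 deg
  Homo_sapiens    122.9 deg
PLS plane: ape slope 1.004 vs hominin 1.005; slope contrast p = 0.706; intercept 95% CIs
are disjoint — parallel lines separated by a lateral transposition.
```

Read: between-module covariation is one-dimensional (big face ↔ small
relative braincase); every extant species shows the same negative
ontogenetic allometry (parallel negative slopes, angles between 90° and
180°: size up, relative neurocranium down); apes and hominins follow
parallel trajectories whose intercepts differ — the hominins carry a
smaller face for any given neurocranium, a lateral transposition. The
remaining drivers (`04`–`06`) decompose each group against the ape
reference trajectory, relate the shape factor to brain size versus
encephalization (the partial correlation with absolute ECV survives
controlling for EQ; the converse does not), and confirm that fossil
placements are stable under ±5% measurement error.

The same stages are available as a CLI on your own data:

```bash
craniomorph validate crania.csv
craniomorph all crania.csv -o out --seed 1
craniomorph rma crania.csv --group "Pongo pygmaeus"
```

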