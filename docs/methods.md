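# Methods

## The measurement model

The unit of analysis is one proximal femur summarised by three
inter-landmark distances in millimetres: AB (most lateral point on the
articular rim of the head → most medially projecting point on the greater
trochanter), BC (greater → lesser trochanter) and AC (head → lesser
trochanter). The three lengths must satisfy the strict triangle inequality;
violations are treated as measurement blunders and rejected at ingestion
with a diagnostic naming the offending side, never repaired or silently
dropped. Lengths are carried at full precision; rounding to two decimals
happens only in reports. Values quoted beyond the 0.01 mm calliper
precision are flagged with a warning but accepted.

## Derived variables

Twelve variables are derived per case:

* **Angles** at vertices A, B, C via the Law of Cosines, with each angle
  opposite the side not containing its vertex (A ↔ BC, B ↔ AC, C ↔ AB).
  Angles are expressed in degrees — the anthropometric convention, and the
  scale that makes the ratio variables interpretable; radians are available
  through a flag. The arccos argument is clamped only within 1e-12 of ±1;
  anything beyond is an error, never a silent clamp.
* **Ratios** ×100 of each angle to a side, paired by vertex *label*
  (angle A/AB, angle B/BC, angle C/AC) rather than by the opposite side.
  The labelled pairing is the field's established definition for these
  ratio variables and is kept deliberately, even though the opposite-side
  pairing might look more natural geometrically.
* **Medians** from each vertex to the opposite midpoint via Apollonius'
  theorem, m_A = ½√(2AB² + 2AC² − BC²). The radicand is strictly positive
  for any valid triangle, so a non-positive value raises an internal error
  rather than a validation error.
* **Shape variables** (Darroch–Mosimann): each side divided by the
  per-case geometric mean (AB·BC·AC)^(1/3). They are scale-free, multiply
  to exactly 1, and allow pooling the sexes for ancestry questions.

Feature sets are fixed, ordered schemas: `linear`, `angles`, `ratios`,
`medians`, `shape` (3 columns each) and `pooled` (12 columns: linear +
angles + ratios + medians). The shape variables are excluded from the
pooled set because they are exact functions of the linear variables on a
different scale; pooling them adds collinearity without information.

## Reliability and dimorphism statistics

For a two-repeat intra-observer design with n duplicate pairs,
TEM = √(Σd²/2n); rTEM = 100·TEM / grand mean of the 2n observations;
R = 1 − TEM²/SD². The multi-repeat TEM generalisation is out of scope —
only two repeats are modelled. CV = 100·SD/mean. The sexual dimorphism
index is male-referenced, SDI = 100·(M − F)/M: applied to the published
Egyptian, Indian and pooled cell means it reproduces the published SDI
column to rounding, which the female-referenced alternative does not; the
published Greek SDI cells are reproducible under neither convention
(presumably computed on unrounded or subsampled data) and are flagged
`sdi_reproducible=False` in the reference table. One-way ANOVA is the
classical between/within mean-square ratio (delegated to
`scipy.stats.f_oneway`), with sample (n−1) SDs throughout and p-values
reported to 4 dp against the 0.05 threshold. Tukey HSD and normality
testing are standard library routines and deliberately not wrapped.

## Classifiers

**LDA** uses group means with a pooled within-group covariance; with equal
priors (the default, matching the 1/k chance-level convention) prediction
is minimum Mahalanobis distance. The solver is scikit-learn's
`LinearDiscriminantAnalysis`; the test suite holds it to an independent
brute-force Mahalanobis oracle. Class-proportional priors are available by
flag.

**The bagged ensemble** is an explicit bootstrap-aggregation loop over CART
trees (scikit-learn `DecisionTreeClassifier` base learners): each tree is
grown on an n-out-of-n bootstrap, choosing the best Gini split among a
random `mtry` subset of features at every node, to purity by default.
Defaults: 500 trees, mtry = ⌈√p⌉, min leaf 1 — the canonical recipe, all
config-exposed. The loop is native rather than `RandomForestClassifier`
because the out-of-bag bookkeeping is part of the contract: OOB error is
the misclassification rate of per-row majority votes over the trees whose
bootstrap excluded that row, and permutation importance (MDA) is computed
tree-by-tree on each tree's own OOB rows (accuracy drop after permuting one
feature, averaged over trees). MDI is each tree's normalised
impurity-decrease attribution averaged over the ensemble and renormalised
to sum 1. All majority-vote ties break deterministically by class-name
order. Refitting with the same seed is bit-reproducible, which is also how
forest artifacts are serialised: a JSON manifest of configuration + seed,
reproduced by refit, instead of tree-by-tree dumps (LDA manifests store the
discriminant coefficients in full).

Splits are stratified 70/30 by the task label (stratification prevents
empty-class test partitions in the six-way task, whose smallest cell has 40
members) and deterministic per seed. k-fold cross-validation is stratified
with k = 5 by default; k may not exceed the smallest class size, which also
rules out leave-one-out on stratified data. The 2D visualisation uses a
Gaussian random projection (entries N(0, 1/2) for two components), which
approximately preserves pairwise distances.

## Experiments

Five tasks: sex only (2 classes, populations pooled), ancestry only
(3 classes, sexes pooled), sex × ancestry (6 classes), and ancestry within
each recorded sex (3 classes on the filtered subset). `run_matrix` sweeps
tasks × feature sets × classifiers over replicate seeds and reports
replicate mean ± SD of overall and per-class test accuracies: a single
70/30 split at these cell sizes has high variance, so 25 replicates is the
default reporting unit; a single split is just one seed. Accuracies are
stored unrounded and rounded only in emitted tables. Matrix-level plots
are cosmetic conveniences and untested.

## The synthetic-data generator

Each of the six (population, sex) cells is a trivariate normal with the
published cell means and SDs and a common correlation matrix. The
inter-measurement correlations were never published; the default is 0.5 on
all off-diagonals — a moderate positive value reflecting shared body-size
scaling — and is a configuration surface. Draws violating the strict
triangle inequality are rejected and redrawn (rejection keeps the
within-constraint distribution well-defined, unlike projection); the count
is recorded and an acceptance rate below 1 % aborts. Truncation to the
published min/max windows is off by default because truncation biases the
realised moments away from the nominal parameters. Cell sizes default to
the published study (Egyptian 40 M/61 F, Indian 200 M/80 F, Greek
112 M/91 F; 584 rows), with a `scale` multiplier for convergence studies.

**Known bias from the triangle constraint.** In the Egyptian cells the
nominal parameters put the constraint margin AB + AC − BC only ~1.2–1.6
SDs above zero, so roughly 10 % (females) to 18 % (males) of normal draws
are rejected; the accepted rows then run ~0.3–0.9 mm high in AB and AC
with slightly shrunken SDs. Convergence tests therefore compare sample
moments against the constrained output distribution (estimated once from a
large draw) rather than the nominal normal parameters. The other cells
reject < 1 % of draws and the distinction is negligible there.

**What the generator does and does not emulate.** It reproduces per-cell
location, scale and (assumed) normality, a plausible correlation
structure, and the feasibility constraint. It does not model left/right
asymmetry, age structure, secular change, measurement blunders, or the
true (unpublished) covariance — so classification accuracies on synthetic
data characterise the pipeline under the assumed covariance, not the
historical samples. Relatedly, which of BC and AC ranks first in
permutation importance for the pooled-sex task is sensitive to that
unknown correlation (their pooled standardized sex separations are nearly
tied, ~1.35 vs ~1.26 SD units): BC is the modal winner across replicates
at the default settings, but not an overwhelming one. Passing tests
demonstrate internal correctness and qualitative structure (dimorphism
ordering, above-chance classification, same-sex-block confusion), not
quantitative agreement with any real collection.

## Numerical and design notes

* Problem sizes used in tests and the acceptance script: study-scale
  samples (584 rows), 200-tree ensembles, 10–25 replicate seeds, 50×
  scaling for parameter recovery, 20 000-row draws for reference moments —
  sizes chosen so the whole suite runs in a few minutes on one CPU.
* Singular pooled covariances in LDA are handled by the SVD solver's
  implicit regularisation.
* All seeds are explicit; every CLI output directory carries a JSON
  manifest with the seed and a configuration hash.
* The statistical convergence tests use multiplicity-aware bounds
  (e.g. a Bonferroni-adjusted z bound across 18 simultaneous cells) so the
  suite's family-wise false-alarm rate stays near 1 %.
* Angle/shape/median invariants hold to 1e-9 against an independent
  coordinate-geometry embedding for well-conditioned triangles (relative
  constraint margin ≥ 1e-3).

## Limitations

* The emulator cannot recover the historical samples' absolute
  classification accuracies; the unpublished covariance dominates those.
* Greek SDI reference cells are non-reproducible from the published means
  and are excluded from reproduction checks.
* Only intra-observer, two-repeat reliability designs are covered.
* The CLI reads and writes CSV only; no spreadsheet, database or imaging
  formats.
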