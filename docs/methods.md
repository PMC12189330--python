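# Methods

## Model and procedure

All computations operate on a validated pedigree: records in stable
topological order (parents before offspring, ties broken by birth date
then id), acyclicity certified, unknown-parent sentinels normalized, and
referenced-but-undeclared parents materialized as flagged founder stubs.
The stub policy is what lets every decomposition conserve its total over
an explicit founder set.

### Relationship algebra

The numerator relationship matrix is never stored. With `U` the unit
lower-triangular matrix carrying −½ from each animal to each known
parent and `B` the diagonal of Mendelian sampling variances (MSVs),
`A = U⁻¹B(U⁻¹)ᵀ`, so `A·x` is computed as an upward accumulation pass
(solve `Uᵀw = x`), a diagonal scaling, and a downward gene-dropping pass
(solve `Uy = w·b`). Inbreeding coefficients come from a Meuwissen–Luo
style climb: `1 + F_i = Σ_k c_ik² b_k` over the ancestors of `i`, one
animal at a time in pedigree order. MSVs for animals with one unknown
parent use `b = ¾ − ¼F_known`; this unknown-parent convention is what
keeps the factorization exact on incomplete pedigrees. A classical
recursive tabular construction of dense `A` is kept (capped at 2000
animals) purely as an oracle for tests.

### Decomposition targets and scales

Three targets are supported: an individual's F, a group mean F̄, and a
group mean coancestry f̄ (self-pairs included, `x'Ax/n²` for the group
indicator). Every vector is exposed on two scales — relationship
(entries of A) and coancestry (half of it) — because the two scales are
easy to conflate in herdbook software output; the per-ancestor loop
contribution on the relationship scale is exactly twice the
coancestry-scale value, and the package makes that identity explicit
rather than implicit.

### MSV → NCA → founder

- `m_k = b_k·c_k(s)·c_k(d)` (individual F), `m_k = b_k·c̄_k²` (group
  coancestry, with `c̄` the mean gene-proportion vector of the group),
  and an average of per-member sire/dam passes for group mean F.
- Nodal-common-ancestor contributions `u` are defined by marginal
  attribution: the mass of an ancestor whose loops all run through a
  younger NCA belongs to that younger NCA. Implementation: weighted gene
  pairs are propagated up the pedigree (the younger member of a pair is
  replaced by its parents at half weight) and a pair coalescing at
  animal `a` attributes its full pair-relationship `(1+F_a)` there and
  stops. First-coalescence attribution reproduces Wright's
  path-counting attribution of non-self-intersecting loops exactly —
  the test suite asserts elementwise agreement at 1e-10 against an
  explicit path enumerator on hundreds of random pedigrees — while
  costing one table sweep instead of exponential path enumeration.
- Founder contributions push `u` to founder-like sources by expectation
  gene dropping. Animals with a missing parent retain the unrecorded
  half themselves, so `Σv = Σu` holds even on incomplete pedigrees;
  such partial sources and phantom stubs are identifiable from the
  pedigree record.

Two independent backends cross-check the MSV route: Wright path counting
(capped at 10⁶ paths; small-pedigree oracle) and the gene-pair
frequency-table ("upward exploration") backend, which attributes `b_a`
at each coincidence and continues with quarter weights to the parent
pairs. The table backend is memory-capped (default 2·10⁷ pair entries)
because deep pedigrees can inflate the pair table.

### Canonical discriminant analysis

The feature table holds one row per contributing ancestor: loop
contribution (relationship scale), founder contributions to mean F and
mean coancestry, coancestry C (coancestry scale), and the per-record
non-random-mating coefficient α = 1 − 1/(1−C). Two identities hold by
construction (loop = 2C; α from C), which makes parts of the table
*exactly* collinear. The VIF screen (threshold 5, iterative removal of
the worst column, floor of two survivors, exact dependence reported as
infinite VIF) therefore always removes two of the {loop, C, α} trio;
ties are broken by dropping the later column so the leading variable of
a duplicated pair survives. This is a deliberate difference from
analyses in which the five variables are computed by separate programs
and are only *nearly* collinear: with exact identities, retaining both
scale twins of the same quantity is impossible for any honest screen.

The eigen-solution uses the symmetric generalized problem
`B_between v = λ W v` (scipy `eigh`), with `min(p, g−1)` functions
scaled to unit pooled within-group score variance and a deterministic
sign convention (largest coefficient positive). Exactly dependent
columns are dropped via pivoted QR before inversion; a residually
singular within-scatter receives a logged ridge of `1e-8·trace/p`.
Significance testing: Wilks' Λ = Π1/(1+λ) with Rao's F approximation,
Bartlett residual χ² = −[n−1−(p+g)/2]·lnΛ_residual with df
(p−k)(g−1−k), Pillai's V = Σλ/(1+λ) with its standard F approximation,
and per-variable one-way Λ = SSW/SST. These identities are tested
against statsmodels' MANOVA on random data.

Forward stepwise selection (exposed, not wired into the default
pipeline chain) maximizes a ridge-penalized multinomial likelihood with
BIC stopping; the ridge is small (0.01) so that a duplicated predictor
cannot buy likelihood through penalty relief.

Leave-one-out classification refits centroids and the pooled
within-group covariance for every held-out row (true cross-validation,
the conservative choice) and assigns by squared Mahalanobis distance
penalized by −2·ln(prior); priors default to group-size proportional
with a uniform option. Press's Q = (N−nK)²/(N(K−1)) is compared with
the 1% χ² critical value 6.63, the hit ratio with 1.25× the
proportional- and maximum-chance criteria. Mahalanobis centroid
distances (square-rooted, pooled within-group metric) feed a UPGMA
dendrogram (linkage configurable: single/complete/average), exported as
Newick with ultrametric branch lengths (node height = merge
distance/2).

## Synthetic data: what it emulates and what it does not

The generator mimics the demographic structure a regional herdbook of an
endangered breed presents to this pipeline: discrete non-overlapping
generations; region-specific founder pools (optionally unequal, so one
nucleus can dominate); municipalities nested in regions; per-mating
migration (a dam taking an out-of-region sire), optionally per-region so
one region can be fully isolated; deliberate relative matings with
probability `loop_intensity` (full sibs preferred over half sibs — the
tightest loop); and first-generation parent masking emulating incomplete
early records. Sexes alternate within cohorts to guarantee feasible
matings at small sizes. Defaults: 3 regions × 30 founders, 7
generations, mean 2 offspring per mating, migration 0.15, loop intensity
0.10, unknown-parent rate 0.10, base year 1994.

Not emulated: overlapping generations and age structure, selection on
phenotypes, unequal family sizes by sire usage (every dam is mated
once per generation), seasonal or spatial mating preferences within a
region, and genotype data of any kind. Passing tests therefore show that
the *decomposition arithmetic* and the *discriminant machinery* behave
correctly and that regional isolation produces the expected loop and
classification signals; they do not validate demographic realism for any
particular breed.

The isolated-region recovery check uses three regions with migration
(0, 0.3, 0.3) and founder pools (45, 25, 19): the isolated region is
also the dominant nucleus, as in the study system this package targets,
which is what drives the proportional-prior classifier to concentrate
assignments there (isolated-region accuracy near 100%, connected
regions near 0) rather than leaving the sink group to chance.

## Numerical choices

- Conservation tolerance 1e-10 in tests; the pipeline logs residuals
  and warns (rather than fails) above 1e-8.
- Topological tie-breaks (birth date, then id) make every downstream
  vector a pure function of the record set.
- Pair-table and path-enumeration caps raise informative errors
  pointing at the MSV route.
- Rate of coancestry ΔC = 1 − (1−C)^(2/(t_b+t_a)) with the convention
  ΔC = 0 when C = 0 and both equivalent-generation counts are 0, and an
  error when C > 0 with no pedigree depth. A mean-over-pairs
  convenience is provided alongside the pairwise primitive (dense,
  capped at 2000 animals); whether upstream tools average over all
  pairs or cohort pairs varies, so both conventions are reachable.
- Report floats are serialized at 6 significant digits, making
  re-exports byte-identical.

## Problem sizes

Default test and demonstration sizes are deliberately modest: random
oracle pedigrees of 20–200 animals (dense comparisons are quadratic),
synthetic herds of ~700 animals for pipeline tests and ~2,500 for the
large conservation check, 10 replicates for the isolated-region
recovery experiment and 200 label permutations for the size check of
the Wilks test. All closed-form fixtures are exact at these sizes; the
algorithms themselves are linear or near-linear per pass and handle
herdbook-scale pedigrees (10⁴–10⁵ animals) for the MSV and
first-coalescence routes.

## Known limitations

- Group NCA contributions report per-ancestor sums over all
  contributing members/pairs (not per-individual maxima); coalescence
  at a living group member attributes that self-pair to the member
  itself.
- The pair-table route for group coancestry is quadratic in group size
  at initialization; very large reference populations should use the
  MSV route and convert only where marginality is needed.
- The CDA operates on heavily right-skewed contribution variables
  without transformation, matching field practice; users wanting
  variance-stabilized analyses should transform the feature table
  before fitting.
- Wilks/Bartlett/Pillai p-values rely on the usual large-sample
  approximations and are not permutation-calibrated by default (the
  test suite demonstrates a permutation size check).
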