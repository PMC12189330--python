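# pedloop

Decomposition of pedigree inbreeding and coancestry into ancestral
components — Mendelian sampling variances, nodal common ancestors and
founders — followed by a canonical discriminant analysis of ancestor
birth origins.

`pedloop` is aimed at conservation geneticists managing endangered
livestock breeds from herdbook data. It answers two linked questions:
*which ancestors created the homozygosity a population carries today*,
and *whether the geographic origins of those ancestors are genetically
distinguishable* (isolated breeding nuclei versus regions connected by
historical gene flow such as transhumance routes).

## The method

Pedigree algebra rests on the factorization of the numerator
relationship matrix

```
A = U⁻¹ B (U⁻¹)ᵀ
```

where `U` has 1 on the diagonal and −½ linking each animal to each known
parent, and `B = diag(b)` holds the Mendelian sampling variances (MSVs):
`b = 1` for founders, `b = ½ − ¼(F_s + F_d)` with both parents known.
Products `A·x` then cost one upward pedigree pass, a diagonal scaling and
one downward pass — no dense matrix is ever formed.

Three nested decompositions of a target statistic (an individual F, a
group mean F̄, or a group mean coancestry f̄) follow:

- **MSV contributions** `m_k = b_k c_k(s) c_k(d)` with `c` the expected
  gene proportions: the share of the statistic injected at ancestor k's
  birth. `Σ m = F` exactly.
- **Nodal-common-ancestor (NCA) contributions** `u`: the marginal share
  of each ancestor at which an inbreeding loop actually closes. An NCA
  appears on both the paternal and maternal side of a pedigree; when a
  younger NCA sits below an older one on all connecting paths, the
  younger captures the mass (Wright's path counting attributes each
  non-self-intersecting loop `(½)^(n₁+n₂+1)(1+F_a)` to its apex).
  `pedloop` computes `u` without enumerating paths, by propagating
  labeled gene pairs upward and attributing each pair to the vertex of
  first coalescence; the path-counting and gene-pair-table routines are
  retained as independent cross-checks.
- **Founder contributions** `v = Tᵀu`, with `T` the expected
  gene-proportion matrix of founders in NCAs. `Σ m = Σ u = Σ v` holds to
  1e-10 at every stage.

Per-ancestor contributions (plus the per-record non-random mating
coefficient `α = 1 − 1/(1−C)` and the population-level
`(1−F̄) = (1−f̄)(1−α)`) feed a canonical discriminant analysis of birth
origin: VIF collinearity screen (threshold 5), eigen-solution of
`W⁻¹B_between`, Wilks' Λ with Rao's F, Bartlett residual χ², Pillai's
trace, leave-one-out cross-validated classification with Press's Q, and
Mahalanobis centroid distances agglomerated into a UPGMA dendrogram.

Because real herdbooks are rarely public, the package ships a
synthetic-pedigree generator (`pedloop.simulate`) with regional founder
pools, nested municipality labels, configurable migration between
regions, deliberate relative matings (inbreeding loops) and masked early
parentage — every pipeline stage is testable end to end.

## Worked example

```
pedloop simulate --seed 42 --out herd.csv
pedloop run --pedigree herd.csv --out report/
cat report/summary.txt
```

```
pedloop 0.1.0 pipeline summary

Pedigree: n_animals=687, n_subset=577, subset=reference, n_founders=91, n_inbred=329, mean_F=0.0570164, mean_coancestry=0.0282852, alpha=0.0295675
Conservation residuals: m_meanF=6.939e-18, u_meanF=6.939e-18, v_meanF=1.388e-17, m_meanC=6.939e-18, u_meanC=6.939e-18, v_meanC=6.939e-18
CDA eigenvalues: 0.00677901, 3.95396e-08
Wilks lambda: 0.993267 (p=0.3486); Pillai V: 0.00673341 (p=0.3487)
LOOCV hit ratio: 0.451662; Press's Q: 41.7107
```

Reading this: of 687 simulated animals, the 577 with both parents known
form the reference population; 329 are inbred. Mean inbreeding (0.057)
exceeds mean coancestry (0.028), so mates are more related than random
pairs (α = +0.030 — the default configuration deliberately mates
relatives 10% of the time). The conservation lines confirm that the MSV,
NCA and founder decompositions of both targets reproduce the directly
computed statistics to machine precision. With the default three
symmetric regions, origin separation is weak (Λ close to 1, p ≈ 0.35),
but classification still beats chance (Press's Q = 41.7 > 6.63).
Isolating one region (`migration_rates: [0.0, 0.3, 0.3]`) makes its
ancestors' loop contributions rise and its LOOCV accuracy approach 100%,
while the connected regions blur — the signature of an isolated breeding
nucleus.

The feature table behind the analysis satisfies two built-in identities
on every row: loop contribution = 2 × coancestry (relationship versus
coancestry scale) and α = 1 − 1/(1−C).

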