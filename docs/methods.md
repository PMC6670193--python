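# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `coabund`, in the order the pipeline runs.

## Abundance model and preprocessing

The unit of data is a genes-by-samples matrix of per-gene sequencing
depth. Depths are made comparable across samples by sum normalization
(each sample column divided by its total), the only normalization
offered because cosine distance is invariant to per-gene rescaling and
the downstream CLR transform is invariant to per-sample rescaling —
other normalizations would change nothing the method looks at. Genes
detected (nonzero) in fewer than `min_samples` samples (default 10) are
excluded before clustering: a co-abundance profile supported by a
handful of samples carries no usable correlation signal. Excluded genes
are reported, not silently dropped, and are omitted from the catalog
rather than forced into singleton groups.

## CAG clustering

Dissimilarity is the cosine distance between abundance profiles,
d ∈ [0, 1] for nonnegative data and invariant to gene-level scale (gene
length, detectability). Groups are defined by average-linkage (UPGMA)
hierarchical clustering cut at a cophenetic distance threshold
`max_dist` (default 0.3, inclusive: a merge at exactly the threshold is
accepted).

All-pairs UPGMA is quadratic in genes and intractable at catalog scale,
so `find_cags` iterates:

1. **Candidate retrieval.** Each item (gene, later cluster) queries an
   approximate-nearest-neighbor index for `ann_k` neighbors (default
   100) under cosine distance on its representative profile — the mean
   of the members' L2-normalized profiles.
2. **Exact verification.** A candidate pair enters the graph only if
   its *exact* average-linkage distance is ≤ `max_dist`. Because the
   mean pairwise cosine distance between clusters A and B equals
   1 − (s_A·s_B)/(|A||B|) for summed unit member profiles s, the exact
   quantity is O(dims) per pair at any cluster size; no centroid
   approximation is ever used for a merge decision.
3. **Local exact clustering.** Connected components of the verified
   graph are clustered independently by exact UPGMA (the same summed-
   profile identity gives the standard weighted update s_{A∪B} = s_A +
   s_B), cut at `max_dist`.
4. Rounds repeat on the resulting clusters until no merges occur or
   `max_rounds` (default 8) is reached.

Step 3 is sound because any two flat UPGMA clusters at cut t have mean
pairwise distance > t, and every merge at height ≤ t links items
connected in the ≤ t threshold graph; hence with exhaustive candidate
retrieval the iterative scheme returns exactly the all-pairs UPGMA
partition (asserted against the brute-force oracle on 20 fixtures in the
test suite). With restricted `ann_k`, missed edges can only split
components, and later rounds re-expose them through cluster
representatives; agreement with the oracle is quantified (ARI ≥ 0.95
required at default settings).

Determinism is treated as a feature: candidate lists and merge queues
break ties by (distance, lexicographically smallest member gene id), the
ANN index is seeded, and CAG ids are assigned densely from 0 by
descending size (ties by smallest member id). Single-gene clusters are
kept in the catalog; the size distribution is available from the catalog
so a minimum-size-2 convention can be applied by the caller.

Two neighbor backends exist behind one interface: brute-force exact kNN
(used automatically below 2,000 items, where a dense similarity matrix
is cheaper than any index) and a seeded NN-descent graph index
(pynndescent) for larger inputs. Both feed the same exact verification.

CAG abundance is the sum of member genes' relative abundances — additive
in depth units, singleton CAGs equal their gene, and per-sample totals
are conserved (asserted in tests).

## Association testing

CAG abundances are compositional: closure forces spurious negative
dependence, and a genuine decrease of a large fraction of the community
would otherwise read as an increase of the rest. The centered log-ratio,
clr(x)_i = log x_i − mean_j log x_j (natural log; coefficients are
reported on this scale), removes per-sample scale. Zeros are replaced
per sample by half the smallest nonzero value in that sample before
taking logs — the standard multiplicative replacement; it keeps
geometric means finite while preserving ordering.

Per CAG, the CLR abundance is regressed on a healthy indicator (coded 1
for healthy, so positive coefficients mean more abundant in health).
When any subject contributed more than one sample the model is a linear
mixed model with a subject random intercept (REML); otherwise ordinary
least squares, to which the mixed model provably reduces (agreement to
1e-6 asserted). Inference is a two-sided Wald test with a normal
reference for the mixed model; no small-sample correction is applied,
and calibration at the sample sizes used is verified by simulation
(null p-values pass a Kolmogorov–Smirnov uniformity check at 100 CAGs).
Singular fits are flagged with missing p and excluded from q-value
estimation. Perfectly degenerate responses (zero residual variance)
return coefficient 0 with p = 1.

**Q-values.** FDR control uses Storey q-values with the smoother π0
estimate: π0(λ) = #{p > λ}/(m(1−λ)) on the grid λ = 0.05, …, 0.95,
cubic smoothing spline, evaluated at λ = 0.95, clamped to (0, 1].
Forcing π0 = 1 reproduces Benjamini–Hochberg exactly (asserted against
statsmodels). Below 10 p-values the smoother is unstable and the
function falls back to BH with a warning.

**Discovery/validation.** Discovery keeps CAGs with q ≤ 0.2
(inclusive — "0.2 or less"). Validation recomputes q-values within the
discovered subset only, since only those hypotheses are carried forward,
and requires both q ≤ 0.2 and a matching coefficient sign. The
conservative global-null bound is Pr(Binomial(C1, ½) ≥ C2) for C2 sign
agreements among C1 testable discovered CAGs, computed as a log-space
sum of binomial log-masses so it remains exact at arbitrarily extreme
counts; the normal approximation with denominator √(C1/2) is reported
alongside for fidelity, although the Binomial(C1, ½) standard deviation
is √(C1)/2 — the √(C1/2) form is more conservative in the far tail and
is kept verbatim rather than second-guessed. When C1 = 0 the bound is
vacuously 1. For the unclustered comparison,
`select_representative_genes` draws one uniform member per CAG
(seeded), and the identical pipeline runs on those genes' CLR
abundances.

**Enrichment.** Functional-label enrichment of a gene set against a
background uses the two-sided Fisher exact test per label with
Holm–Šidák family-wise control at α = 0.01 by default.

## Single-cell co-occurrence

The statistic counts (cell, gene) detections for which at least one
*other* gene of the same CAG is detected in the same cell — so one gene
detected in two cells can count twice, and both members of a
co-detected pair count. The null permutes the gene→CAG assignment
uniformly over the catalog's whole gene universe (not only cell-detected
genes; the number of detections outside the catalog is logged so the
alternative reading can be audited), exactly preserving the CAG size
multiset, with 1000 replicates by default. Enrichment is
observed / mean(permuted); it is flagged undefined when the permutation
mean is zero.

## The simulator

`simulate_cohort` plants: CAG base log-abundances m_c ~ Normal(0, 1)
(heavy-tailed relative abundances after exponentiation); per-subject
random intercepts (sd 0.5) with 1–3 samples per subject to exercise the
mixed-model path; per-sample latent noise (sd 1.0); an additive disease
effect on the log latent abundance of selected CAGs *before* closure, so
compositional artefacts are present in fixtures; fixed per-gene scale
offsets (sd 0.5, cosine-invisible) plus per-observation log-normal gene
noise (sd 0.1 by default); and Poisson counts at an expected depth of
10^6, so detection sparsity exercises `min_samples`. Defaults — 20 CAGs
of 10–50 genes, 100 samples from 60 subjects per cohort, 5 effect CAGs
with a log-scale shift of 1.0 — are the study conditions used throughout
the tests. Paired cohorts share the planted structure and effect signs
with independent subjects and noise, mirroring a validation cohort
quantified against the discovery catalog. An additive shift δ on one
CAG's log abundance appears in CLR coordinates as δ(1 − 1/D) on that CAG
and −δ/D elsewhere (D = number of CAGs); `TruthSet.expected_clr_shift`
exposes this for parameter-recovery tests.

What the simulator does *not* emulate: read-level error, assembly and
gene-calling artifacts, taxonomic correlation structure between CAGs,
overdispersed (non-Poisson) counts, covariate confounding, and
unbalanced or drifting cohort protocols. Passing tests therefore
demonstrate correctness of the algorithms and calibration under the
stated generative model, not robustness to everything real cohorts do.

## Numerical and design choices

- Distances in double precision throughout; pairwise cosine values are
  clipped at 0 to absorb −1e-16-scale rounding.
- Threshold comparisons (`max_dist`, q ≤ 0.2) are inclusive.
- Problem sizes in the test suite (≤ 500-gene clustering fixtures, 100
  null replicates of 100 CAGs × 40 samples, 1000-replicate permutation
  tests) were chosen so the full suite runs in about a minute while
  keeping every statistical check at the replication counts stated
  above.
- The global-null calibration check pools sign agreements across
  replicates (ΣC2/ΣC1), the natural estimator of the agreement
  probability, because under the null most replicates discover nothing
  and per-replicate fractions are undefined; replicates with C1 = 0
  contribute the vacuous bound p = 1.
- The acceptance report floors underflowing p-values at the smallest
  positive subnormal double (5e-324) so the JSON holds a representable
  upper bound; exact base-10 logarithms are printed alongside.

## Known limitations

- The iterative scheme guarantees oracle equivalence only with
  exhaustive candidate retrieval; with small `ann_k` on data whose
  clusters exceed `ann_k` members, splits are possible (mitigated by
  later rounds; quantified, not bounded, by the ARI tests).
- Mixed-model inference uses the normal reference; at very small cohort
  sizes (tens of samples) Wald p-values can be mildly anticonservative.
- The π0 smoother is noisy below a few hundred p-values; the BH
  fallback below 10 is abrupt by design.
- CLR zero replacement is sample-local; catalogs dominated by zeros
  (sparser than anything the simulator produces) would make results
  sensitive to the replacement policy.
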