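# coabund

Gene-level metagenomics with **Co-Abundant Gene groups (CAGs)**: cluster
microbial genes whose sequencing depth tracks together across samples,
then test those groups — not millions of individual genes — for
reproducible association with host disease.

Shotgun metagenomes contain millions of microbial genes, far too many to
treat as independent hypotheses, yet genes on the same chromosome,
plasmid, or operon rise and fall together across samples. `coabund` is
for microbiome researchers who want to exploit that structure: it groups
genes by co-abundance, associates the groups with a binary phenotype in
a discovery/validation design, and quantifies physical linkage of group
members in single-cell data.

## The method

**Clustering.** Genes are compared by cosine distance between their
depth-normalized abundance profiles, d(u, v) = 1 − u·v / (‖u‖‖v‖), and
grouped by average-linkage (UPGMA) clustering cut at a fixed cophenetic
distance (default `max_dist = 0.3`), after discarding genes detected in
fewer than `min_samples = 10` samples. All-pairs UPGMA is intractable at
scale, so an approximate-nearest-neighbor index proposes candidate
subsets: every verified pair with exact mean member-pair distance ≤
`max_dist` becomes a graph edge, connected components are clustered
exactly and independently, and the procedure iterates on the resulting
clusters until no merges remain. The identity

d(A, B) = 1 − (s_A · s_B) / (|A||B|),  with s_X the summed unit profiles of X,

makes the exact average-linkage distance cheap at any cluster size, so
ANN approximation affects only candidate retrieval, never a merge
decision. An exact all-pairs oracle (`exact_average_linkage`) is
included; on small inputs the iterative scheme reproduces it identically.

**Association.** CAG relative abundances are mapped through the
centered log-ratio, clr(x)_i = log x_i − mean_j log x_j, to handle
compositionality. Per CAG, the mean CLR difference between disease and
healthy samples is tested in a linear model (mixed model with a subject
random intercept when subjects contribute repeated samples; positive
coefficients mean more abundant in health). Storey q-values control the
FDR: CAGs with q ≤ 0.2 in the discovery cohort are *discovered*; those
with q ≤ 0.2 (recomputed within the discovered subset) and the same
coefficient sign in an independent validation cohort are *validated*.
If C2 of C1 discovered CAGs keep their sign in validation, the global
null of no association is bounded by

Pr(Binomial(C1, ½) ≥ C2) ≈ Pr(Normal(0,1) ≥ (C2 − C1/2) / √(C1/2)),

computed exactly in log space (the normal form is also reported).

**Single-cell co-occurrence.** Genes of a real CAG should co-occur in
the same physical cell. The statistic is the number of (cell, gene)
detections sharing a cell with another same-CAG gene, compared with the
same count under random permutations of the gene→CAG assignment.

Real cohorts require a heavy upstream pipeline (assembly, gene calling,
alignment), so the package ships a first-class simulator that plants
known CAG structure, disease effects, repeated measures, and single-cell
co-placement, letting every stage be tested against ground truth.

## Worked example

```python
import coabund as cb

config = cb.SimulationConfig(seed=1)          # 20 CAGs, 5 with a planted effect
(dm, dmeta), (vm, vmeta), truth = cb.simulate_paired_cohorts(config)

catalog = cb.find_cags(dm, cb.ClusteringParams())          # cluster discovery cohort

def pipeline(m, meta):
    sub = cb.GeneAbundanceMatrix(m.values.loc[catalog.gene_ids])
    cags = cb.cag_abundance(cb.sum_normalize(sub), catalog)
    return cb.add_qvalues(cb.fit_cag_association(cb.clr_transform(cags), meta))

dres, vres = pipeline(dm, dmeta), pipeline(vm, vmeta)
report = cb.validate(cb.discover(dres), dres, vres)

cells = cb.simulate_single_cells(catalog, n_cells=200, genes_per_cell=10,
                                 within_cag_enrichment=50, seed=1)
cooc = cb.permutation_ratio(cells, catalog, n_reps=1000, seed=1)
```

With seed 1 this prints (via the attributes shown):

```
genes: 580   samples per cohort: 100
CAGs: 20   sizes 11 - 48
discovered 20 CAGs at q<=0.2; validated 6
C1=20  C2=14  exact p=0.02069... -> 0.05766  normal approx=0.103
co-occurrence observed=1654  null mean=807.2  ratio=2.05
```

The clustering recovers all 20 planted CAGs exactly. Discovery flags
every CAG — an instructive compositional artefact: shifting five CAGs
moves the per-sample geometric mean, so *every* CLR coordinate shifts a
little — but the validation stage cuts this to 6 CAGs, which include all
5 truly affected ones plus one false positive (1/6 ≈ 17%, consistent
with the 20% FDR target). The sign-agreement count C2 = 14 of C1 = 20
gives a conservative global-null p of 0.058: with only 20 groups the
binomial bound is, as intended, hard to push below conventional levels
unless most signs agree. The single-cell ratio 2.05 means same-CAG genes
share a cell at twice the rate expected by chance.

The same flow is available from the shell:

```bash
coabund simulate --out-dir run/ --seed 1
coabund cluster --abundance run/discovery_abundance.tsv \
    --max-dist 0.3 --min-samples 10 --out run/catalog.csv
coabund associate --abundance run/discovery_abundance.tsv \
    --metadata run/discovery_metadata.csv --catalog run/catalog.csv \
    --out run/discovery_results.csv
# ... associate the validation cohort, then:
coabund validate --discovery run/discovery_results.csv \
    --validation run/validation_results.csv --out run/report.csv
```

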