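"""Synthetic cohorts with planted co-abundance structure.

Real gene-level metagenomic cohorts require terabytes of raw sequencing
data and a long upstream pipeline (assembly, gene calling, alignment).
This module instead generates abundance matrices with known, planted CAG
structure so every downstream stage — clustering, CLR association models,
discovery/validation, single-cell co-occurrence — can be tested against
ground truth.

Generative model
----------------
Each CAG ``c`` has a base log-abundance ``m_c ~ Normal(0, 1)``, giving
heavy-tailed relative abundances across CAGs.  For sample ``s`` from
subject ``j``, the latent log-abundance of the CAG is

    L[c, s] = m_c + u[j, c] + eps[c, s] + sign_c * effect_size * healthy(s)

with a subject-level random intercept ``u ~ Normal(0, subject_sd)``
(repeated measures), per-sample biological noise
``eps ~ Normal(0, latent_sd)``, and an additive disease effect on the log
scale for the planted effect CAGs (positive sign = more abundant in
healthy subjects).  The shift is applied before closure, so the
compositional artefacts the CLR transform is meant to address are present
in the fixtures.  Each member gene multiplies the CAG latent abundance by
a fixed gene-specific scale (gene length / detectability analogue) and a
per-observation log-normal noise term ``exp(Normal(0, gene_noise_sd))``;
at ``gene_noise_sd = 0`` genes within a CAG are exactly proportional and
have pairwise cosine distance 0.  Sequencing counts are drawn
``Poisson(depth * relative_abundance)`` so that detection sparsity (and
hence ``min_samples`` filtering) is exercised; set ``poisson_counts=False``
for noiseless expected-depth matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    CAGCatalog,
    CellGeneTable,
    GeneAbundanceMatrix,
    ParameterError,
    SampleMetadata,
)

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "simulate_cohort",
    "simulate_paired_cohorts",
    "simulate_single_cells",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-structure simulation.

    Defaults describe a cohort of 100 stool metagenomes from 60 subjects
    (1-3 samples each), 20 CAGs of 10-50 genes, and mild per-gene
    multiplicative noise around the shared CAG profile.
    """

    n_cags: int = 20
    genes_per_cag: tuple[int, int] = (10, 50)
    n_samples: int = 100
    n_subjects: int = 60
    effect_cags: int = 5
    effect_size: float = 1.0
    gene_noise_sd: float = 0.1
    latent_sd: float = 1.0
    subject_sd: float = 0.5
    gene_scale_sd: float = 0.5
    depth: int = 1_000_000
    poisson_counts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.genes_per_cag
        positive = {
            "n_cags": self.n_cags,
            "genes_per_cag low": lo,
            "genes_per_cag high": hi,
            "n_samples": self.n_samples,
            "n_subjects": self.n_subjects,
            "depth": self.depth,
        }
        for name, value in positive.items():
            if int(value) != value or value < 1:
                raise ParameterError(f"{name} must be a positive integer, got {value!r}")
        if lo > hi:
            raise ParameterError("genes_per_cag range is inverted")
        if not 0 <= self.effect_cags <= self.n_cags:
            raise ParameterError("effect_cags must be between 0 and n_cags")
        if self.gene_noise_sd < 0 or self.latent_sd < 0 or self.subject_sd < 0:
            raise ParameterError("noise standard deviations must be nonnegative")
        if self.n_subjects > self.n_samples:
            raise ParameterError("n_subjects may not exceed n_samples")
        if self.n_samples > 3 * self.n_subjects:
            raise ParameterError("subjects contribute at most 3 samples each")


@dataclass
class TruthSet:
    """Planted ground truth: CAG membership, effect signs, subjects."""

    gene_to_cag: pd.Series          # gene id -> planted CAG index
    effect_sign: pd.Series          # CAG index -> -1 / 0 / +1
    subjects: pd.DataFrame = field(default_factory=pd.DataFrame)
    # per-sample subject / status, concatenated across cohorts

    def true_catalog(self) -> CAGCatalog:
        """The planted partition as a catalog with canonical CAG ids."""
        members = [
            self.gene_to_cag.index[self.gene_to_cag == c].tolist()
            for c in np.sort(self.gene_to_cag.unique())
        ]
        return CAGCatalog.from_members(members)

    def expected_clr_shift(self, cag: int) -> float:
        """Expected CLR coefficient of the healthy indicator for one CAG.

        An additive shift ``delta_c = sign_c * effect_size`` on the log
        latent abundance propagates to the CLR (log minus per-sample mean
        log) as ``delta_c - mean_c'(delta_c')``, because the closure term
        cancels.
        """
        deltas = self.effect_sign.astype(float)
        return float(deltas.loc[cag] - deltas.mean())


def _plant_structure(config: SimulationConfig, rng: np.random.Generator):
    """Draw the cohort-independent truth: genes, CAG means, effect signs."""
    lo, hi = config.genes_per_cag
    sizes = rng.integers(lo, hi + 1, size=config.n_cags)
    gene_cag = np.repeat(np.arange(config.n_cags), sizes)
    gene_ids = pd.Index([f"g{i:05d}" for i in range(len(gene_cag))], name="gene")
    cag_mean = rng.normal(0.0, 1.0, size=config.n_cags)
    gene_offset = rng.normal(0.0, config.gene_scale_sd, size=len(gene_cag))
    signs = np.zeros(config.n_cags, dtype=np.int64)
    if config.effect_cags and config.effect_size != 0:
        chosen = rng.choice(config.n_cags, size=config.effect_cags, replace=False)
        signs[chosen] = rng.choice([-1, 1], size=config.effect_cags)
    truth = TruthSet(
        gene_to_cag=pd.Series(gene_cag, index=gene_ids, name="true_cag"),
        effect_sign=pd.Series(signs, index=pd.RangeIndex(config.n_cags), name="sign"),
    )
    return truth, cag_mean, gene_offset


def _draw_samples(
    config: SimulationConfig,
    rng: np.random.Generator,
    truth: TruthSet,
    cag_mean: np.ndarray,
    gene_offset: np.ndarray,
    cohort: str,
    prefix: str,
) -> tuple[GeneAbundanceMatrix, SampleMetadata]:
    n_sub, n_samp = config.n_subjects, config.n_samples
    # each subject contributes 1-3 samples; extras assigned round-robin to a
    # random subject ordering so repeat counts vary across seeds
    counts = np.ones(n_sub, dtype=np.int64)
    extra = n_samp - n_sub
    order = rng.permutation(n_sub)
    for k in range(extra):
        counts[order[k % n_sub]] += 1
    subj_of_sample = np.repeat(np.arange(n_sub), counts)
    status_of_subject = (np.arange(n_sub) % 2).astype(np.int64)  # balanced 0/1

    sample_ids = pd.Index(
        [f"{prefix}S{i:04d}" for i in range(n_samp)], name="sample"
    )
    subject_ids = np.array([f"{prefix}subj{j:03d}" for j in range(n_sub)])
    status = status_of_subject[subj_of_sample]
    healthy = (1 - status).astype(float)

    u = rng.normal(0.0, config.subject_sd, size=(config.n_cags, n_sub))
    eps = rng.normal(0.0, config.latent_sd, size=(config.n_cags, n_samp))
    shift = (
        config.effect_size
        * truth.effect_sign.to_numpy(dtype=float)[:, None]
        * healthy[None, :]
    )
    latent = cag_mean[:, None] + u[:, subj_of_sample] + eps + shift

    gene_cag = truth.gene_to_cag.to_numpy()
    log_abund = latent[gene_cag, :] + gene_offset[:, None]
    if config.gene_noise_sd > 0:
        log_abund = log_abund + rng.normal(
            0.0, config.gene_noise_sd, size=log_abund.shape
        )
    abund = np.exp(log_abund)
    rel = abund / abund.sum(axis=0, keepdims=True)
    if config.poisson_counts:
        values = rng.poisson(config.depth * rel).astype(float)
    else:
        values = config.depth * rel

    matrix = GeneAbundanceMatrix(
        pd.DataFrame(values, index=truth.gene_to_cag.index, columns=sample_ids),
        normalized=False,
    )
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "subject": subject_ids[subj_of_sample],
                "status": status,
                "cohort": cohort,
            },
            index=sample_ids,
        )
    )
    return matrix, meta


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[GeneAbundanceMatrix, SampleMetadata, TruthSet]:
    """Simulate one cohort with planted CAG structure.

    Returns the raw-depth genes-by-samples matrix, per-sample metadata
    (cohort role ``"discovery"``), and the ground truth.  Deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    truth, cag_mean, gene_offset = _plant_structure(config, rng)
    matrix, meta = _draw_samples(
        config, rng, truth, cag_mean, gene_offset, "discovery", "D"
    )
    truth.subjects = meta.table[["subject", "status"]].copy()
    return matrix, meta, truth


def simulate_paired_cohorts(
    config: SimulationConfig,
) -> tuple[
    tuple[GeneAbundanceMatrix, SampleMetadata],
    tuple[GeneAbundanceMatrix, SampleMetadata],
    TruthSet,
]:
    """Simulate a discovery and a validation cohort sharing one truth.

    Both cohorts share the gene universe, planted CAG structure, and
    effect signs (as when the validation cohort is quantified against the
    discovery gene catalog); subjects and sampling noise are independent.
    """
    rng = np.random.default_rng(config.seed)
    truth, cag_mean, gene_offset = _plant_structure(config, rng)
    disc = _draw_samples(config, rng, truth, cag_mean, gene_offset, "discovery", "D")
    val = _draw_samples(config, rng, truth, cag_mean, gene_offset, "validation", "V")
    truth.subjects = pd.concat(
        [disc[1].table[["subject", "status"]], val[1].table[["subject", "status"]]]
    )
    return disc, val, truth


def simulate_single_cells(
    catalog: CAGCatalog,
    n_cells: int,
    genes_per_cell: int,
    within_cag_enrichment: float = 1.0,
    seed: int = 0,
    resident_cags: int = 2,
) -> CellGeneTable:
    """Simulate single-cell gene detections with tunable CAG co-placement.

    Each cell picks ``resident_cags`` CAGs and samples ``genes_per_cell``
    distinct genes with weight ``within_cag_enrichment`` on resident-CAG
    genes and 1 elsewhere.  ``within_cag_enrichment = 1`` reduces to
    uniform sampling (the null construction for the permutation test).
    """
    if len(catalog) == 0:
        raise ParameterError("catalog is empty")
    if genes_per_cell < 1:
        raise ParameterError("genes_per_cell must be >= 1")
    if genes_per_cell > len(catalog):
        raise ParameterError(
            f"genes_per_cell={genes_per_cell} exceeds the {len(catalog)} catalog genes"
        )
    if within_cag_enrichment < 1:
        raise ParameterError("within_cag_enrichment must be >= 1")
    if n_cells < 0:
        raise ParameterError("n_cells must be nonnegative")

    rng = np.random.default_rng(seed)
    genes = catalog.gene_ids.to_numpy()
    labels = catalog.gene_to_cag.to_numpy()
    cag_ids = np.unique(labels)
    cells: dict[str, frozenset[str]] = {}
    for i in range(n_cells):
        weights = np.ones(len(genes))
        if within_cag_enrichment > 1:
            k = min(resident_cags, len(cag_ids))
            resident = rng.choice(cag_ids, size=k, replace=False)
            weights[np.isin(labels, resident)] = within_cag_enrichment
        chosen = rng.choice(
            len(genes), size=genes_per_cell, replace=False, p=weights / weights.sum()
        )
        cells[f"cell{i:05d}"] = frozenset(genes[chosen])
    return CellGeneTable(cells)
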