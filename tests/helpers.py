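"""Shared test helpers: the end-to-end association pipeline on a catalog."""

from __future__ import annotations

import numpy as np
import pandas as pd

import coabund as cb


def cag_pipeline(
    matrix: cb.GeneAbundanceMatrix,
    meta: cb.SampleMetadata,
    catalog: cb.CAGCatalog,
    model: str = "auto",
) -> pd.DataFrame:
    """Normalize -> aggregate -> CLR -> per-CAG models -> q-values."""
    sub = cb.GeneAbundanceMatrix(
        matrix.values.loc[catalog.gene_ids], normalized=False
    )
    cags = cb.cag_abundance(cb.sum_normalize(sub), catalog)
    clr = cb.clr_transform(cags)
    return cb.add_qvalues(cb.fit_cag_association(clr, meta, model=model))


def gene_pipeline(
    matrix: cb.GeneAbundanceMatrix,
    meta: cb.SampleMetadata,
    genes,
    model: str = "auto",
) -> pd.DataFrame:
    """The unclustered comparison: CLR association on selected genes."""
    sub = cb.sum_normalize(
        cb.GeneAbundanceMatrix(matrix.values.loc[list(genes)], normalized=False)
    )
    clr = cb.clr_transform(sub.values)
    return cb.add_qvalues(cb.fit_cag_association(clr, meta, model=model))


def canonical_ids(truth: cb.TruthSet, catalog: cb.CAGCatalog) -> dict[int, int]:
    """Map each planted CAG index to its id in the canonical catalog."""
    first = truth.gene_to_cag.reset_index().groupby("true_cag")["gene"].first()
    return {int(tc): int(catalog.gene_to_cag[g]) for tc, g in first.items()}


def same_partition(a: cb.CAGCatalog, b: cb.CAGCatalog) -> bool:
    """Identical partitions (labels may differ only by renaming)."""
    if set(a.gene_ids) != set(b.gene_ids):
        return False
    la = a.gene_to_cag.loc[b.gene_ids].to_numpy()
    lb = b.gene_to_cag.to_numpy()
    pairs = set(zip(la.tolist(), lb.tolist()))
    return len(pairs) == len(set(la.tolist())) == len(set(lb.tolist()))


def null_config(seed: int) -> cb.SimulationConfig:
    """Global-null paired-cohort conditions used for calibration checks."""
    return cb.SimulationConfig(
        seed=seed,
        n_cags=100,
        genes_per_cag=(2, 5),
        n_samples=40,
        n_subjects=40,
        effect_cags=0,
        effect_size=0.0,
    )


def replicate_seeds(base_seed: int, n: int) -> list[int]:
    """Independent per-replicate seeds derived from one base seed."""
    return [int(s) for s in np.random.SeedSequence(base_seed).generate_state(n) % (2**31)]
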