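"""Single-cell co-occurrence test for CAG physical linkage.

If the genes of a CAG truly ride on the same piece of DNA, they should be
detected together in the same physical cell of a single-cell microbiome
sequencing experiment.  The statistic is the number of (cell, gene)
detections for which at least one *other* gene of the same CAG is
detected in the same cell; the null distribution comes from uniformly
permuting the gene-to-CAG assignment over the gene universe (preserving
the multiset of CAG sizes), and enrichment is reported as
observed / mean(permuted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CAGCatalog, CellGeneTable, ParameterError

logger = logging.getLogger(__name__)

__all__ = ["CooccurrenceResult", "cooccurrence_count", "permutation_ratio"]


@dataclass
class CooccurrenceResult:
    """Observed co-occurrence against its permutation null.

    ``ratio`` is observed / permutation mean; it is undefined (NaN, with
    ``ratio_defined`` False) when no permuted replicate produced any
    co-occurrence.
    """

    observed: int
    perm_mean: float
    perm_sd: float
    ratio: float
    n_reps: int
    seed: int
    ratio_defined: bool = True


def _detections(
    cells: CellGeneTable, catalog: CAGCatalog
) -> tuple[np.ndarray, np.ndarray]:
    """(cell index, gene index) arrays over catalog-covered detections."""
    if cells.n_cells == 0:
        raise ParameterError("empty cell table: co-occurrence undefined")
    gene_pos = {g: i for i, g in enumerate(catalog.gene_ids)}
    cell_idx: list[int] = []
    gene_idx: list[int] = []
    dropped = 0
    for ci, barcode in enumerate(sorted(cells.cells)):
        for gene in cells.cells[barcode]:
            pos = gene_pos.get(gene)
            if pos is None:
                dropped += 1
            else:
                cell_idx.append(ci)
                gene_idx.append(pos)
    if dropped:
        logger.warning(
            "%d detections of genes absent from the catalog were dropped", dropped
        )
    if not cell_idx:
        raise ParameterError("no detections remain after catalog filtering")
    return np.asarray(cell_idx, dtype=np.int64), np.asarray(gene_idx, dtype=np.int64)


def _count(cell_idx: np.ndarray, labels_of_detection: np.ndarray, n_labels: int) -> int:
    """Detections whose (cell, CAG) group contains >= 2 detections.

    Gene sets per cell are distinct genes, so two detections in the same
    (cell, CAG) group are two different genes of one CAG in one cell.
    """
    key = cell_idx * np.int64(n_labels) + labels_of_detection
    _, counts = np.unique(key, return_counts=True)
    return int(counts[counts >= 2].sum())


def cooccurrence_count(cells: CellGeneTable, catalog: CAGCatalog) -> int:
    """Number of detections sharing a cell with a same-CAG gene."""
    cell_idx, gene_idx = _detections(cells, catalog)
    labels = catalog.gene_to_cag.to_numpy()
    return _count(cell_idx, labels[gene_idx], catalog.n_cags)


def permutation_ratio(
    cells: CellGeneTable,
    catalog: CAGCatalog,
    n_reps: int = 1000,
    seed: int = 0,
) -> CooccurrenceResult:
    """Observed co-occurrence over its permutation-null expectation.

    Each replicate permutes the CAG assignment uniformly over the whole
    gene universe of the catalog (not only cell-detected genes), exactly
    preserving the CAG size distribution, and recounts.  Deterministic
    given ``seed``.
    """
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    cell_idx, gene_idx = _detections(cells, catalog)
    labels = catalog.gene_to_cag.to_numpy()
    n_labels = catalog.n_cags
    observed = _count(cell_idx, labels[gene_idx], n_labels)

    rng = np.random.default_rng(seed)
    null = np.empty(n_reps, dtype=np.int64)
    for r in range(n_reps):
        permuted = labels[rng.permutation(len(labels))]
        null[r] = _count(cell_idx, permuted[gene_idx], n_labels)
    perm_mean = float(null.mean())
    perm_sd = float(null.std(ddof=1)) if n_reps > 1 else 0.0
    defined = perm_mean > 0
    ratio = observed / perm_mean if defined else float("nan")
    if not defined:
        logger.warning("permutation mean is zero: enrichment ratio undefined")
    return CooccurrenceResult(
        observed=observed,
        perm_mean=perm_mean,
        perm_sd=perm_sd,
        ratio=ratio,
        n_reps=n_reps,
        seed=seed,
        ratio_defined=defined,
    )
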