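"""Co-abundant gene (CAG) clustering by cosine distance.

Genes that ride on the same replicon rise and fall together across
samples, so their depth profiles have small cosine distance.  Exhaustive
average-linkage clustering of millions of genes is intractable (all-pairs
distances), so the main entry point :func:`find_cags` uses an approximate
nearest neighbor (ANN) index to propose candidate subsets of co-abundant
items that can be clustered independently of the whole, and iterates:

  round r:
    1. retrieve ``ann_k`` approximate neighbors of every item (round 1:
       genes; later rounds: cluster mean profiles plus unmerged items)
       under cosine distance;
    2. keep candidate pairs whose *exact* inter-cluster distance — the
       mean cosine distance over all member pairs — is at most
       ``max_dist``; candidate subsets are the connected components of
       that graph;
    3. run exact average-linkage (UPGMA) within each subset, cutting the
       dendrogram at cophenetic distance ``max_dist``;
  stop when a round merges nothing (or ``max_rounds`` is reached).

The mean member-pair cosine distance between clusters A and B is computed
exactly at any size via the identity

    d(A, B) = 1 - (s_A . s_B) / (|A| |B|),    s_X = sum of L2-normalized
                                              member profiles,

which also gives the standard UPGMA update (s_{A+B} = s_A + s_B), so no
centroid approximation is ever needed.  A brute-force all-pairs oracle,
:func:`exact_average_linkage`, is provided for verification on small
inputs; on candidate subsets covering the true ≤ ``max_dist`` graph the
iterative scheme provably returns the same partition the oracle does.

All candidate lists and merge queues are ordered by (distance, smallest
member gene id), making the procedure deterministic given the seed and
input ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist

from .containers import (
    CAGCatalog,
    FormatError,
    GeneAbundanceMatrix,
    ParameterError,
)

__all__ = [
    "ClusteringParams",
    "CAGAbundanceMatrix",
    "sum_normalize",
    "filter_min_samples",
    "cosine_distance",
    "exact_average_linkage",
    "ann_candidate_groups",
    "find_cags",
    "cag_abundance",
]

#: all-pairs oracle refuses above this many genes
ORACLE_MAX_GENES = 5000

#: below this many items the "auto" backend uses exact kNN (a dense
#: similarity matrix is cheaper than building an ANN index)
EXACT_BACKEND_MAX_ITEMS = 2000


@dataclass(frozen=True)
class ClusteringParams:
    """Knobs of the CAG clustering procedure.

    ``max_dist`` is the cophenetic cosine-distance threshold at which the
    average-linkage dendrogram is cut (default 0.3); ``min_samples`` is
    the minimum number of samples a gene must be detected in (default
    10); ``ann_k`` is the number of neighbors retrieved per query.
    ``ann_backend`` selects the neighbor search: ``"exact"`` (brute
    force), ``"nndescent"`` (pynndescent graph index), or ``"auto"``
    (exact below :data:`EXACT_BACKEND_MAX_ITEMS` items).
    """

    max_dist: float = 0.3
    min_samples: int = 10
    ann_k: int = 100
    ann_backend: str = "auto"
    max_rounds: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.max_dist <= 1:
            raise ParameterError("max_dist must be in (0, 1]")
        if self.min_samples < 1:
            raise ParameterError("min_samples must be >= 1")
        if self.ann_k < 2:
            raise ParameterError("ann_k must be >= 2")
        if self.max_rounds < 1:
            raise ParameterError("max_rounds must be >= 1")
        if self.ann_backend not in ("auto", "exact", "nndescent"):
            raise ParameterError(f"unknown ann_backend {self.ann_backend!r}")


@dataclass
class CAGAbundanceMatrix:
    """CAGs-by-samples matrix of aggregated relative abundance.

    Each value is the sum of the member genes' normalized abundances in
    that sample, so singleton CAGs equal their gene and per-sample totals
    are conserved.
    """

    values: pd.DataFrame  # index: CAG id; columns: sample id

    @property
    def cag_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


# ---------------------------------------------------------------------------
# normalization and filtering


def sum_normalize(m: GeneAbundanceMatrix) -> GeneAbundanceMatrix:
    """Divide each sample column by its total depth (idempotent)."""
    totals = m.values.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ParameterError(f"sample {zero[0]!r} has zero total depth")
    return GeneAbundanceMatrix(m.values / totals, normalized=True)


def filter_min_samples(
    m: GeneAbundanceMatrix, min_samples: int
) -> tuple[GeneAbundanceMatrix, list[str]]:
    """Keep genes detected (nonzero) in at least ``min_samples`` samples.

    Returns the retained matrix and the list of excluded gene ids.  A
    retained normalized matrix is re-flagged raw because its columns no
    longer sum to one; callers re-normalize if needed (cosine distance is
    unaffected either way).
    """
    if min_samples < 1:
        raise ParameterError("min_samples must be >= 1")
    detected = (m.values > 0).sum(axis=1)
    keep = detected >= min_samples
    excluded = m.gene_ids[~keep].tolist()
    kept = m.values.loc[keep]
    still_normalized = m.normalized and not excluded
    return GeneAbundanceMatrix(kept, normalized=still_normalized), excluded


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine distance 1 - (u.v)/(|u||v|); in [0, 1] for nonnegative input."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ParameterError("cosine distance undefined for a zero vector")
    return float(1.0 - (u @ v) / (nu * nv))


# ---------------------------------------------------------------------------
# exact all-pairs oracle


def exact_average_linkage(m: GeneAbundanceMatrix, max_dist: float) -> CAGCatalog:
    """Brute-force UPGMA on all pairwise cosine distances, cut at ``max_dist``.

    Test oracle: quadratic in the number of genes, refused above
    :data:`ORACLE_MAX_GENES`.
    """
    n = m.shape[0]
    if n > ORACLE_MAX_GENES:
        raise ParameterError(
            f"exact oracle limited to {ORACLE_MAX_GENES} genes, got {n}"
        )
    if n == 0:
        raise ParameterError("empty matrix")
    X = m.values.to_numpy(dtype=float)
    if n == 1:
        return CAGCatalog.from_members([[m.gene_ids[0]]])
    d = np.clip(pdist(X, metric="cosine"), 0.0, None)
    tree = linkage(d, method="average")
    flat = fcluster(tree, t=max_dist, criterion="distance")
    members: dict[int, list[str]] = {}
    for gene, lab in zip(m.gene_ids, flat):
        members.setdefault(int(lab), []).append(gene)
    return CAGCatalog.from_members(list(members.values()))


# ---------------------------------------------------------------------------
# neighbor retrieval


def _unit_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        raise ParameterError("cannot cluster an all-zero abundance profile")
    return X / norms[:, None]


def _knn_graph(
    reps: np.ndarray, k: int, backend: str, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """k nearest items per row under cosine distance, with rep dot products.

    Returns ``(neighbors, dots)`` where ``dots[i, t] = reps[i] . reps[nb]``.
    Because a cluster's rep is the mean of its members' unit vectors, this
    dot product is exactly the mean pairwise cosine *similarity* between
    the two clusters, so ``1 - dots`` is the exact average-linkage
    distance — the ANN retrieval is approximate, the verification exact.
    Self-neighbors may appear and are filtered by callers.
    """
    n = len(reps)
    k = min(k, n - 1)
    if backend == "auto":
        backend = "exact" if n <= EXACT_BACKEND_MAX_ITEMS else "nndescent"
    if backend == "exact":
        dots_full = reps @ reps.T
        norms = np.sqrt(np.diag(dots_full))
        sim = dots_full / np.outer(norms, norms)
        np.fill_diagonal(sim, -np.inf)
        idx = np.argpartition(-sim, kth=k - 1, axis=1)[:, :k]
        return idx, np.take_along_axis(dots_full, idx, axis=1)
    # NN-descent graph index; exact re-verification downstream makes the
    # approximation safe (missed edges only defer merges to a later round)
    import pynndescent

    index = pynndescent.NNDescent(
        reps,
        metric="cosine",
        n_neighbors=min(k + 1, n),
        random_state=seed,
        verbose=False,
    )
    neighbors, cos_dist = index.neighbor_graph
    norms = np.linalg.norm(reps, axis=1)
    dots = (1.0 - cos_dist) * norms[:, None] * norms[neighbors]
    return neighbors, dots


def _verified_edges(
    neighbors: np.ndarray, dots: np.ndarray, max_dist: float
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate pairs whose exact mean member-pair distance is <= max_dist."""
    n = len(neighbors)
    src = np.repeat(np.arange(n), neighbors.shape[1])
    dst = neighbors.ravel()
    dist = 1.0 - dots.ravel()
    ok = (src != dst) & (dist <= max_dist)
    return src[ok], dst[ok]


# ---------------------------------------------------------------------------
# weighted UPGMA on cluster summaries


def _upgma_merge(
    S: np.ndarray,
    sizes: np.ndarray,
    keys: list[str],
    max_dist: float,
) -> list[list[int]]:
    """Agglomerate clusters (rows of S = summed unit vectors) by UPGMA.

    Returns groups of input indices merged into one output cluster.  Ties
    in the merge queue break on the (smallest member id, second-smallest)
    pair of the candidate clusters, for determinism.
    """
    m = len(sizes)
    S = S.copy()
    sizes = sizes.astype(float).copy()
    keys = list(keys)
    groups: list[list[int]] = [[i] for i in range(m)]
    active = np.ones(m, dtype=bool)

    D = 1.0 - (S @ S.T) / np.outer(sizes, sizes)
    np.fill_diagonal(D, np.inf)

    while active.sum() > 1:
        dmin = D.min()
        if dmin > max_dist:
            break
        ii, jj = np.nonzero(D == dmin)
        pairs = [(i, j) for i, j in zip(ii, jj) if i < j]
        i, j = min(pairs, key=lambda p: tuple(sorted((keys[p[0]], keys[p[1]]))))
        # UPGMA update via summed unit vectors
        S[i] += S[j]
        sizes[i] += sizes[j]
        keys[i] = min(keys[i], keys[j])
        groups[i].extend(groups[j])
        active[j] = False
        D[j, :] = np.inf
        D[:, j] = np.inf
        act = np.flatnonzero(active)
        act = act[act != i]
        if len(act):
            d_new = 1.0 - (S[act] @ S[i]) / (sizes[act] * sizes[i])
            D[i, act] = d_new
            D[act, i] = d_new
        D[i, i] = np.inf
    return [groups[i] for i in np.flatnonzero(active)]


# ---------------------------------------------------------------------------
# candidate subsets and the main iterative procedure


def _candidate_components(
    S: np.ndarray, sizes: np.ndarray, params: ClusteringParams
) -> np.ndarray:
    """Connected-component label per item of the verified candidate graph."""
    n = len(S)
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    reps = S / sizes[:, None]
    neighbors, dots = _knn_graph(reps, params.ann_k, params.ann_backend, params.seed)
    src, dst = _verified_edges(neighbors, dots, params.max_dist)
    graph = coo_matrix(
        (np.ones(len(src)), (src, dst)), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    return labels


def ann_candidate_groups(
    m: GeneAbundanceMatrix, params: ClusteringParams | None = None
) -> list[list[str]]:
    """Subsets of genes likely to be co-abundant, clusterable independently.

    For each gene, ``ann_k`` approximate neighbors are retrieved under
    cosine distance; pairs are kept only after exact verification of
    distance <= ``max_dist``, and the candidate subsets are the connected
    components of the resulting graph.  Every gene lands in exactly one
    subset (possibly a singleton).
    """
    params = params or ClusteringParams()
    X = m.values.to_numpy(dtype=float)
    U = _unit_rows(X)
    sizes = np.ones(len(U))
    labels = _candidate_components(U, sizes, params)
    groups: dict[int, list[str]] = {}
    for gene, lab in zip(m.gene_ids, labels):
        groups.setdefault(int(lab), []).append(gene)
    return sorted(groups.values(), key=lambda g: min(g))


def find_cags(
    m: GeneAbundanceMatrix, params: ClusteringParams | None = None
) -> CAGCatalog:
    """Group genes into CAGs (main entry point).

    Applies sum normalization and ``min_samples`` filtering, then runs
    the iterative ANN-candidate / local-UPGMA scheme described in the
    module docstring.  Genes excluded by the detection filter are omitted
    from the catalog (no co-abundance evidence); retrieve them with
    :func:`filter_min_samples`.
    """
    params = params or ClusteringParams()
    if not m.normalized:
        m = sum_normalize(m)
    m, _excluded = filter_min_samples(m, params.min_samples)
    if m.shape[0] == 0:
        raise ParameterError("no genes remain after min_samples filtering")

    gene_ids = m.gene_ids.to_numpy()
    U = _unit_rows(m.values.to_numpy(dtype=float))

    # cluster state: summed unit vectors, sizes, member gene-index lists,
    # smallest member id per cluster (tie-break key)
    S = U.copy()
    sizes = np.ones(len(U))
    members: list[list[int]] = [[i] for i in range(len(U))]
    keys: list[str] = [str(g) for g in gene_ids]

    for _round in range(params.max_rounds):
        labels = _candidate_components(S, sizes, params)
        new_S: list[np.ndarray] = []
        new_sizes: list[float] = []
        new_members: list[list[int]] = []
        new_keys: list[str] = []
        merged_any = False
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            if len(idx) == 1:
                i = idx[0]
                new_S.append(S[i])
                new_sizes.append(sizes[i])
                new_members.append(members[i])
                new_keys.append(keys[i])
                continue
            groups = _upgma_merge(
                S[idx], sizes[idx], [keys[i] for i in idx], params.max_dist
            )
            if len(groups) < len(idx):
                merged_any = True
            for g in groups:
                orig = [idx[t] for t in g]
                new_S.append(np.sum(S[orig], axis=0) if len(orig) > 1 else S[orig[0]])
                new_sizes.append(float(sum(sizes[o] for o in orig)))
                new_members.append([gi for o in orig for gi in members[o]])
                new_keys.append(min(keys[o] for o in orig))
        S = np.vstack(new_S)
        sizes = np.asarray(new_sizes)
        members = new_members
        keys = new_keys
        if not merged_any:
            break

    return CAGCatalog.from_members(
        [[str(gene_ids[i]) for i in grp] for grp in members]
    )


# ---------------------------------------------------------------------------
# CAG-level abundance


def cag_abundance(
    m: GeneAbundanceMatrix, catalog: CAGCatalog
) -> CAGAbundanceMatrix:
    """Sum member genes' relative abundances per CAG per sample.

    ``m`` must be normalized; every catalog gene must be present in the
    matrix (matrix genes outside the catalog — e.g. excluded by the
    detection filter — are ignored).
    """
    if not m.normalized:
        raise ParameterError("cag_abundance requires a normalized matrix")
    missing = catalog.gene_ids.difference(m.gene_ids)
    if len(missing):
        raise FormatError(
            f"catalog genes absent from matrix: {list(missing)[:5]}"
        )
    sub = m.values.loc[catalog.gene_ids]
    agg = sub.groupby(catalog.gene_to_cag).sum()
    agg.index.name = "cag"
    return CAGAbundanceMatrix(agg.sort_index())
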