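"""Core in-memory containers shared across the pipeline.

The fundamental unit of analysis is the Co-Abundant Gene group (CAG): a set
of microbial genes whose sequencing depth tracks together across samples,
presumed to lie on the same chromosome, plasmid, or operon.  These light
wrappers around pandas objects carry the invariants each stage relies on:
a nonnegative genes-by-samples abundance matrix, per-sample metadata with a
binary disease status, a gene-to-CAG partition, gene annotations, and the
single-cell barcode-to-genes table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CoabundError",
    "FormatError",
    "ParameterError",
    "GeneAbundanceMatrix",
    "SampleMetadata",
    "CAGCatalog",
    "AnnotationTable",
    "CellGeneTable",
]


class CoabundError(Exception):
    """Base class for errors raised by this package."""


class FormatError(CoabundError):
    """A file or table violates the declared format."""


class ParameterError(CoabundError):
    """A parameter or configuration value is invalid."""


@dataclass
class GeneAbundanceMatrix:
    """Genes-by-samples abundance matrix.

    ``values`` holds nonnegative reals: raw per-gene sequencing depth, or
    relative abundance if ``normalized`` is True (each sample column then
    sums to 1 over the retained genes).
    """

    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("abundance values must be numeric")
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise FormatError(
                f"missing value at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative abundance {arr[g, s]!r} at gene {df.index[g]!r}, "
                f"sample {df.columns[s]!r}"
            )
        if self.normalized:
            sums = arr.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = df.columns[np.argmax(np.abs(sums - 1.0))]
                raise FormatError(
                    f"matrix flagged normalized but sample {bad!r} does not sum to 1"
                )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SampleMetadata:
    """Per-sample metadata: subject, binary disease status, cohort role.

    ``status`` is 1 for disease, 0 for healthy.  ``cohort`` is either
    ``"discovery"`` or ``"validation"``.
    """

    table: pd.DataFrame  # index: sample id; columns: subject, status, cohort

    REQUIRED = ("subject", "status", "cohort")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        if t.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")
        if t["status"].isna().any():
            bad = t.index[t["status"].isna()][0]
            raise FormatError(f"missing disease status for sample {bad!r}")
        if not set(np.unique(t["status"])) <= {0, 1}:
            raise FormatError("disease status must be binary (0/1)")
        bad_roles = set(t["cohort"].unique()) - {"discovery", "validation"}
        if bad_roles:
            raise FormatError(f"unknown cohort roles: {sorted(bad_roles)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def check_covers(self, matrix: GeneAbundanceMatrix) -> None:
        """Every sample in the abundance matrix must have exactly one row."""
        missing = matrix.sample_ids.difference(self.table.index)
        if len(missing):
            raise FormatError(f"samples without metadata: {list(missing)[:5]}")

    def repeated_measures(self) -> bool:
        return bool(self.table["subject"].duplicated().any())


@dataclass
class CAGCatalog:
    """Partition of genes into CAGs.

    CAG ids are dense integers from 0, assigned in order of descending CAG
    size with ties broken by the lexicographically smallest member gene id,
    so catalogs are deterministic and diff-friendly.
    """

    gene_to_cag: pd.Series  # index: gene id; values: int CAG id

    def __post_init__(self) -> None:
        s = self.gene_to_cag
        if s.index.has_duplicates:
            raise FormatError("a gene appears in more than one CAG")
        self.gene_to_cag = s.astype(np.int64)

    @classmethod
    def from_members(cls, members: list[list[str]]) -> "CAGCatalog":
        """Build a catalog from member lists, applying the canonical id order."""
        ordered = sorted(members, key=lambda m: (-len(m), min(m)))
        mapping: dict[str, int] = {}
        for cag_id, genes in enumerate(ordered):
            for g in genes:
                if g in mapping:
                    raise FormatError(f"gene {g!r} appears in more than one CAG")
                mapping[g] = cag_id
        return cls(pd.Series(mapping, name="cag"))

    @property
    def gene_ids(self) -> pd.Index:
        return self.gene_to_cag.index

    @property
    def cag_ids(self) -> np.ndarray:
        return np.sort(self.gene_to_cag.unique())

    @property
    def n_cags(self) -> int:
        return int(self.gene_to_cag.nunique())

    def members(self, cag_id: int) -> list[str]:
        return self.gene_to_cag.index[self.gene_to_cag == cag_id].tolist()

    def sizes(self) -> pd.Series:
        return self.gene_to_cag.value_counts().sort_index()

    def __len__(self) -> int:
        return len(self.gene_to_cag)


@dataclass
class AnnotationTable:
    """Gene id -> set of functional/taxonomic labels (opaque strings)."""

    labels: dict[str, frozenset[str]] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs) -> "AnnotationTable":
        out: dict[str, set[str]] = {}
        for gene, label in pairs:
            out.setdefault(str(gene), set()).add(str(label))
        return cls({g: frozenset(v) for g, v in out.items()})

    def get(self, gene: str) -> frozenset[str]:
        return self.labels.get(gene, frozenset())

    def all_labels(self) -> set[str]:
        out: set[str] = set()
        for v in self.labels.values():
            out |= v
        return out


@dataclass
class CellGeneTable:
    """Single-cell barcode -> set of detected gene ids."""

    cells: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for barcode, genes in self.cells.items():
            if not genes:
                raise FormatError(f"cell {barcode!r} has an empty gene set")

    @classmethod
    def from_pairs(cls, pairs) -> "CellGeneTable":
        out: dict[str, set[str]] = {}
        for barcode, gene in pairs:
            out.setdefault(str(barcode), set()).add(str(gene))
        return cls({b: frozenset(v) for b, v in out.items()})

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_pairs(self) -> list[tuple[str, str]]:
        return [
            (b, g) for b in sorted(self.cells) for g in sorted(self.cells[b])
        ]
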