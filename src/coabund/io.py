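"""Readers and writers for the pipeline's tabular artifacts.

Delimited text for everything a user inspects (abundance TSV/CSV with
genes as rows, metadata / catalog / annotation / results CSV), plus a
single hierarchical HDF5 container grouping the outputs of a whole run.
Delimiter is inferred from the file extension (``.tsv`` tab, otherwise
comma); everything is UTF-8 with unquoted identifiers.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import (
    AnnotationTable,
    CAGCatalog,
    CellGeneTable,
    FormatError,
    GeneAbundanceMatrix,
    SampleMetadata,
)

__all__ = [
    "read_abundance",
    "write_abundance",
    "read_metadata",
    "write_metadata",
    "read_catalog",
    "write_catalog",
    "read_annotations",
    "write_annotations",
    "read_cells",
    "write_cells",
    "read_association",
    "write_association",
    "write_results_store",
    "read_results_store",
]


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def _read_table(path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        return pd.read_csv(path, sep=_sep(path), **kwargs)
    except pd.errors.ParserError as exc:  # ragged rows etc.; pandas names the line
        raise FormatError(f"{path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc


# ---------------------------------------------------------------------------
# abundance matrices


def read_abundance(path, orientation: str = "genes") -> GeneAbundanceMatrix:
    """Read a delimited genes-by-samples abundance matrix (raw depth).

    Header row holds sample ids, first column gene ids; pass
    ``orientation="samples"`` for transposed (samples-as-rows) input.
    """
    if orientation not in ("genes", "samples"):
        raise FormatError(f"orientation must be 'genes' or 'samples', got {orientation!r}")
    df = _read_table(path, index_col=0)
    if orientation == "samples":
        df = df.T
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise FormatError(
                f"{path}: non-numeric value {bad.iloc[0]!r} at gene {row!r}, "
                f"sample {col!r}"
            )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return GeneAbundanceMatrix(df.astype(float), normalized=False)


def write_abundance(matrix: GeneAbundanceMatrix, path) -> None:
    matrix.values.to_csv(path, sep=_sep(path), index_label="gene")


# ---------------------------------------------------------------------------
# metadata, catalogs, annotations, cells, results


def read_metadata(path) -> SampleMetadata:
    """CSV with columns sample,subject,status,cohort."""
    df = _read_table(path)
    if "sample" not in df.columns:
        raise FormatError(f"{path}: missing 'sample' column")
    df = df.set_index("sample")
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep=_sep(path), index_label="sample")


def read_catalog(path) -> CAGCatalog:
    """CSV with columns gene,cag."""
    df = _read_table(path)
    if not {"gene", "cag"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns gene,cag")
    return CAGCatalog(pd.Series(df["cag"].to_numpy(), index=df["gene"].astype(str), name="cag"))


def write_catalog(catalog: CAGCatalog, path) -> None:
    catalog.gene_to_cag.rename_axis("gene").to_csv(path, sep=_sep(path))


def read_annotations(path) -> AnnotationTable:
    """CSV with columns gene,label; one row per (gene, label) pair."""
    df = _read_table(path)
    if not {"gene", "label"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns gene,label")
    return AnnotationTable.from_pairs(zip(df["gene"], df["label"]))


def write_annotations(annotations: AnnotationTable, path) -> None:
    rows = [
        (g, label)
        for g in sorted(annotations.labels)
        for label in sorted(annotations.labels[g])
    ]
    pd.DataFrame(rows, columns=["gene", "label"]).to_csv(path, sep=_sep(path), index=False)


def read_cells(path) -> CellGeneTable:
    """CSV with columns barcode,gene; one row per detection."""
    df = _read_table(path)
    if not {"barcode", "gene"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns barcode,gene")
    return CellGeneTable.from_pairs(zip(df["barcode"], df["gene"]))


def write_cells(cells: CellGeneTable, path) -> None:
    pd.DataFrame(cells.to_pairs(), columns=["barcode", "gene"]).to_csv(
        path, sep=_sep(path), index=False
    )


def read_association(path) -> pd.DataFrame:
    df = _read_table(path)
    if "cag" not in df.columns:
        raise FormatError(f"{path}: missing 'cag' column")
    return df.set_index("cag")


def write_association(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep=_sep(path), index_label="cag")


# ---------------------------------------------------------------------------
# HDF5 results store

_STR = h5py.string_dtype(encoding="utf-8")


def _write_strings(group: h5py.Group, name: str, values) -> None:
    group.create_dataset(name, data=np.asarray([str(v) for v in values], dtype=object), dtype=_STR)


def _read_strings(group: h5py.Group, name: str) -> list[str]:
    return [v.decode() if isinstance(v, bytes) else str(v) for v in group[name][()]]


def write_results_store(
    path,
    abundance: GeneAbundanceMatrix | None = None,
    catalog: CAGCatalog | None = None,
    results: pd.DataFrame | None = None,
    metadata: SampleMetadata | None = None,
) -> None:
    """Write a single hierarchical HDF5 container for a run.

    Group names: ``abund`` (values + gene/sample ids + normalized flag),
    ``cags`` (gene -> CAG id), ``stats`` (association results), and
    ``metadata``.  A ``complete`` attribute is set only after all groups
    are written; readers treat its absence as a partial (invalid) store.
    """
    if abundance is None and catalog is None and results is None and metadata is None:
        raise FormatError("nothing to store")
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = "coabund-store-v1"
        if abundance is not None:
            g = fh.create_group("abund")
            g.create_dataset("values", data=abundance.values.to_numpy(dtype=float))
            _write_strings(g, "genes", abundance.gene_ids)
            _write_strings(g, "samples", abundance.sample_ids)
            g.attrs["normalized"] = bool(abundance.normalized)
        if catalog is not None:
            g = fh.create_group("cags")
            _write_strings(g, "genes", catalog.gene_ids)
            g.create_dataset("cag", data=catalog.gene_to_cag.to_numpy(dtype=np.int64))
        if results is not None:
            g = fh.create_group("stats")
            _write_strings(g, "cag", results.index)
            for col in results.columns:
                vals = results[col]
                if np.issubdtype(vals.dtype, np.number) or vals.dtype == bool:
                    g.create_dataset(col, data=vals.to_numpy())
                else:
                    _write_strings(g, col, vals)
            g.attrs["columns"] = ",".join(results.columns)
        if metadata is not None:
            g = fh.create_group("metadata")
            _write_strings(g, "sample", metadata.table.index)
            _write_strings(g, "subject", metadata.table["subject"])
            g.create_dataset("status", data=metadata.table["status"].to_numpy(dtype=np.int64))
            _write_strings(g, "cohort", metadata.table["cohort"])
        fh.attrs["complete"] = True


def read_results_store(path) -> dict:
    """Read a results store back into in-memory objects.

    Returns a dict with any of the keys ``abundance``, ``catalog``,
    ``results``, ``metadata``.  Raises :class:`FormatError` on corrupt
    files or stores whose write did not complete.
    """
    try:
        fh = h5py.File(path, "r")
    except (OSError, FileNotFoundError) as exc:
        raise FormatError(f"cannot open store {path}: {exc}") from exc
    with fh:
        if not fh.attrs.get("complete", False):
            raise FormatError(f"store {path} is marked invalid (partial write)")
        out: dict = {}
        if "abund" in fh:
            g = fh["abund"]
            df = pd.DataFrame(
                g["values"][()],
                index=pd.Index(_read_strings(g, "genes"), name="gene"),
                columns=pd.Index(_read_strings(g, "samples"), name="sample"),
            )
            out["abundance"] = GeneAbundanceMatrix(df, normalized=bool(g.attrs["normalized"]))
        if "cags" in fh:
            g = fh["cags"]
            out["catalog"] = CAGCatalog(
                pd.Series(
                    g["cag"][()],
                    index=pd.Index(_read_strings(g, "genes"), name="gene"),
                    name="cag",
                )
            )
        if "stats" in fh:
            g = fh["stats"]
            cols = [c for c in g.attrs["columns"].split(",") if c]
            data = {}
            for col in cols:
                raw = g[col][()]
                data[col] = (
                    _read_strings(g, col) if raw.dtype.kind in ("O", "S") else raw
                )
            idx = _read_strings(g, "cag")
            try:
                idx = [int(v) for v in idx]
            except ValueError:
                pass
            out["results"] = pd.DataFrame(data, index=pd.Index(idx, name="cag"))
        if "metadata" in fh:
            g = fh["metadata"]
            out["metadata"] = SampleMetadata(
                pd.DataFrame(
                    {
                        "subject": _read_strings(g, "subject"),
                        "status": g["status"][()],
                        "cohort": _read_strings(g, "cohort"),
                    },
                    index=pd.Index(_read_strings(g, "sample"), name="sample"),
                )
            )
    return out
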