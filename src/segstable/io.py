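"""Readers and writers for count matrices, annotations and SEG sets.

Supported inputs are the 10x Genomics triplet layout (``matrix.mtx`` +
``barcodes.tsv`` + ``features.tsv``, MatrixMarket coordinate integer) and
dense TSV with genes as rows.  No reader normalizes or otherwise alters
count values.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .model import (
    META_COLUMNS,
    CellMatrix,
    EmptyJoinError,
    FormatError,
    IntegrityError,
    SegSet,
    logger,
)

_MTX_FILES = ("matrix.mtx", "barcodes.tsv", "features.tsv")


def _read_id_column(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", header=None, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def read_counts(
    path: str | Path,
    format: str = "mtx_dir",
    genes_as_rows: bool = True,
) -> CellMatrix:
    """Read a UMI count matrix into a :class:`CellMatrix`.

    Parameters
    ----------
    path
        Triplet directory (``mtx_dir``) or a TSV file (``tsv``; header row
        of cell ids, first column of gene ids).
    format
        ``"mtx_dir"`` or ``"tsv"``.
    genes_as_rows
        Orientation of the stored matrix.  The 10x convention is genes as
        rows; pass ``False`` to transpose on read.  Explicit, so a
        transposition can never happen silently.
    """
    path = Path(path)
    if format == "mtx_dir":
        return _read_mtx_dir(path, genes_as_rows)
    if format == "tsv":
        return _read_tsv(path, genes_as_rows)
    raise ValueError(f"unknown format {format!r}")


def _read_mtx_dir(path: Path, genes_as_rows: bool) -> CellMatrix:
    if not path.is_dir():
        raise FormatError(f"not a directory: {path}")
    missing = [f for f in _MTX_FILES if not (path / f).exists()]
    if missing:
        raise FormatError(f"{path} lacks {missing}")
    try:
        mat = sp.csr_matrix(mmread(path / "matrix.mtx"))
    except Exception as exc:
        raise FormatError(f"cannot parse {path/'matrix.mtx'}: {exc}") from exc
    if not genes_as_rows:
        mat = sp.csr_matrix(mat.T)
    barcodes = _read_id_column(path / "barcodes.tsv")[0].to_numpy()
    features = _read_id_column(path / "features.tsv")
    gene_ids = features[0].to_numpy()
    symbols = features[1].to_numpy() if features.shape[1] > 1 else None
    if mat.shape[0] != len(gene_ids) or mat.shape[1] != len(barcodes):
        raise IntegrityError(
            f"matrix is {mat.shape} but features/barcodes give "
            f"({len(gene_ids)}, {len(barcodes)})"
        )
    return CellMatrix(counts=mat, gene_ids=gene_ids, cell_ids=barcodes,
                      gene_symbols=symbols)


def _read_tsv(path: Path, genes_as_rows: bool) -> CellMatrix:
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not genes_as_rows:
        df = df.T
    counts = sp.csr_matrix(df.to_numpy())
    return CellMatrix(
        counts=counts,
        gene_ids=df.index.to_numpy(dtype=object),
        cell_ids=df.columns.to_numpy(dtype=object),
    )


def write_counts_tsv(m: CellMatrix, path: str | Path) -> None:
    """Write counts as dense TSV (genes as rows); exact read-back inverse."""
    df = pd.DataFrame(
        m.counts.toarray().astype(np.int64),
        index=pd.Index(m.gene_ids, name="gene_id"),
        columns=m.cell_ids,
    )
    df.to_csv(path, sep="\t")


def write_mtx_dir(m: CellMatrix, path: str | Path) -> None:
    """Write the 10x triplet layout (uncompressed, coordinate integer)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mmwrite(path / "matrix.mtx", sp.coo_matrix(m.counts), field="integer")
    pd.Series(m.cell_ids).to_csv(path / "barcodes.tsv", sep="\t",
                                 header=False, index=False)
    feats = pd.DataFrame({0: m.gene_ids})
    if m.gene_symbols is not None:
        feats[1] = m.gene_symbols
    feats.to_csv(path / "features.tsv", sep="\t", header=False, index=False)


def attach_annotations(m: CellMatrix, table: pd.DataFrame | str | Path) -> CellMatrix:
    """Join a per-cell annotation table onto a :class:`CellMatrix`.

    The table is keyed by cell id (index or a ``cell_id`` column) and must
    provide ``sample_id``, ``tissue``, ``stage``, ``cluster_id`` and
    ``cell_type``.  Cells absent from the table are dropped (count logged);
    zero overlap is an error.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", dtype=str)
    table = table.copy()
    if "cell_id" in table.columns:
        table = table.set_index("cell_id")
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()].unique().tolist()[:5]
        raise IntegrityError(f"duplicate cell_id rows in annotation table: {dup}")
    missing_cols = [c for c in META_COLUMNS if c not in table.columns]
    if missing_cols:
        raise FormatError(f"annotation table lacks columns {missing_cols}")
    keep = np.array([c in table.index for c in m.cell_ids])
    if not keep.any():
        raise EmptyJoinError("no overlap between matrix cells and annotation table")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d cells absent from the annotation table", dropped)
    sub = m.subset_cells(keep)
    meta = table.loc[list(sub.cell_ids), list(META_COLUMNS)].copy()
    meta.index.name = "cell_id"
    extra = sub.cell_meta.drop(columns=list(META_COLUMNS), errors="ignore")
    meta = pd.concat([meta, extra], axis=1)
    return CellMatrix(
        counts=sub.counts,
        gene_ids=sub.gene_ids,
        cell_ids=sub.cell_ids,
        cell_meta=meta,
        gene_symbols=sub.gene_symbols,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def write_seg_sets(sets: Sequence[SegSet], path: str | Path) -> None:
    """Serialize SEG sets: one TSV per level plus ``manifest.json``.

    Gene order inside each set is preserved via an explicit rank column, so
    :func:`read_seg_sets` is a lossless inverse.  Output is byte-stable for
    identical inputs (no timestamps; manifest keys sorted).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = []
    by_level: dict[str, list[SegSet]] = {}
    for s in sets:
        by_level.setdefault(s.level, []).append(s)
    for level, level_sets in sorted(by_level.items()):
        rows = []
        for s in level_sets:
            for rank, gene in enumerate(s.genes):
                rows.append((s.scope_id, rank, gene))
        fname = f"seg_{level}.tsv"
        pd.DataFrame(rows, columns=["scope_id", "rank", "gene"]).to_csv(
            path / fname, sep="\t", index=False
        )
    for s in sets:
        manifest.append(
            {
                "level": s.level,
                "scope_id": s.scope_id,
                "n_genes": len(s.genes),
                "file": f"seg_{s.level}.tsv",
                "params": _jsonable(s.params),
                "flags": _jsonable(s.flags),
            }
        )
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_seg_sets(path: str | Path) -> list[SegSet]:
    """Read back SEG sets written by :func:`write_seg_sets`."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"no manifest.json under {path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    tables: dict[str, pd.DataFrame] = {}
    out = []
    for entry in manifest:
        fname = entry["file"]
        if fname not in tables:
            tables[fname] = pd.read_csv(path / fname, sep="\t", dtype={"gene": str})
        t = tables[fname]
        rows = t[t["scope_id"] == entry["scope_id"]].sort_values("rank")
        genes = rows["gene"].tolist()
        if len(genes) != entry["n_genes"]:
            raise IntegrityError(
                f"manifest says {entry['n_genes']} genes for "
                f"{entry['scope_id']} but TSV has {len(genes)}"
            )
        out.append(
            SegSet(
                level=entry["level"],
                scope_id=entry["scope_id"],
                genes=genes,
                params=entry.get("params", {}),
                flags=entry.get("flags", {}),
            )
        )
    return out
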