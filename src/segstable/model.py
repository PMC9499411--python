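"""Shared data model for SEG identification.

The central container is :class:`CellMatrix`, a genes × cells UMI count
matrix with per-cell annotations (sample, tissue, developmental stage,
cluster, cell type).  Counts are stored genes-as-rows throughout the
package; readers accept either orientation behind an explicit flag so a
transposition can never happen silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger("segstable")

#: annotation columns every SEG step relies on
META_COLUMNS = ("sample_id", "tissue", "stage", "cluster_id", "cell_type")

#: recognised SEG-set levels
SEG_LEVELS = (
    "cluster",
    "cell_type",
    "sample",
    "tissue",
    "global",
    "stage_specific",
    "cell_specific",
    "marker",
)


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class IntegrityError(ValueError):
    """Inputs are well-formed but mutually inconsistent (dims, duplicate ids...)."""


class EmptyJoinError(IntegrityError):
    """An annotation join matched no cells."""


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(np.unique(ids)) != len(ids):
        dup = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()[:5]
        raise IntegrityError(f"duplicate {what} ids: {dup}")


@dataclass
class CellMatrix:
    """Sparse genes × cells UMI counts plus per-cell annotations.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes as rows, cells as columns.
    gene_ids, cell_ids
        Unique identifiers matching the matrix dimensions.
    cell_meta
        One row per cell (indexed by cell id).  The SEG pipeline requires
        the columns in :data:`META_COLUMNS`; ``stage`` is ``"adult"``,
        ``"fetal"`` or NA (NA only when stage-aware steps are skipped).
    gene_symbols
        Optional human-readable symbols; identity is always ``gene_ids``
        because symbols collide.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    gene_symbols: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise IntegrityError("negative counts")
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise IntegrityError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise IntegrityError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        else:
            self.cell_meta = self.cell_meta.loc[list(self.cell_ids)]
        if self.gene_symbols is not None:
            self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
            if len(self.gene_symbols) != n_genes:
                raise IntegrityError("gene_symbols length mismatch")

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def is_annotated(self) -> bool:
        return all(c in self.cell_meta.columns for c in META_COLUMNS)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        idx = pd.Index(self.gene_ids)
        pos = idx.get_indexer(list(genes))
        if (pos < 0).any():
            missing = [g for g, p in zip(genes, pos) if p < 0][:5]
            raise KeyError(f"genes not in matrix: {missing}")
        return pos

    # -- subsetting -----------------------------------------------------
    def subset_cells(self, mask: np.ndarray) -> "CellMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            cols = np.flatnonzero(mask)
        else:
            cols = mask
        return CellMatrix(
            counts=self.counts[:, cols],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[cols],
            cell_meta=self.cell_meta.iloc[cols],
            gene_symbols=self.gene_symbols,
        )

    def cells_where(self, **conditions) -> np.ndarray:
        """Boolean mask over cells matching all ``column=value`` conditions."""
        mask = np.ones(self.n_cells, dtype=bool)
        for col, val in conditions.items():
            mask &= (self.cell_meta[col] == val).to_numpy()
        return mask

    def drop_unlabeled(self) -> "CellMatrix":
        """Remove cells with missing cluster_id or cell_type (SEG steps are
        defined only on labeled cells); the number dropped is logged."""
        if not self.is_annotated:
            raise IntegrityError(
                f"cell_meta lacks required columns {META_COLUMNS}; "
                "attach annotations first"
            )
        ok = self.cell_meta["cluster_id"].notna() & self.cell_meta["cell_type"].notna()
        n_drop = int((~ok).sum())
        if n_drop:
            logger.info("dropping %d cells with missing cluster/cell-type labels", n_drop)
            return self.subset_cells(ok.to_numpy())
        return self

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()


@dataclass
class SegSet:
    """A named gene set at one level of the SEG hierarchy.

    ``params`` records every parameter that produced the set (provenance is
    mandatory); ``flags`` records degeneracies, e.g. a single-cluster cell
    type whose inter-cluster filter was vacuous.
    """

    level: str
    scope_id: str
    genes: list[str]
    params: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in SEG_LEVELS:
            raise ValueError(f"unknown SEG level {self.level!r}")
        self.genes = list(self.genes)
        if len(set(self.genes)) != len(self.genes):
            raise IntegrityError(f"duplicate genes in SegSet {self.scope_id}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def as_set(self) -> frozenset:
        return frozenset(self.genes)


@dataclass
class BinMatrix:
    """Genes × bins combined-UMI matrix for one cluster of one sample.

    Before normalization each bin column is the elementwise sum of its
    ``n`` member cells' columns; ``norm_factor`` is set once depth
    normalization has been applied.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    cluster_id: str
    sample_id: str
    bin_members: list[list[str]]
    norm_factor: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.counts.shape[0] != len(self.gene_ids):
            raise IntegrityError("gene dimension mismatch in BinMatrix")
        if self.counts.shape[1] != len(self.bin_members):
            raise IntegrityError("bin dimension mismatch in BinMatrix")
        sizes = {len(m) for m in self.bin_members}
        if len(sizes) > 1:
            raise IntegrityError(f"unequal bin sizes {sorted(sizes)}")
        for members in self.bin_members:
            if len(set(members)) != len(members):
                raise IntegrityError("repeated cell within one bin")

    @property
    def r(self) -> int:
        return self.counts.shape[1]

    @property
    def n(self) -> int:
        return len(self.bin_members[0]) if self.bin_members else 0


@dataclass
class GesiTable:
    """Per-gene GESI at one grouping level.

    ``table`` is indexed by gene id with columns ``mean``, ``sd`` and
    ``gesi``; silent genes (mean 0) carry ``gesi = NaN`` — undefined, never
    zero — and are excluded from SEG candidacy.
    """

    level: str
    scope_id: str
    table: pd.DataFrame

    LEVELS = ("across_bins", "across_clusters", "across_cell_types", "across_groups")

    def __post_init__(self) -> None:
        if self.level not in self.LEVELS:
            raise ValueError(f"unknown GESI level {self.level!r}")
        missing = {"mean", "sd", "gesi"} - set(self.table.columns)
        if missing:
            raise IntegrityError(f"GesiTable missing columns {sorted(missing)}")

    def defined(self) -> pd.DataFrame:
        """Rows with a defined (non-NaN) GESI."""
        return self.table[self.table["gesi"].notna()]


@dataclass
class DeconSignature:
    """Genes × cell-types weight matrix for SEG-based deconvolution.

    ``W[s, c]`` is the average UMI count of signature gene ``s`` per cell of
    type ``c`` in the training data.  The system must be overdetermined
    (more genes than types).
    """

    genes: list[str]
    cell_types: list[str]
    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (len(self.genes), len(self.cell_types)):
            raise IntegrityError("W shape does not match genes × cell_types")
        if len(self.genes) <= len(self.cell_types):
            raise IntegrityError(
                f"underdetermined signature: {len(self.genes)} genes for "
                f"{len(self.cell_types)} cell types"
            )
        if (self.W < 0).any():
            raise IntegrityError("negative signature weights")
        if (self.W.max(axis=1) <= 0).any():
            bad = [g for g, row in zip(self.genes, self.W) if row.max() <= 0][:5]
            raise IntegrityError(f"signature genes with no positive weight: {bad}")


@dataclass
class FractionEstimate:
    """Solved cell-type fractions with optional accuracy against truth."""

    cell_types: list[str]
    fractions: np.ndarray          # reported (constrained by default)
    raw_fractions: np.ndarray      # unconstrained least-squares solution
    residual_norm: float
    mode: str = "constrained"
    per_type_accuracy: dict | None = None
    average_accuracy: float | None = None

    def as_series(self) -> pd.Series:
        return pd.Series(self.fractions, index=self.cell_types, name="fraction")
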