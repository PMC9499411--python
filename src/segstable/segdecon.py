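"""SEGdecon: cell-composition inference from SEG signatures.

Cell-specific SEGs behave like per-cell-type constants, so the average
expression of signature gene *s* in a mixed sample is a linear blend of
per-type weights:

    sum_c  W[s, c] * f_c  =  E_s            (one equation per gene)

where ``W[s, c]`` is the average UMI count of gene *s* per cell of type
*c* in a training dataset, ``f_c`` the unknown fraction of type *c*, and
``E_s`` the average UMI count of gene *s* over all cells of the test
sample.  With more signature genes than cell types the system is
overdetermined and solved by least squares.  The reported fractions are,
by default, the least-squares solution with negatives clamped to zero and
renormalized to sum to one (fractions are physical); ``mode="raw"`` keeps
the literal unconstrained solution.

Per-type accuracy against known composition is 1 − |real − pred| / real
(can be negative for gross errors), averaged over evaluated types.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import CellMatrix, DeconSignature, FractionEstimate, IntegrityError, logger


def _mean_umi(m: CellMatrix, gene_rows: np.ndarray, col_mask: np.ndarray,
              cpm: bool) -> np.ndarray:
    sub = m.counts[:, np.flatnonzero(col_mask)]
    if cpm:
        totals = np.asarray(sub.sum(axis=0)).ravel().astype(float)
        totals[totals == 0] = 1.0
        sub = sub.multiply(1e6 / totals[None, :])
    return np.asarray(sub.mean(axis=1)).ravel()[gene_rows]


def fit_signature(
    train: CellMatrix,
    seg_genes,
    cell_types: list[str] | None = None,
    cpm: bool = False,
) -> DeconSignature:
    """Average per-cell expression of each signature gene per cell type.

    ``W[s, c]`` is the plain average UMI count (``cpm=True`` switches to
    counts-per-million for cross-platform use).  Requires every listed
    cell type to have at least one training cell and more genes than
    types (overdetermined system).
    """
    genes = list(seg_genes)
    gidx = train.gene_index(genes)
    if cell_types is None:
        cell_types = sorted(train.cell_meta["cell_type"].dropna().unique())
    W = np.empty((len(genes), len(cell_types)))
    for j, ct in enumerate(cell_types):
        mask = train.cells_where(cell_type=ct)
        if not mask.any():
            raise ValueError(f"no training cells of type {ct!r}")
        W[:, j] = _mean_umi(train, gidx, mask, cpm)
    keep = W.max(axis=1) > 0
    if not keep.all():
        dropped = [g for g, k in zip(genes, keep) if not k]
        logger.warning("dropping %d signature genes silent in training data: %s",
                       len(dropped), dropped[:5])
        genes = [g for g, k in zip(genes, keep) if k]
        W = W[keep]
    return DeconSignature(genes=genes, cell_types=list(cell_types), W=W)


def bulk_expression(test: CellMatrix, seg_genes, cpm: bool = False) -> np.ndarray:
    """Average UMI count of each signature gene over all test cells."""
    gidx = test.gene_index(list(seg_genes))
    E = _mean_umi(test, gidx, np.ones(test.n_cells, dtype=bool), cpm)
    if not E.any():
        logger.warning("bulk expression vector is all zero")
    return E


def solve_fractions(
    sig: DeconSignature,
    E: np.ndarray,
    mode: str = "constrained",
) -> FractionEstimate:
    """Least-squares solution of W f = E for cell-type fractions.

    ``raw_fractions`` is the unconstrained argmin of ``‖W f − E‖₂``;
    ``fractions`` is, in the default constrained mode, that solution with
    negatives clamped to zero and renormalized to sum to one.  A
    rank-deficient W (collinear cell-type profiles) is an error.
    """
    E = np.asarray(E, dtype=float).ravel()
    if len(E) != len(sig.genes):
        raise ValueError(f"E has {len(E)} entries for {len(sig.genes)} genes")
    rank = np.linalg.matrix_rank(sig.W)
    if rank < len(sig.cell_types):
        corr = np.corrcoef(sig.W.T)
        pairs = [
            (sig.cell_types[i], sig.cell_types[j])
            for i in range(len(sig.cell_types))
            for j in range(i + 1, len(sig.cell_types))
            if abs(corr[i, j]) > 0.999
        ]
        raise IntegrityError(
            f"rank-deficient signature (rank {rank} < {len(sig.cell_types)} "
            f"types); near-collinear pairs: {pairs}"
        )
    raw, *_ = np.linalg.lstsq(sig.W, E, rcond=None)
    if mode == "raw":
        f = raw.copy()
    elif mode == "constrained":
        f = np.clip(raw, 0.0, None)
        s = f.sum()
        if s <= 0:
            raise ValueError("all fitted fractions nonpositive; cannot renormalize")
        f = f / s
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return FractionEstimate(
        cell_types=list(sig.cell_types),
        fractions=f,
        raw_fractions=raw,
        residual_norm=float(np.linalg.norm(sig.W @ raw - E)),
        mode=mode,
    )


def accuracy(
    real_f,
    pred_f,
    cell_types: list[str] | None = None,
) -> tuple[dict, float]:
    """Per-type and average prediction accuracy: 1 − |real − pred| / real.

    Types with a true fraction of zero are excluded (with a warning)
    because the metric is undefined there.  Accuracy may be negative.
    """
    real = np.asarray(real_f, dtype=float).ravel()
    pred = np.asarray(pred_f, dtype=float).ravel()
    if real.shape != pred.shape:
        raise ValueError("real and predicted fraction vectors differ in length")
    if cell_types is None:
        cell_types = [f"type_{i}" for i in range(len(real))]
    per_type = {}
    for ct, r, p in zip(cell_types, real, pred):
        if r == 0:
            logger.warning("cell type %s has real fraction 0; excluded from accuracy", ct)
            continue
        per_type[ct] = 1.0 - abs(r - p) / r
    if not per_type:
        raise ValueError("no cell type with positive real fraction")
    avg = float(np.mean(list(per_type.values())))
    return per_type, avg


def merge_fractions(est: FractionEstimate, groups: dict[str, list[str]]) -> pd.Series:
    """Sum predicted fractions over declared type groups.

    Supports evaluation against annotations that merge cell types (e.g. a
    combined NK/T label): ``groups`` maps a group name to the member cell
    types; ungrouped types pass through unchanged.
    """
    f = est.as_series()
    grouped = {}
    covered: set[str] = set()
    for name, members in groups.items():
        missing = [m for m in members if m not in f.index]
        if missing:
            raise KeyError(f"unknown cell types in group {name!r}: {missing}")
        grouped[name] = float(f[members].sum())
        covered.update(members)
    for ct in f.index:
        if ct not in covered:
            grouped[ct] = float(f[ct])
    return pd.Series(grouped, name="fraction")
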