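"""Gene Expression Stability Index (GESI).

GESI = 1 / (1 + δ/u), where δ and u are the standard deviation and mean of
a gene's expression over the grouping units (bins within a cluster, or
cluster/cell-type means at higher levels).  It equals 1 for zero variance,
falls toward 0 as the coefficient of variation δ/u grows, and is undefined
(NaN) for silent genes (u = 0) — a 0/0, not an "unstable" call.

The same formula is applied at every level; the sample (n−1) standard
deviation is used throughout, with a standard-error variant (δ/√k)
available behind a flag for the inter-group levels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .model import BinMatrix, GesiTable


def gesi(values, ddof: int = 1) -> float:
    """Stability index of one expression vector.

    Returns ``1 / (1 + sd/mean)`` with the sample standard deviation
    (``ddof=1``); NaN when the mean is zero.  Requires at least two values.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("gesi needs a 1-d vector of length >= 2")
    if (v < 0).any():
        raise ValueError("expression values must be nonnegative")
    u = v.mean()
    if u == 0:
        return float("nan")
    return float(1.0 / (1.0 + v.std(ddof=ddof) / u))


def _gesi_frame(matrix: np.ndarray, gene_ids, use_sem: bool = False) -> pd.DataFrame:
    """Row-wise mean/sd/GESI over the columns of ``matrix`` (genes × units)."""
    matrix = np.asarray(matrix, dtype=float)
    k = matrix.shape[1]
    u = matrix.mean(axis=1)
    d = matrix.std(axis=1, ddof=1)
    if use_sem:
        d = d / np.sqrt(k)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(u > 0, 1.0 / (1.0 + d / np.where(u > 0, u, 1.0)), np.nan)
    return pd.DataFrame(
        {"mean": u, "sd": d, "gesi": g},
        index=pd.Index(np.asarray(gene_ids, dtype=object), name="gene_id"),
    )


def within_cluster_gesi(b: BinMatrix) -> GesiTable:
    """GESI of every gene across the r bins of one cluster."""
    if b.r < 2:
        raise ValueError("need at least 2 bins")
    return GesiTable(
        level="across_bins",
        scope_id=f"{b.sample_id}/{b.cluster_id}",
        table=_gesi_frame(b.counts, b.gene_ids),
    )


def inter_group_gesi(
    group_means: pd.DataFrame,
    level: str = "across_groups",
    scope_id: str = "",
    use_sem: bool = False,
) -> GesiTable:
    """GESI of every gene across group mean profiles.

    ``group_means`` is genes × groups, each column the per-bin mean
    expression of one cluster (or the per-cluster mean of one cell type).
    Used for both the across-clusters and across-cell-types levels.
    ``use_sem`` divides the deviation by √k (standard error of the mean)
    instead of using the standard deviation.
    """
    if group_means.shape[1] < 2:
        raise ValueError("inter-group GESI needs at least 2 groups")
    return GesiTable(
        level=level,
        scope_id=scope_id,
        table=_gesi_frame(group_means.to_numpy(), group_means.index.to_numpy(),
                          use_sem=use_sem),
    )


def inter_sample_pcc(
    genes,
    profile_a: pd.Series,
    profile_b: pd.Series,
    log: bool = True,
) -> float:
    """Pearson correlation of two cluster mean-expression profiles over a
    gene list — the between-sample consistency check for a SEG set.

    Profiles are log1p-transformed by default (expression spans orders of
    magnitude); pass ``log=False`` for the raw scale.  NaN when either
    restricted profile has zero variance.
    """
    genes = list(genes)
    a = profile_a.reindex(genes).to_numpy(dtype=float)
    b = profile_b.reindex(genes).to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 shared genes with finite values")
    a, b = a[ok], b[ok]
    if log:
        a, b = np.log1p(a), np.log1p(b)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)
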