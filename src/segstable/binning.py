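"""Resampled cell binning.

UMI counts of individual droplet cells are dominated by sampling noise.
Within each transcriptionally homogeneous cluster, ``r`` rounds of
resampling each draw ``n`` cells without replacement and sum their UMI
vectors into a pseudobulk *bin*; bins retain real heterogeneity while
averaging out per-cell sampling error.  Clusters with fewer than ``m``
cells within a sample are excluded.  Defaults n=10, m=100, r=100.
"""

from __future__ import annotations

import zlib

import numpy as np

from .model import BinMatrix, CellMatrix, IntegrityError, logger


def substream_seed(seed: int, sample_id: str, cluster_id: str) -> np.random.SeedSequence:
    """Deterministic per-(sample, cluster) RNG substream.

    Derived from stable CRC32 hashes of the identifiers so reproducibility
    does not depend on cluster iteration order.
    """
    return np.random.SeedSequence(
        [
            int(seed),
            zlib.crc32(str(sample_id).encode("utf-8")),
            zlib.crc32(str(cluster_id).encode("utf-8")),
        ]
    )


def eligible_clusters(m: CellMatrix, min_cells: int = 100) -> list[tuple[str, str]]:
    """(sample_id, cluster_id) pairs with at least ``min_cells`` cells.

    Size is counted per sample: the same cluster label in two samples is
    two clusters.  Returns an empty list (with a warning) when nothing
    qualifies.
    """
    if not m.is_annotated:
        raise IntegrityError("cluster labels not attached")
    sizes = m.cell_meta.groupby(["sample_id", "cluster_id"], sort=True).size()
    out = [(s, c) for (s, c), k in sizes.items() if k >= min_cells]
    if not out:
        logger.warning("no cluster reaches %d cells; nothing to bin", min_cells)
    return out


def make_bins(
    m: CellMatrix,
    sample_id: str,
    cluster_id: str,
    n: int = 10,
    r: int = 100,
    seed: int | np.random.SeedSequence = 0,
) -> BinMatrix:
    """Form ``r`` bins of ``n`` distinct cells from one cluster.

    Within a round the ``n`` cells are drawn without replacement; rounds
    are independent, so a cell may recur across bins.  Identical seeds
    yield identical bins.
    """
    mask = m.cells_where(sample_id=sample_id, cluster_id=cluster_id)
    cols = np.flatnonzero(mask)
    if len(cols) < n:
        raise ValueError(
            f"cluster {cluster_id!r} of sample {sample_id!r} has "
            f"{len(cols)} cells < bin size n={n}"
        )
    if isinstance(seed, np.random.SeedSequence):
        rng = np.random.default_rng(seed)
    else:
        rng = np.random.default_rng(substream_seed(seed, sample_id, cluster_id))
    X = np.asarray(m.counts[:, cols].todense(), dtype=float)
    picks = np.stack([rng.choice(len(cols), size=n, replace=False) for _ in range(r)])
    bins = X[:, picks.reshape(-1)].reshape(m.n_genes, r, n).sum(axis=2)
    members = [[m.cell_ids[cols[j]] for j in row] for row in picks]
    return BinMatrix(
        counts=bins,
        gene_ids=m.gene_ids,
        cluster_id=str(cluster_id),
        sample_id=str(sample_id),
        bin_members=members,
    )


def normalize_bins(b: BinMatrix, target_sum: float = 1e4) -> BinMatrix:
    """Scale each bin so its total combined UMI equals ``target_sum``.

    Member cells have unequal sequencing depth, so without this the
    stability index would conflate depth variance with expression
    variance.  The applied factor is recorded per bin.
    """
    totals = b.counts.sum(axis=0)
    zero = np.flatnonzero(totals <= 0)
    if len(zero):
        raise ValueError(f"bins with zero total count: indices {zero.tolist()[:5]}")
    factors = target_sum / totals
    return BinMatrix(
        counts=b.counts * factors[None, :],
        gene_ids=b.gene_ids,
        cluster_id=b.cluster_id,
        sample_id=b.sample_id,
        bin_members=b.bin_members,
        norm_factor=factors,
    )
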