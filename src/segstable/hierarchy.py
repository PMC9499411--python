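"""Hierarchical SEG calling: cluster → cell type → sample → tissue → global.

The six-step caller takes an annotated :class:`~segstable.model.CellMatrix`
(clusters and cell types supplied as input — clustering itself is outside
this package) and produces SEG sets at every level:

1. clusters with ≥ m cells per sample are binned (n cells/bin, r rounds);
2. within-cluster SEGs = the K genes with largest GESI across bins;
3. cell-type SEGs = within-cluster SEGs shared by enough clusters
   (sharing fraction relaxed 100% → 75% → 50% until ≥ S candidates)
   with inter-cluster GESI > g;
4. sample SEGs = intersection of the sample's cell-type SEG sets with
   inter-cell-type GESI > g;
5. tissue SEGs = sample SEGs recurring in ≥ c samples of the tissue
   (c = 2 when the tissue has more than one sample, else 1);
6. global (spatial-temporal) SEGs = tissue SEGs present in ≥ l tissues
   including at least one adult and one fetal tissue (the dual-stage
   requirement; a relaxed mode drops it).

Defaults: n=10, m=100, r=100, K=1000, g=0.667 (δ/u < 0.5), S=500, l=2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .binning import eligible_clusters, make_bins, normalize_bins, substream_seed
from .gesi import inter_group_gesi, within_cluster_gesi
from .model import CellMatrix, GesiTable, IntegrityError, SegSet, logger

#: sharing-fraction relaxation grid for the cell-type step
SHARE_GRID = (1.0, 0.75, 0.5)


@dataclass
class PipelineParams:
    """Tunable parameters of the SEG caller, recorded into every SegSet."""

    n: int = 10          # cells per bin
    m: int = 100         # minimum cluster size per sample
    r: int = 100         # resampling rounds (bins per cluster)
    K: int = 1000        # top within-cluster genes kept by GESI
    g: float = 0.667     # inter-group GESI cutoff (δ/u < 0.5)
    S: int = 500         # minimum retained cell-type candidates
    c: int | None = None  # tissue recurrence cutoff; None → 2 if >1 sample else 1
    l: int = 2           # minimum tissues for a global call
    seed: int = 0
    normalize: bool = True        # depth-normalize bins before GESI
    target_sum: float = 1e4       # combined UMI per bin after normalization
    strict_stage: bool = True     # require >=1 adult and >=1 fetal tissue
    use_sem: bool = False         # standard error instead of sd at group levels
    share_grid: tuple = SHARE_GRID

    def __post_init__(self) -> None:
        if not (0 < self.g < 1):
            raise ValueError("g must lie in (0, 1)")
        for name in ("n", "m", "r", "K", "S", "l"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["share_grid"] = list(self.share_grid)
        return d


def within_cluster_segs(t: GesiTable, K: int = 1000) -> SegSet:
    """The K genes with largest GESI across a cluster's bins.

    Undefined-GESI (silent) genes are excluded.  Ties at rank K are broken
    by descending mean expression, then gene id, so the set is
    deterministic and favors well-measured genes.  When fewer than K
    defined genes exist, all are returned.
    """
    d = t.defined()
    # id-sort first so the stable sort leaves gene id as the final tie-break
    order = (
        d.sort_index()
        .sort_values(by=["gesi", "mean"], ascending=[False, False], kind="mergesort")
    )
    genes = order.index[:K].tolist()
    return SegSet(
        level="cluster",
        scope_id=t.scope_id,
        genes=genes,
        params={"K": K},
        flags={"n_defined": int(len(d))},
    )


def _shared_genes(sets: list[SegSet], threshold: int) -> list[str]:
    counts: dict[str, int] = {}
    for s in sets:
        for gene in s.genes:
            counts[gene] = counts.get(gene, 0) + 1
    return sorted(g for g, k in counts.items() if k >= threshold)


def cell_type_segs(
    cluster_sets: list[SegSet],
    cluster_means: pd.DataFrame,
    g: float = 0.667,
    S: int = 500,
    share_grid: tuple = SHARE_GRID,
    scope_id: str = "",
    use_sem: bool = False,
) -> SegSet:
    """Inter-cluster SEGs for one cell type of one sample.

    Candidate genes are those shared by a fraction of the cell type's
    clusters, starting at 100% and relaxing down the ``share_grid`` until
    at least ``S`` candidates are found (or the grid is exhausted).
    Candidates with inter-cluster GESI > g over ``cluster_means`` (genes ×
    clusters) become cell-type SEGs.  A single-cluster cell type skips the
    vacuous inter-cluster filter, flagged in the result.
    """
    if not cluster_sets:
        raise ValueError("need at least one cluster SegSet")
    params = {"g": g, "S": S, "share_grid": list(share_grid)}
    if len(cluster_sets) == 1:
        only = cluster_sets[0]
        return SegSet(
            level="cell_type",
            scope_id=scope_id or only.scope_id,
            genes=list(only.genes),
            params=params | {"share_fraction": 1.0},
            flags={"single_cluster": True},
        )
    n_cl = len(cluster_sets)
    candidates: list[str] = []
    used_frac = share_grid[-1]
    for frac in share_grid:
        threshold = max(1, math.ceil(frac * n_cl))
        candidates = _shared_genes(cluster_sets, threshold)
        used_frac = frac
        if len(candidates) >= S:
            break
    gt = inter_group_gesi(
        cluster_means.loc[cluster_means.index.intersection(candidates)],
        level="across_clusters",
        scope_id=scope_id,
        use_sem=use_sem,
    )
    passing = gt.defined().query("gesi > @g")
    genes = sorted(passing.index.tolist())
    return SegSet(
        level="cell_type",
        scope_id=scope_id,
        genes=genes,
        params=params | {"share_fraction": used_frac},
        flags={"n_candidates": len(candidates), "n_clusters": n_cl},
    )


def sample_segs(
    cell_type_sets: list[SegSet],
    cell_type_means: pd.DataFrame,
    g: float = 0.667,
    scope_id: str = "",
    use_sem: bool = False,
) -> SegSet:
    """Sample SEGs: genes in every cell-type SEG set of the sample whose
    GESI across the cell-type mean profiles exceeds g."""
    if not cell_type_sets:
        raise ValueError("need at least one cell-type SegSet")
    shared = set(cell_type_sets[0].genes)
    for s in cell_type_sets[1:]:
        shared &= s.as_set()
    if len(cell_type_sets) == 1:
        return SegSet(
            level="sample",
            scope_id=scope_id,
            genes=sorted(shared),
            params={"g": g},
            flags={"single_cell_type": True},
        )
    if not shared:
        return SegSet(level="sample", scope_id=scope_id, genes=[], params={"g": g})
    gt = inter_group_gesi(
        cell_type_means.loc[cell_type_means.index.intersection(sorted(shared))],
        level="across_cell_types",
        scope_id=scope_id,
        use_sem=use_sem,
    )
    genes = sorted(gt.defined().query("gesi > @g").index.tolist())
    return SegSet(
        level="sample",
        scope_id=scope_id,
        genes=genes,
        params={"g": g},
        flags={"n_cell_types": len(cell_type_sets)},
    )


def resolve_c(n_samples: int, c: int | None) -> int:
    """Tissue recurrence cutoff: 2 when the tissue has more than one
    sample, 1 otherwise, unless set explicitly."""
    if c is not None:
        return c
    return 2 if n_samples > 1 else 1


def tissue_segs(
    sample_sets: list[SegSet],
    c: int | None = None,
    scope_id: str = "",
) -> SegSet:
    """Tissue SEGs: genes present in ≥ c of the tissue's sample SEG sets."""
    if not sample_sets:
        raise ValueError("need at least one sample SegSet")
    c_eff = resolve_c(len(sample_sets), c)
    genes = _shared_genes(sample_sets, c_eff)
    return SegSet(
        level="tissue",
        scope_id=scope_id,
        genes=genes,
        params={"c": c_eff},
        flags={"n_samples": len(sample_sets)},
    )


def global_segs(
    tissue_sets: list[SegSet],
    l: int = 2,
    strict_stage: bool = True,
) -> SegSet:
    """Global (spatial-temporal) SEGs.

    A gene qualifies when present in at least ``l`` tissue SEG sets; in
    strict mode it must additionally be covered by at least one adult and
    one fetal tissue.  Every tissue set must carry a ``stage`` param
    ("adult" or "fetal") in strict mode.
    """
    if not tissue_sets:
        raise ValueError("need at least one tissue SegSet")
    stages: dict[str, set[str]] = {}
    counts: dict[str, int] = {}
    for s in tissue_sets:
        stage = s.params.get("stage")
        if strict_stage and stage not in ("adult", "fetal"):
            raise IntegrityError(
                f"tissue set {s.scope_id!r} lacks an adult/fetal stage label"
            )
        for gene in s.genes:
            counts[gene] = counts.get(gene, 0) + 1
            stages.setdefault(gene, set()).add(stage)
    genes = []
    for gene, k in counts.items():
        if k < l:
            continue
        if strict_stage and not {"adult", "fetal"} <= stages[gene]:
            continue
        genes.append(gene)
    return SegSet(
        level="global",
        scope_id="global",
        genes=sorted(genes),
        params={"l": l, "strict_stage": strict_stage},
        flags={"n_tissues": len(tissue_sets)},
    )


@dataclass
class PipelineResult:
    """Everything the six-step caller produced, with provenance.

    Intermediate tables (per-cluster GESI, cluster/cell-type mean profiles)
    are kept so higher-level cutoffs (g, c, l) can be re-applied without
    re-binning.
    """

    params: PipelineParams
    cluster_sets: dict = field(default_factory=dict)       # (sample, cluster) -> SegSet
    cell_type_sets: dict = field(default_factory=dict)     # (sample, cell_type) -> SegSet
    sample_sets: dict = field(default_factory=dict)        # sample -> SegSet
    tissue_sets: dict = field(default_factory=dict)        # tissue -> SegSet
    global_set: SegSet | None = None
    cluster_gesi: dict = field(default_factory=dict)       # (sample, cluster) -> GesiTable
    cluster_means: dict = field(default_factory=dict)      # sample -> DataFrame genes × clusters
    cell_type_means: dict = field(default_factory=dict)    # sample -> DataFrame genes × cell types
    tissue_stage: dict = field(default_factory=dict)       # tissue -> stage
    sample_tissue: dict = field(default_factory=dict)      # sample -> tissue

    def all_sets(self) -> list[SegSet]:
        out = list(self.cluster_sets.values())
        out += list(self.cell_type_sets.values())
        out += list(self.sample_sets.values())
        out += list(self.tissue_sets.values())
        if self.global_set is not None:
            out.append(self.global_set)
        return out

    def step_counts(self) -> dict:
        return {
            "clusters": len(self.cluster_sets),
            "cell_types": len(self.cell_type_sets),
            "samples": len(self.sample_sets),
            "tissues": len(self.tissue_sets),
            "global_segs": len(self.global_set) if self.global_set else 0,
        }


def run_pipeline(m: CellMatrix, p: PipelineParams | None = None) -> PipelineResult:
    """Execute the full six-step SEG caller on an annotated matrix.

    Deterministic given ``p.seed``: per-cluster RNG substreams are derived
    from (seed, sample_id, cluster_id), so results do not depend on
    iteration order.
    """
    p = p or PipelineParams()
    m = m.drop_unlabeled()
    res = PipelineResult(params=p)
    meta = m.cell_meta

    # sample -> tissue -> stage maps (each sample belongs to one tissue)
    samp_info = meta.groupby("sample_id", sort=True)[["tissue", "stage"]].agg(
        lambda s: s.iloc[0]
    )
    for tissue, grp in meta.groupby("tissue", sort=True):
        res.tissue_stage[tissue] = grp["stage"].iloc[0]
    for sample_id in samp_info.index:
        res.sample_tissue[sample_id] = samp_info.loc[sample_id, "tissue"]

    # steps 1-2: bin eligible clusters, compute GESI, take top-K per cluster
    elig = eligible_clusters(m, min_cells=p.m)
    for sample_id, cluster_id in elig:
        try:
            b = make_bins(
                m, sample_id, cluster_id, n=p.n, r=p.r,
                seed=substream_seed(p.seed, sample_id, cluster_id),
            )
        except ValueError as exc:
            raise ValueError(f"step 2 (binning) failed: {exc}") from exc
        if p.normalize:
            b = normalize_bins(b, target_sum=p.target_sum)
        gt = within_cluster_gesi(b)
        res.cluster_gesi[(sample_id, cluster_id)] = gt
        seg = within_cluster_segs(gt, K=p.K)
        seg.params.update(n=p.n, m=p.m, r=p.r, seed=p.seed)
        res.cluster_sets[(sample_id, cluster_id)] = seg

    if not res.cluster_sets:
        logger.warning("no eligible clusters; pipeline produced empty results")
        res.global_set = SegSet(level="global", scope_id="global", genes=[],
                                params={"l": p.l, "strict_stage": p.strict_stage})
        return res

    # per-sample cluster mean profiles (mean over bins, i.e. the bin-level u)
    for (sample_id, cluster_id), gt in res.cluster_gesi.items():
        res.cluster_means.setdefault(sample_id, {})[cluster_id] = gt.table["mean"]
    for sample_id in list(res.cluster_means):
        res.cluster_means[sample_id] = pd.DataFrame(res.cluster_means[sample_id])

    # step 3: inter-cluster SEGs per (sample, cell type)
    cl_to_ct = meta.groupby(["sample_id", "cluster_id"], sort=True)["cell_type"].agg(
        lambda s: s.iloc[0]
    )
    for sample_id, means in res.cluster_means.items():
        by_type: dict[str, list[str]] = {}
        for cluster_id in means.columns:
            by_type.setdefault(cl_to_ct[(sample_id, cluster_id)], []).append(cluster_id)
        ct_mean_cols = {}
        for cell_type, clusters in sorted(by_type.items()):
            sets = [res.cluster_sets[(sample_id, c)] for c in clusters]
            seg = cell_type_segs(
                sets,
                means[clusters],
                g=p.g,
                S=p.S,
                share_grid=p.share_grid,
                scope_id=f"{sample_id}/{cell_type}",
                use_sem=p.use_sem,
            )
            seg.params.update(n=p.n, m=p.m, r=p.r, K=p.K, seed=p.seed)
            res.cell_type_sets[(sample_id, cell_type)] = seg
            ct_mean_cols[cell_type] = means[clusters].mean(axis=1)
        res.cell_type_means[sample_id] = pd.DataFrame(ct_mean_cols)

    # step 4: sample SEGs
    for sample_id, ct_means in res.cell_type_means.items():
        sets = [
            res.cell_type_sets[(s, t)]
            for (s, t) in sorted(res.cell_type_sets)
            if s == sample_id
        ]
        seg = sample_segs(sets, ct_means, g=p.g, scope_id=sample_id, use_sem=p.use_sem)
        seg.params.update(n=p.n, m=p.m, r=p.r, K=p.K, S=p.S, seed=p.seed)
        res.sample_sets[sample_id] = seg

    # step 5: tissue SEGs
    by_tissue: dict[str, list[str]] = {}
    for sample_id in res.sample_sets:
        by_tissue.setdefault(samp_info.loc[sample_id, "tissue"], []).append(sample_id)
    for tissue, sample_ids in sorted(by_tissue.items()):
        sets = [res.sample_sets[s] for s in sorted(sample_ids)]
        seg = tissue_segs(sets, c=p.c, scope_id=tissue)
        seg.params.update(stage=res.tissue_stage.get(tissue), seed=p.seed)
        res.tissue_sets[tissue] = seg

    # step 6: global (spatial-temporal) SEGs
    res.global_set = global_segs(
        [res.tissue_sets[t] for t in sorted(res.tissue_sets)],
        l=p.l,
        strict_stage=p.strict_stage,
    )
    res.global_set.params.update(seed=p.seed)
    logger.info("pipeline step counts: %s", res.step_counts())
    return res
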