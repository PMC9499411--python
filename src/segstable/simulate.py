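"""Synthetic multi-sample, multi-tissue UMI data with planted ground truth.

The generator emulates the structure the SEG caller assumes: droplet-style
UMI counts (negative binomial / Gamma-Poisson, the standard count model
for UMI data), per-cell depth heterogeneity (log-normal depth factors),
and planted gene classes with known truth:

``global_seg``
    constant true mean across every cluster, cell type, sample and tissue
    (CV of true means = 0), drawn from an abundant base-mean distribution
    — stably expressed genes are characteristically well expressed;
``tissue_seg``
    constant within one home tissue, independently variable elsewhere;
``cell_specific``
    constant within one target cell type; in other types the mean is the
    same (no planted fold — these are the non-marker cell-specific SEGs)
    but strongly overdispersed, so the gene is a SEG only for its target
    type;
``marker``
    like ``cell_specific`` but elevated by a planted fold (default 5×)
    in the target type relative to the other types;
``variable``
    true mean drawn independently per cluster (CV of true means ≥ 1);
``silent``
    all-zero rows.

Defaults match the benchmark scale of 2,000 genes across 2 stages × 3
tissues × 2 samples × 4 cell types × 250 cells (~12,000 cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from math import log

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .model import CellMatrix


@dataclass
class SimConfig:
    """Generator configuration; defaults are the benchmark conditions."""

    n_genes: int = 2000
    cells_per_cluster: int = 250
    clusters_per_cell_type: int = 1
    cell_types: tuple = ("T", "B", "NK", "M")
    samples_per_tissue: int = 2
    tissues_per_stage: int = 3
    stages: tuple = ("adult", "fetal")

    n_global_seg: int = 50
    n_tissue_seg: int = 30
    n_cell_specific: int = 40
    n_marker: int = 20
    n_silent: int = 100

    # expression model
    seg_meanlog: float = log(5.0)     # abundant base means for stable genes
    seg_sdlog: float = 0.4
    var_meanlog: float = 0.0          # variable genes: per-cluster log-normal
    var_sdlog: float = 1.0            # CV of true means ≈ 1.3
    cs_meanlog: float = log(3.0)      # cell-specific target-type mean
    cs_sdlog: float = 0.4
    marker_base_meanlog: float = log(0.5)
    marker_base_sdlog: float = 0.3
    marker_fold: float = 5.0
    cs_offtarget_factor: float = 1.0   # mean ratio target/other for cell_specific
    nb_size: float = 2.0               # NB size (inverse dispersion)
    unstable_nb_size: float = 0.05     # off-target cell_specific/marker rows
    depth_sd: float = 0.3              # log-normal per-cell depth factor sd

    seed: int = 0

    def __post_init__(self) -> None:
        planted = (self.n_global_seg + self.n_tissue_seg + self.n_cell_specific
                   + self.n_marker + self.n_silent)
        if planted > self.n_genes:
            raise ValueError(
                f"planted classes ({planted}) exceed n_genes ({self.n_genes})"
            )
        for name in ("cells_per_cluster", "clusters_per_cell_type",
                     "samples_per_tissue", "tissues_per_stage"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must exceed 1")

    @property
    def tissues(self) -> list[str]:
        return [f"{st}_t{i+1}" for st in self.stages
                for i in range(self.tissues_per_stage)]

    def as_dict(self) -> dict:
        d = asdict(self)
        d["cell_types"] = list(self.cell_types)
        d["stages"] = list(self.stages)
        return d


@dataclass
class SimTruth:
    """Planted ground truth accompanying a simulated dataset."""

    gene_class: dict                     # gene id -> class name
    global_segs: list
    tissue_segs: dict                    # tissue -> [gene]
    cell_specific: dict                  # cell type -> [gene]
    markers: dict                        # cell type -> [gene]
    silent: list
    variable: list
    type_mean_profiles: pd.DataFrame     # true per-cell means, genes × cell types
    config: dict = field(default_factory=dict)

    def genes_of_class(self, cls: str) -> list[str]:
        return [g for g, c in self.gene_class.items() if c == cls]


def _nb_counts(rng, mu: np.ndarray, size: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draw; ``mu`` and ``size`` broadcast to genes × cells."""
    lam = rng.gamma(shape=size, scale=np.where(size > 0, mu / size, 0.0))
    return rng.poisson(lam)


def simulate_dataset(cfg: SimConfig | None = None) -> tuple[CellMatrix, SimTruth]:
    """Generate an annotated multi-tissue UMI matrix plus its truth.

    Deterministic under ``cfg.seed``.  Counts are drawn per cell as
    negative binomial around the cluster's true mean vector, scaled by a
    per-cell log-normal depth factor.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    genes = np.array([f"g{i:05d}" for i in range(cfg.n_genes)], dtype=object)

    # partition genes into classes (front-loaded, disjoint by construction)
    cursor = 0

    def take(k):
        nonlocal cursor
        out = genes[cursor:cursor + k].tolist()
        cursor += k
        return out

    g_global = take(cfg.n_global_seg)
    g_tissue = take(cfg.n_tissue_seg)
    g_cs = take(cfg.n_cell_specific)
    g_mk = take(cfg.n_marker)
    g_silent = take(cfg.n_silent)
    g_var = genes[cursor:].tolist()

    gene_pos = {g: i for i, g in enumerate(genes)}
    tissues = cfg.tissues
    types = list(cfg.cell_types)

    # base means
    base_global = rng.lognormal(cfg.seg_meanlog, cfg.seg_sdlog, len(g_global))
    base_tissue = rng.lognormal(cfg.seg_meanlog, cfg.seg_sdlog, len(g_tissue))
    base_cs = rng.lognormal(cfg.cs_meanlog, cfg.cs_sdlog, len(g_cs))
    base_mk = rng.lognormal(cfg.marker_base_meanlog, cfg.marker_base_sdlog, len(g_mk))

    tissue_home = {g: tissues[i % len(tissues)] for i, g in enumerate(g_tissue)}
    cs_target = {g: types[i % len(types)] for i, g in enumerate(g_cs)}
    mk_target = {g: types[i % len(types)] for i, g in enumerate(g_mk)}

    gene_class = {}
    for g in g_global:
        gene_class[g] = "global_seg"
    for g in g_tissue:
        gene_class[g] = "tissue_seg"
    for g in g_cs:
        gene_class[g] = "cell_specific"
    for g in g_mk:
        gene_class[g] = "marker"
    for g in g_silent:
        gene_class[g] = "silent"
    for g in g_var:
        gene_class[g] = "variable"

    # true per-cell-type mean profiles (context-free classes only)
    prof = np.zeros((cfg.n_genes, len(types)))
    for i, g in enumerate(g_global):
        prof[gene_pos[g], :] = base_global[i]
    for i, g in enumerate(g_cs):
        j = types.index(cs_target[g])
        prof[gene_pos[g], :] = base_cs[i] / cfg.cs_offtarget_factor
        prof[gene_pos[g], j] = base_cs[i]
    for i, g in enumerate(g_mk):
        j = types.index(mk_target[g])
        prof[gene_pos[g], :] = base_mk[i]
        prof[gene_pos[g], j] = base_mk[i] * cfg.marker_fold
    type_mean_profiles = pd.DataFrame(
        prof, index=pd.Index(genes, name="gene_id"), columns=types
    )

    # per-cluster mean/size matrices, then counts
    blocks, cell_ids, meta_rows = [], [], []
    n_cells_cluster = cfg.cells_per_cluster
    cell_counter = 0
    for stage in cfg.stages:
        for t_i in range(cfg.tissues_per_stage):
            tissue = f"{stage}_t{t_i+1}"
            for s_i in range(cfg.samples_per_tissue):
                sample = f"{tissue}_s{s_i+1}"
                for ct in types:
                    for c_i in range(cfg.clusters_per_cell_type):
                        cluster = f"{ct}_c{c_i+1}"
                        mu = np.zeros(cfg.n_genes)
                        size = np.full(cfg.n_genes, cfg.nb_size)
                        for i, g in enumerate(g_global):
                            mu[gene_pos[g]] = base_global[i]
                        for i, g in enumerate(g_tissue):
                            if tissue_home[g] == tissue:
                                mu[gene_pos[g]] = base_tissue[i]
                            else:
                                mu[gene_pos[g]] = rng.lognormal(
                                    cfg.var_meanlog, cfg.var_sdlog
                                )
                        for i, g in enumerate(g_cs):
                            p = gene_pos[g]
                            if cs_target[g] == ct:
                                mu[p] = base_cs[i]
                            else:
                                mu[p] = base_cs[i] / cfg.cs_offtarget_factor
                                size[p] = cfg.unstable_nb_size
                        for i, g in enumerate(g_mk):
                            p = gene_pos[g]
                            if mk_target[g] == ct:
                                mu[p] = base_mk[i] * cfg.marker_fold
                            else:
                                mu[p] = base_mk[i]
                                size[p] = cfg.unstable_nb_size
                        if g_var:
                            mu[[gene_pos[g] for g in g_var]] = rng.lognormal(
                                cfg.var_meanlog, cfg.var_sdlog, len(g_var)
                            )
                        depth = rng.lognormal(0.0, cfg.depth_sd, n_cells_cluster)
                        counts = _nb_counts(
                            rng,
                            mu[:, None] * depth[None, :],
                            size[:, None],
                        )
                        blocks.append(sp.csr_matrix(counts))
                        for _ in range(n_cells_cluster):
                            cell_ids.append(f"{sample}-{cell_counter:06d}")
                            meta_rows.append((sample, tissue, stage, cluster, ct))
                            cell_counter += 1

    counts = sp.hstack(blocks, format="csr")
    meta = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "tissue", "stage", "cluster_id", "cell_type"],
        index=pd.Index(cell_ids, name="cell_id"),
    )
    cm = CellMatrix(
        counts=counts,
        gene_ids=genes,
        cell_ids=np.array(cell_ids, dtype=object),
        cell_meta=meta,
    )
    truth = SimTruth(
        gene_class=gene_class,
        global_segs=g_global,
        tissue_segs={t: [g for g in g_tissue if tissue_home[g] == t] for t in tissues},
        cell_specific={ct: [g for g in g_cs if cs_target[g] == ct] for ct in types},
        markers={ct: [g for g in g_mk if mk_target[g] == ct] for ct in types},
        silent=g_silent,
        variable=g_var,
        type_mean_profiles=type_mean_profiles,
        config=cfg.as_dict(),
    )
    return cm, truth


def simulate_mixture(
    type_means: pd.DataFrame,
    fractions,
    n_cells: int,
    seed: int = 0,
    nb_size: float = 2.0,
    depth_sd: float = 0.3,
) -> CellMatrix:
    """Simulate a mixed test sample with known cell-type composition.

    Cells are assigned to types multinomially with probabilities
    ``fractions`` (nonnegative, summing to 1); counts are negative
    binomial around each type's true mean profile (``type_means``: genes
    × cell types).
    """
    f = np.asarray(fractions, dtype=float)
    if (f < 0).any() or not np.isclose(f.sum(), 1.0):
        raise ValueError("fractions must be nonnegative and sum to 1")
    if len(f) != type_means.shape[1]:
        raise ValueError("fractions length must match number of cell types")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E6]))
    types = list(type_means.columns)
    assignment = rng.choice(len(types), size=n_cells, p=f)
    M = type_means.to_numpy()
    depth = rng.lognormal(0.0, depth_sd, n_cells)
    mu = M[:, assignment] * depth[None, :]
    counts = _nb_counts(rng, mu, np.full((type_means.shape[0], 1), nb_size))
    cell_ids = np.array([f"mix-{i:06d}" for i in range(n_cells)], dtype=object)
    meta = pd.DataFrame(
        {
            "sample_id": "mixture",
            "tissue": "mixture",
            "stage": pd.NA,
            "cluster_id": [types[a] for a in assignment],
            "cell_type": [types[a] for a in assignment],
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return CellMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=type_means.index.to_numpy(dtype=object),
        cell_ids=cell_ids,
        cell_meta=meta,
    )
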