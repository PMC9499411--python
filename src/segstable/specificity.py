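"""Stage-specific, cell-specific and marker SEGs, plus set comparisons.

* stage-specific SEGs: present in ≥ k tissues of one developmental stage
  and in **no** tissue of the other (zero tolerance); k = 5 for a
  high-confidence list, k = 2 for enrichment-style analyses.
* within-tissue cell-specific SEGs: SEGs unique to exactly one cell
  type's SEG set inside a tissue.
* marker SEGs: cell-specific SEGs additionally >2-fold elevated in the
  target cell type versus every other type, with a one-sided Welch t-test
  p < 0.05 per comparison, in every analyzed sample of the tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hierarchy import resolve_c
from .model import CellMatrix, SegSet


def stage_specific_segs(
    tissue_sets: list[SegSet],
    k: int = 2,
) -> tuple[SegSet, SegSet]:
    """Adult- and fetal-specific SEG sets from stage-labeled tissue sets.

    A gene is adult-specific when it appears in at least ``k`` adult tissue
    sets and in zero fetal sets (and symmetrically).  The two sets are
    disjoint by construction.
    """
    counts: dict[str, dict[str, int]] = {}
    for s in tissue_sets:
        stage = s.params.get("stage")
        if stage not in ("adult", "fetal"):
            raise ValueError(f"tissue set {s.scope_id!r} lacks a stage label")
        for gene in s.genes:
            d = counts.setdefault(gene, {"adult": 0, "fetal": 0})
            d[stage] += 1
    adult = sorted(g for g, d in counts.items() if d["adult"] >= k and d["fetal"] == 0)
    fetal = sorted(g for g, d in counts.items() if d["fetal"] >= k and d["adult"] == 0)
    params = {"k": k}
    return (
        SegSet(level="stage_specific", scope_id="adult", genes=adult, params=params),
        SegSet(level="stage_specific", scope_id="fetal", genes=fetal, params=params),
    )


def within_tissue_cell_type_sets(
    result,
    tissue: str,
    c: int | None = None,
) -> dict[str, SegSet]:
    """Per-cell-type SEG sets for one tissue, aggregated over its samples.

    For each cell type, keeps genes present in that cell type's SEG set in
    at least ``c`` of the tissue's samples (same recurrence rule as tissue
    SEGs: c = 2 when more than one sample carries the cell type, else 1).
    ``result`` is a :class:`~segstable.hierarchy.PipelineResult`.
    """
    samples = sorted(
        {
            sample_id
            for (sample_id, _ct) in result.cell_type_sets
            if result.sample_tissue.get(sample_id) == tissue
        }
    )
    by_type: dict[str, list[SegSet]] = {}
    for (sample_id, cell_type), seg in result.cell_type_sets.items():
        if sample_id in samples:
            by_type.setdefault(cell_type, []).append(seg)
    out = {}
    for cell_type, sets in sorted(by_type.items()):
        c_eff = resolve_c(len(sets), c)
        counts: dict[str, int] = {}
        for s in sets:
            for gene in s.genes:
                counts[gene] = counts.get(gene, 0) + 1
        genes = sorted(g for g, n in counts.items() if n >= c_eff)
        out[cell_type] = SegSet(
            level="cell_type",
            scope_id=f"{tissue}/{cell_type}",
            genes=genes,
            params={"c": c_eff, "tissue": tissue},
            flags={"n_samples": len(sets)},
        )
    return out


def cell_specific_segs(cell_type_sets: dict[str, SegSet] | list[SegSet]) -> dict[str, SegSet]:
    """Within-tissue cell-specific SEGs: genes unique to one cell type.

    Input is one SEG set per cell type of a single tissue (≥ 2 types).
    For every cell type, returns the genes found in its set and in no
    other type's set.
    """
    if isinstance(cell_type_sets, list):
        cell_type_sets = {s.scope_id: s for s in cell_type_sets}
    if len(cell_type_sets) < 2:
        raise ValueError("cell-specific SEGs need at least 2 cell types")
    membership: dict[str, int] = {}
    for s in cell_type_sets.values():
        for gene in s.genes:
            membership[gene] = membership.get(gene, 0) + 1
    out = {}
    for cell_type, s in sorted(cell_type_sets.items()):
        genes = sorted(g for g in s.genes if membership[g] == 1)
        out[cell_type] = SegSet(
            level="cell_specific",
            scope_id=s.scope_id,
            genes=genes,
            params=dict(s.params),
            flags={"n_cell_types": len(cell_type_sets)},
        )
    return out


def _depth_normalized(m: CellMatrix, target_sum: float = 1e4) -> np.ndarray:
    """Dense per-cell depth-normalized expression (genes × cells)."""
    X = np.asarray(m.counts.todense(), dtype=float)
    totals = X.sum(axis=0)
    totals[totals == 0] = 1.0
    return X * (target_sum / totals)[None, :]


def marker_segs(
    specific: SegSet,
    m: CellMatrix,
    tissue: str,
    target_cell_type: str,
    fold: float = 2.0,
    alpha: float = 0.05,
    target_sum: float = 1e4,
) -> tuple[SegSet, pd.DataFrame]:
    """Marker SEGs among one cell type's cell-specific SEGs.

    For every sample of the tissue and every other cell type present in
    that sample, the candidate must show (1) a mean fold change above
    ``fold`` in depth-normalized per-cell expression (other-type mean 0 →
    fold +inf, flagged) and (2) one-sided Welch t-test p < ``alpha``
    (target > other).  No multiple-testing correction is applied (plain
    per-comparison p-values); pass a smaller ``alpha`` to correct.

    Returns the marker SegSet and a per-comparison evidence table with
    columns gene, sample_id, other_cell_type, fold_change, p_value.
    """
    genes = list(specific.genes)
    if not genes:
        return (
            SegSet(level="marker", scope_id=specific.scope_id, genes=[],
                   params={"fold": fold, "alpha": alpha}),
            pd.DataFrame(columns=["gene", "sample_id", "other_cell_type",
                                  "fold_change", "p_value"]),
        )
    tm = m.subset_cells(m.cells_where(tissue=tissue))
    gidx = tm.gene_index(genes)
    rows = []
    passing = {g: True for g in genes}
    for sample_id in sorted(tm.cell_meta["sample_id"].unique()):
        sm = tm.subset_cells(tm.cells_where(sample_id=sample_id))
        types = sorted(sm.cell_meta["cell_type"].dropna().unique())
        if target_cell_type not in types or len(types) < 2:
            continue
        X = _depth_normalized(sm, target_sum)[gidx]
        tmask = (sm.cell_meta["cell_type"] == target_cell_type).to_numpy()
        target = X[:, tmask]
        t_mean = target.mean(axis=1)
        for other in types:
            if other == target_cell_type:
                continue
            omask = (sm.cell_meta["cell_type"] == other).to_numpy()
            other_x = X[:, omask]
            o_mean = other_x.mean(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                fc = np.where(o_mean > 0, t_mean / np.where(o_mean > 0, o_mean, 1.0),
                              np.inf)
            p = stats.ttest_ind(
                target, other_x, axis=1, equal_var=False, alternative="greater"
            ).pvalue
            for i, gene in enumerate(genes):
                ok = (fc[i] > fold) and (p[i] < alpha)
                passing[gene] = passing[gene] and bool(ok)
                rows.append((gene, sample_id, other, float(fc[i]), float(p[i])))
    evidence = pd.DataFrame(
        rows, columns=["gene", "sample_id", "other_cell_type", "fold_change", "p_value"]
    )
    tested = set(evidence["gene"]) if len(evidence) else set()
    marker_genes = [g for g in genes if g in tested and passing[g]]
    seg = SegSet(
        level="marker",
        scope_id=specific.scope_id,
        genes=marker_genes,
        params={"fold": fold, "alpha": alpha, "tissue": tissue,
                "target_cell_type": target_cell_type},
        flags={"zero_mean_inf_fold": bool(np.isinf(evidence["fold_change"]).any())
               if len(evidence) else False},
    )
    return seg, evidence


def compare_seg_sets(a: SegSet, b: SegSet) -> dict:
    """Overlap record between two SEG sets.

    Returns ``|a∩b|``, ``|a\\b|``, ``|b\\a|`` and the coverage fraction of
    ``a`` (``|a∩b| / |a|``; NaN for empty ``a``).
    """
    sa, sb = a.as_set(), b.as_set()
    inter = len(sa & sb)
    return {
        "intersection": inter,
        "a_only": len(sa - sb),
        "b_only": len(sb - sa),
        "coverage_a": inter / len(sa) if sa else float("nan"),
    }
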