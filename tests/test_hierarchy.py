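import numpy as np
import pandas as pd
import pytest

import segstable as st
from segstable.hierarchy import (
    PipelineParams,
    cell_type_segs,
    global_segs,
    sample_segs,
    tissue_segs,
    within_cluster_segs,
)
from conftest import small_config, small_params


def _gesi_table(rows: dict, scope="s1/c1"):
    """rows: gene -> (mean, gesi)"""
    df = pd.DataFrame(
        {g: {"mean": m, "sd": 0.0, "gesi": v} for g, (m, v) in rows.items()}
    ).T
    df.index.name = "gene_id"
    return st.GesiTable(level="across_bins", scope_id=scope, table=df)


def _set(genes, level="cell_type", scope="x", **params):
    return st.SegSet(level=level, scope_id=scope, genes=list(genes), params=params)


class TestWithinClusterSegs:
    def test_fewer_defined_than_K_returns_all(self):
        t = _gesi_table({f"g{i}": (1.0, 0.9 - i / 100) for i in range(5)})
        assert len(within_cluster_segs(t, K=1000)) == 5

    def test_exact_top_K_with_distinct_gesi(self):
        rng = np.random.default_rng(0)
        vals = rng.permutation(np.linspace(0.1, 0.99, 200))
        t = _gesi_table({f"g{i:03d}": (1.0, v) for i, v in enumerate(vals)})
        seg = within_cluster_segs(t, K=50)
        expected = set(t.table["gesi"].nlargest(50).index)
        assert set(seg.genes) == expected

    def test_tie_break_matches_brute_force(self):
        # ties in GESI at the cutoff rank, broken by mean then gene id
        rows = {
            "g_d": (5.0, 0.8),
            "g_c": (7.0, 0.5),
            "g_b": (3.0, 0.5),
            "g_a": (3.0, 0.5),
            "g_e": (9.0, 0.2),
        }
        t = _gesi_table(rows)
        brute = sorted(rows, key=lambda g: (-rows[g][1], -rows[g][0], g))
        for K in range(1, 6):
            assert within_cluster_segs(t, K).genes == brute[:K]

    def test_undefined_genes_excluded(self):
        t = _gesi_table({"g0": (1.0, 0.9), "g1": (0.0, float("nan"))})
        assert within_cluster_segs(t, K=10).genes == ["g0"]


class TestCellTypeSegs:
    def test_single_cluster_degenerate_flagged(self):
        only = _set(["g1", "g2"], level="cluster", scope="s1/c1")
        means = pd.DataFrame({"c1": [1.0, 2.0]}, index=["g1", "g2"])
        seg = cell_type_segs([only], means, scope_id="s1/T")
        assert seg.genes == ["g1", "g2"]
        assert seg.flags["single_cluster"]

    def test_all_shared_low_cv_no_relaxation(self):
        genes = [f"g{i:03d}" for i in range(600)]
        sets = [_set(genes, level="cluster", scope=f"s1/c{i}") for i in range(3)]
        means = pd.DataFrame(
            {f"c{i}": np.full(600, 10.0) for i in range(3)}, index=genes
        )
        seg = cell_type_segs(sets, means, g=0.667, S=500, scope_id="s1/T")
        assert set(seg.genes) == set(genes)
        assert seg.params["share_fraction"] == 1.0

    def test_relaxation_down_the_grid_until_S(self):
        shared3 = [f"a{i:03d}" for i in range(200)]   # in all 3 clusters
        shared2 = [f"b{i:03d}" for i in range(400)]   # in exactly 2 of 3
        sets = [
            _set(shared3 + shared2, level="cluster", scope="s1/c0"),
            _set(shared3 + shared2, level="cluster", scope="s1/c1"),
            _set(shared3, level="cluster", scope="s1/c2"),
        ]
        all_genes = shared3 + shared2
        means = pd.DataFrame(
            {f"c{i}": np.full(600, 5.0) for i in range(3)}, index=all_genes
        )
        seg = cell_type_segs(sets, means, g=0.667, S=500, scope_id="s1/T")
        # 100% gives 200 < 500; 75% of 3 clusters still requires all 3;
        # 50% admits the 2-of-3 genes -> 600 candidates, all pass GESI
        assert seg.params["share_fraction"] == 0.5
        assert set(seg.genes) == set(all_genes)


class TestSampleSegs:
    def test_disjoint_sets_empty(self):
        means = pd.DataFrame(np.ones((4, 2)), index=list("abcd"), columns=["T", "B"])
        seg = sample_segs([_set("ab"), _set("cd")], means, scope_id="s1")
        assert seg.genes == []

    def test_identical_sets_and_means_keep_all(self):
        means = pd.DataFrame(np.ones((2, 2)), index=["a", "b"], columns=["T", "B"])
        seg = sample_segs([_set("ab"), _set("ab")], means, scope_id="s1")
        assert set(seg.genes) == {"a", "b"}

    def test_cv_above_half_excluded(self):
        # means (10, 25): sd 10.61, mean 17.5, delta/u = 0.606 > 0.5
        means = pd.DataFrame({"T": [10.0], "B": [25.0]}, index=["a"])
        seg = sample_segs([_set("a"), _set("a")], means, g=0.667, scope_id="s1")
        assert seg.genes == []


class TestTissueSegs:
    def test_single_sample_defaults_c1(self):
        seg = tissue_segs([_set("abc", level="sample", scope="s1")], scope_id="lung")
        assert set(seg.genes) == {"a", "b", "c"} and seg.params["c"] == 1

    def test_two_of_three_samples_included_at_c2(self):
        sets = [_set("ax", level="sample"), _set("ay", level="sample"),
                _set("z", level="sample")]
        seg = tissue_segs(sets, scope_id="lung")
        assert seg.params["c"] == 2
        assert seg.genes == ["a"]

    def test_c_larger_than_sample_count_empty(self):
        assert tissue_segs([_set("ab", level="sample")], c=5).genes == []


class TestGlobalSegs:
    def _tissues(self):
        mk = lambda genes, scope, stage: st.SegSet(
            level="tissue", scope_id=scope, genes=list(genes),
            params={"stage": stage})
        return [
            mk("apx", "adult_1", "adult"),
            mk("apx", "adult_2", "adult"),
            mk("ap", "adult_3", "adult"),
            mk("fp", "fetal_1", "fetal"),
        ]

    def test_dual_stage_requirement(self):
        sets = self._tissues()
        strict = global_segs(sets, l=2, strict_stage=True)
        relaxed = global_segs(sets, l=2, strict_stage=False)
        # 'a' and 'x' are adult-only; 'p' spans both stages
        assert strict.genes == ["p"]
        assert set(relaxed.genes) == {"a", "p", "x"}
        assert set(strict.genes) <= set(relaxed.genes)

    def test_one_adult_plus_one_fetal_at_l2_included(self):
        sets = self._tissues()
        assert "p" in global_segs(sets, l=2).genes

    def test_l_equal_to_tissue_count(self):
        sets = self._tissues()
        assert global_segs(sets, l=4, strict_stage=False).genes == ["p"]

    def test_missing_stage_label_rejected_in_strict_mode(self):
        bad = [st.SegSet(level="tissue", scope_id="t", genes=["a"], params={})]
        with pytest.raises(st.IntegrityError):
            global_segs(bad, strict_stage=True)


class TestParams:
    def test_defaults_match_published_settings(self):
        p = PipelineParams()
        assert (p.n, p.m, p.r, p.K, p.g, p.S, p.l) == (10, 100, 100, 1000, 0.667, 500, 2)

    def test_validation(self):
        with pytest.raises(ValueError):
            PipelineParams(g=1.5)
        with pytest.raises(ValueError):
            PipelineParams(K=0)


class TestRunPipeline:
    def test_nesting_invariants(self, small_result):
        res = small_result
        for sample_id, sset in res.sample_sets.items():
            for (s, ct), ctset in res.cell_type_sets.items():
                if s == sample_id:
                    assert sset.as_set() <= ctset.as_set()
        for tissue, tset in res.tissue_sets.items():
            union = set()
            for s, seg in res.sample_sets.items():
                if res.sample_tissue[s] == tissue:
                    union |= seg.as_set()
            assert tset.as_set() <= union
        tissue_union = set().union(*(t.as_set() for t in res.tissue_sets.values()))
        assert res.global_set.as_set() <= tissue_union

    def test_provenance_recorded_everywhere(self, small_result):
        for seg in small_result.all_sets():
            assert seg.params, f"no provenance on {seg.level}/{seg.scope_id}"

    def test_planted_global_segs_recovered_on_small_benchmark(
        self, small_dataset, small_result
    ):
        _, truth = small_dataset
        got = small_result.global_set.as_set()
        planted = set(truth.global_segs)
        assert len(got & planted) / len(planted) >= 0.9
        assert len(got & planted) / max(len(got), 1) >= 0.9

    def test_no_eligible_clusters_completes_empty(self, toy_cm):
        res = st.run_pipeline(toy_cm, PipelineParams(m=100, n=2, r=5))
        assert res.cluster_sets == {} and res.global_set.genes == []

    def test_same_seed_reproduces_all_levels(self):
        cm, _ = st.simulate_dataset(small_config(seed=5))
        r1 = st.run_pipeline(cm, small_params(seed=5))
        r2 = st.run_pipeline(cm, small_params(seed=5))
        assert r1.global_set.genes == r2.global_set.genes
        for key in r1.cluster_sets:
            assert r1.cluster_sets[key].genes == r2.cluster_sets[key].genes

    def test_monotonicity_in_thresholds(self, small_result):
        """Raising g, c or l never enlarges a set; raising K never shrinks
        within-cluster sets."""
        res = small_result
        for key, gt in res.cluster_gesi.items():
            k_small = within_cluster_segs(gt, K=100).as_set()
            k_large = within_cluster_segs(gt, K=150).as_set()
            assert k_small <= k_large
        for sample_id, ct_means in res.cell_type_means.items():
            sets = [seg for (s, _), seg in sorted(res.cell_type_sets.items())
                    if s == sample_id]
            low = sample_segs(sets, ct_means, g=0.667, scope_id=sample_id).as_set()
            high = sample_segs(sets, ct_means, g=0.833, scope_id=sample_id).as_set()
            assert high <= low
        for tissue in res.tissue_sets:
            samples = [res.sample_sets[s] for s in sorted(res.sample_sets)
                       if res.sample_tissue[s] == tissue]
            assert tissue_segs(samples, c=2).as_set() <= tissue_segs(samples, c=1).as_set()
        tsets = [res.tissue_sets[t] for t in sorted(res.tissue_sets)]
        assert global_segs(tsets, l=3).as_set() <= global_segs(tsets, l=2).as_set()
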