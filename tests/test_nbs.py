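"""Network-based statistic: edge stats, components, permutation FWE machinery."""

import itertools

import numpy as np
import pytest

from rsconn.nbs import (
    NetworkBasedStatistic,
    cohens_d_equivalent,
    extract_components,
    nbs_test,
    subnetwork_mean_connectivity,
)
from rsconn.panel import CohortPanel
from rsconn._utils import vec_to_mat, mat_to_vec
import pandas as pd


def _panel_from_mats(mats_by_key, groups_by_subject):
    rows = [(s, groups_by_subject[s], tp) for (s, tp) in mats_by_key]
    manifest = pd.DataFrame(rows, columns=["subject_id", "group", "time_point"])
    return CohortPanel(manifest, mats_by_key)


class TestEdgeStats:
    def test_identical_groups_give_zero_t(self, rng):
        base = vec_to_mat(rng.standard_normal(10), 5)
        mats = {}
        groups = {}
        for i in range(4):
            mats[(f"A{i}", "TP1")] = base.copy()
            groups[f"A{i}"] = "AN"
        for i in range(4):
            mats[(f"H{i}", "TP1")] = base.copy()
            groups[f"H{i}"] = "HC"
        panel = _panel_from_mats(mats, groups)
        from rsconn.nbs import edge_stats

        t = edge_stats(panel, groups=("AN", "HC"), time_point="TP1")
        assert np.allclose(t, 0.0)

    def test_single_edge_matches_pooled_t_formula(self):
        a_vals = np.array([0.1, 0.3, 0.2, 0.4, 0.25, 0.15])
        b_vals = np.array([0.5, 0.45, 0.6, 0.4, 0.55, 0.5])
        mats, groups = {}, {}
        for i, v in enumerate(a_vals):
            mats[(f"A{i}", "TP1")] = vec_to_mat(np.array([v, 0.0, 0.0]), 3)
            groups[f"A{i}"] = "AN"
        for i, v in enumerate(b_vals):
            mats[(f"H{i}", "TP1")] = vec_to_mat(np.array([v, 0.0, 0.0]), 3)
            groups[f"H{i}"] = "HC"
        panel = _panel_from_mats(mats, groups)
        from rsconn.nbs import edge_stats

        t = edge_stats(panel, groups=("AN", "HC"), time_point="TP1")[0, 1]
        n1 = n2 = 6
        sp = np.sqrt(((n1 - 1) * a_vals.var(ddof=1) + (n2 - 1) * b_vals.var(ddof=1)) / (n1 + n2 - 2))
        expected = (a_vals.mean() - b_vals.mean()) / (sp * np.sqrt(1 / n1 + 1 / n2))
        assert t == pytest.approx(expected, abs=1e-10)

    def test_subject_order_does_not_change_statistics(self, small_panel):
        X, ids = small_panel.stack(group="AN", time_point="TP1")
        Xh, idsh = small_panel.stack(group="HC", time_point="TP1")
        data = np.concatenate([X, Xh])
        y = np.array(["AN"] * len(ids) + ["HC"] * len(idsh))
        est = NetworkBasedStatistic(n_perm=100, threshold=2.0)
        t1 = est.fit(data, y).stat_
        perm = np.random.default_rng(3).permutation(len(y))
        t2 = NetworkBasedStatistic(n_perm=100, threshold=2.0).fit(data[perm], y[perm]).stat_
        assert np.allclose(t1, t2, atol=1e-10)


def _brute_force_components(stat, thresh):
    """Exhaustive connected-component search over all node subsets (<= 7 nodes)."""
    n = stat.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if stat[i, j] > thresh]
    nodes = sorted({x for e in edges for x in e})
    comps = []
    seen = set()
    for start in nodes:
        if start in seen:
            continue
        comp = {start}
        changed = True
        while changed:
            changed = False
            for i, j in edges:
                if (i in comp) != (j in comp):
                    comp |= {i, j}
                    changed = True
        seen |= comp
        comp_edges = sorted(e for e in edges if e[0] in comp)
        comps.append((sorted(comp), comp_edges))
    comps.sort(key=lambda c: (-len(c[1]), c[0][0]))
    return comps


class TestExtractComponents:
    def test_threshold_above_max_gives_empty(self, rng):
        stat = vec_to_mat(rng.random(21), 7)
        assert extract_components(stat, stat.max() + 1) == []

    def test_two_disjoint_paths(self):
        stat = np.zeros((5, 5))
        for i, j in [(0, 1), (1, 2), (2, 0)]:  # 3-edge triangle
            stat[i, j] = stat[j, i] = 5.0
        stat[3, 4] = stat[4, 3] = 5.0  # separate dyad
        comps = extract_components(stat, 1.0)
        assert [len(c[1]) for c in comps] == [3, 1]
        assert comps[0][0] == [0, 1, 2]
        assert comps[1][1] == [(3, 4)]

    def test_complete_graph_single_component(self):
        n = 6
        stat = np.full((n, n), 9.0)
        np.fill_diagonal(stat, 0)
        comps = extract_components(stat, 1.0)
        assert len(comps) == 1
        assert len(comps[0][1]) == n * (n - 1) // 2

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle_on_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        stat = vec_to_mat(rng.normal(1.0, 1.0, n * (n - 1) // 2), n)
        comps = extract_components(stat, 1.2)
        oracle = _brute_force_components(stat, 1.2)
        assert [(c[0], c[1]) for c in comps] == oracle

    def test_raising_threshold_never_grows_extents(self, rng):
        stat = vec_to_mat(rng.normal(1, 1, 45), 10)
        lo = extract_components(stat, 0.8)
        hi = extract_components(stat, 1.5)
        max_lo = max((len(c[1]) for c in lo), default=0)
        max_hi = max((len(c[1]) for c in hi), default=0)
        assert max_hi <= max_lo


class TestNbsTest:
    def test_same_seed_reproducible(self, small_panel):
        r1 = nbs_test(small_panel, groups=("AN", "HC"), time_point="TP1", threshold=2.0, n_perm=200, seed=4)
        r2 = nbs_test(small_panel, groups=("AN", "HC"), time_point="TP1", threshold=2.0, n_perm=200, seed=4)
        assert [(c.extent, c.p_fwe) for c in r1] == [(c.extent, c.p_fwe) for c in r2]

    def test_p_values_in_open_unit_interval(self, small_panel):
        res = nbs_test(small_panel, groups=("AN", "HC"), time_point="TP1", threshold=1.5, n_perm=200, seed=0)
        for c in res:
            assert 0.0 < c.p_fwe <= 1.0
            assert c.extent == len(c.edges)

    def test_strong_planted_difference_detected(self, rng):
        # group B has a dramatically weakened 5-node clique on 12 nodes
        n, n_edges = 12, 66
        mats, groups = {}, {}
        iu, ju = np.triu_indices(n, k=1)
        clique = (iu < 5) & (ju < 5)
        for i in range(15):
            vec = 0.4 + 0.05 * rng.standard_normal(n_edges)
            mats[(f"H{i}", "TP1")] = vec_to_mat(vec, n)
            groups[f"H{i}"] = "HC"
        for i in range(15):
            vec = 0.4 + 0.05 * rng.standard_normal(n_edges)
            vec[clique] -= 0.3
            mats[(f"A{i}", "TP1")] = vec_to_mat(vec, n)
            groups[f"A{i}"] = "AN"
        panel = _panel_from_mats(mats, groups)
        res = nbs_test(panel, groups=("AN", "HC"), time_point="TP1", contrast="less", threshold=3.0, n_perm=500, seed=1)
        assert res and res[0].p_fwe < 0.05
        assert set(res[0].nodes) >= {0, 1, 2, 3, 4}

    def test_paired_design_detects_within_subject_change(self, rng):
        n = 8
        mats, groups = {}, {}
        for i in range(12):
            base = 0.3 + 0.05 * rng.standard_normal(28)
            mats[(f"A{i}", "TP1")] = vec_to_mat(base, n)
            mats[(f"A{i}", "TP2")] = vec_to_mat(base + 0.15 + 0.02 * rng.standard_normal(28), n)
            groups[f"A{i}"] = "AN"
        panel = _panel_from_mats(mats, groups)
        res = nbs_test(panel, design="paired", groups=("AN",), times=("TP1", "TP2"), threshold=3.0, n_perm=500, seed=2)
        assert res and res[0].p_fwe < 0.05

    def test_design_validation(self, small_panel):
        with pytest.raises(ValueError, match="n_perm"):
            nbs_test(small_panel, time_point="TP1", n_perm=50)
        with pytest.raises(ValueError, match="times"):
            nbs_test(small_panel, design="interaction", n_perm=200)


class TestEffectSizeConversion:
    def test_primary_threshold_meets_stated_bound(self):
        assert cohens_d_equivalent(3.0, 27, 40) >= 0.7
        assert cohens_d_equivalent(3.0, 27, 40) == pytest.approx(3.0 * np.sqrt(1 / 27 + 1 / 40), abs=1e-15)

    def test_sensitive_threshold_meets_stated_bound(self):
        assert cohens_d_equivalent(1.0, 27, 40) >= 0.2

    def test_zero_t_gives_zero_d(self):
        assert cohens_d_equivalent(0.0, 27, 40) == 0.0


class TestSubnetworkMeanConnectivity:
    def test_constant_connectome(self):
        mats = {("S1", "TP1"): vec_to_mat(np.full(6, 0.5), 4)}
        panel = _panel_from_mats(mats, {"S1": "AN"})
        table = subnetwork_mean_connectivity(panel, [(0, 1), (1, 2), (0, 3)])
        assert table["mean_connectivity"].iloc[0] == pytest.approx(0.5)

    def test_hand_computed_three_edges(self):
        vec = np.zeros(6)
        mat = vec_to_mat(vec, 4)
        mat[0, 1] = mat[1, 0] = 0.1
        mat[0, 2] = mat[2, 0] = 0.2
        mat[1, 2] = mat[2, 1] = 0.6
        panel = _panel_from_mats({("S1", "TP1"): mat}, {"S1": "AN"})
        table = subnetwork_mean_connectivity(panel, [(0, 1), (0, 2), (1, 2)])
        assert table["mean_connectivity"].iloc[0] == pytest.approx(0.3)

    def test_empty_edge_set_rejected(self, small_panel):
        with pytest.raises(ValueError):
            subnetwork_mean_connectivity(small_panel, [])
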