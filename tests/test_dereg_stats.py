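"""Per-set significance, FDR, ranking, intersection, progressive filter,
core/auxiliary extraction — each checked against an independent brute-force
oracle where the computation is non-trivial."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gsrpipe.dereg_stats import (
    bh_fdr,
    common_deregulated,
    deregulation_table,
    extract_core_auxiliary,
    mann_whitney_per_set,
    progressive_filter,
    rank_deregulated,
    top_k,
)
from gsrpipe.gsr_core import Functionome

from conftest import make_dag


def exact_mwu_p(case, control):
    """Exact two-sided Mann-Whitney p by full enumeration of all
    C(n+m, n) assignments of the pooled tie-free values."""
    pooled = list(case) + list(control)
    n = len(case)
    def u_stat(case_vals, ctrl_vals):
        return sum(1 for a in case_vals for b in ctrl_vals if a > b)
    u_obs = u_stat(case, control)
    m_total = len(pooled)
    us = [u_stat([pooled[i] for i in comb],
                 [pooled[i] for i in range(m_total) if i not in set(comb)])
          for comb in itertools.combinations(range(m_total), n)]
    mean_u = n * (m_total - n) / 2
    extreme = sum(1 for u in us if abs(u - mean_u) >= abs(u_obs - mean_u))
    return extreme / len(us)


def stepup_bh(p):
    """Reference BH step-up: q_(i) = min_{j>=i} m p_(j) / j, clipped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestMannWhitney:
    def test_separated_pairs_exact_third(self):
        assert mann_whitney_per_set([0.1, 0.2], [0.8, 0.9]) == pytest.approx(2 / 6)

    def test_identical_arms_give_one(self):
        assert mann_whitney_per_set([0.5, 0.5], [0.5, 0.5]) == 1.0

    def test_two_sided_symmetry(self):
        a, b = [0.1, 0.4, 0.3], [0.6, 0.9]
        assert mann_whitney_per_set(a, b) == pytest.approx(mann_whitney_per_set(b, a))

    def test_na_excluded_and_empty_arm_is_nan(self):
        p = mann_whitney_per_set([0.1, np.nan, 0.2], [0.8, 0.9])
        assert p == pytest.approx(2 / 6)
        assert np.isnan(mann_whitney_per_set([np.nan], [0.5]))

    def test_exact_mode_agrees_with_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n, m = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            case = rng.normal(size=n)
            ctrl = rng.normal(size=m)
            assert mann_whitney_per_set(case, ctrl) == pytest.approx(
                exact_mwu_p(case, ctrl))


class TestBhFdr:
    def test_hand_stepped_example(self):
        np.testing.assert_allclose(bh_fdr([0.005, 0.03, 0.04]),
                                   [0.015, 0.04, 0.04])

    def test_all_equal_and_single(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
        np.testing.assert_allclose(bh_fdr([0.7]), [0.7])

    def test_nan_propagates_and_reduces_m(self):
        q = bh_fdr([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], stepup_bh([0.01, 0.02]))

    def test_agrees_with_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(12)
        for n in (1, 5, 100, 1000):
            p = rng.uniform(size=n)
            np.testing.assert_allclose(bh_fdr(p), stepup_bh(p))

    def test_monotone_on_sorted_input(self):
        rng = np.random.default_rng(13)
        p = np.sort(rng.uniform(size=200))
        q = bh_fdr(p)
        assert np.all(np.diff(q) >= -1e-12)


def _toy_table():
    return pd.DataFrame({
        "set_id": ["S1", "S2", "S3"],
        "group": "stageI",
        "case_mean": [0.4, 0.5, 0.6],
        "control_mean": [0.8, 0.8, 0.8],
        "ratio": [0.5, 0.7, 0.9],
        "p_value": [0.001, 0.01, 0.01],
        "q_value": [0.003, 0.015, 0.015],
        "rank": [1, 2, 3],
    })


class TestRanking:
    def test_ascending_p(self):
        t = _toy_table()
        t.loc[0, "p_value"], t.loc[1, "p_value"] = 0.01, 0.001
        from gsrpipe.dereg_stats import _rank_order
        t["rank"] = _rank_order(t)
        assert rank_deregulated(t, "stageI")[:2] == ["S2", "S1"]

    def test_p_tie_broken_by_ratio_deviation(self):
        t = _toy_table()
        t["p_value"] = 0.01
        from gsrpipe.dereg_stats import _rank_order
        t["rank"] = _rank_order(t)
        # ratios 0.5, 0.7, 0.9 -> |1-r| = .5, .3, .1
        assert rank_deregulated(t, "stageI") == ["S1", "S2", "S3"]

    def test_top_k_exact_length(self):
        t = _toy_table()
        assert top_k(t, "stageI", 2) == ["S1", "S2"]
        assert top_k(t, "stageI", 10) == ["S1", "S2", "S3"]  # warns, uses all


class TestVenn:
    def test_identical_lists_all_common(self):
        lists = {g: [f"S{i}" for i in range(75)] for g in "ABCD"}
        part = common_deregulated(lists, k=75)
        assert len(part.common) == 75
        assert list(part.regions) == [("A", "B", "C", "D")]

    def test_disjoint_lists_empty_common(self):
        lists = {g: [f"{g}{i}" for i in range(5)] for g in "ABCD"}
        part = common_deregulated(lists, k=5)
        assert part.common == []
        assert len(part.regions) == 4

    def test_region_sizes_sum_to_union(self):
        rng = np.random.default_rng(21)
        universe = [f"S{i}" for i in range(60)]
        lists = {g: list(rng.choice(universe, size=30, replace=False))
                 for g in "ABCD"}
        part = common_deregulated(lists, k=20)
        union = set().union(*(set(l[:20]) for l in lists.values()))
        assert sum(len(v) for v in part.regions.values()) == len(union)


class TestProgressiveFilter:
    STAGES = ("stageI", "stageII", "stageIII", "stageIV")

    def _table(self, ratios, qs):
        rows = []
        for sid, rv in ratios.items():
            for g, r, q in zip(self.STAGES, rv, qs[sid]):
                rows.append({"set_id": sid, "group": g, "ratio": r, "q_value": q})
        return pd.DataFrame(rows)

    def test_monotone_significant_kept(self):
        t = self._table({"S": (0.95, 0.90, 0.85, 0.80)}, {"S": [0.001] * 4})
        assert progressive_filter(t, self.STAGES) == ["S"]

    def test_non_monotone_dropped(self):
        t = self._table({"S": (0.95, 0.96, 0.85, 0.80)}, {"S": [0.001] * 4})
        assert progressive_filter(t, self.STAGES) == []

    def test_insignificant_stage_dropped(self):
        t = self._table({"S": (0.95, 0.90, 0.85, 0.80)},
                        {"S": [0.001, 0.2, 0.001, 0.001]})
        assert progressive_filter(t, self.STAGES) == []

    def test_na_excluded_and_invariant_under_nonmonotone_padding(self):
        t = self._table(
            {"GOOD": (0.9, 0.8, 0.7, 0.6), "NA1": (0.9, np.nan, 0.7, 0.6),
             "UP": (0.5, 0.6, 0.7, 0.8)},
            {"GOOD": [0.01] * 4, "NA1": [0.01] * 4, "UP": [0.01] * 4})
        assert progressive_filter(t, self.STAGES) == ["GOOD"]


class TestCoreAuxiliary:
    def test_exact_match_is_core(self, chain_dag):
        dag = make_dag([("a", "root", "is_a"), ("b", "a", "is_a"),
                        ("c", "b", "is_a"), ("d", "c", "is_a")])
        res = extract_core_auxiliary(["d"], ["d"], dag, min_depth=3)
        assert res.core == ["d"]
        assert res.auxiliary == []

    def test_similar_terms_cluster(self):
        # deep chain: root <- a <- b <- c <- d; sim(c,d) = 4/5 >= 0.5
        dag = make_dag([("a", "root", "is_a"), ("b", "a", "is_a"),
                        ("c", "b", "is_a"), ("d", "c", "is_a")])
        res = extract_core_auxiliary(["c"], ["d"], dag, tau=0.5, min_depth=3)
        assert res.core_clusters == [["c", "d"]]

    def test_dissimilar_terms_are_auxiliary(self):
        dag = make_dag([("x1", "r1", "is_a"), ("x2", "x1", "is_a"),
                        ("x3", "x2", "is_a"),
                        ("y1", "r2", "is_a"), ("y2", "y1", "is_a"),
                        ("y3", "y2", "is_a")])
        res = extract_core_auxiliary(["x3"], ["y3"], dag, min_depth=3)
        assert res.core == []
        assert res.auxiliary == ["x3", "y3"]

    def test_upper_level_terms_excluded(self):
        dag = make_dag([("a", "root", "is_a"), ("b", "a", "is_a"),
                        ("c", "b", "is_a")])
        res = extract_core_auxiliary(["a"], ["a"], dag, min_depth=3)
        assert res.excluded_upper_level == ["a"]
        assert res.core == [] and res.auxiliary == []

    def test_core_and_auxiliary_disjoint(self):
        rng = np.random.default_rng(31)
        edges = []
        for child in range(1, 30):
            parent = int(rng.integers(0, child))
            edges.append((f"t{child}", f"t{parent}", "is_a"))
        dag = make_dag(edges)
        terms = [f"t{i}" for i in range(1, 30)]
        common = list(rng.choice(terms, size=10, replace=False))
        prog = list(rng.choice(terms, size=10, replace=False))
        res = extract_core_auxiliary(common, prog, dag, min_depth=1)
        assert set(res.core).isdisjoint(res.auxiliary)
        assert set(res.core) <= set(common) | set(prog)

    def test_empty_inputs_warn_and_return_empty(self, chain_dag):
        res = extract_core_auxiliary([], [], chain_dag)
        assert res.core == [] and res.auxiliary == []


class TestDeregulationTable:
    def test_columns_and_q_within_group(self):
        rng = np.random.default_rng(41)
        sets = ["S1", "S2", "S3"]
        case = Functionome([f"c{i}" for i in range(10)], sets,
                           rng.uniform(0.2, 0.6, size=(10, 3)))
        ctrl = Functionome([f"n{i}" for i in range(10)], sets,
                           rng.uniform(0.5, 0.9, size=(10, 3)))
        t = deregulation_table({"stageI": case}, {"stageI": ctrl})
        assert list(t.columns) == ["set_id", "group", "case_mean",
                                   "control_mean", "ratio", "p_value",
                                   "q_value", "rank"]
        assert sorted(t["rank"]) == [1, 2, 3]
        np.testing.assert_allclose(t["q_value"], stepup_bh(t["p_value"]))
        assert (t["ratio"] < 1).all()
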