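"""GSR index, rank templates, functionome reconstruction, corrections."""

import itertools

import numpy as np
import pytest

from gsrpipe.gsr_core import (
    Functionome,
    SetSkipped,
    build_rank_template,
    corrected_group_means,
    extract_immunofunctionome,
    gsr_index,
    reconstruct_functionome,
    sc_control_ratio,
    to_ranks,
)
from gsrpipe.io_formats import ExpressionMatrix, GeneSet, GeneSetCollection


class TestToRanks:
    @pytest.mark.parametrize("values,expected", [
        ((5.0, 1.0, 3.0), (3, 1, 2)),
        ((2.0, 2.0, 1.0), (2.5, 2.5, 1)),
        ((1.0, 2.0, 3.0, 4.0), (1, 2, 3, 4)),
    ])
    def test_examples(self, values, expected):
        np.testing.assert_allclose(to_ranks(values), expected)


class TestRankTemplate:
    def test_majority_ordering_and_support(self, abc_controls, abc_set):
        t = build_rank_template(abc_controls, ["s1", "s2", "s3"], abc_set)
        assert t.genes_used == ["A", "B", "C"]
        # pairs (A,B), (A,C), (B,C): majority says lower<higher for all
        assert t.pair_order.tolist() == [True, True, True]
        np.testing.assert_allclose(t.support, [2 / 3, 1.0, 2 / 3])

    def test_single_control_has_full_support(self, abc_controls, abc_set):
        t = build_rank_template(abc_controls, ["s2"], abc_set)
        # s2 = (A:1, B:3, C:2): A<B, A<C, not B<C
        assert t.pair_order.tolist() == [True, True, False]
        np.testing.assert_allclose(t.support, 1.0)

    def test_too_few_genes_skips_set(self, abc_controls):
        gs = GeneSet("ONE", "l", frozenset({"A", "ZZZ"}))
        ok = build_rank_template(abc_controls, ["s1"],
                                 GeneSet("TWO", "l", frozenset({"A", "B"})))
        assert ok.n_pairs == 1
        with pytest.raises(SetSkipped, match="too_few_genes"):
            build_rank_template(abc_controls, ["s1"], gs)

    def test_no_controls_errors(self, abc_controls, abc_set):
        with pytest.raises(ValueError, match="control"):
            build_rank_template(abc_controls, [], abc_set)

    def test_fifty_fifty_tie_resolves_lexicographically(self):
        expr = ExpressionMatrix(["A", "B"], ["s1", "s2"],
                                np.array([[1.0, 2.0], [2.0, 1.0]]))
        t = build_rank_template(expr, ["s1", "s2"],
                                GeneSet("S", "l", frozenset({"A", "B"})))
        assert t.pair_order.tolist() == [True]  # A declared lower
        assert t.support.tolist() == [0.5]


class TestGsrIndex:
    def test_hand_computed_examples(self, abc_controls, abc_set):
        t = build_rank_template(abc_controls, ["s1", "s2", "s3"], abc_set)
        assert gsr_index({"A": 3, "B": 2, "C": 1}, t) == 0.0
        assert gsr_index({"A": 2, "B": 1, "C": 3}, t) == pytest.approx(2 / 3)
        assert gsr_index({"A": 1, "B": 2, "C": 3}, t) == 1.0

    def test_tie_mismatches_strict_template_entry(self, abc_controls, abc_set):
        t = build_rank_template(abc_controls, ["s1", "s2", "s3"], abc_set)
        # A and B tied: A<B unmatched; A<C matched; B<C matched
        assert gsr_index({"A": 1, "B": 1, "C": 2}, t) == pytest.approx(2 / 3)

    def test_missing_gene_value_errors(self, abc_controls, abc_set):
        t = build_rank_template(abc_controls, ["s1", "s2", "s3"], abc_set)
        with pytest.raises(ValueError, match="lacks a value"):
            gsr_index({"A": 1, "B": 2}, t)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(0)
        genes = ["G1", "G2", "G3", "G4", "G5"]
        vals = rng.normal(size=(5, 6))
        sample = dict(zip(genes, rng.normal(size=5)))
        results = []
        for perm in itertools.permutations(range(5)):
            expr = ExpressionMatrix([genes[i] for i in perm],
                                    [f"s{j}" for j in range(6)], vals[list(perm)])
            t = build_rank_template(expr, expr.sample_ids,
                                    GeneSet("S", "l", frozenset(genes)))
            results.append(gsr_index(sample, t))
            if len(results) == 30:
                break
        assert len(set(results)) == 1

    def test_reversal_identity_tie_free(self):
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(6)]
        expr = ExpressionMatrix(genes, [f"s{j}" for j in range(5)],
                                rng.normal(size=(6, 5)))
        t = build_rank_template(expr, expr.sample_ids,
                                GeneSet("S", "l", frozenset(genes)))
        v = rng.normal(size=6)
        g = gsr_index(dict(zip(genes, v)), t)
        g_rev = gsr_index(dict(zip(genes, -v)), t)
        assert g + g_rev == pytest.approx(1.0)


class TestTemplateOptimality:
    def test_majority_template_maximizes_mean_match(self):
        """Among all 2^P pair assignments, the majority template achieves
        the maximal mean matching score over the control cohort."""
        rng = np.random.default_rng(5)
        for _ in range(15):
            n_genes = int(rng.integers(2, 5))
            n_ctrl = int(rng.integers(1, 7))
            genes = [f"G{i}" for i in range(n_genes)]
            vals = rng.normal(size=(n_genes, n_ctrl))
            expr = ExpressionMatrix(genes, [f"s{j}" for j in range(n_ctrl)], vals)
            t = build_rank_template(expr, expr.sample_ids,
                                    GeneSet("S", "l", frozenset(genes)))
            pairs = list(itertools.combinations(range(n_genes), 2))
            less = np.array([[vals[i, s] < vals[j, s] for s in range(n_ctrl)]
                             for i, j in pairs])
            majority_score = (less == t.pair_order[:, None]).mean()
            best = max(
                (less == np.array(assign)[:, None]).mean()
                for assign in itertools.product([True, False], repeat=len(pairs))
            )
            assert majority_score == pytest.approx(best)


class TestReconstructFunctionome:
    def test_hand_example_insample(self, abc_controls, abc_collection):
        case = ExpressionMatrix(["A", "B", "C"], ["c1"],
                                np.array([[3.0], [2.0], [1.0]]))
        cf, nf = reconstruct_functionome(case, abc_controls, abc_collection,
                                         control_scoring="insample")
        assert cf.gsr[0, 0] == 0.0
        np.testing.assert_allclose(nf.gsr[:, 0], [1.0, 2 / 3, 2 / 3])
        assert np.mean(nf.gsr[:, 0]) == pytest.approx(7 / 9)

    def test_absent_set_gets_na_column(self, abc_controls):
        coll = GeneSetCollection([
            GeneSet("PRESENT", "l", frozenset({"A", "B"})),
            GeneSet("ABSENT", "l", frozenset({"X", "Y"})),
        ])
        case = ExpressionMatrix(["A", "B", "C"], ["c1"],
                                np.array([[1.0], [2.0], [3.0]]))
        cf, _ = reconstruct_functionome(case, abc_controls, coll)
        assert np.isnan(cf.gsr[0, 1])
        assert cf.skipped_sets == {"ABSENT": "too_few_genes"}

    def test_case_equal_to_control_sample_scores_equally(self, abc_controls,
                                                         abc_collection):
        case = ExpressionMatrix(["A", "B", "C"], ["c1"],
                                abc_controls.values[:, [1]])
        cf, nf = reconstruct_functionome(case, abc_controls, abc_collection,
                                         control_scoring="insample")
        assert cf.gsr[0, 0] == nf.gsr[1, 0]

    def test_zero_common_genes_errors(self, abc_controls, abc_collection):
        case = ExpressionMatrix(["X"], ["c1"], np.array([[1.0]]))
        with pytest.raises(ValueError, match="no genes"):
            reconstruct_functionome(case, abc_controls, abc_collection)

    def test_split_mode_scores_odd_half_of_controls(self, abc_collection):
        rng = np.random.default_rng(2)
        expr = ExpressionMatrix(["A", "B", "C"], [f"n{i}" for i in range(6)],
                                rng.normal(size=(3, 6)))
        case = ExpressionMatrix(["A", "B", "C"], ["c1"], rng.normal(size=(3, 1)))
        cf, nf = reconstruct_functionome(case, expr, abc_collection)
        assert nf.sample_ids == ["n1", "n3", "n5"]
        assert cf.gsr.shape == (1, 1)

    def test_bounds_on_random_fixtures(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(8)]
        coll = GeneSetCollection([GeneSet("S", "l", frozenset(genes))])
        for _ in range(20):
            ctrl = ExpressionMatrix(genes, [f"n{i}" for i in range(6)],
                                    rng.normal(size=(8, 6)))
            case = ExpressionMatrix(genes, [f"c{i}" for i in range(4)],
                                    rng.normal(size=(8, 4)))
            cf, nf = reconstruct_functionome(case, ctrl, coll)
            vals = np.concatenate([cf.gsr.ravel(), nf.gsr.ravel()])
            assert np.all((vals >= 0) & (vals <= 1))


class TestImmunoExtraction:
    def test_column_subset_preserves_order(self):
        fn = Functionome(["s1"], ["SET_A", "SET_B", "SET_C"],
                         np.array([[0.5, 0.6, 0.7]]))
        mapping = {"SET_A": "GO:1", "SET_B": "GO:2", "SET_C": "GO:3"}
        imm = extract_immunofunctionome(fn, mapping, {"GO:1", "GO:3"})
        assert imm.set_ids == ["SET_A", "SET_C"]
        np.testing.assert_allclose(imm.gsr, [[0.5, 0.7]])

    def test_all_terms_gives_identity(self):
        fn = Functionome(["s1"], ["SET_A", "SET_B"], np.array([[0.1, 0.2]]))
        mapping = {"SET_A": "GO:1", "SET_B": "GO:2"}
        imm = extract_immunofunctionome(fn, mapping, {"GO:1", "GO:2"})
        assert imm.set_ids == fn.set_ids

    def test_empty_result_errors(self):
        fn = Functionome(["s1"], ["SET_A"], np.array([[0.1]]))
        with pytest.raises(ValueError, match="no functionome column"):
            extract_immunofunctionome(fn, {"SET_A": "GO:1"}, {"GO:99"})


class TestCorrectedMeans:
    def test_reproduces_printed_stage_table(self):
        """Multiplicative control-baseline correction reproduces the four
        published corrected stage means from the published raw means."""
        corrected = corrected_group_means(
            [0.6195, 0.6021, 0.5748, 0.5588],
            [0.6461, 0.6459, 0.6518, 0.6486])
        np.testing.assert_allclose(corrected, [0.6214, 0.6041, 0.5715, 0.5583],
                                   atol=1e-3)

    def test_equal_controls_leave_raw_unchanged(self):
        np.testing.assert_allclose(
            corrected_group_means([0.5, 0.6], [0.7, 0.7]), [0.5, 0.6])

    def test_single_group_identity(self):
        np.testing.assert_allclose(corrected_group_means([0.42], [0.9]), [0.42])

    def test_zero_control_mean_errors(self):
        with pytest.raises(ValueError, match="positive"):
            corrected_group_means([0.5], [0.0])


class TestScControlRatio:
    def test_elementwise(self):
        np.testing.assert_allclose(
            sc_control_ratio([0.45, 0.9, 0.3], [0.9, 0.9, 0.6]),
            [0.5, 1.0, 0.5])

    def test_zero_control_gives_nan(self):
        out = sc_control_ratio([0.5], [0.0])
        assert np.isnan(out[0])
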