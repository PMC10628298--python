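import numpy as np
import pandas as pd
import pytest
import scipy.stats

import lineagemem as lm
from lineagemem.containers import CountMatrix, NormalizedMatrix


def _norm(values, genes=None, cells=None):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    return NormalizedMatrix(values, genes, cells)


class TestLognormalize:
    def test_zero_counts_stay_zero(self):
        cm = CountMatrix(np.array([[0, 2], [3, 0]]), ["g1", "g2"], ["c1", "c2"])
        out = lm.lognormalize(cm)
        assert out.values[0, 0] == 0.0 and out.values[1, 1] == 0.0

    def test_single_gene_cell_closed_form(self):
        cm = CountMatrix(np.array([[7]]), ["g1"], ["c1"])
        out = lm.lognormalize(cm, scale=10_000)
        assert out.values[0, 0] == pytest.approx(np.log(1 + 10_000))

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, size=(50, 20)) + (np.arange(20) == 0)  # avoid zero cols
        counts[0] += 1
        cm = CountMatrix(counts, [f"g{i}" for i in range(50)], [f"c{j}" for j in range(20)])
        out = lm.lognormalize(cm, scale=10_000)
        expected = np.log1p(10_000 * counts / counts.sum(axis=0, keepdims=True))
        np.testing.assert_allclose(out.values, expected)

    def test_all_zero_cell_rejected_by_id(self):
        cm = CountMatrix(np.array([[1, 0], [2, 0]]), ["g1", "g2"], ["good", "empty"])
        with pytest.raises(ValueError, match="empty"):
            lm.lognormalize(cm)


class TestSignatureScore:
    def test_top_ranked_signature_scores_one(self):
        # signature genes occupy ranks 1..m in every cell
        values = np.vstack([np.full((3, 4), 9.0) + np.arange(3)[:, None], np.ones((7, 4))])
        nm = _norm(values)
        scores = lm.signature_score(nm, ["g0", "g1", "g2"], rmax=5)
        assert np.allclose(scores, 1.0)

    def test_signature_beyond_rmax_closed_form(self):
        # m=10 signature genes all past rmax=1500: U = 10*1501 - 55 = 14955
        n_genes = 1600
        values = np.zeros((n_genes, 2))
        values[:1590] = np.arange(1590, 0, -1)[:, None]  # signature = last 10 rows, all zero
        nm = _norm(values)
        sig = [f"g{i}" for i in range(1590, 1600)]
        scores = lm.signature_score(nm, sig, rmax=1500)
        # zero-expression genes tie; with all ties past rmax every rank caps at 1501
        assert np.allclose(scores, 1 - 14_955 / 15_000)
        assert scores.iloc[0] == pytest.approx(0.003)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        values = rng.gamma(2, size=(200, 30))
        nm = _norm(values)
        sig = [f"g{i}" for i in range(0, 40, 4)]
        s1 = lm.signature_score(nm, sig, rmax=100)
        s2 = lm.signature_score(_norm(np.exp(values / 3.0)), sig, rmax=100)
        np.testing.assert_allclose(s1.values, s2.values)

    def test_permuting_other_genes_leaves_score_unchanged(self):
        rng = np.random.default_rng(4)
        values = rng.gamma(2, size=(50, 10))
        nm = _norm(values)
        sig = ["g3", "g7"]
        s1 = lm.signature_score(nm, sig, rmax=30)
        other = [i for i in range(50) if i not in (3, 7)]
        perm = rng.permutation(other)
        shuffled = values.copy()
        shuffled[other] = values[perm]
        s2 = lm.signature_score(_norm(shuffled), sig, rmax=30)
        np.testing.assert_allclose(s1.values, s2.values)

    def test_missing_genes_warned_and_intersection_used(self):
        nm = _norm(np.ones((5, 3)))
        with pytest.warns(UserWarning, match="absent"):
            scores = lm.signature_score(nm, ["g1", "nope"], rmax=4)
        assert len(scores) == 3

    def test_all_genes_missing_rejected(self):
        nm = _norm(np.ones((5, 3)))
        with pytest.raises(ValueError, match="no signature genes"), pytest.warns(UserWarning):
            lm.signature_score(nm, ["nope"], rmax=4)


class TestCallStates:
    def test_mixture_separates_bimodal_scores(self):
        rng = np.random.default_rng(0)
        truth = rng.random(2000) < 0.3
        scores = pd.Series(
            np.where(truth, rng.normal(0.8, 0.05, 2000), rng.normal(0.2, 0.05, 2000)),
            index=[f"c{i}" for i in range(2000)],
        )
        calls = lm.call_states(scores, method="mixture")
        accuracy = ((calls == "P") == truth).mean()
        assert accuracy >= 0.99

    def test_quantile_labels_exact_count(self):
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.random(1000), index=[f"c{i}" for i in range(1000)])
        calls = lm.call_states(scores, method="quantile", q=0.02)
        assert (calls == "P").sum() == 20
        # and they are the top-scoring cells
        assert set(calls[calls == "P"].index) == set(scores.nlargest(20).index)

    def test_constant_scores_all_susceptible(self):
        scores = pd.Series(np.full(50, 0.4), index=[f"c{i}" for i in range(50)])
        with pytest.warns(UserWarning, match="constant"):
            calls = lm.call_states(scores)
        assert (calls == "S").all()

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match=">= 20"):
            lm.call_states(pd.Series([0.1] * 5))


class TestDE:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(2)
        nm = _norm(rng.gamma(2, size=(100, 30)))
        cells = list(nm.cells)
        de = lm.de_wilcoxon(nm, cells, cells)
        assert not de["significant"].any()

    def test_complete_separation_exact_p(self):
        # one informative gene, 5 vs 5 cells, complete separation:
        # two-sided exact rank-sum p = 2/252
        values = np.vstack(
            [
                np.array([5.0, 6, 7, 8, 9, 0, 1, 2, 3, 4]),
                np.tile(np.arange(10.0), (3, 1)) + np.random.default_rng(1).normal(0, .01, (3, 10)),
            ]
        )
        nm = _norm(values)
        a, b = nm.cells[:5], nm.cells[5:]
        de = lm.de_wilcoxon(nm, a, b)
        assert de.loc[de.gene == "g0", "p_value"].iloc[0] == pytest.approx(2 / 252)
        # Bonferroni over the 4 tested genes keeps it under alpha; lfc passes
        assert bool(de.loc[de.gene == "g0", "significant"].iloc[0])

    def test_constant_gene_reported_na(self):
        values = np.vstack([np.full(10, 3.0), np.arange(10.0)])
        nm = _norm(values)
        de = lm.de_wilcoxon(nm, nm.cells[:5], nm.cells[5:])
        assert np.isnan(de.loc[de.gene == "g0", "p_value"].iloc[0])
        assert not bool(de.loc[de.gene == "g0", "significant"].iloc[0])

    def test_low_expression_genes_excluded(self):
        rng = np.random.default_rng(3)
        values = rng.gamma(2, size=(3, 40))
        values[0] = 0.0
        values[0, 5] = 1.0  # expressed in <10% of both groups
        nm = _norm(values)
        de = lm.de_wilcoxon(nm, nm.cells[:20], nm.cells[20:])
        assert np.isnan(de.loc[de.gene == "g0", "p_value"].iloc[0])

    def test_null_pvalues_uniform(self):
        # label permutation on null data: KS distance to uniform < 0.1
        rng = np.random.default_rng(8)
        counts = rng.negative_binomial(5, 0.5, size=(2000, 200))
        cm = CountMatrix(counts, [f"g{i}" for i in range(2000)], [f"c{j}" for j in range(200)])
        nm = lm.lognormalize(cm)
        perm = rng.permutation(200)
        a = [nm.cells[i] for i in perm[:100]]
        b = [nm.cells[i] for i in perm[100:]]
        de = lm.de_wilcoxon(nm, a, b)
        p = de["p_value"].dropna()
        ks = scipy.stats.kstest(p, "uniform").statistic
        assert ks < 0.1

    def test_small_groups_rejected(self):
        nm = _norm(np.ones((3, 10)))
        with pytest.raises(ValueError, match=">= 3"):
            lm.de_wilcoxon(nm, nm.cells[:2], nm.cells[2:])

    def test_unknown_cells_rejected(self):
        nm = _norm(np.ones((3, 6)))
        with pytest.raises(ValueError, match="no cells"):
            lm.de_wilcoxon(nm, ["x", "y", "z"], nm.cells[:3])


class TestPrimedGeneset:
    def test_keeps_only_significant_upregulated(self):
        de = pd.DataFrame(
            {
                "gene": list("abcde"),
                "log2_fold_change": [1.0, 0.5, -0.8, 2.0, -1.0],
                "p_value": [1e-5] * 5,
                "p_adjusted": [1e-4] * 5,
                "significant": [True, True, True, True, False],
            }
        )
        assert lm.derive_primed_geneset(de) == {"a", "b", "d"}

    def test_empty_result_warns(self):
        de = pd.DataFrame(
            {"gene": ["a"], "log2_fold_change": [1.0], "p_value": [0.5],
             "p_adjusted": [1.0], "significant": [False]}
        )
        with pytest.warns(UserWarning, match="empty"):
            assert lm.derive_primed_geneset(de) == set()

    def test_recovers_planted_markers_from_synthetic_data(self, two_state_matrix):
        cm, states, cfg = two_state_matrix
        nm = lm.lognormalize(cm)
        primed = [c for c in cm.cells if states[c] == "P"]
        susceptible = [c for c in cm.cells if states[c] == "S"]
        de = lm.de_wilcoxon(nm, primed, susceptible)
        geneset = lm.derive_primed_geneset(de)
        assert set(cfg.marker_up_primed) <= geneset


class TestIntermediateCall:
    def _setup(self, n_s=1000, n_p=30):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(50)]
        cells = [f"s{i}" for i in range(n_s)] + [f"p{i}" for i in range(n_p)]
        values = rng.gamma(2.0, size=(50, n_s + n_p))
        nm = NormalizedMatrix(values, genes, cells)
        states = pd.Series(["S"] * n_s + ["P"] * n_p, index=cells)
        return nm, states

    def test_exact_fraction_relabelled(self):
        nm, states = self._setup()
        out = lm.intermediate_call(nm, states, ["g0", "g1"], q=0.02)
        assert (out == "I").sum() == 20

    def test_q_zero_changes_nothing(self):
        nm, states = self._setup()
        out = lm.intermediate_call(nm, states, ["g0"], q=0.0)
        assert out.equals(states)

    def test_primed_cells_never_relabelled(self):
        nm, states = self._setup()
        out = lm.intermediate_call(nm, states, ["g0", "g1"], q=0.5)
        assert (out[states == "P"] == "P").all()

    def test_at_least_one_intermediate_when_few_susceptible(self):
        nm, states = self._setup(n_s=10, n_p=30)
        out = lm.intermediate_call(nm, states, ["g0"], q=0.02)
        assert (out == "I").sum() == 1

    def test_planted_intermediates_recovered(self):
        # 30 susceptible cells with partially activated crossing genes
        rng = np.random.default_rng(10)
        n_s, n_i = 970, 30
        genes = [f"g{i}" for i in range(60)]
        crossing = genes[:10]
        values = rng.gamma(2.0, size=(60, n_s + n_i))
        values[:10, n_s:] *= 3.0  # partial activation in planted intermediates
        cells = [f"c{i}" for i in range(n_s + n_i)]
        nm = NormalizedMatrix(values, genes, cells)
        states = pd.Series(["S"] * (n_s + n_i), index=cells)
        out = lm.intermediate_call(nm, states, crossing, q=n_i / (n_s + n_i))
        called = set(out[out == "I"].index)
        planted = set(cells[n_s:])
        assert len(called & planted) / len(called) >= 0.7

    def test_empty_gene_set_rejected(self):
        nm, states = self._setup(n_s=30, n_p=5)
        with pytest.raises(ValueError, match="non-empty"):
            lm.intermediate_call(nm, states, [])


class TestFlowGate:
    def test_distinct_control_gates_exactly_two_percent(self):
        rng = np.random.default_rng(0)
        control = rng.permutation(1000) + rng.random(1000) * 0.5
        res = lm.flow_gate(control, q=0.02)
        assert res.percent_primed["control"] == pytest.approx(2.0)
        assert (control >= res.threshold).sum() == 20

    def test_shifted_treated_exceeds_control_percent(self):
        rng = np.random.default_rng(1)
        control = rng.normal(size=2000)
        res = lm.flow_gate(control, {"treated": control + 1.0}, q=0.02)
        assert res.percent_primed["treated"] > 2.0

    def test_percent_matches_mixture_tail_closed_form(self):
        # treated sample from the generator: expected percent primed equals
        # the lognormal mixture tail above the realized threshold
        control = lm.gen_flow(10_000, 0.02, shift=3.0, seed=5)
        treated = lm.gen_flow(10_000, 0.2, shift=3.0, seed=6)
        res = lm.flow_gate(control["intensity"], {"t": treated["intensity"]}, q=0.02)
        log_t = np.log(res.threshold)
        tail = lambda mu: scipy.stats.norm.sf(log_t, loc=mu, scale=0.5)
        expect = 0.2 * tail(4.0 + 3.0) + 0.8 * tail(4.0)
        sigma = np.sqrt(expect * (1 - expect) / 10_000)
        assert abs(res.percent_primed["t"] / 100 - expect) < 3 * sigma + 1e-9

    def test_empty_condition_is_nan_with_warning(self):
        control = np.arange(100.0)
        with pytest.warns(UserWarning, match="no events"):
            res = lm.flow_gate(control, {"empty": []}, q=0.02)
        assert np.isnan(res.percent_primed["empty"])

    def test_control_too_small_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            lm.flow_gate(np.arange(10.0), q=0.02)
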