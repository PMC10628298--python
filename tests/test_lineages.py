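import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import lineagemem as lm
from lineagemem.containers import NormalizedMatrix, make_cell_table

import oracles


def _table(rows):
    """rows: (cell, lineage, state) under one sample."""
    return make_cell_table(
        cell_id=[r[0] for r in rows],
        sample_id=["s"] * len(rows),
        lineage_id=[r[1] for r in rows],
        state=[r[2] for r in rows],
    )


class TestClassify:
    @pytest.mark.parametrize(
        "founder,states,expected",
        [
            ("S", ["S", "S", "S"], "PURE_S"),
            ("S", ["S", "P"], "S_TO_P"),
            ("P", ["P", "P"], "PURE_P"),
            ("P", ["P", "S"], "P_TO_S"),
            ("P", ["S", "S"], "P_TO_S"),  # fully switched still counts as switching
            ("S", ["S", "I"], "PURE_S"),  # intermediates count as susceptible
        ],
    )
    def test_category_rules(self, founder, states, expected):
        rows = [(f"c{i}", "L1", s) for i, s in enumerate(states)]
        classes = lm.classify_lineages(_table(rows), {"L1": founder})
        assert classes.loc["L1", "category"] == expected
        assert classes.loc["L1", "size"] == len(states)

    def test_lineage_missing_from_founder_map_excluded(self):
        rows = [("c1", "L1", "S"), ("c2", "L2", "S")]
        with pytest.warns(UserWarning, match="missing"):
            classes = lm.classify_lineages(_table(rows), {"L1": "S"})
        assert list(classes.index) == ["L1"]

    def test_simulator_truth_classification_exact(self, default_params):
        pop = lm.simulate_population(
            default_params, {"S": 150, "P": 150}, {"doublings": 3}, seed=21
        )
        classes = lm.classify_lineages(pop.to_table(), pop.founder_state_map())
        comp = pop.lineage_compositions().set_index("lineage_id")
        comp = comp[comp["size"] > 0]
        assert len(classes) == len(comp)
        for lid, row in comp.iterrows():
            founder_p = row["founder_state"] == "P"
            pure = row["n_primed"] == row["size"] if founder_p else row["n_primed"] == 0
            expected = (
                ("PURE_P" if pure else "P_TO_S") if founder_p else ("PURE_S" if pure else "S_TO_P")
            )
            assert classes.loc[lid, "category"] == expected
        # categories partition the lineages
        assert classes["category"].isin(lm.lineages.CATEGORIES).all()

    def test_categories_partition(self):
        rows = [("c1", "L1", "S"), ("c2", "L2", "P"), ("c3", "L2", "S")]
        classes = lm.classify_lineages(_table(rows), {"L1": "S", "L2": "P"})
        assert classes["category"].value_counts().sum() == 2


class TestCrossingInputs:
    def test_toy_table_matches_hand_enumeration(self):
        rows = [
            ("a1", "L1", "S"), ("a2", "L1", "S"),          # PURE_S
            ("b1", "L2", "S"), ("b2", "L2", "P"),          # S_TO_P
            ("c1", "L3", "P"), ("c2", "L3", "P"),          # PURE_P
            ("d1", "L4", "P"), ("d2", "L4", "S"),          # P_TO_S
            ("e1", "L5", "S"), ("e2", "L5", "S"), ("e3", "L5", "P"),  # S_TO_P
        ]
        founders = {"L1": "S", "L2": "S", "L3": "P", "L4": "P", "L5": "S"}
        table = _table(rows)
        classes = lm.classify_lineages(table, founders)
        a, b = lm.crossing_de_inputs(table, classes)
        assert set(a) == {"a1", "a2"}
        assert set(b) == {"b1", "e1", "e2"}  # susceptible cells of switching lineages only

    def test_missing_category_rejected(self):
        rows = [("a1", "L1", "S"), ("a2", "L1", "S")]
        classes = lm.classify_lineages(_table(rows), {"L1": "S"})
        with pytest.raises(ValueError, match="PURE_S and one S_TO_P"):
            lm.crossing_de_inputs(_table(rows), classes)


def _cond_tables(spec):
    """spec: condition -> {lineage: state string like 'SSPP'}."""
    out = {}
    for cond, lineages in spec.items():
        rows = []
        for lid, states in lineages.items():
            for i, s in enumerate(states):
                rows.append((f"{cond}_{lid}_{i}", lid, s))
        t = make_cell_table(
            cell_id=[r[0] for r in rows],
            sample_id=[cond] * len(rows),
            lineage_id=[r[1] for r in rows],
            state=[r[2] for r in rows],
        )
        out[cond] = t
    return out


class TestMatchedFractions:
    def test_fraction_arithmetic(self):
        tables = _cond_tables(
            {"untreated": {"L1": "SSS", "L2": "SP"}, "treated": {"L1": "SSPP", "L2": "PP"}}
        )
        frac = lm.matched_lineage_fractions(tables, "untreated", ref_state="S")
        assert list(frac.index) == ["L1"]  # L2 not pure susceptible in reference
        assert frac.loc["L1", "treated"] == pytest.approx(0.5)
        assert frac.loc["L1", "untreated"] == 0.0

    def test_identical_tables_equal_reference(self):
        t = _cond_tables({"u": {"L1": "SSS", "L2": "SS"}})["u"]
        frac = lm.matched_lineage_fractions({"u": t, "t": t.copy()}, "u", ref_state="S")
        assert (frac["t"] == 0.0).all()

    def test_missing_lineage_is_nan(self):
        tables = _cond_tables({"u": {"L1": "SS", "L2": "SS"}, "t": {"L1": "SP"}})
        frac = lm.matched_lineage_fractions(tables, "u", ref_state="S")
        assert np.isnan(frac.loc["L2", "t"])

    def test_reference_absent_rejected(self):
        tables = _cond_tables({"u": {"L1": "SS"}})
        with pytest.raises(ValueError, match="reference"):
            lm.matched_lineage_fractions(tables, "missing")

    def test_treatment_raised_kon_dominates_untreated(self, default_params):
        # split-plate design with S->P switching boosted 10x on the treated plate
        design = lm.ExperimentDesign(
            founders={"S": 400},
            expansion_doublings=3,
            plates={"untreated": {}, "treated": {"p_on": default_params.p_on * 10}},
            treatment_days=10.0,
            barcode_detection_rate=1.0,
        )
        res = lm.simulate_experiment(design, default_params, seed=5)
        tables = {c: t for c, t in res.tables.items()}
        frac = lm.matched_lineage_fractions(tables, "untreated", ref_state="S")
        both = frac.dropna()
        assert len(both) >= 200
        p = scipy.stats.wilcoxon(
            both["treated"], both["untreated"], alternative="greater"
        ).pvalue
        assert p < 0.01


class TestFractionReduced:
    def test_identical_condition_zero(self):
        frac = pd.DataFrame({"u": [0.5, 0.2], "t": [0.5, 0.2]}, index=["L1", "L2"])
        assert lm.fraction_reduced(frac, "t", "u") == 0.0

    def test_all_drop_to_zero_is_one(self):
        frac = pd.DataFrame({"u": [1.0, 1.0], "t": [0.0, 0.0]}, index=["L1", "L2"])
        assert lm.fraction_reduced(frac, "t", "u") == 1.0

    def test_no_comparable_lineages_nan(self):
        frac = pd.DataFrame({"u": [1.0], "t": [np.nan]}, index=["L1"])
        with pytest.warns(UserWarning):
            assert np.isnan(lm.fraction_reduced(frac, "t", "u"))

    def test_raised_koff_reduces_most_primed_lineages(self, default_params):
        # PI3K-inhibitor analog: P->S switching up 5x on the treated plate.
        # Treatment spans several primed division times so the 5x effect
        # can express (primed cells divide ~ every 7 days here).
        design = lm.ExperimentDesign(
            founders={"S": 200, "P": 400},
            expansion_doublings=2,
            plates={"untreated": {}, "treated": {"p_off": min(default_params.p_off * 5, 1.0)}},
            treatment_days=30.0,
            barcode_detection_rate=1.0,
        )
        res = lm.simulate_experiment(design, default_params, seed=11)
        frac = lm.matched_lineage_fractions(res.tables, "untreated", ref_state=None)
        primed_containing = frac[frac["untreated"] > 0].dropna()
        assert len(primed_containing) >= 100
        assert lm.fraction_reduced(primed_containing, "treated", "untreated") > 0.8


class TestSwitchProbEstimator:
    def test_full_purity_gives_zero(self):
        assert lm.estimate_switch_prob_from_purity(1.0, 4) == 0.0

    def test_inverts_enumerated_purity_exactly(self):
        # d=2: six daughter draws; purity from exhaustive enumeration
        p = 0.05
        purity = oracles.purity_by_enumeration(p, doublings=2)
        assert purity == pytest.approx((1 - p) ** 6)
        assert lm.estimate_switch_prob_from_purity(purity, 2) == pytest.approx(p)

    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_matches_enumeration_for_small_trees(self, d):
        p = 0.01
        purity = oracles.purity_by_enumeration(p, d)
        assert lm.estimate_switch_prob_from_purity(purity, d) == pytest.approx(p, rel=1e-12)

    def test_monte_carlo_bias_small(self):
        # 10,000 simulated complete 4-doubling trees at p = 0.02
        rng = np.random.default_rng(12)
        p, d, n = 0.02, 4, 10_000
        draws = 2 * (2**d - 1)
        pure = (rng.random((n, draws)) >= p).all(axis=1)
        p_hat = lm.estimate_switch_prob_from_purity(pure.mean(), d)
        assert abs(p_hat - p) / p < 0.10

    def test_zero_purity_is_nan(self):
        assert math.isnan(lm.estimate_switch_prob_from_purity(0.0, 2))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            lm.estimate_switch_prob_from_purity(1.2, 2)
        with pytest.raises(ValueError):
            lm.estimate_switch_prob_from_purity(0.5, 0)


class TestGeneMemoryICC:
    def _table_for(self, cells, lineage_of):
        return make_cell_table(
            cell_id=cells,
            sample_id=["s"] * len(cells),
            lineage_id=[lineage_of[c] for c in cells],
            state=["S"] * len(cells),
        )

    def test_perfect_lineage_memory_gives_one(self):
        k, m = 20, 4
        cells = [f"c{i}" for i in range(k * m)]
        lineage_of = {c: f"L{i // m}" for i, c in enumerate(cells)}
        lineage_means = np.repeat(np.arange(k, dtype=float), m)
        values = np.vstack([lineage_means, lineage_means * 2 + 5])
        nm = NormalizedMatrix(values, ["g0", "g1"], cells)
        icc = lm.gene_memory_icc(nm, self._table_for(cells, lineage_of))
        assert (icc > 0.99).all()

    def test_iid_expression_gives_near_zero(self):
        rng = np.random.default_rng(6)
        k, m = 200, 5
        cells = [f"c{i}" for i in range(k * m)]
        lineage_of = {c: f"L{i // m}" for i, c in enumerate(cells)}
        values = rng.normal(size=(20, k * m))
        nm = NormalizedMatrix(values, [f"g{i}" for i in range(20)], cells)
        icc = lm.gene_memory_icc(nm, self._table_for(cells, lineage_of))
        assert (icc < 0.05).all()

    def test_planted_heritability_near_expected(self):
        # lineage variance == cell variance -> ICC expectation 0.5
        rng = np.random.default_rng(7)
        k, m = 200, 5
        cells = [f"c{i}" for i in range(k * m)]
        lineage_of = {c: f"L{i // m}" for i, c in enumerate(cells)}
        b = np.repeat(rng.normal(size=(30, k)), m, axis=1)
        values = b + rng.normal(size=(30, k * m))
        nm = NormalizedMatrix(values, [f"g{i}" for i in range(30)], cells)
        icc = lm.gene_memory_icc(nm, self._table_for(cells, lineage_of))
        assert abs(icc.mean() - 0.5) < 0.05

    def test_constant_gene_scores_zero(self):
        k, m = 12, 3
        cells = [f"c{i}" for i in range(k * m)]
        lineage_of = {c: f"L{i // m}" for i, c in enumerate(cells)}
        values = np.vstack([np.zeros(k * m), np.random.default_rng(1).normal(size=k * m)])
        nm = NormalizedMatrix(values, ["flat", "noisy"], cells)
        icc = lm.gene_memory_icc(nm, self._table_for(cells, lineage_of))
        assert icc["flat"] == 0.0

    def test_too_few_lineages_rejected(self):
        cells = [f"c{i}" for i in range(8)]
        lineage_of = {c: f"L{i // 2}" for i, c in enumerate(cells)}
        nm = NormalizedMatrix(np.ones((2, 8)), ["g0", "g1"], cells)
        with pytest.raises(ValueError, match=">= 10 lineages"):
            lm.gene_memory_icc(nm, self._table_for(cells, lineage_of))
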