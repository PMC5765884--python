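"""Modal stress, contingency analysis, d'/c, regressions, reliability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stresscue.errors import EvaluationError
from stresscue.evaluation import (
    ContingencyTable,
    agreement_rates,
    condition_proportions,
    contingency,
    cue_logistic,
    dprime_criterion,
    item_reliability,
    modal_stress,
)

RC00 = ContingencyTable(54, 36, 7, 23)
CDPPP = ContingencyTable(79, 11, 14, 16)
SMA09 = ContingencyTable(58, 32, 14, 16)
BAYES = ContingencyTable(66, 24, 17, 13)


class TestModalStress:
    def test_majority(self):
        df = pd.DataFrame({"item": ["a"] * 20,
                           "stressed": [1] * 15 + [2] * 5})
        out = modal_stress(df)
        assert out.loc["a", "modal"] == 1 and not out.loc["a", "tie"]

    def test_tie_goes_to_first(self):
        df = pd.DataFrame({"item": ["a"] * 20,
                           "stressed": [1] * 10 + [2] * 10})
        out = modal_stress(df)
        assert out.loc["a", "modal"] == 1 and out.loc["a", "tie"]

    def test_discards_excluded_and_missing_item_errors(self):
        df = pd.DataFrame(
            {"item": ["a", "a", "b"], "stressed": [2.0, 2.0, np.nan],
             "discarded": [False, False, True]}
        )
        with pytest.raises(EvaluationError):
            modal_stress(df)

    def test_matches_per_item_counting(self, rng=np.random.default_rng(4)):
        items = [f"it{i}" for i in range(30)]
        rows = [
            {"item": it, "stressed": int(rng.integers(1, 3))}
            for it in items for _ in range(21)
        ]
        df = pd.DataFrame(rows)
        out = modal_stress(df)
        for it in items:
            counts = df[df["item"] == it]["stressed"].value_counts()
            expected = 2 if counts.get(2, 0) > counts.get(1, 0) else 1
            assert out.loc[it, "modal"] == expected


class TestContingency:
    def test_cross_tab_counts(self):
        preds = {"a": 1, "b": 2, "c": 2, "d": 1}
        human = {"a": 1, "b": 1, "c": 2, "d": 2}
        t = contingency(preds, human)
        assert t.as_tuple() == (1, 1, 1, 1)

    def test_perfect_agreement_off_diagonal_zero(self):
        preds = {"a": 1, "b": 2}
        t = contingency(preds, preds)
        assert t.n_first_second == 0 and t.n_second_first == 0

    def test_item_mismatch_errors(self):
        with pytest.raises(EvaluationError):
            contingency({"a": 1}, {"b": 1})


class TestSignalDetection:
    @pytest.mark.parametrize(
        "table, d_exp, c_exp",
        [(RC00, 0.98, 0.24), (CDPPP, 1.25, -0.54), (SMA09, 0.45, -0.14)],
    )
    def test_reference_tables(self, table, d_exp, c_exp):
        res = dprime_criterion(table)
        assert round(res.d_prime, 2) == d_exp
        assert round(res.criterion, 2) == c_exp

    def test_equal_rates_give_zero_sensitivity(self):
        res = dprime_criterion(ContingencyTable(30, 30, 10, 10))
        assert res.d_prime == pytest.approx(0.0)

    def test_row_swap_negates_dprime(self):
        for t in (RC00, CDPPP, SMA09, BAYES):
            a = dprime_criterion(t)
            b = dprime_criterion(t.swapped_rows())
            assert a.d_prime == pytest.approx(-b.d_prime)

    def test_extreme_rates_corrected(self):
        # an all-or-none classifier: hit rate 1 corrected to 1 - 1/(2N)
        t = ContingencyTable(40, 0, 10, 0)
        res = dprime_criterion(t)
        assert res.hit_rate == 1 - 1 / 80
        assert np.isfinite(res.d_prime)

    def test_empty_row_errors(self):
        with pytest.raises(EvaluationError):
            dprime_criterion(ContingencyTable(10, 5, 0, 0))


class TestAgreement:
    @pytest.mark.parametrize(
        "table, p1, p2",
        [(RC00, 60, 77), (CDPPP, 88, 53), (SMA09, 64, 53), (BAYES, 73, 43)],
    )
    def test_reference_percentages(self, table, p1, p2):
        a1, a2, _ = agreement_rates(table)
        assert round(a1) == p1 and round(a2) == p2

    def test_mean_agreements(self):
        assert round(agreement_rates(CDPPP)[2]) == 71
        assert round(agreement_rates(SMA09)[2]) == 59

    def test_identity_table(self):
        assert agreement_rates(ContingencyTable(50, 0, 0, 50)) == (100, 100, 100)


class TestConditionProportions:
    def test_per_cell_means(self):
        df = pd.DataFrame(
            {"cell": ["a"] * 4 + ["b"] * 4, "stressed": [2, 2, 1, 1, 1, 1, 1, 2]}
        )
        out = condition_proportions(df, "cell").set_index("cell")
        assert out.loc["a", "p_second"] == 0.5
        assert out.loc["b", "p_second"] == 0.25

    def test_all_first_stress(self):
        df = pd.DataFrame({"cell": ["a", "b"], "stressed": [1, 1]})
        out = condition_proportions(df, "cell")
        assert (out["p_second"] == 0).all()

    def test_empty_cell_flagged(self):
        df = pd.DataFrame({"cell": ["a"], "stressed": [2]})
        out = condition_proportions(df, "cell", expected_cells=["a", "b"])
        row = out[out["cell"] == "b"].iloc[0]
        assert row["empty"] and np.isnan(row["p_second"])


class TestCueLogistic:
    def test_separation_flagged(self):
        # a prefix that perfectly determines the outcome (rule-model style)
        X = pd.DataFrame({"prefix": [0] * 40 + [1] * 40,
                          "weight": [0, 1] * 40})
        y = np.array([1] * 40 + [2] * 40)
        res = cue_logistic(y, X)
        assert res.separation["prefix"]
        assert not res.separation["weight"]
        assert not res.converged

    def test_known_coefficients_recovered(self):
        rng = np.random.default_rng(0)
        n = 4000
        x1 = rng.integers(0, 2, n)
        x2 = rng.integers(0, 2, n)
        eta = -1.0 + 1.2 * x1 + 0.6 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int) + 1
        res = cue_logistic(y, pd.DataFrame({"x1": x1, "x2": x2}))
        assert res.converged
        assert res.table.loc["x1", "coef"] == pytest.approx(1.2, abs=0.25)
        assert res.table.loc["x2", "coef"] == pytest.approx(0.6, abs=0.25)

    def test_constant_outcome_errors(self):
        X = pd.DataFrame({"x": [0, 1, 0, 1]})
        with pytest.raises(EvaluationError):
            cue_logistic([1, 1, 1, 1], X)

    def test_rank_deficiency_names_columns(self):
        X = pd.DataFrame({"x1": [0, 1, 0, 1, 0, 1], "x2": [0, 2, 0, 2, 0, 2]})
        with pytest.raises(EvaluationError, match="collinear"):
            cue_logistic([1, 2, 1, 2, 2, 1], X)


class TestItemReliability:
    def test_identical_vectors(self):
        a = pd.Series([0.1, 0.4, 0.9, 0.2], index=list("abcd"))
        r, p = item_reliability(a, a)
        assert r == pytest.approx(1.0)

    def test_too_few_shared_items(self):
        a = pd.Series([0.1, 0.2], index=["a", "b"])
        with pytest.raises(EvaluationError):
            item_reliability(a, a)

    def test_matches_direct_pearson(self):
        rng = np.random.default_rng(1)
        idx = [f"i{k}" for k in range(40)]
        a = pd.Series(rng.random(40), index=idx)
        b = pd.Series(0.5 * a.to_numpy() + 0.5 * rng.random(40), index=idx)
        r, p = item_reliability(a, b)
        r_direct, p_direct = stats.pearsonr(a, b)
        assert r == pytest.approx(float(r_direct))
        assert p == pytest.approx(float(p_direct))
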