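"""Diagnostic metrics, group tests, power machinery."""

import math

import numpy as np
import pandas as pd
import pytest

from ceuskit import (
    DiagnosticCounts,
    NormalEffectSpec,
    chi_square_test,
    closed_form_power,
    compare_groups,
    diagnostic_metrics,
    paired_t_test,
    power_simulation,
    welch_t_test,
)
from ceuskit.errors import InvalidInputError, UndefinedMetricError
from ceuskit.stats import holm_adjust


class TestDiagnosticMetrics:
    def test_worked_confusion_matrix(self):
        m = diagnostic_metrics(DiagnosticCounts(TP=9, FN=1, TN=8, FP=2))
        assert m.sensitivity == pytest.approx(90.0)
        assert m.specificity == pytest.approx(80.0)
        assert m.accuracy == pytest.approx(85.0)
        assert m.PPV == pytest.approx(81.82, abs=0.005)
        assert m.NPV == pytest.approx(88.89, abs=0.005)

    def test_perfect_classifier(self):
        m = diagnostic_metrics(DiagnosticCounts(TP=10, FN=0, TN=10, FP=0))
        assert m.rounded() == {
            "sensitivity": 100.0, "specificity": 100.0, "accuracy": 100.0,
            "PPV": 100.0, "NPV": 100.0,
        }

    def test_coin_flip_symmetry(self):
        m = diagnostic_metrics(DiagnosticCounts(TP=5, FN=5, TN=7, FP=7))
        assert m.sensitivity == m.specificity == m.accuracy == 50.0

    def test_rate_complements_sum_to_one_exactly(self):
        from fractions import Fraction

        c = DiagnosticCounts(TP=13, FN=7, TN=11, FP=3)
        m = diagnostic_metrics(c)
        assert m.exact["sensitivity"] + Fraction(100 * c.FN, c.TP + c.FN) == 100
        assert m.exact["specificity"] + Fraction(100 * c.FP, c.TN + c.FP) == 100

    def test_zero_denominator_names_the_metric(self):
        with pytest.raises(UndefinedMetricError, match="sensitivity"):
            diagnostic_metrics(DiagnosticCounts(TP=0, FN=0, TN=5, FP=5))


class TestWelch:
    def test_identical_samples(self):
        res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_shift(self):
        a = [1.0, 2.0, 3.0]
        b = [11.0, 12.0, 13.0]
        res = welch_t_test(a, b)
        # equal variances 1, n=3: t = -10 / sqrt(2/3), df = 4
        assert res.statistic == pytest.approx(-10.0 / math.sqrt(2.0 / 3.0))
        assert res.df == pytest.approx(4.0)
        assert res.direction == -1

    def test_undersized_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_null_rejection_rate_small_sim(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            if welch_t_test(rng.normal(size=30), rng.normal(size=30)).p_value < 0.05:
                rejections += 1
        assert 0.035 < rejections / reps < 0.065


class TestPaired:
    def test_identical_pairs_degenerate_p_one(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_constant_nonzero_differences_flagged_infinite(self):
        res = paired_t_test([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])
        assert res.degenerate
        assert math.isinf(res.statistic)
        assert res.p_value == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            paired_t_test([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_null_p_values_uniform(self):
        """Paired p-values on exchangeable pairs follow the uniform law."""
        from scipy import stats as sps

        rng = np.random.default_rng(7)
        pvals = [
            paired_t_test(rng.normal(size=20), rng.normal(size=20)).p_value
            for _ in range(2000)
        ]
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestChiSquare:
    def test_balanced_table_is_null(self):
        res = chi_square_test([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_table(self):
        from scipy import stats as sps

        res = chi_square_test([[20, 10], [10, 20]])
        # n*(ad-bc)^2 / (r1*r2*c1*c2) = 60*300^2 / 30^4
        expected = 60 * 300.0**2 / 30.0**4
        assert res.statistic == pytest.approx(expected)
        assert res.p_value == pytest.approx(float(sps.chi2.sf(expected, 1)))

    def test_matches_scipy_without_correction(self):
        from scipy import stats as sps

        table = [[13, 7], [6, 14]]
        res = chi_square_test(table)
        ref = sps.chi2_contingency(np.asarray(table), correction=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_zero_marginal_rejected(self):
        with pytest.raises(InvalidInputError):
            chi_square_test([[0, 0], [5, 5]])


class TestCompareGroups:
    def table(self, rng, shift=0.0, n=12):
        return pd.DataFrame({
            "group": ["a"] * n + ["b"] * n,
            "TTP": np.concatenate([rng.normal(size=n), rng.normal(shift, 1, n)]),
        })

    def test_identical_groups_nonsignificant(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=12)
        tab = pd.DataFrame({
            "group": ["a"] * 12 + ["b"] * 12,
            "TTP": np.concatenate([values, values]),
        })
        (res,) = compare_groups(tab, "TTP")
        assert res.p_value == pytest.approx(1.0)

    def test_three_groups_give_three_pairs(self):
        rng = np.random.default_rng(6)
        tab = pd.DataFrame({
            "group": ["A"] * 5 + ["B"] * 5 + ["C"] * 5,
            "I_max": rng.normal(size=15),
        })
        assert len(compare_groups(tab, "I_max")) == 3

    def test_missing_values_dropped(self):
        rng = np.random.default_rng(8)
        tab = self.table(rng, shift=3.0)
        tab.loc[0, "TTP"] = np.nan
        (res,) = compare_groups(tab, "TTP")
        assert res.n1 == 11 and res.n2 == 12

    def test_unknown_parameter_rejected(self):
        with pytest.raises(InvalidInputError):
            compare_groups(pd.DataFrame({"group": []}), "TTP")


class TestPower:
    def test_holm_is_monotone_and_bounded(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert all(0 <= p <= 1 for p in adj)
        assert adj[0] == pytest.approx(0.03)

    def test_closed_form_matches_published_value(self):
        # classic benchmark: d=0.5, n=64/group gives ~80% power
        assert closed_form_power(0.5, 1.0, 64) == pytest.approx(0.80, abs=0.01)

    def test_normal_effect_simulation_tracks_closed_form(self):
        spec = NormalEffectSpec(delta=0.8, sd=1.0, n_per_group=25)
        result = power_simulation(spec, n_reps=400, alpha=0.05, seed=3)
        target = closed_form_power(0.8, 1.0, 25)
        assert abs(result["delta"]["power"] - target) < 3 * result["delta"]["mc_se"]

    def test_power_monotone_in_group_size(self):
        powers = []
        for n in (10, 20, 40):
            spec = NormalEffectSpec(delta=1.0, sd=1.0, n_per_group=n)
            powers.append(power_simulation(spec, n_reps=300, seed=9)["delta"]["power"])
        assert powers[0] <= powers[1] <= powers[2]

    def test_too_few_reps_rejected(self):
        with pytest.raises(InvalidInputError):
            power_simulation(NormalEffectSpec(delta=1.0), n_reps=50)
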