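"""Univariate test selection, contingency tests and logistic regression."""

import numpy as np
import pytest

from eppm import (
    compare_categorical,
    compare_continuous,
    default_config,
    fit_multivariate,
    generate_cohort,
    normality_gate,
    screen_cohort,
    select_predictors,
)
from eppm.screening import (
    DegenerateTableError,
    InsufficientDataError,
    LogisticResult,
    SeparationError,
    UnivariateResult,
    ordinal_design,
)
from eppm.simulate import generate_null_cohort


def pearson_chi2(table):
    """From-scratch Pearson statistic oracle."""
    t = np.asarray(table, dtype=float)
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    expected = row @ col / t.sum()
    return float(((t - expected) ** 2 / expected).sum())


class TestNormalityGate:
    def test_normal_samples_pass(self):
        rng = np.random.default_rng(41)
        assert normality_gate(rng.normal(0, 1, 100), rng.normal(5, 2, 100)) is True

    def test_heavy_tailed_group_fails(self):
        rng = np.random.default_rng(43)
        assert normality_gate(rng.normal(0, 1, 200), rng.standard_cauchy(200)) is False

    def test_constant_group_is_degenerate(self):
        rng = np.random.default_rng(45)
        assert normality_gate([3.0, 3.0, 3.0, 3.0], rng.normal(0, 1, 50)) is False

    def test_tiny_group_raises(self):
        with pytest.raises(InsufficientDataError):
            normality_gate([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_false_rejection_rate_near_alpha(self):
        """Gate rejects normal data at roughly the combined two-test rate."""
        rng = np.random.default_rng(47)
        fails = sum(
            not normality_gate(rng.normal(0, 1, 40), rng.normal(0, 1, 40))
            for _ in range(400)
        )
        # two independent tests at alpha=0.05 -> ~9.75% combined; +-3 MC SE
        rate = fails / 400
        assert abs(rate - 0.0975) < 3 * np.sqrt(0.0975 * 0.9025 / 400)


class TestCompareContinuous:
    def test_normal_data_uses_t_test(self):
        rng = np.random.default_rng(49)
        res = compare_continuous(rng.normal(14.2, 5.7, 78), rng.normal(12.0, 3.8, 90))
        assert res.test_used == "t_test"
        assert res.group_summaries["poor"]["n"] == 78

    def test_skewed_data_uses_mann_whitney(self):
        rng = np.random.default_rng(51)
        res = compare_continuous(rng.lognormal(1, 1, 100), rng.lognormal(1.2, 1, 100))
        assert res.test_used == "mann_whitney"

    def test_identical_groups_not_significant(self):
        vals = list(np.linspace(10, 20, 30))
        res = compare_continuous(vals, vals)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert not res.selected

    def test_printed_crp_effect_detected_most_of_the_time(self):
        """At the published effect (14.20±5.73 vs 11.97±3.84, n=78/90) the
        comparison rejects in the large majority of replicates."""
        rng = np.random.default_rng(53)
        hits = sum(
            compare_continuous(rng.normal(14.20, 5.73, 78), rng.normal(11.97, 3.84, 90)).selected
            for _ in range(300)
        )
        assert hits / 300 > 0.7

    def test_null_type_I_error_near_alpha(self):
        rng = np.random.default_rng(55)
        hits = sum(
            compare_continuous(rng.normal(0, 1, 40), rng.normal(0, 1, 40)).selected
            for _ in range(1000)
        )
        rate = hits / 1000
        assert abs(rate - 0.05) < 2 * np.sqrt(0.05 * 0.95 / 1000) + 0.01

    def test_undersized_group_raises(self):
        with pytest.raises(InsufficientDataError):
            compare_continuous([1.0], [1.0, 2.0, 3.0])


class TestCompareCategorical:
    def test_chi_square_matches_hand_formula(self):
        rng = np.random.default_rng(57)
        for _ in range(100):
            tab = rng.integers(5, 60, size=(2, int(rng.integers(2, 5))))
            res = compare_categorical(tab)
            assert res.test_used == "chi_square"
            assert res.statistic == pytest.approx(pearson_chi2(tab), abs=1e-10)

    def test_published_age_counts_are_significant(self):
        """Age counts poor (34, 20, 24) vs good (15, 31, 44) give p < 0.001."""
        res = compare_categorical([[34, 20, 24], [15, 31, 44]])
        assert res.statistic == pytest.approx(pearson_chi2([[34, 20, 24], [15, 31, 44]]), abs=1e-10)
        assert res.p_value < 0.001
        assert res.selected

    def test_identical_rows_give_zero_statistic(self):
        res = compare_categorical([[10, 20], [10, 20]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_small_expected_count_switches_to_fisher(self):
        res = compare_categorical([[2, 30], [3, 25]])
        assert res.test_used == "fisher_exact"

    def test_small_expected_count_in_larger_table_warns(self):
        with pytest.warns(UserWarning, match="expected count"):
            compare_categorical([[1, 30, 20], [2, 25, 22]])

    def test_zero_margin_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            compare_categorical([[0, 10], [0, 20]])

    def test_null_type_I_error_near_alpha(self):
        rng = np.random.default_rng(59)
        p = np.array([0.3, 0.45, 0.25])
        hits = 0
        for _ in range(1000):
            a = rng.multinomial(90, p)
            b = rng.multinomial(90, p)
            if (a + b > 0).all():
                hits += compare_categorical(np.vstack([a, b])).selected
        rate = hits / 1000
        assert abs(rate - 0.05) < 2 * np.sqrt(0.05 * 0.95 / 1000) + 0.01


def _logistic_cohort(rng, n, betas, intercept=-0.5):
    """Synthetic cohort whose poor-outcome log-odds follow a known linear
    model over (apoe carrier, marshall level, damaged-area level)."""
    import dataclasses

    from conftest import random_valid_record
    from eppm.cohort import Cohort

    records = []
    for i in range(n):
        rec = random_valid_record(rng, i)
        x = np.array([
            float(rec.apoe_e4_carrier),
            float(("I", "II", "III", "IV", "V", "VI").index(rec.marshall)),
            float(("parietal", "occipital", "temporal", "frontal").index(rec.damaged_area)),
        ])
        logit = intercept + betas @ x
        outcome = "poor" if rng.random() < 1.0 / (1.0 + np.exp(-logit)) else "good"
        records.append(dataclasses.replace(rec, outcome=outcome))
    return Cohort(records=records)


class TestFitMultivariate:
    CANDIDATES = ("apoe_e4_carrier", "marshall", "damaged_area")
    BETAS = np.array([0.8, 0.45, -0.3])

    def test_single_binary_predictor_equals_cross_product_ratio(self):
        """Closed-form oracle: the univariate binary-logistic OR is the
        contingency-table cross-product ratio."""
        rng = np.random.default_rng(61)
        cohort = _logistic_cohort(rng, 800, np.array([0.9, 0.0, 0.0]))
        res = fit_multivariate(cohort, ["apoe_e4_carrier"])
        tab = np.zeros((2, 2))
        for r in cohort:
            tab[int(r.apoe_e4_carrier), int(r.outcome == "poor")] += 1
        cpr = (tab[1, 1] * tab[0, 0]) / (tab[1, 0] * tab[0, 1])
        assert res[0].odds_ratio == pytest.approx(cpr, rel=1e-6)

    def test_parameter_recovery_at_large_n(self):
        rng = np.random.default_rng(63)
        cohort = _logistic_cohort(rng, 5000, self.BETAS)
        results = {r.predictor: r for r in fit_multivariate(cohort, self.CANDIDATES)}
        for name, beta in zip(self.CANDIDATES, self.BETAS):
            assert results[name].odds_ratio == pytest.approx(np.exp(beta), rel=0.15)
            lo, hi = results[name].ci95
            assert lo <= results[name].odds_ratio <= hi

    def test_null_coefficient_ci_covers_one(self):
        """A predictor with true coefficient 0 has a CI covering OR=1 in
        roughly 95% of replicates."""
        rng = np.random.default_rng(65)
        covered = 0
        reps = 120
        for _ in range(reps):
            cohort = _logistic_cohort(rng, 400, np.array([0.8, 0.4, 0.0]))
            res = {r.predictor: r for r in fit_multivariate(cohort, self.CANDIDATES)}
            lo, hi = res["damaged_area"].ci95
            covered += lo <= 1.0 <= hi
        assert covered / reps > 0.90

    def test_perfect_separation_is_explicit_error(self):
        rng = np.random.default_rng(67)
        cohort = _logistic_cohort(rng, 200, np.array([0.0, 0.0, 0.0]))
        import dataclasses
        from eppm.cohort import Cohort

        records = [
            dataclasses.replace(r, outcome="poor" if r.apoe_e4_carrier else "good")
            for r in cohort
        ]
        with pytest.raises(SeparationError):
            fit_multivariate(Cohort(records=records), ["apoe_e4_carrier"])

    def test_empty_candidates(self, small_cohort):
        assert fit_multivariate(small_cohort, []) == []

    def test_ordinal_design_levels(self, small_cohort):
        design = ordinal_design(small_cohort, ("age", "gcs", "marshall"))
        assert set(design["age"].unique()) <= {0, 1, 2}
        assert set(design["gcs"].unique()) <= {0, 1, 2}
        assert set(design["marshall"].unique()) <= {0, 1, 2, 3, 4, 5}
        assert set(design["poor"].unique()) <= {0, 1}


class TestSelectPredictors:
    def _uni(self, name, p):
        return UnivariateResult(name, "chi_square", 1.0, p, {})

    def _multi(self, name, p, orr=2.0):
        return LogisticResult(name, "ordinal", np.log(orr), orr, (orr / 2, orr * 2), p)

    def test_retains_jointly_significant(self):
        uni = [self._uni(n, 0.01) for n in ("gcs", "marshall", "crp")]
        multi = [self._multi("gcs", 0.001), self._multi("marshall", 0.02), self._multi("crp", 0.20)]
        assert select_predictors(uni, multi) == ["gcs", "marshall"]

    def test_empty(self):
        assert select_predictors([], []) == []


class TestScreenCohort:
    def test_strongest_effects_selected_on_default_cohorts(self):
        """GCS and the Marshall class — the strongest published effects —
        survive the full screen on most default-parameter cohorts."""
        hits = 0
        for seed in range(20):
            cohort = generate_cohort(default_config(n=168, seed=100 + seed))
            selected = set(screen_cohort(cohort)["selected"])
            hits += {"gcs", "marshall"} <= selected
        assert hits >= 18  # >= 90% of seeds

    def test_null_cohort_selects_little(self):
        """With all signal removed, the univariate screen rejects at ~alpha."""
        flags = []
        for seed in range(25):
            cohort = generate_null_cohort(default_config(n=300, seed=200 + seed))
            res = screen_cohort(cohort)
            flags.extend(r.selected for r in res["univariate"])
        rate = np.mean(flags)
        assert rate < 0.12  # ~0.05 expected; generous MC slack at 25 replicates

    def test_unlabelled_cohort_is_error(self, small_cohort):
        import dataclasses
        from eppm.cohort import Cohort

        records = [dataclasses.replace(r, outcome=None) for r in small_cohort]
        with pytest.raises(ValueError):
            screen_cohort(Cohort(records=records))
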