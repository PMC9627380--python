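"""Predictor screening: univariate tests then multivariate logistic regression.

The screening pipeline mirrors common clinical-study practice. Continuous
variables are compared between poor- and good-prognosis groups with a
Student's t-test when a Shapiro–Wilk gate finds both groups consistent with
normality (Welch's form when a Levene test rejects equal variances), and
with the Mann–Whitney U test otherwise. Categorical variables use the
Pearson chi-square test without continuity correction, replaced by Fisher's
exact test when a 2×2 table has an expected count below 5. Variables that
pass the univariate screen at alpha are then entered jointly into a
maximum-likelihood logistic regression of poor outcome; predictors with a
Wald p-value below alpha are retained as independent risk factors.

Multi-level predictors are coded ordinally (equally spaced integer levels
in increasing severity order), so each reported odds ratio is per one-level
increase in severity. No multiple-testing correction is applied across the
univariate screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, MARSHALL_CLASSES

__all__ = [
    "UnivariateResult",
    "LogisticResult",
    "InsufficientDataError",
    "DegenerateTableError",
    "SeparationError",
    "ConvergenceError",
    "normality_gate",
    "compare_continuous",
    "compare_categorical",
    "fit_multivariate",
    "select_predictors",
    "screen_cohort",
    "ordinal_design",
    "ORDINAL_CODINGS",
    "DEFAULT_ALPHA",
]

DEFAULT_ALPHA = 0.05
DEFAULT_ALPHA_NORM = 0.05


class InsufficientDataError(ValueError):
    """A group is too small for the requested test."""


class DegenerateTableError(ValueError):
    """A contingency table has a zero row or column margin."""


class SeparationError(RuntimeError):
    """The logistic likelihood has no finite maximizer (perfect separation)."""


class ConvergenceError(RuntimeError):
    """The logistic fit did not converge."""

    def __init__(self, message: str, diagnostics: Mapping | None = None):
        super().__init__(message)
        self.diagnostics = dict(diagnostics or {})


@dataclass
class UnivariateResult:
    """One predictor's univariate comparison between outcome groups."""

    predictor: str
    test_used: str  # t_test | mann_whitney | chi_square | fisher_exact
    statistic: float
    p_value: float
    group_summaries: dict
    alpha: float = DEFAULT_ALPHA

    @property
    def selected(self) -> bool:
        return self.p_value < self.alpha


@dataclass
class LogisticResult:
    """One predictor's multivariate logistic-regression estimate.

    ``odds_ratio`` is ``exp(coefficient)``; for ordinal predictors it is the
    multiplicative change in odds of poor outcome per one severity level.
    """

    predictor: str
    coding: str  # binary | ordinal | continuous
    coefficient: float
    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float

    def __post_init__(self) -> None:
        assert self.ci95[0] <= self.odds_ratio <= self.ci95[1]


# ---------------------------------------------------------------------------
# univariate tests

def normality_gate(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alpha_norm: float = DEFAULT_ALPHA_NORM,
) -> bool:
    """True iff both groups pass the Shapiro–Wilk normality test at alpha_norm.

    A zero-variance (constant) group is non-normal by convention. Groups
    smaller than 3 cannot be tested and raise
    :class:`InsufficientDataError`.
    """
    out = True
    for g in (group_a, group_b):
        arr = np.asarray(g, dtype=float)
        if arr.size < 3:
            raise InsufficientDataError(f"normality test needs >= 3 values, got {arr.size}")
        if np.ptp(arr) == 0.0:
            return False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # scipy warns for n > 5000; p stays usable
            p = stats.shapiro(arr).pvalue
        out = out and bool(p >= alpha_norm)
    return out


def compare_continuous(
    group_poor: Sequence[float],
    group_good: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
    predictor: str = "",
    alpha_norm: float = DEFAULT_ALPHA_NORM,
) -> UnivariateResult:
    """Two-sided comparison of a continuous variable between outcome groups.

    Uses the t-test when the normality gate passes (Welch's version when
    Levene's test rejects variance homogeneity at ``alpha_norm``), otherwise
    the Mann–Whitney U test.
    """
    a = np.asarray(group_poor, dtype=float)
    b = np.asarray(group_good, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    summaries = {
        "poor": {"n": int(a.size), "mean": float(a.mean()), "sd": float(a.std(ddof=1))},
        "good": {"n": int(b.size), "mean": float(b.mean()), "sd": float(b.std(ddof=1))},
    }
    if a.size >= 3 and b.size >= 3 and normality_gate(a, b, alpha_norm):
        equal_var = stats.levene(a, b).pvalue >= alpha_norm
        if np.ptp(np.concatenate([a, b])) == 0.0:
            stat, p = 0.0, 1.0
        else:
            res = stats.ttest_ind(a, b, equal_var=equal_var)
            stat, p = float(res.statistic), float(res.pvalue)
        test = "t_test"
    else:
        if np.ptp(np.concatenate([a, b])) == 0.0:
            stat, p = float(a.size * b.size / 2.0), 1.0
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        test = "mann_whitney"
    return UnivariateResult(
        predictor=predictor,
        test_used=test,
        statistic=stat,
        p_value=p,
        group_summaries=summaries,
        alpha=alpha,
    )


def compare_categorical(
    table,
    alpha: float = DEFAULT_ALPHA,
    predictor: str = "",
) -> UnivariateResult:
    """Outcome × category contingency-table test.

    Pearson chi-square without continuity correction, unless any expected
    count is below 5: then Fisher's exact test for 2×2 tables, or the
    chi-square with a warning for larger tables.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError(f"need at least a 2x2 table, got shape {tab.shape}")
    if (tab < 0).any():
        raise ValueError("counts must be non-negative")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero row or column margin")
    expected = stats.contingency.expected_freq(tab)
    summaries = {"counts": tab.astype(int).tolist()}
    if (expected < 5).any() and tab.shape == (2, 2):
        stat, p = stats.fisher_exact(tab.astype(int), alternative="two-sided")
        test = "fisher_exact"
        stat = float(stat)
    else:
        if (expected < 5).any():
            warnings.warn(
                f"{predictor or 'table'}: expected count < 5 in a table larger than 2x2; "
                "chi-square approximation may be poor",
                stacklevel=2,
            )
        chi2 = stats.chi2_contingency(tab, correction=False)
        stat, p = float(chi2.statistic), float(chi2.pvalue)
        test = "chi_square"
    return UnivariateResult(
        predictor=predictor,
        test_used=test,
        statistic=stat,
        p_value=float(p),
        group_summaries=summaries,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# multivariate logistic regression

#: severity-ordered level codings for the EPPM predictors (0 = least severe)
ORDINAL_CODINGS: dict[str, dict] = {
    "age": {"kind": "ordinal", "levels": ("le45", "46-59", "ge60")},
    "gcs": {"kind": "ordinal", "levels": ("13-15", "9-12", "le8")},
    # severity order fixed by observed poor-prognosis rates:
    # parietal < occipital < temporal < frontal
    "damaged_area": {"kind": "ordinal", "levels": ("parietal", "occipital", "temporal", "frontal")},
    "crp": {"kind": "ordinal", "levels": ("lt10", "10-15", "ge15")},
    "il8": {"kind": "ordinal", "levels": ("lt10", "10-20", "ge20")},
    "marshall": {"kind": "ordinal", "levels": MARSHALL_CLASSES},
    "apoe_e4_carrier": {"kind": "binary", "levels": ("no", "yes")},
    "sex": {"kind": "binary", "levels": ("female", "male")},
}


def _ordinal_level(record, predictor: str) -> int:
    if predictor == "age":
        return 0 if record.age <= 45 else (1 if record.age <= 59 else 2)
    if predictor == "gcs":
        return 2 if record.gcs <= 8 else (1 if record.gcs <= 12 else 0)
    if predictor == "crp":
        return 0 if record.crp < 10 else (1 if record.crp < 15 else 2)
    if predictor == "il8":
        return 0 if record.il8 < 10 else (1 if record.il8 < 20 else 2)
    if predictor == "marshall":
        return MARSHALL_CLASSES.index(record.marshall)
    if predictor == "damaged_area":
        return ORDINAL_CODINGS["damaged_area"]["levels"].index(record.damaged_area)
    if predictor == "apoe_e4_carrier":
        return int(record.apoe_e4_carrier)
    if predictor == "sex":
        return int(record.sex == "male")
    raise ValueError(f"no ordinal coding for predictor {predictor!r}")


def ordinal_design(cohort: Cohort, candidates: Sequence[str]) -> pd.DataFrame:
    """Severity-coded design matrix (one integer column per candidate) plus
    the binary response column ``poor``."""
    rows = []
    for rec in cohort:
        if rec.outcome is None:
            raise ValueError(f"record {rec.patient_id} lacks an outcome label")
        row = {name: _ordinal_level(rec, name) for name in candidates}
        row["poor"] = int(rec.outcome == "poor")
        rows.append(row)
    return pd.DataFrame(rows)


def fit_multivariate(
    cohort: Cohort,
    candidates: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
) -> list[LogisticResult]:
    """Joint maximum-likelihood logistic regression of poor outcome on all
    candidates, with Wald odds ratios, 95% CIs and p-values.

    Raises :class:`SeparationError` on (quasi-)perfect separation and
    :class:`ConvergenceError` when the optimizer does not converge.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

    if not candidates:
        return []
    design = ordinal_design(cohort, candidates)
    y = design["poor"].to_numpy()
    X = sm.add_constant(design[list(candidates)].astype(float), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(f"perfect separation in logistic fit: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise ConvergenceError(
            "logistic fit did not converge",
            diagnostics={k: fit.mle_retvals.get(k) for k in ("iterations", "converged")},
        )
    if not np.all(np.isfinite(fit.bse)):
        raise SeparationError("non-finite standard errors; data are (quasi-)separated")
    conf = fit.conf_int(alpha=0.05)
    results = []
    for name in candidates:
        coding = ORDINAL_CODINGS.get(name, {}).get("kind", "continuous")
        lo, hi = float(conf.loc[name, 0]), float(conf.loc[name, 1])
        results.append(
            LogisticResult(
                predictor=name,
                coding=coding,
                coefficient=float(fit.params[name]),
                odds_ratio=float(np.exp(fit.params[name])),
                ci95=(float(np.exp(lo)), float(np.exp(hi))),
                p_value=float(fit.pvalues[name]),
            )
        )
    return results


def select_predictors(
    univariate: Sequence[UnivariateResult],
    multivariate: Sequence[LogisticResult],
    alpha: float = DEFAULT_ALPHA,
) -> list[str]:
    """Candidates significant in both screens, in multivariate order."""
    uni_selected = {r.predictor for r in univariate if r.p_value < alpha}
    return [r.predictor for r in multivariate if r.p_value < alpha and r.predictor in uni_selected]


# ---------------------------------------------------------------------------
# cohort-level pipeline

#: default candidate pools for a full screen
CATEGORICAL_CANDIDATES = (
    "sex",
    "mechanism",
    "age",
    "damaged_area",
    "gcs",
    "apoe_e4_carrier",
    "marshall",
    "smoking",
    "alcohol",
    "hypertension",
    "diabetes",
)
CONTINUOUS_CANDIDATES = ("crp", "il8")  # extra serum analytes are added per cohort


def _categorical_table(cohort: Cohort, predictor: str) -> np.ndarray:
    """2 × k counts (rows: poor, good) for a categorical/binned predictor."""
    if predictor in ORDINAL_CODINGS:
        k = len(ORDINAL_CODINGS[predictor]["levels"])
        levels = [_ordinal_level(r, predictor) for r in cohort]
    elif predictor == "mechanism":
        from .cohort import MECHANISMS

        k = len(MECHANISMS)
        levels = [MECHANISMS.index(r.mechanism) for r in cohort]
    elif predictor in ("smoking", "alcohol", "hypertension", "diabetes"):
        k = 2
        levels = [int(bool(r.comorbidities.get(predictor, False))) for r in cohort]
    else:
        raise ValueError(f"no categorical coding for predictor {predictor!r}")
    tab = np.zeros((2, k))
    for rec, lev in zip(cohort, levels):
        tab[0 if rec.outcome == "poor" else 1, lev] += 1
    return tab[:, tab.sum(axis=0) > 0]  # drop empty categories


def screen_cohort(cohort: Cohort, alpha: float = DEFAULT_ALPHA) -> dict:
    """Run the full screening pipeline on a labelled cohort.

    Univariate tests over the default candidate pools (plus any serum
    analytes present in ``extra_labs``), then a joint logistic model over
    the univariate-selected EPPM-codable candidates.
    """
    poor = [r for r in cohort if r.outcome == "poor"]
    good = [r for r in cohort if r.outcome == "good"]
    if not poor or not good:
        raise ValueError("screening needs both outcome groups present")

    univariate: list[UnivariateResult] = []
    for name in CATEGORICAL_CANDIDATES:
        tab = _categorical_table(cohort, name)
        if tab.shape[1] < 2:
            continue  # predictor constant in this cohort
        univariate.append(compare_categorical(tab, alpha=alpha, predictor=name))
    analytes = sorted({k for r in cohort for k in r.extra_labs})
    for name in CONTINUOUS_CANDIDATES:
        univariate.append(
            compare_continuous(
                [getattr(r, name) for r in poor],
                [getattr(r, name) for r in good],
                alpha=alpha,
                predictor=name,
            )
        )
    for name in analytes:
        a = [r.extra_labs[name] for r in poor if name in r.extra_labs]
        b = [r.extra_labs[name] for r in good if name in r.extra_labs]
        if len(a) >= 3 and len(b) >= 3:
            univariate.append(compare_continuous(a, b, alpha=alpha, predictor=name))

    codable = [r.predictor for r in univariate if r.predictor in ORDINAL_CODINGS]
    candidates = [p for p in codable if next(r for r in univariate if r.predictor == p).p_value < alpha]
    multivariate = fit_multivariate(cohort, candidates, alpha=alpha)
    selected = select_predictors(univariate, multivariate, alpha=alpha)
    return {
        "alpha": alpha,
        "univariate": univariate,
        "multivariate": multivariate,
        "selected": selected,
    }
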