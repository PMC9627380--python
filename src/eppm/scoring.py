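"""The EPPM scoring system.

The early-prognosis prediction model (EPPM) is a point score over seven
predictors available at TBI admission: age, dominant damaged lobe, GCS,
APOE ε4 carrier status, serum CRP, serum IL-8, and the Marshall CT class.
Each predictor value falls into a severity bin carrying an integer number of
points; a patient's score is the sum over predictors, and prognosis is
classified poor when the total exceeds a decision threshold (default 23.5,
i.e. poor iff total ≥ 24 for integer scores).

Grading rules are data, not code: the published scheme ships as a YAML file
(``eppm/data/default_rules.yaml``) and alternative point schemes can be
loaded with :func:`load_rules`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

from .cohort import PatientRecord

__all__ = [
    "GradingRules",
    "ScoreBreakdown",
    "Threshold",
    "DEFAULT_THRESHOLD",
    "PREDICTORS",
    "load_rules",
    "default_rules",
    "grade_predictor",
    "score_patient",
    "classify",
]

#: the seven EPPM predictors, in grading-rule order
PREDICTORS = (
    "age",
    "damaged_area",
    "gcs",
    "apoe_e4_carrier",
    "crp",
    "il8",
    "marshall",
)

DEFAULT_THRESHOLD = 23.5


class DomainError(ValueError):
    """A predictor value lies outside the predictor's valid domain."""


@dataclass(frozen=True)
class NumericRule:
    """Left-closed severity bins over a numeric domain.

    ``uppers`` are the ascending bin edges; bin *i* covers
    ``[uppers[i-1], uppers[i])`` (with the domain minimum below the first
    edge and +inf above the last), so an abutting edge belongs to the
    higher bin.
    """

    domain: tuple[float, float]
    uppers: tuple[float, ...]  # len = number of bins - 1
    points: tuple[int, ...]

    def grade(self, value: float) -> int:
        lo, hi = self.domain
        if not (isinstance(value, (int, float)) and math.isfinite(float(value))):
            raise DomainError(f"value {value!r} is not a finite number")
        if not (lo <= float(value) <= hi):
            raise DomainError(f"value {value} outside domain [{lo}, {hi}]")
        for upper, pts in zip(self.uppers, self.points):
            if float(value) < upper:
                return pts
        return self.points[-1]


@dataclass(frozen=True)
class CategoricalRule:
    """Direct level → points mapping."""

    levels: Mapping[str, int]

    def grade(self, value) -> int:
        if isinstance(value, bool):
            value = "yes" if value else "no"
        key = str(value)
        if key not in self.levels:
            raise DomainError(f"value {value!r} not among levels {tuple(self.levels)}")
        return self.levels[key]


@dataclass
class GradingRules:
    """Per-predictor bin → points mapping of the EPPM.

    All point values are non-negative integers and each predictor's bins are
    exhaustive and non-overlapping over its valid domain, so every valid
    patient receives exactly one number of points per predictor.
    """

    rules: dict[str, NumericRule | CategoricalRule] = field(default_factory=dict)

    @property
    def predictors(self) -> tuple[str, ...]:
        return tuple(self.rules)

    def min_total(self, predictors: Sequence[str] | None = None) -> int:
        """Minimum achievable total over ``predictors`` (default: all)."""
        return sum(min(self._points(p)) for p in (predictors or self.predictors))

    def max_total(self, predictors: Sequence[str] | None = None) -> int:
        return sum(max(self._points(p)) for p in (predictors or self.predictors))

    def _points(self, predictor: str) -> tuple[int, ...]:
        rule = self.rules[predictor]
        if isinstance(rule, NumericRule):
            return rule.points
        return tuple(rule.levels.values())

    def validate(self) -> None:
        for name, rule in self.rules.items():
            pts = self._points(name)
            if any((not isinstance(p, int)) or p < 0 for p in pts):
                raise ValueError(f"{name}: point values must be non-negative integers, got {pts}")
            if isinstance(rule, NumericRule):
                if list(rule.uppers) != sorted(rule.uppers):
                    raise ValueError(f"{name}: bin edges must be ascending, got {rule.uppers}")
                if len(rule.points) != len(rule.uppers) + 1:
                    raise ValueError(f"{name}: need one more bin than edges")


def _parse_rules(spec: Mapping) -> GradingRules:
    rules: dict[str, NumericRule | CategoricalRule] = {}
    for name, entry in spec.items():
        kind = entry.get("kind")
        if kind == "numeric":
            bins = entry["bins"]
            uppers = tuple(float(b["upper"]) for b in bins[:-1])
            if "upper" in bins[-1]:
                raise ValueError(f"{name}: last bin must be open above (no 'upper')")
            points = tuple(int(b["points"]) for b in bins)
            lo, hi = entry["domain"]
            rules[name] = NumericRule(domain=(float(lo), float(hi)), uppers=uppers, points=points)
        elif kind == "categorical":
            levels = {str(k): int(v) for k, v in entry["levels"].items()}
            rules[name] = CategoricalRule(levels=levels)
        else:
            raise ValueError(f"{name}: unknown rule kind {kind!r}")
    out = GradingRules(rules=rules)
    out.validate()
    return out


def load_rules(path) -> GradingRules:
    """Load a grading-rules YAML file (see the shipped default for format)."""
    with open(path, "r", encoding="utf-8") as fh:
        return _parse_rules(yaml.safe_load(fh))


def default_rules() -> GradingRules:
    """The published EPPM point scheme."""
    text = resources.files("eppm").joinpath("data/default_rules.yaml").read_text(encoding="utf-8")
    return _parse_rules(yaml.safe_load(text))


@dataclass
class ScoreBreakdown:
    """Per-predictor points and the summed EPPM total for one patient."""

    points: dict[str, int]
    total: int
    predicted_outcome: str | None = None

    def __post_init__(self) -> None:
        assert self.total == sum(self.points.values())


@dataclass(frozen=True)
class Threshold:
    """Decision threshold on the total score; poor iff total > value."""

    value: float = DEFAULT_THRESHOLD

    def validate_for(self, rules: GradingRules, predictors: Sequence[str] | None = None) -> None:
        lo, hi = rules.min_total(predictors), rules.max_total(predictors)
        if not (lo < self.value < hi):
            raise ValueError(
                f"threshold {self.value} not strictly inside achievable totals ({lo}, {hi})"
            )


def grade_predictor(predictor: str, value, rules: GradingRules | None = None) -> int:
    """Points assigned to one predictor value.

    >>> grade_predictor("age", 46)
    5
    >>> grade_predictor("marshall", "III")
    4
    """
    rules = rules if rules is not None else default_rules()
    if predictor not in rules.rules:
        raise ValueError(f"unknown predictor {predictor!r}; known: {rules.predictors}")
    return rules.rules[predictor].grade(value)


def score_patient(
    record: PatientRecord,
    rules: GradingRules | None = None,
    predictors: Iterable[str] | None = None,
) -> ScoreBreakdown:
    """Grade each requested predictor of ``record`` and sum the points.

    ``predictors`` defaults to all seven EPPM predictors. Missing values are
    an error (the model does not impute).
    """
    rules = rules if rules is not None else default_rules()
    names = tuple(predictors) if predictors is not None else rules.predictors
    points: dict[str, int] = {}
    for name in names:
        if name not in rules.rules:
            raise ValueError(f"unknown predictor {name!r}; known: {rules.predictors}")
        if not hasattr(record, name):
            raise ValueError(f"record has no value for predictor {name!r}")
        value = getattr(record, name)
        if value is None:
            raise ValueError(f"missing value for predictor {name!r} (no imputation)")
        points[name] = rules.rules[name].grade(value)
    return ScoreBreakdown(points=points, total=sum(points.values()))


def classify(total: float, threshold: Threshold | float = DEFAULT_THRESHOLD) -> str:
    """Classify a total score: ``"poor"`` iff strictly above the threshold.

    With the default threshold 23.5 and integer totals this means poor iff
    total ≥ 24.
    """
    cut = threshold.value if isinstance(threshold, Threshold) else float(threshold)
    return "poor" if total > cut else "good"
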