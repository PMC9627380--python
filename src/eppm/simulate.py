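"""Synthetic TBI cohort generator.

The study that produced the EPPM deposited no patient-level data, so this
module generates cohorts that reproduce the published outcome-conditional
structure of the training set: for each predictor the category frequencies
conditional on poor/good prognosis, and for each serum analyte the
conditional mean ± SD. Predictors are drawn conditionally independent given
the outcome — the publication prints only per-outcome marginals, so no
correlation structure is recoverable; see docs/methods.md for what that
does and does not let the tests show.

Each record is drawn as: outcome ~ Bernoulli(poor prevalence); each
categorical predictor from its outcome-conditional probability vector, with
a concrete value drawn uniformly inside the sampled bin (age and GCS);
each analyte from the outcome-conditional normal, truncated at 0 by
resampling. Non-informative covariates (sex, injury mechanism,
comorbidities) are drawn outcome-independently at their observed marginal
frequencies so the screening pipeline has true negatives to reject.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    COMORBIDITY_FLAGS,
    DAMAGED_AREAS,
    MARSHALL_CLASSES,
    MECHANISMS,
    Cohort,
    PatientRecord,
)

__all__ = [
    "SyntheticCohortConfig",
    "ConfigError",
    "default_config",
    "generate_cohort",
    "generate_null_cohort",
    "summarize_cohort",
]


class ConfigError(ValueError):
    """Invalid generator configuration; message lists every violation."""


# Published training-set (n=168) outcome-conditional parameters.
# Categorical counts condition on outcome (78 poor / 90 good); continuous
# analytes are mean ± SD per outcome group.
_POOR_N, _GOOD_N = 78, 90

_AGE_LEVELS = ("le45", "46-59", "ge60")
_AGE_RANGES = {"le45": (15, 45), "46-59": (46, 59), "ge60": (60, 75)}
_GCS_LEVELS = ("13-15", "9-12", "le8")
_GCS_RANGES = {"13-15": (13, 15), "9-12": (9, 12), "le8": (3, 8)}

_CATEGORICAL_COUNTS = {
    # level order: least to most severe (matches screening.ORDINAL_CODINGS)
    "age": {"levels": _AGE_LEVELS, "poor": (24, 20, 34), "good": (44, 31, 15)},
    "damaged_area": {
        "levels": ("parietal", "occipital", "temporal", "frontal"),
        "poor": (5, 7, 19, 47),
        "good": (17, 18, 24, 31),
    },
    "gcs": {"levels": _GCS_LEVELS, "poor": (8, 36, 34), "good": (22, 53, 15)},
    "apoe_e4_carrier": {"levels": ("no", "yes"), "poor": (41, 37), "good": (62, 28)},
    "marshall": {"levels": MARSHALL_CLASSES, "poor": (3, 8, 15, 13, 20, 19), "good": (15, 24, 23, 14, 8, 6)},
}

#: analyte -> (poor mean, poor SD, good mean, good SD); units per name
_CONTINUOUS_PARAMS = {
    "crp": (14.20, 5.73, 11.97, 3.84),  # mg/L
    "il8": (23.68, 5.35, 21.59, 4.10),  # pg/mL
    "hemoglobin": (112.00, 27.20, 116.70, 18.51),  # g/L
    "wbc": (11.63, 3.61, 12.05, 3.72),  # 10^9/L
    "albumin": (37.83, 5.81, 35.91, 6.40),  # g/L
    "aptt": (38.11, 6.31, 36.24, 7.26),  # s
    "pt": (18.46, 4.12, 18.91, 5.11),  # s
    "inr": (1.42, 0.31, 1.32, 0.40),
    "pct": (0.62, 0.41, 0.59, 0.36),  # ng/L
    "il6": (7.53, 2.35, 6.97, 1.29),  # pg/mL
    "tb": (5.9, 1.6, 6.7, 1.8),  # umol/L
    "db": (3.5, 1.6, 3.4, 1.3),  # umol/L
    "alt": (30.1, 15.3, 32.4, 18.3),  # U/L
    "ast": (33.2, 16.5, 34.5, 11.2),  # U/L
    "potassium": (3.8, 1.2, 4.0, 1.1),  # mmol/L
    "sodium": (141.0, 13.5, 139.0, 15.2),  # mmol/L
    "calcium": (2.34, 0.36, 2.26, 0.41),  # mmol/L
    "creatinine": (80.12, 17.46, 71.58, 13.05),  # umol/L
    "cholesterol": (4.07, 1.85, 4.28, 2.32),  # mmol/L
}

#: outcome-independent marginal frequencies of the non-informative covariates
_NUISANCE_MARGINALS = {
    "sex": {"levels": ("male", "female"), "p": (91 / 168, 77 / 168)},
    "mechanism": {"levels": MECHANISMS, "p": (38 / 168, 35 / 168, 53 / 168, 42 / 168)},
    "smoking": 75 / 168,
    "alcohol": 89 / 168,
    "hypertension": 78 / 168,
    "diabetes": 70 / 168,
}


def _normalize(counts: Sequence[float]) -> tuple[float, ...]:
    arr = np.asarray(counts, dtype=float)
    return tuple(arr / arr.sum())


@dataclass
class SyntheticCohortConfig:
    """Generator configuration.

    Defaults encode the published training-set structure: poor-outcome
    prevalence 78/168 and the outcome-conditional category frequencies and
    analyte means ± SDs of that cohort. ``poor_prevalence`` may be set to 0
    or 1 to draw a single outcome group (e.g. for calibration checks).
    """

    n: int = 168
    poor_prevalence: float = _POOR_N / (_POOR_N + _GOOD_N)
    categorical_conditionals: dict = field(
        default_factory=lambda: {
            name: {
                "levels": tuple(spec["levels"]),
                "poor": _normalize(spec["poor"]),
                "good": _normalize(spec["good"]),
            }
            for name, spec in _CATEGORICAL_COUNTS.items()
        }
    )
    continuous_conditionals: dict = field(
        default_factory=lambda: {
            name: {"poor": (m1, s1), "good": (m2, s2)}
            for name, (m1, s1, m2, s2) in _CONTINUOUS_PARAMS.items()
        }
    )
    nuisance_marginals: dict = field(default_factory=lambda: dict(_NUISANCE_MARGINALS))
    seed: int = 0

    def violations(self) -> list[str]:
        v: list[str] = []
        if self.n < 1:
            v.append(f"n must be >= 1, got {self.n}")
        if not (0.0 <= self.poor_prevalence <= 1.0):
            v.append(f"poor_prevalence {self.poor_prevalence} outside [0, 1]")
        for name, spec in self.categorical_conditionals.items():
            for grp in ("poor", "good"):
                p = np.asarray(spec[grp], dtype=float)
                if len(p) != len(spec["levels"]):
                    v.append(f"{name}/{grp}: {len(p)} probabilities for {len(spec['levels'])} levels")
                elif abs(p.sum() - 1.0) > 1e-12 or (p < 0).any():
                    v.append(f"{name}/{grp}: probabilities must be non-negative and sum to 1")
        for name, spec in self.continuous_conditionals.items():
            for grp in ("poor", "good"):
                mean, sd = spec[grp]
                if sd <= 0:
                    v.append(f"{name}/{grp}: SD must be positive, got {sd}")
        return v

    def validate(self) -> None:
        v = self.violations()
        if v:
            raise ConfigError("; ".join(v))

    def config_hash(self) -> str:
        """Stable hash of all distribution parameters (seed excluded)."""
        payload = {
            "n": self.n,
            "poor_prevalence": self.poor_prevalence,
            "categorical": {
                k: {g: list(map(float, np.atleast_1d(v[g]))) for g in ("poor", "good")}
                for k, v in sorted(self.categorical_conditionals.items())
            },
            "continuous": {
                k: {g: list(map(float, v[g])) for g in ("poor", "good")}
                for k, v in sorted(self.continuous_conditionals.items())
            },
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def default_config(n: int = 168, seed: int = 0, poor_prevalence: float | None = None) -> SyntheticCohortConfig:
    """Config with the published training-set parameters."""
    cfg = SyntheticCohortConfig(n=n, seed=seed)
    if poor_prevalence is not None:
        cfg = replace(cfg, poor_prevalence=poor_prevalence)
    return cfg


def _draw_truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draws truncated at 0 by resampling (negligible distortion at
    the configured means/SDs, all several SDs above zero)."""
    out = rng.normal(mean, sd, size)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < 0
    return out


def _value_within_bin(rng: np.random.Generator, predictor: str, level: str):
    if predictor == "age":
        lo, hi = _AGE_RANGES[level]
        return int(rng.integers(lo, hi + 1))
    if predictor == "gcs":
        lo, hi = _GCS_RANGES[level]
        return int(rng.integers(lo, hi + 1))
    if predictor == "apoe_e4_carrier":
        return level == "yes"
    return level  # damaged_area, marshall: the level is the value


def _generate(config: SyntheticCohortConfig, pooled: bool) -> Cohort:
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    outcomes = rng.random(n) < config.poor_prevalence
    # under the null, predictors follow the outcome-pooled mixture: condition
    # them on an independent dummy outcome instead of the real label
    cond = (rng.random(n) < config.poor_prevalence) if pooled else outcomes

    cat_draws: dict[str, list] = {}
    for name, spec in config.categorical_conditionals.items():
        levels = spec["levels"]
        idx = np.empty(n, dtype=int)
        for grp, mask in (("poor", cond), ("good", ~cond)):
            k = int(mask.sum())
            if k:
                idx[mask] = rng.choice(len(levels), size=k, p=np.asarray(spec[grp], dtype=float))
        cat_draws[name] = [levels[i] for i in idx]

    cont_draws: dict[str, np.ndarray] = {}
    for name, spec in config.continuous_conditionals.items():
        vals = np.empty(n)
        for grp, mask in (("poor", cond), ("good", ~cond)):
            k = int(mask.sum())
            if k:
                vals[mask] = _draw_truncated_normal(rng, *spec[grp], k)
        cont_draws[name] = vals

    sex_spec = config.nuisance_marginals["sex"]
    sexes = rng.choice(sex_spec["levels"], size=n, p=sex_spec["p"])
    mech_spec = config.nuisance_marginals["mechanism"]
    mechanisms = rng.choice(mech_spec["levels"], size=n, p=mech_spec["p"])
    flags = {f: rng.random(n) < config.nuisance_marginals[f] for f in COMORBIDITY_FLAGS}

    width = len(str(n))
    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                patient_id=f"S{i + 1:0{width}d}",
                age=_value_within_bin(rng, "age", cat_draws["age"][i]),
                sex=str(sexes[i]),
                mechanism=str(mechanisms[i]),
                damaged_area=cat_draws["damaged_area"][i],
                gcs=_value_within_bin(rng, "gcs", cat_draws["gcs"][i]),
                apoe_e4_carrier=cat_draws["apoe_e4_carrier"][i] == "yes",
                crp=float(cont_draws["crp"][i]),
                il8=float(cont_draws["il8"][i]),
                marshall=cat_draws["marshall"][i],
                extra_labs={k: float(v[i]) for k, v in cont_draws.items() if k not in ("crp", "il8")},
                outcome="poor" if outcomes[i] else "good",
                comorbidities={f: bool(flags[f][i]) for f in COMORBIDITY_FLAGS},
            )
        )
    return Cohort(records=records, label="unlabeled")


def generate_cohort(config: SyntheticCohortConfig | None = None, **overrides) -> Cohort:
    """Generate a cohort with outcome-conditional signal.

    Deterministic for a fixed ``config.seed``. Every record satisfies the
    cohort-model invariants by construction.
    """
    config = config if config is not None else SyntheticCohortConfig()
    if overrides:
        config = replace(config, **overrides)
    return _generate(config, pooled=False)


def generate_null_cohort(config: SyntheticCohortConfig | None = None, **overrides) -> Cohort:
    """Generate a cohort in which no predictor carries outcome signal.

    Outcome labels are drawn as usual but every predictor is drawn from the
    outcome-pooled mixture distribution, so the true AUC of any score is 0.5
    and any rejection in the screening pipeline is a type-I error.
    """
    config = config if config is not None else SyntheticCohortConfig()
    if overrides:
        config = replace(config, **overrides)
    return _generate(config, pooled=True)


def summarize_cohort(cohort: Cohort) -> dict[str, pd.DataFrame]:
    """Per-outcome summary tables shaped for eyeball comparison with the
    published cohort tables.

    Returns ``{"continuous": mean ± SD per analyte and outcome,
    "categorical": counts per predictor level and outcome}``. The SD of a
    single-patient group is reported as missing.
    """
    poor = [r for r in cohort if r.outcome == "poor"]
    good = [r for r in cohort if r.outcome == "good"]
    if not poor and not good:
        raise ValueError("summaries need outcome labels")

    def _cont_row(name: str, getter) -> dict:
        row: dict[str, object] = {"analyte": name}
        for grp, recs in (("poor", poor), ("good", good)):
            vals = np.asarray([getter(r) for r in recs if getter(r) is not None], dtype=float)
            row[f"{grp}_n"] = vals.size
            row[f"{grp}_mean"] = float(vals.mean()) if vals.size else np.nan
            row[f"{grp}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
        return row

    analytes = sorted({k for r in cohort for k in r.extra_labs})
    cont = pd.DataFrame(
        [_cont_row("crp", lambda r: r.crp), _cont_row("il8", lambda r: r.il8)]
        + [_cont_row(a, lambda r, a=a: r.extra_labs.get(a)) for a in analytes]
    )

    from .screening import ORDINAL_CODINGS, _ordinal_level

    cat_rows = []
    for name in ("age", "damaged_area", "gcs", "apoe_e4_carrier", "marshall"):
        levels = ORDINAL_CODINGS[name]["levels"]
        for j, level in enumerate(levels):
            cat_rows.append(
                {
                    "predictor": name,
                    "level": level,
                    "poor": sum(1 for r in poor if _ordinal_level(r, name) == j),
                    "good": sum(1 for r in good if _ordinal_level(r, name) == j),
                }
            )
    return {"continuous": cont, "categorical": pd.DataFrame(cat_rows)}


def config_from_summary(summary: Mapping[str, pd.DataFrame], n: int = 168, seed: int = 0) -> SyntheticCohortConfig:
    """Build a config whose conditionals are a cohort's empirical summaries
    (moment-matching round trip; analytes or levels absent from the summary
    keep their defaults)."""
    cfg = default_config(n=n, seed=seed)
    cont = summary["continuous"].set_index("analyte")
    for name in cfg.continuous_conditionals:
        if name in cont.index:
            row = cont.loc[name]
            if row[["poor_sd", "good_sd"]].notna().all():
                cfg.continuous_conditionals[name] = {
                    "poor": (float(row["poor_mean"]), float(row["poor_sd"])),
                    "good": (float(row["good_mean"]), float(row["good_sd"])),
                }
    cat = summary["categorical"]
    for name, spec in cfg.categorical_conditionals.items():
        sub = cat[cat["predictor"] == name].set_index("level")
        if set(spec["levels"]) <= set(sub.index) and (sub[["poor", "good"]].sum() > 0).all():
            cfg.categorical_conditionals[name] = {
                "levels": spec["levels"],
                "poor": _normalize([sub.loc[l, "poor"] for l in spec["levels"]]),
                "good": _normalize([sub.loc[l, "good"] for l in spec["levels"]]),
            }
    total = cat[cat["predictor"] == "age"][["poor", "good"]].sum()
    if total.sum() > 0:
        cfg = replace(cfg, poor_prevalence=float(total["poor"] / total.sum()))
    return cfg
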