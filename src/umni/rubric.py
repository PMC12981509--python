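"""Deterministic rubric-based rater.

A rubric maps a structured disease attribute profile to the eleven 1-5
criterion scores through explicit threshold tables: numeric criteria use four
ordered cut-points defining five half-open, lower-inclusive bands on the
attribute scale; categorical criteria use an explicit category -> score map.
Higher scores always mean greater unmet need, so criteria whose driving
attribute runs the other way (commonality: rarer disease => higher need)
carry a ``decreasing`` direction flag.

All anchors are configuration, never constants: the default rubric shipped
here is a documented, clinically plausible instantiation (e.g. 5-year
mortality bands <1 / 1-10 / 10-30 / 30-60 / >=60 %), and any criterion can be
re-anchored from JSON without touching code.
"""

from __future__ import annotations

import json
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Union

import numpy as np
import pandas as pd

from .criteria import CriterionSet, default_criteria
from .exceptions import RubricError

DURATION_UNITS = ("weeks", "months", "years", "lifelong")

_UNIT_TO_YEARS = {"weeks": 1 / 52, "months": 1 / 12, "years": 1.0}


@dataclass(frozen=True)
class DiseaseProfile:
    """Raw quantitative/categorical disease attributes feeding the rubric."""

    disease_id: str
    prevalence_per_100k: float
    duration_value: float
    duration_unit: str  # weeks | months | years | lifelong
    qaly_loss_fraction: float  # per year of illness, in [0, 1]
    five_year_mortality_pct: float  # in [0, 100]
    soc_disease_modification: str
    soc_adverse_event_burden: str
    admin_route: str
    admin_frequency_per_year: float  # doses per year
    annual_cost_band: str
    supply_robustness: str
    regulatory_barrier: str

    def __post_init__(self) -> None:
        if self.prevalence_per_100k < 0:
            raise RubricError(f"{self.disease_id}: negative prevalence")
        if self.duration_unit not in DURATION_UNITS:
            raise RubricError(
                f"{self.disease_id}: duration unit {self.duration_unit!r} not in "
                f"{DURATION_UNITS}"
            )
        if not 0 <= self.qaly_loss_fraction <= 1:
            raise RubricError(f"{self.disease_id}: qaly_loss_fraction outside [0,1]")
        if not 0 <= self.five_year_mortality_pct <= 100:
            raise RubricError(f"{self.disease_id}: 5-year mortality outside [0,100]")
        if self.admin_frequency_per_year < 0:
            raise RubricError(f"{self.disease_id}: negative administration frequency")

    @property
    def duration_years(self) -> float:
        if self.duration_unit == "lifelong":
            return math.inf
        return self.duration_value * _UNIT_TO_YEARS[self.duration_unit]


@dataclass(frozen=True)
class NumericRubric:
    """Four strictly increasing cut-points -> five lower-inclusive bands.

    ``direction="increasing"``: attribute below the first cut-point scores 1,
    at/above the last scores 5.  ``"decreasing"`` inverts the scores (used
    when a *small* attribute value signals high need).
    """

    attribute: str
    cutpoints: tuple[float, ...]
    direction: str = "increasing"
    domain_min: float = 0.0
    domain_max: float = math.inf

    def __post_init__(self) -> None:
        if self.direction not in ("increasing", "decreasing"):
            raise RubricError(f"bad direction {self.direction!r}")

    def score(self, x: float) -> int:
        n_below = bisect_right(list(self.cutpoints), x)  # cut-points <= x
        return 1 + n_below if self.direction == "increasing" else 5 - n_below

    def band(self, score: int) -> tuple[float, float]:
        """Half-open attribute interval [low, high) mapping to ``score``."""
        edges = [self.domain_min, *self.cutpoints, math.inf]
        i = score - 1 if self.direction == "increasing" else 5 - score
        return edges[i], edges[i + 1]


@dataclass(frozen=True)
class CategoricalRubric:
    """Explicit category -> score map over an enumerated attribute."""

    attribute: str
    mapping: dict[str, int] = field(default_factory=dict)

    def score(self, value: str) -> int:
        try:
            return self.mapping[value]
        except KeyError:
            raise RubricError(
                f"attribute {self.attribute!r}: value {value!r} outside the "
                f"rubric domain {sorted(self.mapping)}"
            ) from None

    def levels_for(self, score: int) -> list[str]:
        return [k for k, v in self.mapping.items() if v == score]


CriterionRubric = Union[NumericRubric, CategoricalRubric]


@dataclass(frozen=True)
class RubricConfig:
    """Per-criterion threshold tables covering the active criterion set."""

    rules: dict[str, CriterionRubric]

    def __getitem__(self, criterion: str) -> CriterionRubric:
        return self.rules[criterion]

    def to_json(self, path: str | Path) -> None:
        data = {}
        for name, rule in self.rules.items():
            if isinstance(rule, NumericRubric):
                data[name] = {
                    "kind": "numeric", "attribute": rule.attribute,
                    "cutpoints": list(rule.cutpoints),
                    "direction": rule.direction,
                    "domain_min": rule.domain_min,
                    "domain_max": (None if math.isinf(rule.domain_max)
                                   else rule.domain_max),
                }
            else:
                data[name] = {
                    "kind": "categorical", "attribute": rule.attribute,
                    "mapping": rule.mapping,
                }
        Path(path).write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "RubricConfig":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        rules: dict[str, CriterionRubric] = {}
        for name, cfg in data.items():
            if cfg.get("kind") == "numeric":
                dmax = cfg.get("domain_max")
                rules[name] = NumericRubric(
                    cfg["attribute"], tuple(cfg["cutpoints"]),
                    cfg.get("direction", "increasing"),
                    cfg.get("domain_min", 0.0),
                    math.inf if dmax is None else float(dmax),
                )
            elif cfg.get("kind") == "categorical":
                rules[name] = CategoricalRubric(
                    cfg["attribute"], {k: int(v) for k, v in cfg["mapping"].items()}
                )
            else:
                raise RubricError(f"criterion {name!r}: unknown rubric kind")
        return cls(rules)


def _ordinal(attribute: str, levels: tuple[str, ...]) -> CategoricalRubric:
    return CategoricalRubric(attribute, {lv: i + 1 for i, lv in enumerate(levels)})


def default_rubric() -> RubricConfig:
    """The documented default anchors for all 11 criteria.

    Numeric bands (lower-inclusive):

    * Commonality: prevalence/100k >= 500 -> 1 ... < 0.5 -> 5 (need-inverted).
    * Duration: < 3 months -> 1 ... >= 20 years or lifelong -> 5.
    * QALYs lost: fraction/year < 0.05 -> 1 ... >= 0.5 -> 5.
    * Mortality: 5-year % < 1 -> 1, 1-10 -> 2, 10-30 -> 3, 30-60 -> 4, >= 60 -> 5.
    * Frequency: doses/year < 4 -> 1 ... >= 365 (daily or more) -> 5.

    Categorical ladders run from best-served (score 1) to worst-served (5).
    """
    return RubricConfig({
        "Commonality": NumericRubric(
            "prevalence_per_100k", (0.5, 5.0, 50.0, 500.0), "decreasing"),
        "Duration": NumericRubric(
            "duration_years", (0.25, 1.0, 5.0, 20.0), "increasing"),
        "QALYs lost": NumericRubric(
            "qaly_loss_fraction", (0.05, 0.15, 0.3, 0.5), "increasing",
            domain_max=1.0),
        "Mortality": NumericRubric(
            "five_year_mortality_pct", (1.0, 10.0, 30.0, 60.0), "increasing",
            domain_max=100.0),
        "Disease modification": _ordinal("soc_disease_modification", (
            "curative", "substantially_modifying", "moderately_modifying",
            "minimally_modifying", "none")),
        "Adverse events": _ordinal("soc_adverse_event_burden", (
            "negligible", "mild", "moderate", "severe", "intolerable")),
        "Route of administration": _ordinal("admin_route", (
            "oral", "topical_or_inhaled", "self_injection",
            "clinic_infusion", "implanted_or_hospital")),
        "Frequency of administration": NumericRubric(
            "admin_frequency_per_year", (4.0, 12.0, 52.0, 365.0), "increasing"),
        "Cost to patients": _ordinal("annual_cost_band", (
            "minimal", "low", "moderate", "high", "catastrophic")),
        "Robust supply": _ordinal("supply_robustness", (
            "very_robust", "robust", "moderate", "fragile", "precarious")),
        "Regulatory barriers": _ordinal("regulatory_barrier", (
            "none", "low", "moderate", "high", "prohibitive")),
    })


def score_profile(
    p: DiseaseProfile,
    r: RubricConfig,
    criteria: CriterionSet | None = None,
) -> np.ndarray:
    """Score one profile: an 11-vector of integers in criterion-set order.

    Deterministic: identical profile + rubric always yields the identical
    vector.  Raises :class:`RubricError` when an attribute value falls
    outside the rubric domain, naming criterion and value.
    """
    criteria = criteria or default_criteria()
    out = np.empty(len(criteria), dtype=int)
    for i, crit in enumerate(criteria):
        try:
            rule = r[crit.name]
        except KeyError:
            raise RubricError(f"rubric has no rule for criterion {crit.name!r}") from None
        value = getattr(p, rule.attribute)
        try:
            out[i] = rule.score(value)
        except RubricError as exc:
            raise RubricError(f"criterion {crit.name!r}: {exc}") from None
    return out


class RubricIssue(NamedTuple):
    criterion: str
    kind: str  # "gap" | "overlap" | "missing"
    detail: str


def rubric_coverage_check(
    r: RubricConfig, criteria: CriterionSet | None = None
) -> list[RubricIssue]:
    """Report gaps/overlaps; empty list iff every criterion's map is total
    and single-valued over its attribute domain."""
    criteria = criteria or default_criteria()
    issues: list[RubricIssue] = []
    for crit in criteria:
        if crit.name not in r.rules:
            issues.append(RubricIssue(crit.name, "missing", "no rubric rule"))
            continue
        rule = r.rules[crit.name]
        if isinstance(rule, NumericRubric):
            cuts = rule.cutpoints
            if len(cuts) < 4:
                issues.append(RubricIssue(
                    crit.name, "gap",
                    f"{len(cuts)} cut-points define only {len(cuts) + 1} bands"))
            elif len(cuts) > 4:
                issues.append(RubricIssue(
                    crit.name, "overlap", f"{len(cuts)} cut-points exceed 5 bands"))
            if any(b <= a for a, b in zip(cuts, cuts[1:])):
                issues.append(RubricIssue(
                    crit.name, "overlap", f"cut-points not strictly increasing: {cuts}"))
        else:
            if not rule.mapping:
                issues.append(RubricIssue(crit.name, "gap", "empty category map"))
            bad = {k: v for k, v in rule.mapping.items() if not 1 <= v <= 5}
            if bad:
                issues.append(RubricIssue(
                    crit.name, "gap", f"scores outside 1-5: {bad}"))
    return issues


_PROFILE_COLUMNS = [
    "disease_id", "prevalence_per_100k", "duration_value", "duration_unit",
    "qaly_loss_fraction", "five_year_mortality_pct", "soc_disease_modification",
    "soc_adverse_event_burden", "admin_route", "admin_frequency_per_year",
    "annual_cost_band", "supply_robustness", "regulatory_barrier",
]


def profiles_to_csv(profiles: list[DiseaseProfile], path: str | Path) -> None:
    pd.DataFrame([
        {c: getattr(p, c) for c in _PROFILE_COLUMNS} for p in profiles
    ]).to_csv(path, index=False, encoding="utf-8")


def profiles_from_csv(path: str | Path) -> list[DiseaseProfile]:
    df = pd.read_csv(path, encoding="utf-8")
    missing = set(_PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise RubricError(f"{path}: missing profile columns {sorted(missing)}")
    return [DiseaseProfile(**{c: row[c] for c in _PROFILE_COLUMNS})
            for _, row in df.iterrows()]
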