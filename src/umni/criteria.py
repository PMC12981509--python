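"""The 11-criterion unmet-medical-need framework and its weighting scheme.

The index scores every disease on eleven ordinal criteria grouped into three
categories — patient suffering, current standard of care, and accessibility of
that standard of care — and combines them as a weighted sum.  The default
weights deliberately up-weight mortality/morbidity and effective-treatment
criteria so that rare, poorly served, high-mortality diseases score highest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

from .exceptions import ConfigError

PATIENT_SUFFERING = "patient_suffering"
STANDARD_OF_CARE = "standard_of_care"
ACCESSIBILITY = "accessibility"

CATEGORIES = (PATIENT_SUFFERING, STANDARD_OF_CARE, ACCESSIBILITY)


@dataclass(frozen=True)
class Criterion:
    """One scoring dimension of the index."""

    name: str
    category: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ConfigError(
                f"criterion {self.name!r}: unknown category {self.category!r}"
            )


@dataclass(frozen=True)
class CriterionSet:
    """Ordered collection of exactly 11 uniquely named criteria."""

    criteria: tuple[Criterion, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.criteria]
        if len(self.criteria) != 11:
            raise ConfigError(f"expected 11 criteria, got {len(self.criteria)}")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigError(f"duplicate criterion names: {dupes}")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.criteria]

    def __iter__(self) -> Iterator[Criterion]:
        return iter(self.criteria)

    def __len__(self) -> int:
        return len(self.criteria)

    def by_category(self, category: str) -> list[Criterion]:
        return [c for c in self.criteria if c.category == category]


def default_criteria() -> CriterionSet:
    """The default 11-criterion framework (4 suffering / 4 care / 3 access)."""
    mk = Criterion
    return CriterionSet((
        mk("Commonality", PATIENT_SUFFERING,
           "How common the disease is (prevalence per 100,000); rarer diseases "
           "indicate greater unmet need under the rare-disease weighting intent."),
        mk("Duration", PATIENT_SUFFERING,
           "Typical duration of illness, from weeks to lifelong."),
        mk("QALYs lost", PATIENT_SUFFERING,
           "Quality-adjusted life years lost per year of illness (morbidity)."),
        mk("Mortality", PATIENT_SUFFERING,
           "Five-year mortality rate of the disease."),
        mk("Disease modification", STANDARD_OF_CARE,
           "Disease-modifying activity of the current standard of care, from "
           "curative to none."),
        mk("Adverse events", STANDARD_OF_CARE,
           "Adverse events / side-effect burden of the standard of care."),
        mk("Route of administration", STANDARD_OF_CARE,
           "Burden of the administration route, oral through implanted/infused."),
        mk("Frequency of administration", STANDARD_OF_CARE,
           "Dosing frequency burden of the standard of care."),
        mk("Cost to patients", ACCESSIBILITY,
           "Annual out-of-pocket cost burden of the standard of care."),
        mk("Robust supply", ACCESSIBILITY,
           "Robustness of the supply chain for the standard of care."),
        mk("Regulatory barriers", ACCESSIBILITY,
           "Regulatory barriers to accessing the standard of care."),
    ))


@dataclass(frozen=True)
class WeightScheme:
    """Map criterion name -> non-negative weight used in the composite sum."""

    weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, w in self.weights.items():
            if w < 0:
                raise ConfigError(f"weight for {name!r} is negative: {w}")

    def __getitem__(self, name: str) -> float:
        return self.weights[name]

    def total(self) -> float:
        return float(sum(self.weights.values()))

    def covers(self, criteria: CriterionSet) -> bool:
        return set(self.weights) == set(criteria.names)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dict(self.weights), indent=2, sort_keys=False) + "\n",
            encoding="utf-8",
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "WeightScheme":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: weight file must be a JSON object")
        return cls({str(k): float(v) for k, v in data.items()})


#: Default per-criterion weights.  Patient-suffering weights rise from
#: commonality (0.25) to mortality (1); standard-of-care weights fall from
#: disease modification (1) to administration frequency (0.25); the three
#: accessibility weights are all 0.25.  They sum to 5.75.
_DEFAULT_WEIGHTS = {
    "Commonality": 0.25,
    "Duration": 0.5,
    "QALYs lost": 0.75,
    "Mortality": 1.0,
    "Disease modification": 1.0,
    "Adverse events": 0.75,
    "Route of administration": 0.5,
    "Frequency of administration": 0.25,
    "Cost to patients": 0.25,
    "Robust supply": 0.25,
    "Regulatory barriers": 0.25,
}


def default_weights() -> WeightScheme:
    """Return the default weight scheme (a fresh, immutable copy each call)."""
    return WeightScheme(dict(_DEFAULT_WEIGHTS))
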