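"""Synthetic-data generators: every input the pipeline needs, offline.

Three generators cover the study design end to end:

* :func:`gen_profiles` — disease attribute profiles whose rubric scores
  realise a target per-criterion score distribution (uniform by default, so
  a 40-disease panel spans the full 1-5 spectrum on every criterion, the way
  a calibration panel is assembled).  Construction is inverse: sample the
  target score first, then draw an attribute from that score's rubric band.
* :func:`gen_rater_pair` — an "expert" matrix plus a second rater derived
  from it with a controlled disagreement profile (probability of +-1 and
  +-2 point shifts), emulating observed two-expert disagreement structure.
* :func:`gen_factor_scores` — 1-5 score matrices with a planted latent
  factor structure: multivariate-normal latents under a loading model,
  discretised at fixed cut-points (-1.5, -0.5, 0.5, 1.5 standard-normal
  quantile anchors by default).

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .criteria import CriterionSet, default_criteria
from .exceptions import ConfigError, RubricError
from .llm import RaterConfig, mock_rate
from .registry import DiseaseRecord
from .rubric import (
    CategoricalRubric,
    DiseaseProfile,
    NumericRubric,
    RubricConfig,
    default_rubric,
    rubric_coverage_check,
)
from .scores import ScoreMatrix


@dataclass(frozen=True)
class SpectrumPlan:
    """Target score distribution over {1..5} per criterion.

    ``distributions`` maps criterion name -> 5 probabilities; criteria not
    listed use ``default`` (uniform unless overridden).
    """

    distributions: dict[str, tuple[float, ...]] = field(default_factory=dict)
    default: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)

    def __post_init__(self) -> None:
        for name, dist in [("default", self.default), *self.distributions.items()]:
            if len(dist) != 5 or any(p < 0 for p in dist):
                raise ConfigError(f"plan for {name!r} must be 5 non-negative probs")
            if abs(sum(dist) - 1.0) > 1e-9:
                raise ConfigError(f"plan for {name!r} must sum to 1")

    def probs(self, criterion: str) -> np.ndarray:
        return np.asarray(self.distributions.get(criterion, self.default))

    @classmethod
    def point_mass(cls, score: int) -> "SpectrumPlan":
        dist = tuple(1.0 if s == score else 0.0 for s in range(1, 6))
        return cls(default=dist)


def synthetic_registry(n: int, prefix: str = "MONDO") -> list[DiseaseRecord]:
    """n synthetic disease records with MONDO-style 7-digit ids."""
    return [
        DiseaseRecord(f"{prefix}:{9000000 + i:07d}", f"synthetic disease {i + 1}")
        for i in range(n)
    ]


def _years_to_duration(years: float) -> tuple[float, str]:
    if math.isinf(years):
        return 0.0, "lifelong"
    if years < 0.25:
        return round(years * 52, 2), "weeks"
    if years < 1:
        return round(years * 12, 2), "months"
    return round(years, 2), "years"


def _sample_numeric(rule: NumericRubric, score: int, rng: np.random.Generator) -> float:
    low, high = rule.band(score)
    if math.isinf(high):
        # open-ended band: cover [low, low + span of the banded region],
        # truncated to the attribute's domain; lifelong illness stands in
        # for the open-ended duration band half the time
        span = rule.cutpoints[-1] - rule.cutpoints[0]
        if rule.attribute == "duration_years" and rng.random() < 0.5:
            return math.inf
        high = min(low + max(span, 1.0), rule.domain_max)
    val = float(rng.uniform(low, high))
    return min(val, math.nextafter(high, low))  # keep inside the half-open band


def gen_profiles(
    n: int,
    plan: SpectrumPlan | None = None,
    rubric: RubricConfig | None = None,
    seed: int | None = None,
    criteria: CriterionSet | None = None,
) -> list[DiseaseProfile]:
    """Generate n profiles whose rubric scores realise the plan's marginals.

    Inverse-constructed: for each criterion a target score is drawn from the
    plan, then an attribute value is drawn uniformly from that score's rubric
    band, so ``score_profile`` recovers the planned score exactly.
    """
    plan = plan or SpectrumPlan()
    rubric = rubric or default_rubric()
    criteria = criteria or default_criteria()
    issues = rubric_coverage_check(rubric, criteria)
    if issues:
        raise RubricError(f"rubric fails coverage check: {issues[:3]}")
    rng = np.random.default_rng(seed)
    registry = synthetic_registry(n)
    profiles = []
    for rec in registry:
        kwargs: dict[str, object] = {"disease_id": rec.id}
        for crit in criteria:
            rule = rubric[crit.name]
            score = int(rng.choice(5, p=plan.probs(crit.name))) + 1
            if isinstance(rule, NumericRubric):
                value = _sample_numeric(rule, score, rng)
                if rule.attribute == "duration_years":
                    dv, du = _years_to_duration(value)
                    kwargs["duration_value"] = dv
                    kwargs["duration_unit"] = du
                else:
                    kwargs[rule.attribute] = value
            else:
                levels = rule.levels_for(score)
                if not levels:
                    raise RubricError(
                        f"criterion {crit.name!r}: no rubric band for score {score}"
                    )
                kwargs[rule.attribute] = levels[int(rng.integers(len(levels)))]
        profiles.append(DiseaseProfile(**kwargs))  # type: ignore[arg-type]
    return profiles


def _matrix_from_plan(
    n_diseases: int,
    plan: SpectrumPlan,
    rng: np.random.Generator,
    criteria: CriterionSet,
    rater_id: str,
) -> ScoreMatrix:
    ids = [rec.id for rec in synthetic_registry(n_diseases)]
    cols = {}
    for crit in criteria:
        cols[crit.name] = rng.choice(5, size=n_diseases, p=plan.probs(crit.name)) + 1
    return ScoreMatrix(rater_id, pd.DataFrame(cols, index=ids, dtype=float))


def gen_rater_pair(
    n_diseases: int,
    plan: SpectrumPlan | None = None,
    rates: dict[int, float] | None = None,
    seed: int | None = None,
    criteria: CriterionSet | None = None,
) -> tuple[ScoreMatrix, ScoreMatrix]:
    """An expert score matrix and a paired second rater with controlled
    disagreement rates (map |shift| -> probability)."""
    plan = plan or SpectrumPlan()
    criteria = criteria or default_criteria()
    rng = np.random.default_rng(seed)
    expert = _matrix_from_plan(n_diseases, plan, rng, criteria, "expert")
    mock_seed = int(rng.integers(2**31))
    second = mock_rate(
        expert,
        RaterConfig(seed=mock_seed, disagreement_rates=dict(rates or {})),
        rater_id="second",
    )
    return expert, second


@dataclass(frozen=True)
class PlantedFactorModel:
    """Latent factor model used to plant structure in generated scores."""

    loadings: np.ndarray  # p x k
    factor_corr: np.ndarray | None = None  # k x k, identity when omitted
    cutpoints: tuple[float, ...] = (-1.5, -0.5, 0.5, 1.5)
    item_names: tuple[str, ...] | None = None

    def implied_corr(self) -> np.ndarray:
        L = np.asarray(self.loadings, dtype=float)
        phi = (np.eye(L.shape[1]) if self.factor_corr is None
               else np.asarray(self.factor_corr, dtype=float))
        common = L @ phi @ L.T
        communality = np.diag(common)
        if np.any(communality >= 1.0):
            raise ConfigError("planted communalities must be < 1")
        R = common + np.diag(1.0 - communality)
        try:
            np.linalg.cholesky(R)
        except np.linalg.LinAlgError:
            raise ConfigError("implied correlation matrix is not positive definite") from None
        return R

    def names(self) -> list[str]:
        if self.item_names is not None:
            return list(self.item_names)
        return [f"item_{i + 1}" for i in range(np.asarray(self.loadings).shape[0])]


def gen_factor_scores(
    n: int, model: PlantedFactorModel, seed: int | None = None
) -> ScoreMatrix:
    """1-5 score matrix with the model's planted correlation structure.

    Latent draws from N(0, implied_corr) are discretised at the model's
    cut-points; the empirical polychoric-ish Pearson correlations converge to
    an attenuated version of the implied matrix as n grows.
    """
    R = model.implied_corr()
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(R)
    latent = rng.standard_normal((n, R.shape[0])) @ chol.T
    scores = 1 + np.searchsorted(np.asarray(model.cutpoints), latent)
    ids = [rec.id for rec in synthetic_registry(n)]
    return ScoreMatrix(
        "planted",
        pd.DataFrame(scores.astype(float), index=ids, columns=model.names()),
    )


def four_factor_model() -> PlantedFactorModel:
    """A 4-factor, 11-criterion planted model mirroring the thematic
    grouping structure of the index (disease burden / access barriers /
    modifiability / treatment complexity), with modestly correlated factors."""
    criteria = default_criteria().names
    L = np.zeros((11, 4))
    primary = {
        "QALYs lost": (0, 0.84), "Frequency of administration": (0, 0.73),
        "Commonality": (1, 0.74), "Robust supply": (1, 0.85),
        "Regulatory barriers": (1, 0.67),
        "Disease modification": (2, -0.78), "Cost to patients": (2, 0.53),
        "Duration": (2, 0.60),
        "Route of administration": (3, 0.85), "Mortality": (3, 0.75),
        "Adverse events": (3, 0.68),
    }
    for name, (j, lam) in primary.items():
        L[criteria.index(name), j] = lam
    L[criteria.index("Adverse events"), 0] = 0.30  # cross-loading
    phi = np.full((4, 4), 0.2)
    np.fill_diagonal(phi, 1.0)
    return PlantedFactorModel(L, phi, item_names=tuple(criteria))


def one_factor_model(loading: float = 0.8, p: int = 6) -> PlantedFactorModel:
    return PlantedFactorModel(np.full((p, 1), loading))


def two_factor_model(loading: float = 0.8, p_per_block: int = 4) -> PlantedFactorModel:
    p = 2 * p_per_block
    L = np.zeros((p, 2))
    L[:p_per_block, 0] = loading
    L[p_per_block:, 1] = loading
    return PlantedFactorModel(L)
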