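"""Inter-rater agreement statistics and performance gates.

Two layers of evaluation:

* **Per-criterion gates** — for each criterion, compare the two raters'
  means and sample standard deviations.  A rater passes when the mean
  difference (expert − candidate) is within ±1 point and the SD difference
  is within ±0.5 points, boundaries inclusive.
* **Pooled rank/error/bias battery** — per criterion across the pooled
  disease set: Spearman rank correlation with a 95% percentile-bootstrap
  confidence interval (1,000 paired resamples), mean absolute error, root
  mean square error, and a paired Wilcoxon signed-rank test of median
  difference zero.

The Spearman test asks whether the candidate preserves rank orderings; the
Wilcoxon test asks whether it systematically over- or under-rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError
from .scores import ScoreMatrix, check_aligned, require_complete

GATE_MEAN_DIFF = 1.0  # |expert mean - candidate mean| tolerance, inclusive
GATE_SD_DIFF = 0.5    # |expert sd - candidate sd| tolerance, inclusive


def criterion_moments(x: Sequence[float]) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1 denominator); needs n >= 2."""
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise DegenerateDataError("need at least 2 scores for moments")
    return float(arr.mean()), float(arr.std(ddof=1))


def gate_check(mean_diff: float, sd_diff: float) -> tuple[str, str]:
    """Performance gates, boundary-inclusive: returns ('pass'|'fail', ...)."""
    gate_mean = "pass" if abs(mean_diff) <= GATE_MEAN_DIFF else "fail"
    gate_sd = "pass" if abs(sd_diff) <= GATE_SD_DIFF else "fail"
    return gate_mean, gate_sd


@dataclass(frozen=True)
class CriterionAgreement:
    """Table-style per-criterion comparison of two raters."""

    criterion: str
    expert_mean: float
    expert_sd: float
    llm_mean: float
    llm_sd: float

    @property
    def mean_diff(self) -> float:  # sign convention: expert - candidate
        return self.expert_mean - self.llm_mean

    @property
    def sd_diff(self) -> float:
        return self.expert_sd - self.llm_sd

    @property
    def gates(self) -> tuple[str, str]:
        return gate_check(self.mean_diff, self.sd_diff)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson on average-ranked data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DegenerateDataError("paired lists must have equal length")
    if x.size < 3:
        raise DegenerateDataError("need n >= 3 for a rank correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("rank correlation undefined for constant input")
    return float(stats.spearmanr(x, y).statistic)


def _rowwise_rank_corr(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    rx = stats.rankdata(xs, axis=1)
    ry = stats.rankdata(ys, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    num = (rx * ry).sum(axis=1)
    den = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    return num / den


def bootstrap_rho_ci(
    x: Sequence[float],
    y: Sequence[float],
    resamples: int = 1000,
    level: float = 95.0,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the Spearman correlation.

    Index pairs are resampled with replacement; resamples where either
    vector comes out constant (rank correlation undefined) are redrawn.
    Deterministic for a fixed seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 5:
        raise DegenerateDataError("need n >= 5 to bootstrap a rank correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("rank correlation undefined for constant input")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(resamples, n))
    xs, ys = x[idx], y[idx]
    for _ in range(1000):
        bad = (np.ptp(xs, axis=1) == 0) | (np.ptp(ys, axis=1) == 0)
        if not bad.any():
            break
        redraw = rng.integers(0, n, size=(int(bad.sum()), n))
        xs[bad], ys[bad] = x[redraw], y[redraw]
    else:  # pragma: no cover - essentially impossible for non-constant input
        raise DegenerateDataError("could not draw non-degenerate resamples")
    rhos = _rowwise_rank_corr(xs, ys)
    alpha = (100.0 - level) / 2.0
    low, high = np.percentile(rhos, [alpha, 100.0 - alpha])
    return float(low), float(high)


class WilcoxonResult(NamedTuple):
    statistic: float
    p_value: float
    degenerate: bool  # True when every paired difference is zero


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test of median difference zero.

    Zero differences are dropped (Wilcoxon's convention).  The exact null
    distribution is used when the effective n is <= 25 with no tied |d|;
    otherwise the normal approximation with tie and continuity corrections.
    All-zero differences give p = 1 with a degeneracy flag.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if d.size < 1:
        raise DegenerateDataError("need at least one pair")
    d = d[d != 0]
    if d.size == 0:
        return WilcoxonResult(0.0, 1.0, True)
    abs_d = np.abs(d)
    has_ties = len(np.unique(abs_d)) < len(abs_d)
    if d.size <= 25 and not has_ties:
        res = stats.wilcoxon(d, zero_method="wilcox", method="exact")
    else:
        res = stats.wilcoxon(
            d, zero_method="wilcox", method="approx", correction=True
        )
    return WilcoxonResult(float(res.statistic), float(res.pvalue), False)


def mae_rmse(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mean absolute error and root mean square error of paired scores."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if d.size < 1:
        raise DegenerateDataError("need at least one pair")
    return float(np.abs(d).mean()), float(np.sqrt((d**2).mean()))


@dataclass(frozen=True)
class PooledAgreement:
    """Rank/error/bias battery for one criterion (or one pooled vector pair)."""

    spearman_rho: float
    rho_ci_low: float
    rho_ci_high: float
    mae: float
    rmse: float
    wilcoxon_p: float


def agreement_battery(
    x: Sequence[float],
    y: Sequence[float],
    resamples: int = 1000,
    seed: int | None = None,
) -> PooledAgreement:
    rho = spearman_rho(x, y)
    low, high = bootstrap_rho_ci(x, y, resamples=resamples, seed=seed)
    mae, rmse = mae_rmse(x, y)
    wil = wilcoxon_signed_rank(x, y)
    return PooledAgreement(rho, low, high, mae, rmse, wil.p_value)


def per_criterion_report(expert: ScoreMatrix, llm: ScoreMatrix) -> pd.DataFrame:
    """Per-criterion moments, differences and gates (development-table shape)."""
    check_aligned(expert, llm)
    require_complete(expert, llm)
    rows = []
    for crit in expert.criteria:
        em, es = criterion_moments(expert.scores[crit])
        lm, ls = criterion_moments(llm.scores.loc[expert.disease_ids, crit])
        ca = CriterionAgreement(crit, em, es, lm, ls)
        gm, gs = ca.gates
        rows.append({
            "criterion": crit,
            "expert_mean": em, "expert_sd": es,
            "llm_mean": lm, "llm_sd": ls,
            "mean_diff": ca.mean_diff, "sd_diff": ca.sd_diff,
            "gate_mean": gm, "gate_sd": gs,
        })
    return pd.DataFrame(rows)


def pooled_report(
    expert: ScoreMatrix,
    llm: ScoreMatrix,
    resamples: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-criterion Spearman/CI/MAE/RMSE/Wilcoxon battery across diseases."""
    check_aligned(expert, llm)
    require_complete(expert, llm)
    rows = []
    for crit in expert.criteria:
        x = expert.scores[crit].to_numpy(float)
        y = llm.scores.loc[expert.disease_ids, crit].to_numpy(float)
        try:
            pa = agreement_battery(x, y, resamples=resamples, seed=seed)
            row = {
                "criterion": crit, "spearman_rho": pa.spearman_rho,
                "rho_ci_low": pa.rho_ci_low, "rho_ci_high": pa.rho_ci_high,
                "mae": pa.mae, "rmse": pa.rmse, "wilcoxon_p": pa.wilcoxon_p,
            }
        except DegenerateDataError:
            mae, rmse = mae_rmse(x, y)
            wil = wilcoxon_signed_rank(x, y)
            row = {
                "criterion": crit, "spearman_rho": np.nan,
                "rho_ci_low": np.nan, "rho_ci_high": np.nan,
                "mae": mae, "rmse": rmse, "wilcoxon_p": wil.p_value,
            }
        rows.append(row)
    return pd.DataFrame(rows)


def write_agreement_csv(report: pd.DataFrame, path: str | Path) -> None:
    report.round(4).to_csv(path, index=False, encoding="utf-8")
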