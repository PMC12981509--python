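"""Two-rater disagreement tabulation and third-rater mediation.

Two raters score independently; cells where they differ by more than one
point are escalated to a mediator whose value becomes the consensus, while
agreements and one-point differences (accepted as a reasonable margin of
uncertainty) are merged as the arithmetic mean — so the consensus lives in
half-integer space.  After mediation every consensus cell is within one
point of at least one of the original raters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import MediationError
from .scores import ScoreMatrix, check_aligned, require_complete


@dataclass(frozen=True)
class DisagreementTable:
    """Counts and percentages of absolute score differences between raters."""

    counts: dict[str, int]  # keys "0", "1", "2", ">=3"
    total: int

    @property
    def percentages(self) -> dict[str, float]:
        return {k: round(100.0 * v / self.total, 2) for k, v in self.counts.items()}

    @property
    def n_disagreements(self) -> int:
        return self.total - self.counts["0"]

    def within_one_point_pct(self) -> float:
        """Share of cells agreeing to within one point, as a percentage."""
        return 100.0 * (self.counts["0"] + self.counts["1"]) / self.total


def diff_histogram(a: ScoreMatrix, b: ScoreMatrix) -> DisagreementTable:
    """Tabulate |a - b| over the shared grid into bands 0 / 1 / 2 / >=3."""
    check_aligned(a, b)
    require_complete(a, b)
    bs = b.scores.loc[a.scores.index, a.scores.columns]
    diff = np.abs(a.scores.to_numpy(float) - bs.to_numpy(float))
    counts = {
        "0": int((diff == 0).sum()),
        "1": int((diff == 1).sum()),
        "2": int((diff == 2).sum()),
        ">=3": int((diff >= 3).sum()),
    }
    return DisagreementTable(counts, int(diff.size))


def mediate(
    a: ScoreMatrix, b: ScoreMatrix, mediator: ScoreMatrix
) -> tuple[ScoreMatrix, pd.DataFrame]:
    """Merge two raters into a consensus matrix.

    Cells with |a-b| <= 1 take the mean of the two raters (half-integers
    permitted); cells with |a-b| > 1 take the mediator's value verbatim and
    are logged.  The mediator must provide a value for every escalated cell,
    and that value must land within one point of at least one original rater.

    Returns the consensus matrix (rater id ``"consensus"``) and the mediation
    log as a DataFrame with columns disease_id, criterion, a, b, mediator,
    consensus.
    """
    check_aligned(a, b)
    require_complete(a, b)
    bs = b.scores.loc[a.scores.index, a.scores.columns]
    med = mediator.scores.reindex(index=a.scores.index, columns=a.scores.columns)

    consensus = (a.scores + bs) / 2.0
    log_rows = []
    gap = (a.scores - bs).abs()
    for disease_id, criterion in zip(*np.where(gap.to_numpy() > 1)):
        did = a.scores.index[disease_id]
        crit = a.scores.columns[criterion]
        m_val = med.loc[did, crit]
        if pd.isna(m_val):
            raise MediationError(
                f"mediator value required for cell ({did}, {crit}) "
                f"with |a-b| > 1, but none provided"
            )
        av, bv = float(a.scores.loc[did, crit]), float(bs.loc[did, crit])
        if min(abs(m_val - av), abs(m_val - bv)) > 1:
            raise MediationError(
                f"mediator score {m_val:g} for cell ({did}, {crit}) is more "
                f"than 1 point from both raters ({av:g}, {bv:g})"
            )
        consensus.loc[did, crit] = float(m_val)
        log_rows.append({
            "disease_id": str(did), "criterion": str(crit),
            "a": av, "b": bv, "mediator": float(m_val),
            "consensus": float(m_val),
        })

    log = pd.DataFrame(
        log_rows,
        columns=["disease_id", "criterion", "a", "b", "mediator", "consensus"],
    )
    return ScoreMatrix("consensus", consensus), log


def write_mediation_log(log: pd.DataFrame, path: str | Path) -> None:
    log.to_csv(path, index=False, encoding="utf-8")
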