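"""Score matrices: the universal currency of the pipeline.

A :class:`ScoreMatrix` holds one rater's integer scores (1-5) over a
disease x criterion grid.  The frozen on-disk dialect is UTF-8 CSV with a
header row of criterion names and the disease id in the first column
(column name ``disease_id``).  Missing cells are representable (empty cell
/ NaN) but downstream statistics refuse rows with missing values rather
than imputing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .criteria import CriterionSet
from .exceptions import GridMismatchError

SCORE_MIN, SCORE_MAX = 1, 5


class Violation(NamedTuple):
    """One audit finding: the offending cell and why it fails."""

    disease_id: str
    criterion: str
    value: float
    reason: str  # "noninteger" | "out of range"


@dataclass
class ScoreMatrix:
    """Rater-attributed score table (rows = diseases, columns = criteria).

    ``scores`` is a float DataFrame so that missing cells (NaN) and the
    half-integer consensus space produced by reconciliation are both
    representable; :func:`validate_scores` enforces the integer 1-5 contract
    where it applies.
    """

    rater_id: str
    scores: pd.DataFrame

    def __post_init__(self) -> None:
        self.scores = self.scores.astype(float)
        self.scores.index = self.scores.index.astype(str)
        self.scores.index.name = "disease_id"

    @property
    def disease_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def criteria(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n_cells(self) -> int:
        return int(self.scores.size)

    def missing_mask(self) -> pd.DataFrame:
        return self.scores.isna()

    def is_complete(self) -> bool:
        return not bool(self.scores.isna().any().any())

    def copy(self, rater_id: str | None = None) -> "ScoreMatrix":
        return ScoreMatrix(rater_id or self.rater_id, self.scores.copy())

    def to_csv(self, path: str | Path) -> None:
        df = self.scores.copy()
        # integer cells print as integers; half-integers keep one decimal
        def _fmt(v: float) -> str:
            if np.isnan(v):
                return ""
            return str(int(v)) if float(v).is_integer() else repr(float(v))
        df = df.map(_fmt)
        df.to_csv(path, encoding="utf-8")

    @classmethod
    def from_csv(cls, path: str | Path, rater_id: str | None = None) -> "ScoreMatrix":
        df = pd.read_csv(path, index_col=0, encoding="utf-8")
        return cls(rater_id or Path(path).stem, df)


def validate_scores(
    m: ScoreMatrix, criteria: CriterionSet | None = None
) -> list[Violation]:
    """Audit every present cell; return all violations (never raises).

    A cell violates when it is not an integer ("noninteger") or is an integer
    outside [1, 5] ("out of range").  Missing cells are not violations.  When
    ``criteria`` is given, columns not in the active criterion set are also
    reported (reason ``"unknown criterion"``).
    """
    out: list[Violation] = []
    if criteria is not None:
        for col in m.criteria:
            if col not in criteria.names:
                out.append(Violation("*", col, float("nan"), "unknown criterion"))
    for disease_id, row in m.scores.iterrows():
        for criterion, value in row.items():
            if pd.isna(value):
                continue
            v = float(value)
            if not v.is_integer():
                out.append(Violation(str(disease_id), str(criterion), v, "noninteger"))
            elif not SCORE_MIN <= v <= SCORE_MAX:
                out.append(Violation(str(disease_id), str(criterion), v, "out of range"))
    return out


def check_aligned(a: ScoreMatrix, b: ScoreMatrix, *more: ScoreMatrix) -> None:
    """Raise :class:`GridMismatchError` unless all matrices share one grid."""
    ref = a
    for other in (b, *more):
        missing_rows = set(ref.disease_ids) ^ set(other.disease_ids)
        missing_cols = set(ref.criteria) ^ set(other.criteria)
        if missing_rows or missing_cols:
            raise GridMismatchError(
                f"score grids of {ref.rater_id!r} and {other.rater_id!r} differ; "
                f"mismatched diseases: {sorted(missing_rows)}; "
                f"mismatched criteria: {sorted(missing_cols)}"
            )


def require_complete(*matrices: ScoreMatrix) -> None:
    """Refuse matrices with missing cells (no imputation anywhere downstream)."""
    for m in matrices:
        if not m.is_complete():
            na = m.scores.isna()
            cells = [
                (str(i), str(c))
                for i, row in na.iterrows()
                for c, v in row.items() if v
            ]
            raise GridMismatchError(
                f"matrix {m.rater_id!r} has {len(cells)} missing cell(s), "
                f"e.g. {cells[:3]}; downstream statistics refuse missing data"
            )
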