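"""Rater abstraction: prompt assembly, reply parsing, audit loop, mock rater.

The scoring method treats an LLM as just another rater: for each
(disease, criterion) cell it renders a system + user prompt, expects back a
JSON object ``{"response": <int 1-5>}``, audits the reply, and re-queries a
cell at most once (by default) when the reply fails the audit.  Everything is
exercisable offline: a scripted fixture rater replays recorded replies, and
:func:`mock_rate` perturbs an existing score matrix with a controlled
disagreement profile to emulate a second (human or machine) rater.

Temperature 0 is the default to minimise sampling variability; note that even
at temperature 0 replies may vary across model versions, which is why the
audit loop, not the adapter, owns correctness.
"""

from __future__ import annotations

import abc
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .criteria import Criterion
from .exceptions import ConfigError, PromptError
from .registry import DiseaseRecord
from .rubric import CategoricalRubric, NumericRubric, RubricConfig, default_rubric
from .scores import ScoreMatrix

_PLACEHOLDER_RE = re.compile(r"\{([a-z_0-9]+)\}")

DEFAULT_SYSTEM_TEMPLATE = (
    "You are a medical doctor and Professor of Epidemiology trying to "
    "determine the unmet medical need for a disease. You wish to do this to "
    "determine the priority of diseases for research and development.\n\n"
    "For each disease name, extract the following feature:\n"
    '"{new_feature_name}: {feature_description}".\n\n'
    'Return ONLY a JSON object with the key "response" and the extracted '
    "values.\nNo explanations or other text."
)

DEFAULT_USER_TEMPLATE = (
    "Output only a number from 1 to 5; 1 = {anchor_1}, 2 = {anchor_2}, "
    "3 = {anchor_3}, 4 = {anchor_4}, 5 = {anchor_5}. "
    "Categorize the {concept} for disease {disease} into the above "
    "categories. {guidance}"
)


@dataclass(frozen=True)
class PromptSpec:
    """Templates for the per-cell system and user prompts."""

    system_template: str = DEFAULT_SYSTEM_TEMPLATE
    user_template: str = DEFAULT_USER_TEMPLATE
    include_synonyms: bool = True
    guidance: str = ""


@dataclass(frozen=True)
class RaterConfig:
    """Rater behaviour knobs (the mock-specific ones are ignored by live raters)."""

    model_name: str = "mock"
    temperature: float = 0.0
    max_regenerations: int = 1
    seed: int | None = None
    #: map |shift| -> probability, e.g. {1: 0.2045, 2: 0.0545}
    disagreement_rates: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ConfigError("temperature must be >= 0")
        if self.max_regenerations < 0:
            raise ConfigError("max_regenerations must be >= 0")
        for k, p in self.disagreement_rates.items():
            if int(k) < 1 or p < 0:
                raise ConfigError(f"bad disagreement rate {k!r}: {p!r}")
        if sum(self.disagreement_rates.values()) > 1 + 1e-12:
            raise ConfigError("disagreement probabilities sum to > 1")


def default_anchor_texts(criterion: Criterion, rubric: RubricConfig | None = None) -> list[str]:
    """Human-readable 1..5 anchor descriptions derived from a rubric rule."""
    rubric = rubric or default_rubric()
    rule = rubric[criterion.name]
    anchors = []
    if isinstance(rule, NumericRubric):
        for s in range(1, 6):
            low, high = rule.band(s)
            unit = rule.attribute.replace("_", " ")
            if high == float("inf"):
                anchors.append(f"{unit} {low:g} or more")
            else:
                anchors.append(f"{unit} at least {low:g} and below {high:g}")
    elif isinstance(rule, CategoricalRubric):
        for s in range(1, 6):
            levels = rule.levels_for(s) or ["(no anchor)"]
            anchors.append("; ".join(lv.replace("_", " ") for lv in levels))
    return anchors


def build_prompt(
    criterion: Criterion,
    disease: DiseaseRecord,
    spec: PromptSpec | None = None,
    anchors: Sequence[str] | None = None,
) -> tuple[str, str]:
    """Render the (system, user) prompt pair for one scoring cell.

    Raises :class:`PromptError` naming the first unresolved placeholder.
    """
    spec = spec or PromptSpec()
    if anchors is None:
        anchors = default_anchor_texts(criterion)
    if len(anchors) != 5:
        raise PromptError(f"need exactly 5 score anchors, got {len(anchors)}")

    disease_text = disease.label
    if spec.include_synonyms and disease.synonyms:
        disease_text += " (also known as: " + "; ".join(disease.synonyms) + ")"

    fields = {
        "new_feature_name": criterion.name,
        "feature_description": criterion.description,
        "concept": criterion.name.lower(),
        "disease": disease_text,
        "guidance": spec.guidance,
        **{f"anchor_{i + 1}": a for i, a in enumerate(anchors)},
    }

    def render(template: str) -> str:
        out = template
        for key, val in fields.items():
            out = out.replace("{" + key + "}", str(val))
        leftover = _PLACEHOLDER_RE.search(out)
        if leftover:
            raise PromptError(f"unresolved placeholder {{{leftover.group(1)}}}")
        return out

    return render(spec.system_template), render(spec.user_template)


class ParseOutcome(NamedTuple):
    """Either an integer score or a typed parse failure (never both)."""

    score: int | None
    failure: str | None  # not-json | missing-key | noninteger | out-of-range

    @property
    def ok(self) -> bool:
        return self.failure is None


def serialize_score(score: int) -> str:
    return json.dumps({"response": int(score)})


def parse_response(text: str) -> ParseOutcome:
    """Parse a raw rater reply into a 1-5 integer score.

    Accepts integer-valued strings ("4") and integer-valued decimals (3.0);
    rejects true non-integers, mirroring the data-type audit of generated
    outputs.
    """
    try:
        obj = json.loads(text)
    except (json.JSONDecodeError, TypeError):
        return ParseOutcome(None, "not-json")
    if not isinstance(obj, dict) or "response" not in obj:
        return ParseOutcome(None, "missing-key")
    raw = obj["response"]
    if isinstance(raw, bool):
        return ParseOutcome(None, "noninteger")
    if isinstance(raw, str):
        try:
            raw = float(raw)
        except ValueError:
            return ParseOutcome(None, "noninteger")
    if isinstance(raw, float):
        if not raw.is_integer():
            return ParseOutcome(None, "noninteger")
        raw = int(raw)
    if not isinstance(raw, int):
        return ParseOutcome(None, "noninteger")
    if not 1 <= raw <= 5:
        return ParseOutcome(None, "out-of-range")
    return ParseOutcome(raw, None)


class LiveAdapter(abc.ABC):
    """Contract for a live LLM backend: one blocking text completion call.

    Implementations own transport, authentication and model selection; the
    package never makes network calls itself and the test suite only ever
    uses recorded fixtures.
    """

    @abc.abstractmethod
    def send(self, system: str, user: str) -> str:  # pragma: no cover - interface
        ...


#: A rater maps a scoring cell to a raw text reply.
RaterFn = Callable[[DiseaseRecord, Criterion], str]


class ScriptedRater:
    """Recorded-fixture rater: replays canned replies per cell, in order.

    ``script`` maps ``(disease_id, criterion_name)`` to a list of raw replies
    consumed one per query; the last reply repeats once exhausted.
    """

    def __init__(self, script: dict[tuple[str, str], list[str]]):
        self.script = {k: list(v) for k, v in script.items()}
        self.query_counts: dict[tuple[str, str], int] = {}

    def __call__(self, disease: DiseaseRecord, criterion: Criterion) -> str:
        key = (disease.id, criterion.name)
        n = self.query_counts.get(key, 0)
        self.query_counts[key] = n + 1
        replies = self.script.get(key, ['{"response": null}'])
        return replies[min(n, len(replies) - 1)]


class AdapterRater:
    """Rater backed by a :class:`LiveAdapter` and a :class:`PromptSpec`."""

    def __init__(self, adapter: LiveAdapter, spec: PromptSpec | None = None):
        self.adapter = adapter
        self.spec = spec or PromptSpec()

    def __call__(self, disease: DiseaseRecord, criterion: Criterion) -> str:
        system, user = build_prompt(criterion, disease, self.spec)
        return self.adapter.send(system, user)


def audit_and_regenerate(
    cells: Sequence[tuple[DiseaseRecord, Criterion]],
    rater: RaterFn,
    config: RaterConfig | None = None,
    rater_id: str = "llm",
) -> tuple[ScoreMatrix, list[dict]]:
    """Query every cell, audit replies, re-query failures at most
    ``config.max_regenerations`` times.

    Returns the (possibly partially complete) score matrix and the audit log:
    one record per query with the cell, attempt number, failure type (or
    None) and whether the cell ended unresolved.  Unresolved cells are left
    missing in the matrix.
    """
    config = config or RaterConfig()
    log: list[dict] = []
    values: dict[tuple[str, str], float] = {}
    diseases: list[str] = []
    criteria: list[str] = []
    for disease, criterion in cells:
        if disease.id not in diseases:
            diseases.append(disease.id)
        if criterion.name not in criteria:
            criteria.append(criterion.name)
        score = np.nan
        for attempt in range(1 + config.max_regenerations):
            reply = rater(disease, criterion)
            outcome = parse_response(reply)
            log.append({
                "disease_id": disease.id, "criterion": criterion.name,
                "attempt": attempt, "failure": outcome.failure,
                "raw": reply, "unresolved": False,
            })
            if outcome.ok:
                score = float(outcome.score)
                break
        else:
            log[-1]["unresolved"] = True
        values[(disease.id, criterion.name)] = score

    table = pd.DataFrame(
        [[values.get((d, c), np.nan) for c in criteria] for d in diseases],
        index=diseases, columns=criteria,
    )
    return ScoreMatrix(rater_id, table), log


def write_audit_log(log: list[dict], path: str | Path) -> None:
    """Audit log as JSONL, one record per query."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for rec in log:
            fh.write(json.dumps(rec) + "\n")


def mock_rate(base: ScoreMatrix, config: RaterConfig, rater_id: str = "mock") -> ScoreMatrix:
    """Emulate a second rater by perturbing ``base`` cell-by-cell.

    With probability ``disagreement_rates[k]`` a cell shifts by +-k (sign
    uniform), otherwise it is unchanged; results are clamped to [1, 5] so the
    perturbed marginal stays on the score scale (a deliberate deviation from
    unbounded noise).  Bit-reproducible for a fixed ``config.seed``; the
    identity when all rates are zero.
    """
    rng = np.random.default_rng(config.seed)
    arr = base.scores.to_numpy(dtype=float)
    u = rng.random(arr.shape)
    signs = rng.integers(0, 2, size=arr.shape) * 2 - 1
    shift = np.zeros(arr.shape)
    lo = 0.0
    for k in sorted(config.disagreement_rates):
        p = config.disagreement_rates[k]
        in_band = (u >= lo) & (u < lo + p)
        shift[in_band] = k
        lo += p
    out = np.clip(arr + shift * signs, 1, 5)
    out[np.isnan(arr)] = np.nan
    return ScoreMatrix(
        rater_id,
        pd.DataFrame(out, index=base.scores.index, columns=base.scores.columns),
    )
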