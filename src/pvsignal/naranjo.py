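"""Naranjo adverse-drug-reaction probability scoring.

The Naranjo scale is a 10-question weighted questionnaire assessing how
likely an adverse event is attributable to a suspect drug.  Each question is
answered yes / no / unknown and contributes the corresponding weight; the
total score maps onto a causality category:

    score >= 9   definite
    5 <= score <= 8   probable
    1 <= score <= 4   possible
    score <= 0   doubtful

The canonical published weights ship as an editable YAML configuration
(``pvsignal/data/naranjo_weights.yaml``); the category cut-offs are fixed.
Case-by-case assessment in practice involves two human raters reaching
consensus — that process is out of scope, but :func:`compare_raters` reports
the per-case disagreements two answer sets produce.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .model import ConfigurationError, FormatError

RESPONSES = ("yes", "no", "unknown")
CATEGORIES = ("doubtful", "possible", "probable", "definite")

#: Canonical question order; answer vectors and weight tables are indexed by it.
QUESTIONS = (
    "previous_conclusive_reports",
    "event_after_drug",
    "improved_on_withdrawal",
    "reappeared_on_rechallenge",
    "alternative_causes",
    "placebo_reaction",
    "toxic_drug_concentration",
    "dose_response",
    "previous_similar_reaction",
    "objective_evidence",
)


@dataclass(frozen=True)
class WeightTable:
    """Per-question (yes, no, unknown) point weights."""

    weights: dict[str, dict[str, int]]

    def __post_init__(self) -> None:
        if set(self.weights) != set(QUESTIONS):
            missing = set(QUESTIONS) - set(self.weights)
            extra = set(self.weights) - set(QUESTIONS)
            raise ConfigurationError(
                f"weight table must cover the 10 canonical questions"
                f" (missing: {sorted(missing)}, unexpected: {sorted(extra)})")
        for q, row in self.weights.items():
            if set(row) != set(RESPONSES):
                raise ConfigurationError(
                    f"question {q!r} must weight exactly {RESPONSES}")

    @property
    def min_score(self) -> int:
        return sum(min(row.values()) for row in self.weights.values())

    @property
    def max_score(self) -> int:
        return sum(max(row.values()) for row in self.weights.values())


def load_weights(path: str | Path | None = None) -> WeightTable:
    """Load a weight table; with no path, the canonical packaged weights."""
    if path is None:
        text = (resources.files("pvsignal") / "data" / "naranjo_weights.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    try:
        rows = {q["id"]: {r: int(q[r]) for r in RESPONSES} for q in raw["questions"]}
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed weight table: {exc}") from exc
    return WeightTable(rows)


def score_case(answers: Mapping[str, str] | Sequence[str],
               weights: WeightTable | None = None) -> int:
    """Sum the response-selected weights over the 10 questions.

    ``answers`` is either a mapping question-id → response or a sequence of
    10 responses in canonical question order.
    """
    weights = weights or load_weights()
    if not isinstance(answers, Mapping):
        if len(answers) != len(QUESTIONS):
            raise ConfigurationError(
                f"expected {len(QUESTIONS)} responses, got {len(answers)}")
        answers = dict(zip(QUESTIONS, answers))
    missing = set(QUESTIONS) - set(answers)
    if missing:
        raise ConfigurationError(f"missing response(s) for: {sorted(missing)}")
    score = 0
    for q in QUESTIONS:
        response = str(answers[q]).strip().lower()
        if response not in RESPONSES:
            raise ConfigurationError(
                f"response for {q!r} must be one of {RESPONSES}, got {answers[q]!r}")
        score += weights.weights[q][response]
    return score


def categorize(score: int) -> str:
    """Map a total score onto the published causality cut-offs."""
    if score >= 9:
        return "definite"
    if score >= 5:
        return "probable"
    if score >= 1:
        return "possible"
    return "doubtful"


def assess_cases(cases: pd.DataFrame | str | Path,
                 weights: WeightTable | None = None
                 ) -> tuple[pd.DataFrame, pd.Series]:
    """Score a table of cases and tally causality categories.

    ``cases`` is a DataFrame or CSV with a ``case_id`` column and one column
    per canonical question (extra columns are carried through untouched).
    Returns the per-case result table (with ``score`` and ``category``
    appended) and a category histogram indexed doubtful → definite.
    """
    weights = weights or load_weights()
    if not isinstance(cases, pd.DataFrame):
        cases = pd.read_csv(cases, dtype=str, keep_default_na=False)
    missing = [q for q in QUESTIONS if q not in cases.columns]
    if missing:
        raise FormatError(f"cases table missing response column(s): {', '.join(missing)}")
    out = cases.copy()
    scores = [
        score_case({q: row[q] for q in QUESTIONS}, weights)
        for row in cases.to_dict("records")
    ]
    out["score"] = scores
    out["category"] = [categorize(s) for s in scores]
    hist = (out["category"].value_counts().reindex(CATEGORIES).fillna(0).astype(int))
    return out, hist


def compare_raters(first: pd.DataFrame, second: pd.DataFrame,
                   weights: WeightTable | None = None) -> pd.DataFrame:
    """Per-case category comparison of two raters' answer sets.

    Both tables must share ``case_id``.  Returns one row per case with each
    rater's score and category and a ``disagree`` flag; no automated
    resolution is attempted.
    """
    weights = weights or load_weights()
    a, _ = assess_cases(first, weights)
    b, _ = assess_cases(second, weights)
    merged = a[["case_id", "score", "category"]].merge(
        b[["case_id", "score", "category"]], on="case_id",
        suffixes=("_rater1", "_rater2"), validate="one_to_one")
    merged["disagree"] = merged["category_rater1"] != merged["category_rater2"]
    return merged
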