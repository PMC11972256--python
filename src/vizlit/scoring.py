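"""Grading raw responses into the binary error matrix.

The analysis operates on an m x n error matrix X (items x participants,
1 = incorrect) together with the vector of per-item error means mu.  This
module turns long-format response records into that matrix:

* :func:`grade_response` — one item, one response, one {0,1} flag.  Fill-in
  responses are normalized (trimmed, lowercased, thousands separators
  stripped) and compared numerically when both sides parse as numbers; the
  one interval-graded item accepts any value in its closed tolerance range.
  A skipped item is scored as an error — the source instruments define no
  partial credit, and this choice is applied uniformly (documented in the
  methods note).
* :func:`filter_complete` — participant exclusions: a participant is retained
  only with exactly one response per bank item and a complete demographics
  row.
* :func:`build_error_matrix` / :func:`participant_scores` — assemble X and
  summarize per-participant accuracy (1 minus mean error).

Row order is bank order; column order is first appearance of each
participant id in the response stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .item_bank import AssessmentBank, ItemSpec

__all__ = [
    "SKIP",
    "ResponseRecord",
    "ErrorMatrix",
    "ScoringError",
    "grade_response",
    "filter_complete",
    "build_error_matrix",
    "participant_scores",
    "read_responses",
    "read_demographics",
]

#: sentinel for a skipped item; the CSV dialect accepts an empty field or
#: the literal string "SKIP" (case-insensitive)
SKIP = "SKIP"


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ResponseRecord:
    participant_id: str
    item_id: str
    response: str  # raw response text, or SKIP


@dataclass
class ErrorMatrix:
    """Binary error matrix X (m items x n participants) with item means mu."""

    X: np.ndarray
    item_order: list[str]
    participant_order: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        m, n = self.X.shape
        if m != len(self.item_order) or n != len(self.participant_order):
            raise ScoringError("matrix dimensions do not match id orders")
        if not np.isin(self.X, (0.0, 1.0)).all():
            raise ScoringError("error matrix entries must be 0 or 1")

    @property
    def mu(self) -> np.ndarray:
        """Per-item error means (row means of X)."""
        return self.X.mean(axis=1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.X, index=self.item_order, columns=self.participant_order
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index_label="item_id")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "ErrorMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(float), list(df.index), list(df.columns))


def _is_skip(response: str | None) -> bool:
    if response is None:
        return True
    s = str(response).strip()
    return s == "" or s.upper() == SKIP


def _normalize(text: str) -> str:
    return str(text).strip().lower().replace(",", "")


def _try_float(text: str) -> float | None:
    s = _normalize(text).rstrip("%")
    try:
        return float(s)
    except ValueError:
        return None


def grade_response(item: ItemSpec, response: str | None) -> int:
    """Grade one response against ``item``; return 0 (correct) or 1 (error).

    Raises :class:`ScoringError` if a non-skippable item is skipped.  An
    unparseable numeric answer on a fill-in item is an ordinary error, not
    an exception.
    """
    if _is_skip(response):
        if not item.skippable:
            raise ScoringError(
                f"item {item.item_id} is not skippable but response is SKIP"
            )
        return 1
    resp = str(response)
    if item.tolerance is not None:
        val = _try_float(resp)
        if val is None:
            return 1
        lo, hi = item.tolerance
        return 0 if lo <= val <= hi else 1
    key_num = _try_float(item.answer_key)
    resp_num = _try_float(resp)
    if key_num is not None and resp_num is not None:
        return 0 if resp_num == key_num else 1
    return 0 if _normalize(resp) == _normalize(item.answer_key) else 1


def filter_complete(
    responses: Iterable[ResponseRecord],
    bank: AssessmentBank,
    demographics: pd.DataFrame,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the completeness exclusions.

    Returns ``(retained_ids, exclusion_log)``; the log has one row per
    excluded participant with columns (participant_id, reason).  Retained
    participants have exactly one response per bank item and a demographics
    row with non-null ``sample_group`` and ``math_courses``.
    """
    item_ids = set(bank.item_ids)
    by_participant: dict[str, dict[str, int]] = {}
    order: list[str] = []
    for rec in responses:
        if rec.item_id not in item_ids:
            raise ScoringError(
                f"response references unknown item {rec.item_id!r}"
            )
        slot = by_participant.setdefault(rec.participant_id, {})
        if rec.participant_id not in order:
            pass
        if not slot:
            order.append(rec.participant_id)
        slot[rec.item_id] = slot.get(rec.item_id, 0) + 1

    demo = demographics.set_index(demographics["participant_id"].astype(str))
    retained: list[str] = []
    log_rows: list[dict] = []
    for pid in order:
        seen = by_participant[pid]
        missing = item_ids - set(seen)
        dup = [iid for iid, c in seen.items() if c > 1]
        if dup:
            log_rows.append(
                {"participant_id": pid, "reason": f"duplicate responses: {sorted(dup)[:3]}"}
            )
            continue
        if missing:
            log_rows.append(
                {
                    "participant_id": pid,
                    "reason": f"incomplete assessment ({len(missing)} items missing)",
                }
            )
            continue
        if pid not in demo.index:
            log_rows.append(
                {"participant_id": pid, "reason": "no demographics row"}
            )
            continue
        row = demo.loc[pid]
        if pd.isna(row.get("sample_group")) or pd.isna(row.get("math_courses")):
            log_rows.append(
                {"participant_id": pid, "reason": "incomplete demographics"}
            )
            continue
        retained.append(pid)
    log = pd.DataFrame(log_rows, columns=["participant_id", "reason"])
    return retained, log


def build_error_matrix(
    bank: AssessmentBank,
    responses: Iterable[ResponseRecord],
    participant_ids: Sequence[str] | None = None,
) -> ErrorMatrix:
    """Grade ``responses`` into an error matrix in bank row order.

    ``participant_ids`` restricts and orders the columns; by default all
    participants are used in first-appearance order.  Every (retained
    participant, item) cell must be covered exactly once.
    """
    records = list(responses)
    if participant_ids is None:
        participant_ids = list(dict.fromkeys(r.participant_id for r in records))
    keep = set(participant_ids)
    cell: dict[tuple[str, str], str] = {}
    for rec in records:
        if rec.participant_id not in keep:
            continue
        key = (rec.participant_id, rec.item_id)
        if key in cell:
            raise ScoringError(
                f"duplicate response for participant {rec.participant_id!r}, "
                f"item {rec.item_id!r}"
            )
        cell[key] = rec.response

    m, n = len(bank), len(participant_ids)
    X = np.empty((m, n))
    for i, item in enumerate(bank):
        for j, pid in enumerate(participant_ids):
            key = (pid, item.item_id)
            if key not in cell:
                raise ScoringError(
                    f"missing response for participant {pid!r}, item "
                    f"{item.item_id!r}"
                )
            X[i, j] = grade_response(item, cell[key])
    return ErrorMatrix(X, list(bank.item_ids), list(participant_ids))


def participant_scores(
    matrix: ErrorMatrix, bank: AssessmentBank, subset: str | None = None
) -> np.ndarray:
    """Per-participant accuracy (1 - mean error), optionally over one test."""
    if subset is None:
        rows = np.arange(len(bank))
    else:
        rows = np.array(
            [i for i, it in enumerate(bank) if it.test == subset], dtype=int
        )
        if rows.size == 0:
            raise ScoringError(f"no items in subset {subset!r}")
    if list(matrix.item_order) != list(bank.item_ids):
        raise ScoringError("matrix item order does not match bank")
    return 1.0 - matrix.X[rows].mean(axis=0)


# ---------------------------------------------------------------------------
# CSV dialects.
# ---------------------------------------------------------------------------

def read_responses(path: str | Path) -> list[ResponseRecord]:
    """Read long-format responses (participant_id,item_id,response).

    An empty response field or the literal "SKIP" is a skip.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"participant_id", "item_id", "response"}
    if not required.issubset(df.columns):
        raise ScoringError(
            f"responses file {path} must have columns {sorted(required)}"
        )
    return [
        ResponseRecord(str(r.participant_id), str(r.item_id), str(r.response))
        for r in df.itertuples(index=False)
    ]


def read_demographics(path: str | Path) -> pd.DataFrame:
    """Read demographics (participant_id, sample_group, math_courses)."""
    df = pd.read_csv(path)
    required = {"participant_id", "sample_group", "math_courses"}
    if not required.issubset(df.columns):
        raise ScoringError(
            f"demographics file {path} must have columns {sorted(required)}"
        )
    df["participant_id"] = df["participant_id"].astype(str)
    return df
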