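"""Structural metadata for visualization-literacy item banks.

The combined instrument studied here joins two published assessments:

* **GGR** — a 13-item graph-literacy scale whose items are organized into a
  three-level hierarchy (read the data / read between the data / read beyond
  the data) across four graph types (bar, line, pie, icon array).
* **VLAT** — a 53-item visualization-literacy test whose items are organized
  into eight task types across twelve graph types.

Together the 66 items span 13 distinct graph types and 11 distinct question
types; those three taxonomies (test, graph type, question type) are the
"facets" every downstream analysis indexes into.  The canonical label
spellings and their ordering are frozen here so that every matrix built by
the rest of the package inherits a reproducible row ordering.

The built-in :func:`combined_bank` fixture carries the structural layout of
the combined instrument (counts per test, response format, graph and question
type) with placeholder answer keys.  The per-item level/task assignment is a
structurally faithful stand-in, not the copyrighted item text or true keys;
users analysing real administrations should load their own bank via
:func:`load_item_bank`.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "TESTS",
    "GRAPH_TYPES",
    "QUESTION_TYPES",
    "GGR_QUESTION_TYPES",
    "VLAT_QUESTION_TYPES",
    "RESPONSE_FORMATS",
    "FACETS",
    "ItemSpec",
    "AssessmentBank",
    "BankValidationError",
    "combined_bank",
    "load_item_bank",
    "save_item_bank",
    "category_inventory",
]

# ---------------------------------------------------------------------------
# Canonical label tables.  Order is frozen: matrices inherit it.
# ---------------------------------------------------------------------------

TESTS: tuple[str, ...] = ("GGR", "VLAT")

GRAPH_TYPES: tuple[str, ...] = (
    "bar",
    "line",
    "pie",
    "icon_array",
    "stacked_bar",
    "pct_stacked_bar",
    "histogram",
    "scatter",
    "bubble",
    "area",
    "stacked_area",
    "choropleth_map",
    "treemap",
)

GGR_QUESTION_TYPES: tuple[str, ...] = ("read_data", "read_between", "read_beyond")
VLAT_QUESTION_TYPES: tuple[str, ...] = (
    "retrieve_value",
    "find_extremum",
    "find_anomalies",
    "make_comparisons",
    "determine_range",
    "find_correlations_trends",
    "characterize_distribution",
    "find_clusters",
)
QUESTION_TYPES: tuple[str, ...] = GGR_QUESTION_TYPES + VLAT_QUESTION_TYPES

RESPONSE_FORMATS: tuple[str, ...] = ("fill_in", "mc3", "mc4", "true_false")

#: graph types each test may use
_GGR_GRAPHS = frozenset({"bar", "line", "pie", "icon_array"})
_VLAT_GRAPHS = frozenset(GRAPH_TYPES) - {"icon_array"}

FACETS: tuple[str, ...] = ("test", "graph_type", "question_type")


class BankValidationError(ValueError):
    """Raised when an item bank violates a structural invariant."""


@dataclass(frozen=True)
class ItemSpec:
    """One assessment item: taxonomy membership, format and grading key.

    ``tolerance``, when present, is a closed numeric interval ``(lo, hi)``;
    any fill-in response parsing to a number inside it is graded correct.
    """

    item_id: str
    test: str
    graph_type: str
    question_type: str
    response_format: str
    answer_key: str
    tolerance: tuple[float, float] | None = None
    skippable: bool = True

    def validate(self) -> None:
        if self.test not in TESTS:
            raise BankValidationError(f"unknown test label {self.test!r}")
        if self.graph_type not in GRAPH_TYPES:
            raise BankValidationError(f"unknown graph type {self.graph_type!r}")
        if self.question_type not in QUESTION_TYPES:
            raise BankValidationError(
                f"unknown question type {self.question_type!r}"
            )
        if self.response_format not in RESPONSE_FORMATS:
            raise BankValidationError(
                f"unknown response format {self.response_format!r}"
            )
        if self.test == "GGR":
            if self.question_type not in GGR_QUESTION_TYPES:
                raise BankValidationError(
                    f"GGR item {self.item_id} has non-GGR question type "
                    f"{self.question_type!r}"
                )
            if self.graph_type not in _GGR_GRAPHS:
                raise BankValidationError(
                    f"GGR item {self.item_id} uses graph type "
                    f"{self.graph_type!r} outside the GGR set"
                )
            if self.response_format == "true_false":
                raise BankValidationError(
                    f"true_false format is VLAT-only (item {self.item_id})"
                )
        else:
            if self.question_type not in VLAT_QUESTION_TYPES:
                raise BankValidationError(
                    f"VLAT item {self.item_id} has non-VLAT question type "
                    f"{self.question_type!r}"
                )
            if self.response_format == "fill_in":
                raise BankValidationError(
                    f"fill_in format is GGR-only (item {self.item_id})"
                )
        if self.tolerance is not None:
            lo, hi = self.tolerance
            if not lo <= hi:
                raise BankValidationError(
                    f"item {self.item_id}: tolerance interval [{lo}, {hi}] is empty"
                )


@dataclass
class AssessmentBank:
    """An ordered collection of items.  Item order defines matrix row order."""

    items: list[ItemSpec]
    name: str = "bank"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.items:
            raise BankValidationError("item bank is empty")
        seen: set[str] = set()
        n_tol_ggr = 0
        for item in self.items:
            item.validate()
            if item.item_id in seen:
                raise BankValidationError(f"duplicate item_id {item.item_id!r}")
            seen.add(item.item_id)
            if item.test == "GGR" and item.tolerance is not None:
                n_tol_ggr += 1
        if n_tol_ggr > 1:
            raise BankValidationError(
                f"at most one GGR item may carry a tolerance interval "
                f"(found {n_tol_ggr})"
            )

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def item(self, item_id: str) -> ItemSpec:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def subset(self, test: str) -> "AssessmentBank":
        """Bank restricted to one test, preserving order."""
        if test not in TESTS:
            raise BankValidationError(f"unknown test label {test!r}")
        return AssessmentBank(
            [it for it in self.items if it.test == test],
            name=f"{self.name}:{test}",
        )


# ---------------------------------------------------------------------------
# Built-in combined fixture.
#
# The layout below reproduces every published structural count of the
# combined instrument (13 GGR + 53 VLAT items; 9 fill-in + 4 three-option MC
# in GGR; 16 true-false + 3 three-option + 34 four-option MC in VLAT; one
# GGR fill-in item graded against a numeric interval).  The item-by-item
# level/task assignment is a placeholder consistent with those counts —
# NOT the copyrighted original items or answer keys.
# ---------------------------------------------------------------------------

# (graph_type, question_type, response_format) per GGR item, in order.
_GGR_LAYOUT: list[tuple[str, str, str]] = [
    ("line", "read_data", "fill_in"),
    ("line", "read_between", "fill_in"),
    ("line", "read_beyond", "fill_in"),  # the interval-graded item
    ("bar", "read_data", "fill_in"),
    ("bar", "read_between", "fill_in"),
    ("bar", "read_data", "fill_in"),
    ("bar", "read_between", "fill_in"),
    ("pie", "read_data", "fill_in"),
    ("line", "read_between", "fill_in"),
    ("line", "read_beyond", "mc3"),
    ("bar", "read_beyond", "mc3"),
    ("icon_array", "read_between", "mc3"),
    ("line", "read_beyond", "mc3"),
]

# (question_type, response_format) per VLAT item, grouped per graph.
_VLAT_LAYOUT: list[tuple[str, list[tuple[str, str]]]] = [
    ("line", [
        ("retrieve_value", "mc3"),
        ("find_extremum", "true_false"),
        ("determine_range", "true_false"),
        ("find_correlations_trends", "mc4"),
        ("make_comparisons", "mc4"),
    ]),
    ("bar", [
        ("retrieve_value", "mc4"),
        ("find_extremum", "true_false"),
        ("determine_range", "true_false"),
        ("make_comparisons", "mc4"),
        ("make_comparisons", "mc4"),
    ]),
    ("stacked_bar", [
        ("retrieve_value", "mc4"),
        ("retrieve_value", "mc4"),
        ("find_extremum", "true_false"),
        ("make_comparisons", "mc4"),
        ("make_comparisons", "mc4"),
    ]),
    ("pct_stacked_bar", [
        ("retrieve_value", "mc4"),
        ("find_extremum", "true_false"),
        ("make_comparisons", "mc4"),
        ("make_comparisons", "mc4"),
    ]),
    ("pie", [
        ("retrieve_value", "mc3"),
        ("find_extremum", "true_false"),
        ("make_comparisons", "mc3"),
    ]),
    ("histogram", [
        ("retrieve_value", "mc4"),
        ("find_extremum", "true_false"),
        ("characterize_distribution", "mc4"),
        ("characterize_distribution", "mc4"),
    ]),
    ("scatter", [
        ("retrieve_value", "mc4"),
        ("find_extremum", "true_false"),
        ("find_anomalies", "mc4"),
        ("find_clusters", "mc4"),
        ("find_correlations_trends", "mc4"),
    ]),
    ("bubble", [
        ("retrieve_value", "mc4"),
        ("find_extremum", "true_false"),
        ("find_anomalies", "mc4"),
        ("find_clusters", "mc4"),
        ("find_correlations_trends", "mc4"),
    ]),
    ("area", [
        ("retrieve_value", "mc4"),
        ("find_extremum", "true_false"),
        ("determine_range", "true_false"),
        ("make_comparisons", "mc4"),
    ]),
    ("stacked_area", [
        ("retrieve_value", "mc4"),
        ("find_extremum", "true_false"),
        ("make_comparisons", "mc4"),
        ("find_correlations_trends", "mc4"),
        ("characterize_distribution", "mc4"),
    ]),
    ("choropleth_map", [
        ("retrieve_value", "mc4"),
        ("find_extremum", "true_false"),
        ("determine_range", "true_false"),
        ("find_anomalies", "mc4"),
    ]),
    ("treemap", [
        ("retrieve_value", "mc4"),
        ("find_extremum", "true_false"),
        ("make_comparisons", "mc4"),
        ("find_clusters", "mc4"),
    ]),
]

_PLACEHOLDER_KEYS = {"mc3": "b", "mc4": "c", "true_false": "true"}


def combined_bank() -> AssessmentBank:
    """The built-in 66-item combined GGR + VLAT fixture (placeholder keys)."""
    items: list[ItemSpec] = []
    for k, (graph, qtype, fmt) in enumerate(_GGR_LAYOUT, start=1):
        if fmt == "fill_in":
            key = "24" if k == 3 else str(10 * k)
            tol = (23.0, 25.0) if k == 3 else None
        else:
            key = _PLACEHOLDER_KEYS[fmt]
            tol = None
        items.append(
            ItemSpec(
                item_id=f"ggr_{k:02d}",
                test="GGR",
                graph_type=graph,
                question_type=qtype,
                response_format=fmt,
                answer_key=key,
                tolerance=tol,
                skippable=fmt != "fill_in",
            )
        )
    k = 0
    for graph, qs in _VLAT_LAYOUT:
        for qtype, fmt in qs:
            k += 1
            items.append(
                ItemSpec(
                    item_id=f"vlat_{k:02d}",
                    test="VLAT",
                    graph_type=graph,
                    question_type=qtype,
                    response_format=fmt,
                    answer_key=_PLACEHOLDER_KEYS[fmt],
                    skippable=True,
                )
            )
    return AssessmentBank(items, name="combined_ggr_vlat")


# ---------------------------------------------------------------------------
# Serialization: JSON (native) and CSV (one row per item).
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "item_id",
    "test",
    "graph_type",
    "question_type",
    "response_format",
    "answer_key",
    "tolerance_low",
    "tolerance_high",
    "skippable",
]


def _item_from_record(rec: dict) -> ItemSpec:
    tol = None
    if rec.get("tolerance") is not None:
        lo, hi = rec["tolerance"]
        tol = (float(lo), float(hi))
    return ItemSpec(
        item_id=str(rec["item_id"]),
        test=str(rec["test"]),
        graph_type=str(rec["graph_type"]),
        question_type=str(rec["question_type"]),
        response_format=str(rec["response_format"]),
        answer_key=str(rec["answer_key"]),
        tolerance=tol,
        skippable=bool(rec.get("skippable", True)),
    )


def load_item_bank(path: str | Path) -> AssessmentBank:
    """Load and validate an item bank from a JSON or CSV file.

    JSON schema: ``{"name": str, "items": [{item_id, test, graph_type,
    question_type, response_format, answer_key, tolerance?, skippable?}]}``.
    CSV: one row per item with columns ``item_id,test,graph_type,
    question_type,response_format,answer_key,tolerance_low,tolerance_high,
    skippable`` (tolerance columns may be blank).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise BankValidationError(f"cannot parse {path}: {exc}") from exc
        if not isinstance(payload, dict) or "items" not in payload:
            raise BankValidationError(
                f"{path}: expected an object with an 'items' list"
            )
        items = [_item_from_record(rec) for rec in payload["items"]]
        return AssessmentBank(items, name=str(payload.get("name", path.stem)))
    # CSV fallback
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        items = []
        for row in reader:
            lo, hi = row.get("tolerance_low", ""), row.get("tolerance_high", "")
            rec = dict(row)
            rec["tolerance"] = (lo, hi) if lo.strip() and hi.strip() else None
            skip = row.get("skippable", "true").strip().lower()
            rec["skippable"] = skip in {"1", "true", "yes"}
            items.append(_item_from_record(rec))
    return AssessmentBank(items, name=path.stem)


def save_item_bank(bank: AssessmentBank, path: str | Path) -> Path:
    """Write a bank to JSON or CSV (by extension); round-trips with load."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "name": bank.name,
            "items": [
                {k: v for k, v in asdict(it).items() if v is not None}
                for it in bank.items
            ],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_COLUMNS)
            for it in bank.items:
                lo, hi = it.tolerance if it.tolerance else ("", "")
                writer.writerow(
                    [
                        it.item_id,
                        it.test,
                        it.graph_type,
                        it.question_type,
                        it.response_format,
                        it.answer_key,
                        lo,
                        hi,
                        str(it.skippable).lower(),
                    ]
                )
    return path


# ---------------------------------------------------------------------------
# Facet inventories.
# ---------------------------------------------------------------------------

_FACET_ORDER = {
    "test": TESTS,
    "graph_type": GRAPH_TYPES,
    "question_type": QUESTION_TYPES,
}


def facet_labels(bank: AssessmentBank, facet: str) -> list[str]:
    """Labels of ``facet`` present in ``bank``, in canonical order."""
    if facet not in _FACET_ORDER:
        raise ValueError(f"unknown facet {facet!r}; expected one of {FACETS}")
    present = {getattr(it, facet) for it in bank.items}
    return [lab for lab in _FACET_ORDER[facet] if lab in present]


def category_inventory(bank: AssessmentBank, facet: str) -> dict[str, int]:
    """Item counts per category of ``facet``, keys in canonical order."""
    labels = facet_labels(bank, facet)
    counts = {lab: 0 for lab in labels}
    for it in bank.items:
        counts[getattr(it, facet)] += 1
    return counts
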