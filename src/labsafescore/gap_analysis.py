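"""Improvement planning: what the next rubric level asks of each weak item.

Every answered subcategory below level 4 yields a gap item carrying the
practice text of the next level up. Blank subcategories are surfaced in a
separate "unassessed" section (pointed at the level-1 text to establish a
baseline) rather than silently dropped. Items are ordered weakest category
first (ascending category percent, then instrument order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .scoring import Assessment, ScoreReport, score_assessment
from .taxonomy import Taxonomy

__all__ = ["GapItem", "GapReport", "gap_report", "format_gap_plan"]


@dataclass(frozen=True)
class GapItem:
    subcategory_id: str
    subcategory_name: str
    category_id: str
    current_level: int | None          # None for unassessed (Blank) items
    next_level: int
    next_practice_text: str
    category_percent: float | None
    unassessed: bool = False

    def to_dict(self) -> dict:
        return {
            "subcategory_id": self.subcategory_id,
            "subcategory_name": self.subcategory_name,
            "category_id": self.category_id,
            "current_level": self.current_level,
            "next_level": self.next_level,
            "next_practice_text": self.next_practice_text,
            "category_percent": self.category_percent,
            "unassessed": self.unassessed,
        }


@dataclass
class GapReport:
    label: str
    taxonomy: str
    policy: str
    items: list[GapItem]          # answered below level 4
    unassessed: list[GapItem]     # blank, flagged "establish baseline"
    n_optimal: int                # answered at level 4
    n_not_applicable: int
    score: ScoreReport

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "taxonomy": self.taxonomy,
            "policy": self.policy,
            "items": [i.to_dict() for i in self.items],
            "unassessed": [i.to_dict() for i in self.unassessed],
            "n_optimal": self.n_optimal,
            "n_not_applicable": self.n_not_applicable,
        }


def gap_report(a: Assessment, t: Taxonomy,
               policy: str = "exclude") -> GapReport:
    """Build the improvement plan for one assessment.

    Pure function of (assessment, taxonomy, policy): identical inputs give
    identical reports.
    """
    report = score_assessment(a, t, policy)
    cat_percent = {s.scope: s.percent for s in report.per_category}

    items: list[GapItem] = []
    unassessed: list[GapItem] = []
    n_optimal = 0
    n_na = 0

    order: dict[str, int] = {}
    for cat in t.iter_categories():
        for sid in cat.subcategory_ids:
            order[sid] = len(order)
            sub = t.subcategory(sid)
            v = a.value_for(sid)
            if v == "NA":
                n_na += 1
            elif v is None:
                unassessed.append(GapItem(
                    subcategory_id=sid,
                    subcategory_name=sub.name,
                    category_id=cat.id,
                    current_level=None,
                    next_level=1,
                    next_practice_text=sub.practice(1),
                    category_percent=cat_percent[cat.id],
                    unassessed=True,
                ))
            elif v == 4:
                n_optimal += 1
            else:
                items.append(GapItem(
                    subcategory_id=sid,
                    subcategory_name=sub.name,
                    category_id=cat.id,
                    current_level=v,
                    next_level=v + 1,
                    next_practice_text=sub.practice(v + 1),
                    category_percent=cat_percent[cat.id],
                ))

    def sort_key(item: GapItem):
        p = item.category_percent
        return (p if p is not None else math.inf, order[item.subcategory_id])

    items.sort(key=sort_key)
    unassessed.sort(key=sort_key)

    return GapReport(
        label=a.label,
        taxonomy=t.ref,
        policy=report.policy,
        items=items,
        unassessed=unassessed,
        n_optimal=n_optimal,
        n_not_applicable=n_na,
        score=report,
    )


def format_gap_plan(report: GapReport, t: Taxonomy) -> str:
    """Human-readable plan grouped by category, weakest first."""
    lines = [f"Improvement plan — {report.label} "
             f"(policy: {report.policy})", ""]

    def emit(section: str, items: list[GapItem]) -> None:
        if not items:
            return
        lines.append(section)
        current_cat = None
        for item in items:
            if item.category_id != current_cat:
                current_cat = item.category_id
                cat = t.category(item.category_id)
                pct = ("N/A" if item.category_percent is None
                       else f"{item.category_percent:.1f}")
                lines.append(f"  {cat.name} — category score {pct}")
            if item.unassessed:
                lines.append(
                    f"    - {item.subcategory_name}: unassessed; establish "
                    f"baseline at level 1: {item.next_practice_text}")
            else:
                lines.append(
                    f"    - {item.subcategory_name}: level "
                    f"{item.current_level} -> {item.next_level}: "
                    f"{item.next_practice_text}")
        lines.append("")

    if not report.items and not report.unassessed:
        lines.append("No gaps: every assessed subcategory is at the optimum "
                     "level.")
        lines.append("")
    emit("Gaps (answered below optimum):", report.items)
    emit("Unassessed (left blank):", report.unassessed)
    lines.append(f"At optimum: {report.n_optimal}   "
                 f"Not applicable: {report.n_not_applicable}")
    return "\n".join(lines)
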