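"""Align repeat assessments of one laboratory and measure progress/agreement."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import ComparisonError
from .scoring import Assessment, ScoreReport, score_assessment
from .taxonomy import Taxonomy

__all__ = ["ComparisonReport", "ConcordanceSummary", "compare", "concordance"]

#: The spreadsheet exchange format holds at most this many assessments;
#: the library itself accepts any number >= 2.
WORKBOOK_MAX_ASSESSMENTS = 3


@dataclass
class ComparisonReport:
    """Per-scope score series for >=2 assessments, with deltas vs the first."""

    labels: list[str]
    taxonomy: str
    policy: str
    scopes: list[str]                           # taxonomy order, "overall" first
    per_scope_series: dict[str, list[float | None]]
    deltas: dict[str, list[float | None]]       # deltas[scope][i] = s[i]-s[0]
    completion_series: list[float]
    confidence_series: list[str]
    reports: list[ScoreReport]

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "taxonomy": self.taxonomy,
            "policy": self.policy,
            "scopes": self.scopes,
            "per_scope_series": self.per_scope_series,
            "deltas": self.deltas,
            "completion_series": self.completion_series,
            "confidence_series": self.confidence_series,
        }


@dataclass(frozen=True)
class ConcordanceSummary:
    """Item-level agreement between two assessors over shared answered items."""

    n_both_answered: int
    n_agree: int
    proportion_agreement: float | None   # None when no shared answered items
    diff_histogram: dict[int, int]       # |level difference| -> count

    def to_dict(self) -> dict:
        return {
            "n_both_answered": self.n_both_answered,
            "n_agree": self.n_agree,
            "proportion_agreement": self.proportion_agreement,
            "diff_histogram": {str(k): v
                               for k, v in sorted(self.diff_histogram.items())},
        }


def compare(assessments: Sequence[Assessment], t: Taxonomy,
            policy: str = "exclude") -> ComparisonReport:
    """Score each assessment against ``t`` and align the results by scope.

    Deltas are relative to the first (baseline) assessment; a pair with an
    Undefined member yields an Undefined (None) delta.
    """
    if len(assessments) < 2:
        raise ComparisonError(
            f"need at least 2 assessments to compare, got {len(assessments)}")
    reports = [score_assessment(a, t, policy) for a in assessments]

    scopes = (["overall"] + [a.id for a in t.areas]
              + [c.id for c in t.iter_categories()])
    series: dict[str, list[float | None]] = {s: [] for s in scopes}
    for r in reports:
        pm = r.scope_percent_map()
        for s in scopes:
            series[s].append(pm[s])

    deltas: dict[str, list[float | None]] = {}
    for s in scopes:
        base = series[s][0]
        deltas[s] = [
            (v - base) if (v is not None and base is not None) else None
            for v in series[s]
        ]

    return ComparisonReport(
        labels=[r.label for r in reports],
        taxonomy=t.ref,
        policy=reports[0].policy,
        scopes=scopes,
        per_scope_series=series,
        deltas=deltas,
        completion_series=[r.completion_percent for r in reports],
        confidence_series=[r.confidence_band for r in reports],
        reports=reports,
    )


def concordance(a1: Assessment, a2: Assessment,
                t: Taxonomy) -> ConcordanceSummary:
    """Agreement between two assessments over items both answered at a level.

    N/A and Blank items are excluded from the comparison set.  Symmetric in
    its two assessment arguments.
    """
    # scoring validates response ids against the taxonomy
    score_assessment(a1, t)
    score_assessment(a2, t)

    hist: dict[int, int] = {}
    n_both = 0
    n_agree = 0
    for sid in t.subcategory_ids():
        v1, v2 = a1.value_for(sid), a2.value_for(sid)
        if isinstance(v1, int) and isinstance(v2, int):
            n_both += 1
            d = abs(v1 - v2)
            hist[d] = hist.get(d, 0) + 1
            if d == 0:
                n_agree += 1
    return ConcordanceSummary(
        n_both_answered=n_both,
        n_agree=n_agree,
        proportion_agreement=(n_agree / n_both) if n_both else None,
        diff_histogram=hist,
    )
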