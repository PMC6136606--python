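"""Cohort statistics: mean +/- SD and range per scope across laboratories.

Statistics are computed over *defined* scope percents only; a laboratory
whose scope is Undefined (no applicable responses) is excluded from that
scope's n. SD is the sample standard deviation (n-1 denominator) and is
reported only when at least two laboratories define the scope.

The "discrepancy" ranking orders scopes by descending inter-laboratory SD
(ties broken by instrument order); the metric choice is recorded in the
summary metadata.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Sequence

from .errors import AggregationError
from .scoring import ScoreReport
from .taxonomy import Taxonomy

__all__ = ["ScopeStats", "CohortSummary", "aggregate", "discrepancy_ranking"]

DISCREPANCY_METRIC = "inter-laboratory sample SD of scope percents"


@dataclass(frozen=True)
class ScopeStats:
    scope: str
    n_defined: int
    mean: float | None
    sd: float | None      # None when n_defined < 2
    min: float | None
    max: float | None

    def to_dict(self) -> dict:
        return {"scope": self.scope, "n_defined": self.n_defined,
                "mean": self.mean, "sd": self.sd,
                "min": self.min, "max": self.max}


@dataclass
class CohortSummary:
    n_labs: int
    taxonomy: str
    policy: str
    per_scope: dict[str, ScopeStats]     # "overall", area ids, category ids
    discrepancy_ranking: list[tuple[str, float | None]]  # category level
    discrepancy_metric: str = DISCREPANCY_METRIC
    labels: list[str] | None = None      # only populated on explicit request

    def to_dict(self) -> dict:
        d = {
            "n_labs": self.n_labs,
            "taxonomy": self.taxonomy,
            "policy": self.policy,
            "per_scope": {s: st.to_dict() for s, st in self.per_scope.items()},
            "discrepancy_ranking": [
                {"scope": s, "sd": sd} for s, sd in self.discrepancy_ranking
            ],
            "discrepancy_metric": self.discrepancy_metric,
        }
        if self.labels is not None:
            d["labels"] = self.labels
        return d


def _stats_for(scope: str, values: Sequence[float]) -> ScopeStats:
    # sorted so the result is bit-identical under input permutation
    vals = sorted(values)
    n = len(vals)
    if n == 0:
        return ScopeStats(scope, 0, None, None, None, None)
    return ScopeStats(
        scope=scope,
        n_defined=n,
        mean=statistics.fmean(vals),
        sd=statistics.stdev(vals) if n >= 2 else None,
        min=vals[0],
        max=vals[-1],
    )


def _check_homogeneous(reports: Sequence[ScoreReport]) -> None:
    taxonomies = {r.taxonomy for r in reports}
    policies = {r.policy for r in reports}
    if len(taxonomies) > 1:
        raise AggregationError(
            f"reports span multiple taxonomies: {sorted(taxonomies)}")
    if len(policies) > 1:
        raise AggregationError(
            f"reports span multiple blank policies: {sorted(policies)}")


def _scope_values(reports: Sequence[ScoreReport]) -> dict[str, list[float]]:
    values: dict[str, list[float]] = {}
    for r in reports:
        for s in r.scope_scores():
            if s.percent is not None:
                values.setdefault(s.scope, []).append(s.percent)
    return values


def aggregate(reports: Sequence[ScoreReport],
              named: bool = False) -> CohortSummary:
    """Summarize a cohort of score reports scope by scope.

    All reports must come from the same taxonomy and blank policy.  Lab
    identities are withheld unless ``named`` is set.
    """
    if not reports:
        raise AggregationError("cannot aggregate an empty cohort")
    _check_homogeneous(reports)

    scope_order = [s.scope for s in reports[0].scope_scores()]
    values = _scope_values(reports)
    per_scope = {
        scope: _stats_for(scope, values.get(scope, []))
        for scope in scope_order
    }

    category_scopes = [s.scope for s in reports[0].per_category]
    ranking = _rank(per_scope, category_scopes)

    return CohortSummary(
        n_labs=len(reports),
        taxonomy=reports[0].taxonomy,
        policy=reports[0].policy,
        per_scope=per_scope,
        discrepancy_ranking=ranking,
        labels=[r.label for r in reports] if named else None,
    )


def _rank(per_scope: dict[str, ScopeStats],
          scopes: Sequence[str]) -> list[tuple[str, float | None]]:
    indexed = [(per_scope[s].sd, i, s) for i, s in enumerate(scopes)]
    indexed.sort(key=lambda e: (-(e[0] if e[0] is not None
                                  else -math.inf), e[1]))
    return [(s, sd) for sd, _, s in indexed]


def discrepancy_ranking(reports: Sequence[ScoreReport],
                        level: str = "category"
                        ) -> list[tuple[str, float | None]]:
    """Rank scopes at ``level`` ("area" | "category") by descending SD.

    Scopes defined by fewer than two laboratories carry an undefined SD and
    sort last; ties keep instrument order.
    """
    if len(reports) < 2:
        raise AggregationError(
            f"discrepancy ranking needs >=2 reports, got {len(reports)}")
    if level not in ("area", "category"):
        raise AggregationError(f"unknown ranking level {level!r}")
    _check_homogeneous(reports)

    scores = (reports[0].per_area if level == "area"
              else reports[0].per_category)
    scopes = [s.scope for s in scores]
    values = _scope_values(reports)
    per_scope = {s: _stats_for(s, values.get(s, [])) for s in scopes}
    return _rank(per_scope, scopes)
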