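"""Percentage-of-optimum scoring, completion, confidence bands, radar bands.

A response to a subcategory is one of:

* ``Answered(level)`` with level 1..4 — 4 is the optimum practice;
* ``NotApplicable`` — removed from both numerator and denominator;
* ``Blank`` — unanswered; a subcategory with no recorded response is Blank.

A scope (a category, an area, or the whole instrument) scores::

    100 * sum(answered levels) / (4 * number of applicable items)

which is 100 exactly when every applicable item is at level 4.  How Blank
items enter the denominator is governed by the *blank policy*:

* ``exclude`` (default): blanks are dropped from scoring entirely; only the
  completion-based confidence band reflects incompleteness.
* ``blank_as_zero``: blanks contribute 0 to the numerator but stay in the
  denominator.

Scopes with an empty denominator score ``None`` (rendered "N/A").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import PolicyError, UnknownSubcategoryError
from .taxonomy import Taxonomy

__all__ = [
    "NA",
    "Response",
    "AssessmentMeta",
    "Assessment",
    "ScopeScore",
    "ScoreReport",
    "POLICIES",
    "normalize_policy",
    "scope_percent",
    "completion_percent",
    "confidence_band",
    "radar_band",
    "score_assessment",
]

#: Marker value for a "Not applicable" response.
NA = "NA"

POLICIES = ("exclude", "blank_as_zero")

CONFIDENCE_BANDS = ("low", "medium", "reliable")

#: Lower edges of the five radar rankings (top band closed at 100).
RADAR_BAND_EDGES = (0.0, 20.0, 40.0, 60.0, 80.0)


def normalize_policy(policy: str) -> str:
    p = str(policy).replace("-", "_").lower()
    if p not in POLICIES:
        raise PolicyError(
            f"unknown blank policy {policy!r}; expected one of {POLICIES}")
    return p


@dataclass(frozen=True)
class Response:
    """One subcategory's response: Answered(1..4), NotApplicable, or Blank.

    ``value`` is an int level, the string ``"NA"``, or ``None`` for an
    explicitly-recorded blank (equivalent to no response at all).
    """

    subcategory_id: str
    value: int | str | None

    def __post_init__(self):
        v = self.value
        if v is None or v == NA:
            return
        if not isinstance(v, int) or isinstance(v, bool) or not 1 <= v <= 4:
            raise ValueError(
                f"{self.subcategory_id}: response level must be 1..4, "
                f"'NA', or blank; got {v!r}")

    @classmethod
    def answered(cls, subcategory_id: str, level: int) -> "Response":
        return cls(subcategory_id, level)

    @classmethod
    def not_applicable(cls, subcategory_id: str) -> "Response":
        return cls(subcategory_id, NA)

    @classmethod
    def blank(cls, subcategory_id: str) -> "Response":
        return cls(subcategory_id, None)

    @property
    def is_answered(self) -> bool:
        return isinstance(self.value, int)

    @property
    def is_na(self) -> bool:
        return self.value == NA

    @property
    def is_blank(self) -> bool:
        return self.value is None


@dataclass(frozen=True)
class AssessmentMeta:
    label: str = "assessment"
    date: str = ""
    assessor_role: str = ""  # "external" | "self" | free text


@dataclass
class Assessment:
    """One laboratory's responses plus free-form lab metadata."""

    responses: dict[str, Response] = field(default_factory=dict)
    meta: AssessmentMeta = field(default_factory=AssessmentMeta)
    lab_info: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_levels(cls, levels: Mapping[str, int | str | None],
                    label: str = "assessment", date: str = "",
                    assessor_role: str = "",
                    lab_info: Mapping[str, str] | None = None) -> "Assessment":
        """Build an assessment from ``{subcategory_id: 1..4 | "NA" | None}``."""
        responses = {sid: Response(sid, v) for sid, v in levels.items()}
        return cls(responses=responses,
                   meta=AssessmentMeta(label=label, date=date,
                                       assessor_role=assessor_role),
                   lab_info=dict(lab_info or {}))

    @property
    def label(self) -> str:
        return self.meta.label

    def value_for(self, subcategory_id: str) -> int | str | None:
        r = self.responses.get(subcategory_id)
        return None if r is None else r.value

    def canonical_levels(self) -> dict[str, int | str]:
        """Responses with blanks dropped (missing ≡ Blank); equality basis."""
        return {sid: r.value for sid, r in self.responses.items()
                if not r.is_blank}

    def equivalent(self, other: "Assessment") -> bool:
        """Same payload up to blank/missing normalization and metadata."""
        return (self.canonical_levels() == other.canonical_levels()
                and self.meta == other.meta
                and self.lab_info == other.lab_info)


@dataclass(frozen=True)
class ScopeScore:
    """Score of one scope ("overall", an area id, or a category id)."""

    scope: str
    percent: float | None      # None = Undefined (no applicable responses)
    answered: int              # non-blank responses (N/A included)
    applicable: int            # answered at a level 1..4
    total: int                 # subcategories in scope
    radar_band: int | None

    @property
    def defined(self) -> bool:
        return self.percent is not None


@dataclass
class ScoreReport:
    label: str
    taxonomy: str              # Taxonomy.ref of the bound instrument
    policy: str
    overall: ScopeScore
    per_area: list[ScopeScore]
    per_category: list[ScopeScore]
    completion_percent: float
    confidence_band: str

    def scope_scores(self) -> list[ScopeScore]:
        return [self.overall, *self.per_area, *self.per_category]

    def scope_percent_map(self) -> dict[str, float | None]:
        return {s.scope: s.percent for s in self.scope_scores()}

    def to_dict(self) -> dict:
        def ss(s: ScopeScore) -> dict:
            return {"scope": s.scope, "percent": s.percent,
                    "answered": s.answered, "applicable": s.applicable,
                    "total": s.total, "radar_band": s.radar_band}
        return {
            "label": self.label,
            "taxonomy": self.taxonomy,
            "policy": self.policy,
            "overall": ss(self.overall),
            "per_area": [ss(s) for s in self.per_area],
            "per_category": [ss(s) for s in self.per_category],
            "completion_percent": self.completion_percent,
            "confidence_band": self.confidence_band,
        }


# ---------------------------------------------------------------------------
# primitive scoring operations


def scope_percent(responses: Iterable[Response],
                  policy: str = "exclude") -> float | None:
    """Percentage-of-optimum over a set of responses, or None if undefined."""
    policy = normalize_policy(policy)
    levels = []
    n_blank = 0
    for r in responses:
        if r.is_answered:
            levels.append(r.value)
        elif r.is_blank:
            n_blank += 1
    denom = len(levels) + (n_blank if policy == "blank_as_zero" else 0)
    if denom == 0:
        return None
    return 100.0 * sum(levels) / (4.0 * denom)


def completion_percent(a: Assessment, t: Taxonomy) -> float:
    """Share of the instrument that is not blank; N/A counts as completed."""
    total = t.n_subcategories
    if total == 0:
        return 0.0
    done = sum(1 for sid in t.subcategory_ids()
               if a.value_for(sid) is not None)
    return 100.0 * done / total


def confidence_band(completion: float) -> str:
    """Band a completion percentage: low [0,70), medium [70,90),
    reliable [90,100]."""
    if not 0.0 <= completion <= 100.0:
        raise ValueError(f"completion must be in [0,100], got {completion!r}")
    if completion < 70.0:
        return "low"
    if completion < 90.0:
        return "medium"
    return "reliable"


def radar_band(percent: float) -> int:
    """Map a percent to one of five 20-point rankings (0..4); 100 -> 4."""
    if not 0.0 <= percent <= 100.0:
        raise ValueError(f"percent must be in [0,100], got {percent!r}")
    return min(int(math.floor(percent / 20.0)), 4)


# ---------------------------------------------------------------------------
# full-assessment scoring


def _score_scope(a: Assessment, scope: str, subcat_ids: Iterable[str],
                 policy: str) -> ScopeScore:
    subcat_ids = list(subcat_ids)
    levels = []
    n_na = 0
    for sid in subcat_ids:
        v = a.value_for(sid)
        if v is None:
            continue
        if v == NA:
            n_na += 1
        else:
            levels.append(v)
    applicable = len(levels)
    answered = applicable + n_na
    total = len(subcat_ids)
    n_blank = total - answered
    denom = applicable + (n_blank if policy == "blank_as_zero" else 0)
    percent = None if denom == 0 else 100.0 * sum(levels) / (4.0 * denom)
    return ScopeScore(
        scope=scope, percent=percent, answered=answered,
        applicable=applicable, total=total,
        radar_band=None if percent is None else radar_band(percent))


def score_assessment(a: Assessment, t: Taxonomy,
                     policy: str = "exclude") -> ScoreReport:
    """Score one assessment at every scope and band its completion.

    Raises :class:`UnknownSubcategoryError` if the assessment references
    subcategories outside the taxonomy, and :class:`PolicyError` for an
    unknown blank policy.
    """
    policy = normalize_policy(policy)
    known = set(t.subcategory_ids())
    unknown = set(a.responses) - known
    if unknown:
        raise UnknownSubcategoryError(unknown)

    per_category = [
        _score_scope(a, c.id, c.subcategory_ids, policy)
        for c in t.iter_categories()
    ]
    per_area = [
        _score_scope(a, area.id, t.subcategory_ids_in_area(area.id), policy)
        for area in t.areas
    ]
    overall = _score_scope(a, "overall", t.subcategory_ids(), policy)
    completion = completion_percent(a, t)
    return ScoreReport(
        label=a.label,
        taxonomy=t.ref,
        policy=policy,
        overall=overall,
        per_area=per_area,
        per_category=per_category,
        completion_percent=completion,
        confidence_band=confidence_band(completion),
    )
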