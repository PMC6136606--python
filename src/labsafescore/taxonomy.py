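"""Instrument definition: areas, categories, subcategories and 4-level rubrics.

The instrument is data, not code: it is described by a versioned YAML
document (the "questionnaire-taxonomy" dialect, see :func:`parse_taxonomy`)
and the built-in LMT-S instrument ships as a packaged file under
``labsafescore/data/lmt_s.yaml``.  Alternative instruments with the same
shape can be loaded from user-supplied files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Iterator

import yaml

from .errors import SchemaParseError, TaxonomyValidationError

__all__ = [
    "RubricLevel",
    "Subcategory",
    "Category",
    "Area",
    "Taxonomy",
    "Finding",
    "parse_taxonomy",
    "load_taxonomy",
    "dump_taxonomy",
    "save_taxonomy",
    "validate_taxonomy",
    "builtin_lmt_s",
]

SCHEMA_NAME = "questionnaire-taxonomy"
SCHEMA_VERSION = 1

RUBRIC_LEVELS = (1, 2, 3, 4)


@dataclass(frozen=True)
class RubricLevel:
    """One graded practice description; level 4 is optimal, 1 most basic."""

    level: int
    practice_text: str


@dataclass(frozen=True)
class Subcategory:
    """A single scored question with a 4-level rubric."""

    id: str
    name: str
    category_id: str
    rubric: tuple[RubricLevel, ...]
    guidance: str = ""

    def practice(self, level: int) -> str:
        """Return the practice text for ``level`` (KeyError if absent)."""
        for rl in self.rubric:
            if rl.level == level:
                return rl.practice_text
        raise KeyError(f"{self.id}: no rubric level {level}")


@dataclass(frozen=True)
class Category:
    id: str
    name: str
    area_id: str
    subcategory_ids: tuple[str, ...]


@dataclass(frozen=True)
class Area:
    id: str
    name: str
    category_ids: tuple[str, ...]


@dataclass(frozen=True)
class Finding:
    """A single validation violation, located by node path."""

    path: str
    rule: str
    message: str

    def __str__(self) -> str:
        return f"{self.path}: [{self.rule}] {self.message}"


@dataclass
class Taxonomy:
    """A full instrument: ordered areas with resolvable children.

    ``categories`` and ``subcategories`` are flat ordered lists so that
    invalid constructions (duplicate ids, orphans, dangling references)
    remain representable for :func:`validate_taxonomy`.
    """

    name: str
    version: str
    areas: list[Area] = field(default_factory=list)
    categories: list[Category] = field(default_factory=list)
    subcategories: list[Subcategory] = field(default_factory=list)

    # -- lookups (first occurrence wins; valid taxonomies have no dupes) --

    def area(self, area_id: str) -> Area:
        for a in self.areas:
            if a.id == area_id:
                return a
        raise KeyError(f"no area {area_id!r}")

    def category(self, category_id: str) -> Category:
        for c in self.categories:
            if c.id == category_id:
                return c
        raise KeyError(f"no category {category_id!r}")

    def subcategory(self, subcategory_id: str) -> Subcategory:
        for s in self.subcategories:
            if s.id == subcategory_id:
                return s
        raise KeyError(f"no subcategory {subcategory_id!r}")

    def find_category(self, name_or_id: str) -> Category:
        """Look a category up by id, or (case-insensitively) by name."""
        wanted = name_or_id.casefold()
        for c in self.categories:
            if c.id == name_or_id or c.name.casefold() == wanted:
                return c
        raise KeyError(f"no category named {name_or_id!r}")

    def find_area(self, name_or_id: str) -> Area:
        wanted = name_or_id.casefold()
        for a in self.areas:
            if a.id == name_or_id or a.name.casefold() == wanted:
                return a
        raise KeyError(f"no area named {name_or_id!r}")

    # -- ordered traversal (instrument order is the report/axis order) --

    def iter_categories(self) -> Iterator[Category]:
        for area in self.areas:
            for cid in area.category_ids:
                yield self.category(cid)

    def iter_subcategories(self) -> Iterator[Subcategory]:
        for cat in self.iter_categories():
            for sid in cat.subcategory_ids:
                yield self.subcategory(sid)

    def subcategory_ids(self) -> list[str]:
        return [s.id for s in self.iter_subcategories()]

    def subcategory_ids_in_category(self, category_id: str) -> list[str]:
        return list(self.category(category_id).subcategory_ids)

    def subcategory_ids_in_area(self, area_id: str) -> list[str]:
        ids: list[str] = []
        for cid in self.area(area_id).category_ids:
            ids.extend(self.category(cid).subcategory_ids)
        return ids

    @property
    def n_subcategories(self) -> int:
        return len(self.subcategories)

    @property
    def ref(self) -> str:
        """Stable identifier used to bind assessments to an instrument."""
        return f"{self.name}@{self.version}"


# ---------------------------------------------------------------------------
# validation


def validate_taxonomy(t: Taxonomy) -> list[Finding]:
    """Check every structural invariant; return one Finding per violation.

    Returns an empty list iff the taxonomy is valid.  Never raises.
    """
    findings: list[Finding] = []

    def bad(path: str, rule: str, message: str) -> None:
        findings.append(Finding(path=path, rule=rule, message=message))

    area_ids = [a.id for a in t.areas]
    cat_ids = [c.id for c in t.categories]
    sub_ids = [s.id for s in t.subcategories]

    for label, ids in (("area", area_ids), ("category", cat_ids),
                       ("subcategory", sub_ids)):
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                bad(f"{label}/{i}", "duplicate-id",
                    f"{label} id {i!r} occurs more than once")
            seen.add(i)

    area_set, cat_set, sub_set = set(area_ids), set(cat_ids), set(sub_ids)

    if not t.areas:
        bad("taxonomy", "empty-taxonomy", "instrument has no areas")

    referenced_cats: set[str] = set()
    for a in t.areas:
        if not a.category_ids:
            bad(f"area/{a.id}", "empty-area", "area has no categories")
        for cid in a.category_ids:
            referenced_cats.add(cid)
            if cid not in cat_set:
                bad(f"area/{a.id}", "dangling-reference",
                    f"category {cid!r} does not exist")

    referenced_subs: set[str] = set()
    for c in t.categories:
        if c.area_id not in area_set:
            bad(f"category/{c.id}", "dangling-reference",
                f"area {c.area_id!r} does not exist")
        elif c.id not in t.area(c.area_id).category_ids:
            bad(f"category/{c.id}", "inconsistent-parent",
                f"area {c.area_id!r} does not list this category")
        if c.id not in referenced_cats:
            bad(f"category/{c.id}", "orphan",
                "category is not referenced by any area")
        if not c.subcategory_ids:
            bad(f"category/{c.id}", "empty-category",
                "category has no subcategories")
        for sid in c.subcategory_ids:
            referenced_subs.add(sid)
            if sid not in sub_set:
                bad(f"category/{c.id}", "dangling-reference",
                    f"subcategory {sid!r} does not exist")

    for s in t.subcategories:
        path = f"subcategory/{s.id}"
        if s.category_id not in cat_set:
            bad(path, "dangling-reference",
                f"category {s.category_id!r} does not exist")
        elif s.id not in t.category(s.category_id).subcategory_ids:
            bad(path, "inconsistent-parent",
                f"category {s.category_id!r} does not list this subcategory")
        if s.id not in referenced_subs:
            bad(path, "orphan",
                "subcategory is not referenced by any category")
        if not s.name:
            bad(path, "empty-name", "subcategory name is empty")

        levels = [rl.level for rl in s.rubric]
        for lvl in levels:
            if lvl not in RUBRIC_LEVELS:
                bad(path, "invalid-level", f"rubric level {lvl} not in 1..4")
        for lvl in RUBRIC_LEVELS:
            n = levels.count(lvl)
            if n == 0:
                bad(path, "missing-rubric-level",
                    f"rubric is missing level {lvl}")
            elif n > 1:
                bad(path, "duplicate-rubric-level",
                    f"rubric defines level {lvl} {n} times")
        for rl in s.rubric:
            if not rl.practice_text.strip():
                bad(path, "empty-practice-text",
                    f"practice text for level {rl.level} is empty")

    return findings


# ---------------------------------------------------------------------------
# YAML dialect


def _expect(mapping, key, types, path):
    if not isinstance(mapping, dict):
        raise SchemaParseError(f"{path}: expected a mapping")
    if key not in mapping:
        raise SchemaParseError(f"{path}: missing required key {key!r}")
    value = mapping[key]
    if not isinstance(value, types):
        raise SchemaParseError(
            f"{path}.{key}: unexpected type {type(value).__name__}")
    return value


def parse_taxonomy(text: str, validate: bool = True) -> Taxonomy:
    """Parse a taxonomy document in the questionnaire-taxonomy dialect.

    Raises :class:`SchemaParseError` on malformed documents and, when
    ``validate`` is true, :class:`TaxonomyValidationError` if structural
    invariants fail.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SchemaParseError(f"not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaParseError("document root must be a mapping")
    if doc.get("schema") != SCHEMA_NAME:
        raise SchemaParseError(
            f"schema: expected {SCHEMA_NAME!r}, got {doc.get('schema')!r}")
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise SchemaParseError(
            f"schema_version: expected {SCHEMA_VERSION}, "
            f"got {doc.get('schema_version')!r}")

    name = _expect(doc, "name", str, "$")
    version = str(_expect(doc, "version", (str, int, float), "$"))

    areas: list[Area] = []
    categories: list[Category] = []
    subcategories: list[Subcategory] = []

    for ai, anode in enumerate(_expect(doc, "areas", list, "$")):
        apath = f"$.areas[{ai}]"
        aid = _expect(anode, "id", str, apath)
        aname = _expect(anode, "name", str, apath)
        cat_ids: list[str] = []
        for ci, cnode in enumerate(_expect(anode, "categories", list, apath)):
            cpath = f"{apath}.categories[{ci}]"
            cid = _expect(cnode, "id", str, cpath)
            cname = _expect(cnode, "name", str, cpath)
            sub_ids: list[str] = []
            for si, snode in enumerate(
                    _expect(cnode, "subcategories", list, cpath)):
                spath = f"{cpath}.subcategories[{si}]"
                sid = _expect(snode, "id", str, spath)
                sname = _expect(snode, "name", str, spath)
                rubric_node = _expect(snode, "rubric", dict, spath)
                rubric = []
                for lvl, txt in rubric_node.items():
                    if not isinstance(lvl, int) or not isinstance(txt, str):
                        raise SchemaParseError(
                            f"{spath}.rubric: levels must be integers "
                            "mapped to text")
                    rubric.append(RubricLevel(level=lvl, practice_text=txt))
                rubric.sort(key=lambda rl: rl.level)
                guidance = snode.get("guidance", "")
                if guidance is None:
                    guidance = ""
                if not isinstance(guidance, str):
                    raise SchemaParseError(f"{spath}.guidance: must be text")
                subcategories.append(Subcategory(
                    id=sid, name=sname, category_id=cid,
                    rubric=tuple(rubric), guidance=guidance))
                sub_ids.append(sid)
            categories.append(Category(
                id=cid, name=cname, area_id=aid,
                subcategory_ids=tuple(sub_ids)))
            cat_ids.append(cid)
        areas.append(Area(id=aid, name=aname, category_ids=tuple(cat_ids)))

    t = Taxonomy(name=name, version=version, areas=areas,
                 categories=categories, subcategories=subcategories)
    if validate:
        findings = validate_taxonomy(t)
        if findings:
            raise TaxonomyValidationError(findings)
    return t


def load_taxonomy(source: str | Path | IO[str], validate: bool = True) -> Taxonomy:
    """Load a taxonomy from a file path or an open text stream."""
    if hasattr(source, "read"):
        return parse_taxonomy(source.read(), validate=validate)
    return parse_taxonomy(Path(source).read_text(encoding="utf-8"),
                          validate=validate)


def dump_taxonomy(t: Taxonomy) -> str:
    """Serialize a taxonomy back to its YAML dialect (round-trip safe)."""
    doc = {
        "schema": SCHEMA_NAME,
        "schema_version": SCHEMA_VERSION,
        "name": t.name,
        "version": t.version,
        "areas": [
            {
                "id": a.id,
                "name": a.name,
                "categories": [
                    {
                        "id": c.id,
                        "name": c.name,
                        "subcategories": [
                            {
                                "id": s.id,
                                "name": s.name,
                                "guidance": s.guidance,
                                "rubric": {
                                    rl.level: rl.practice_text
                                    for rl in s.rubric
                                },
                            }
                            for s in (t.subcategory(sid)
                                      for sid in c.subcategory_ids)
                        ],
                    }
                    for c in (t.category(cid) for cid in a.category_ids)
                ],
            }
            for a in t.areas
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True,
                          width=88)


def save_taxonomy(t: Taxonomy, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(dump_taxonomy(t), encoding="utf-8")
    return path


@lru_cache(maxsize=1)
def _builtin() -> Taxonomy:
    text = (resources.files(__package__) / "data" / "lmt_s.yaml").read_text(
        encoding="utf-8")
    return parse_taxonomy(text)


def builtin_lmt_s() -> Taxonomy:
    """Return the packaged LMT-S instrument (4 areas, 20 categories, 98
    subcategories).

    All subcategories except "Disposable glove usage" carry clearly-labelled
    placeholder rubric text: the instrument's full rubric wording is not
    published, only its structure and one exemplar rubric.
    """
    t = _builtin()
    # defensive copy of the mutable containers; nodes are frozen
    return replace(t, areas=list(t.areas), categories=list(t.categories),
                   subcategories=list(t.subcategories))
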