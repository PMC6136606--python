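"""Assessment interchange: canonical JSON, flat CSV, and a 6-tab workbook.

JSON is the canonical machine format (a versioned envelope).  CSV is a flat
``subcategory_id,response`` table carrying the response payload only.  The
workbook is a presentation/exchange format with six fixed tabs — index,
user guideline, laboratory information, the questionnaire (one row per
subcategory, up to 3 assessment columns), the auto-generated summary, and
rights — matching the spreadsheet the instrument is distributed as.

Response markers everywhere: integers 1–4; the literal string "NA"
(case-insensitive) for Not applicable; an empty cell / null for Blank.
Readers reject out-of-domain values with a located error.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
import json
import re
import warnings
import zipfile
from pathlib import Path
from typing import IO, Sequence

import openpyxl
from openpyxl.utils import get_column_letter

from .errors import FormatError
from .scoring import (NA, Assessment, AssessmentMeta, Response, ScoreReport,
                      score_assessment)
from .taxonomy import Taxonomy

__all__ = [
    "TAB_NAMES",
    "ASSESSMENT_FORMAT",
    "COHORT_FORMAT",
    "SCHEMA_VERSION",
    "read_assessment_json",
    "write_assessment_json",
    "read_cohort_json",
    "write_cohort_json",
    "read_assessment_csv",
    "write_assessment_csv",
    "read_assessments_workbook",
    "write_assessments_workbook",
    "read_any",
    "write_any",
]

ASSESSMENT_FORMAT = "labsafescore-assessment"
COHORT_FORMAT = "labsafescore-cohort"
SCHEMA_VERSION = 1

TAB_NAMES = (
    "Safety Index",
    "User Guideline",
    "Laboratory Information",
    "Safety Module",
    "Safety Summary",
    "Rights and Attribution",
)

#: The workbook format holds at most this many assessment columns.
MAX_WORKBOOK_ASSESSMENTS = 3

#: Fixed timestamp baked into workbook bytes so output is reproducible.
_STABLE_TIME = _dt.datetime(2018, 1, 1, 0, 0, 0)

_QUESTIONNAIRE_HEADER = ("Subcategory ID", "Area", "Category", "Subcategory")
_META_ROWS = ("Label", "Date", "Assessor")
_DATA_START_ROW = 5  # header + 3 metadata rows


def _parse_marker(value, where: str) -> int | str | None:
    """Map a raw cell/field value to a response value; raise on bad input."""
    if value is None:
        return None
    if isinstance(value, str):
        s = value.strip()
        if s == "":
            return None
        if s.upper() == NA:
            return NA
        if s in {"1", "2", "3", "4"}:
            return int(s)
        raise FormatError(f"{where}: illegal response value {value!r} "
                          "(expected 1-4, 'NA', or blank)")
    if isinstance(value, bool):
        raise FormatError(f"{where}: illegal response value {value!r}")
    if isinstance(value, int) or (isinstance(value, float)
                                  and value.is_integer()):
        iv = int(value)
        if 1 <= iv <= 4:
            return iv
    raise FormatError(f"{where}: illegal response value {value!r} "
                      "(expected 1-4, 'NA', or blank)")


# ---------------------------------------------------------------------------
# JSON


def _assessment_payload(a: Assessment) -> dict:
    return {
        "lab_info": dict(a.lab_info),
        "meta": {
            "label": a.meta.label,
            "date": a.meta.date,
            "assessor_role": a.meta.assessor_role,
        },
        "responses": a.canonical_levels(),
    }


def _payload_to_assessment(payload: dict, t: Taxonomy, where: str) -> Assessment:
    if not isinstance(payload, dict):
        raise FormatError(f"{where}: expected an object")
    meta = payload.get("meta", {})
    if not isinstance(meta, dict):
        raise FormatError(f"{where}.meta: expected an object")
    raw = payload.get("responses", {})
    if not isinstance(raw, dict):
        raise FormatError(f"{where}.responses: expected an object")
    responses: dict[str, Response] = {}
    for sid, v in raw.items():
        parsed = _parse_marker(v, f"{where}.responses[{sid!r}]")
        if parsed is None:
            continue
        responses[sid] = Response(sid, parsed)
    a = Assessment(
        responses=responses,
        meta=AssessmentMeta(
            label=str(meta.get("label", "assessment")),
            date=str(meta.get("date", "")),
            assessor_role=str(meta.get("assessor_role", "")),
        ),
        lab_info={str(k): str(v)
                  for k, v in (payload.get("lab_info") or {}).items()},
    )
    score_assessment(a, t)  # rejects unknown subcategory ids
    return a


def _check_envelope(doc: dict, expected_format: str, where: str) -> None:
    if not isinstance(doc, dict):
        raise FormatError(f"{where}: expected a JSON object")
    if doc.get("format") != expected_format:
        raise FormatError(
            f"{where}: format is {doc.get('format')!r}, "
            f"expected {expected_format!r}")
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise FormatError(
            f"{where}: schema_version is {doc.get('schema_version')!r}, "
            f"expected {SCHEMA_VERSION}")


def _read_text(source: str | Path | IO[str]) -> str:
    if hasattr(source, "read"):
        return source.read()
    return Path(source).read_text(encoding="utf-8")


def write_assessment_json(a: Assessment, t: Taxonomy,
                          path: str | Path | None = None) -> str:
    doc = {"format": ASSESSMENT_FORMAT, "schema_version": SCHEMA_VERSION,
           "taxonomy": t.ref, **_assessment_payload(a)}
    text = json.dumps(doc, indent=2, sort_keys=False) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def read_assessment_json(source: str | Path | IO[str],
                         t: Taxonomy) -> Assessment:
    try:
        doc = json.loads(_read_text(source))
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid JSON: {exc}") from exc
    _check_envelope(doc, ASSESSMENT_FORMAT, "$")
    return _payload_to_assessment(doc, t, "$")


def write_cohort_json(assessments: Sequence[Assessment], t: Taxonomy,
                      path: str | Path | None = None) -> str:
    doc = {
        "format": COHORT_FORMAT,
        "schema_version": SCHEMA_VERSION,
        "taxonomy": t.ref,
        "assessments": [_assessment_payload(a) for a in assessments],
    }
    text = json.dumps(doc, indent=2, sort_keys=False) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def read_cohort_json(source: str | Path | IO[str],
                     t: Taxonomy) -> list[Assessment]:
    try:
        doc = json.loads(_read_text(source))
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid JSON: {exc}") from exc
    _check_envelope(doc, COHORT_FORMAT, "$")
    items = doc.get("assessments")
    if not isinstance(items, list):
        raise FormatError("$.assessments: expected a list")
    return [_payload_to_assessment(p, t, f"$.assessments[{i}]")
            for i, p in enumerate(items)]


# ---------------------------------------------------------------------------
# CSV


def write_assessment_csv(a: Assessment, t: Taxonomy,
                         path: str | Path | None = None) -> str:
    """One row per taxonomy subcategory: ``subcategory_id,response``.

    Carries the response payload only; labels and lab metadata live in the
    JSON/workbook formats.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["subcategory_id", "response"])
    for sid in t.subcategory_ids():
        v = a.value_for(sid)
        writer.writerow([sid, "" if v is None else v])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def read_assessment_csv(source: str | Path | IO[str], t: Taxonomy,
                        label: str = "assessment") -> Assessment:
    text = _read_text(source)
    rows = list(csv.reader(io.StringIO(text)))
    if not rows or [c.strip() for c in rows[0][:2]] != ["subcategory_id",
                                                        "response"]:
        raise FormatError(
            "CSV header must be 'subcategory_id,response'; "
            f"got {rows[0] if rows else 'empty file'!r}")
    responses: dict[str, Response] = {}
    seen: set[str] = set()
    dupes: set[str] = set()
    for i, row in enumerate(rows[1:], start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != 2:
            raise FormatError(f"line {i}: expected 2 columns, got {len(row)}")
        sid = row[0].strip()
        if sid in seen:
            dupes.add(sid)
        seen.add(sid)
        v = _parse_marker(row[1], f"line {i}")
        if v is not None:
            responses[sid] = Response(sid, v)
    if dupes:
        raise FormatError(
            "duplicate subcategory rows: " + ", ".join(sorted(dupes)))
    a = Assessment(responses=responses, meta=AssessmentMeta(label=label))
    score_assessment(a, t)  # rejects unknown subcategory ids
    return a


# ---------------------------------------------------------------------------
# workbook


def _stable_save(wb: openpyxl.Workbook, path: str | Path) -> None:
    """Save with all zip-member timestamps pinned, for reproducible bytes."""
    wb.properties.created = _STABLE_TIME
    wb.properties.modified = _STABLE_TIME
    raw = io.BytesIO()
    wb.save(raw)
    raw.seek(0)
    stamp = _STABLE_TIME.strftime("%Y-%m-%dT%H:%M:%SZ").encode()
    out = io.BytesIO()
    with zipfile.ZipFile(raw) as src, \
            zipfile.ZipFile(out, "w", zipfile.ZIP_DEFLATED) as dst:
        for name in src.namelist():
            data = src.read(name)
            if name == "docProps/core.xml":
                # openpyxl stamps 'modified' with now() during save
                data = re.sub(
                    rb'(<dcterms:modified[^>]*>)[^<]*(</dcterms:modified>)',
                    rb"\g<1>" + stamp + rb"\g<2>", data)
            info = zipfile.ZipInfo(name, date_time=_STABLE_TIME.timetuple()[:6])
            info.compress_type = zipfile.ZIP_DEFLATED
            dst.writestr(info, data)
    Path(path).write_bytes(out.getvalue())


def _fmt_percent(p: float | None) -> str:
    return "N/A" if p is None else f"{p:.1f}"


def write_assessments_workbook(
        path: str | Path,
        assessments: Sequence[Assessment],
        t: Taxonomy,
        lab_info: dict | None = None,
        reports: Sequence[ScoreReport] | None = None,
        policy: str = "exclude",
        truncate: bool = False) -> Path:
    """Write the 6-tab workbook; byte-stable for identical inputs.

    At most 3 assessments fit the format; more raise unless ``truncate`` is
    set, in which case the first 3 are written with a warning.
    """
    assessments = list(assessments)
    if not assessments:
        raise FormatError("workbook needs at least 1 assessment")
    if len(assessments) > MAX_WORKBOOK_ASSESSMENTS:
        if not truncate:
            raise FormatError(
                f"workbook format holds at most {MAX_WORKBOOK_ASSESSMENTS} "
                f"assessments, got {len(assessments)} "
                "(pass truncate=True to keep the first 3)")
        warnings.warn(
            f"truncating {len(assessments)} assessments to the first "
            f"{MAX_WORKBOOK_ASSESSMENTS} for the workbook format",
            stacklevel=2)
        assessments = assessments[:MAX_WORKBOOK_ASSESSMENTS]
    if reports is None:
        reports = [score_assessment(a, t, policy) for a in assessments]
    if lab_info is None:
        lab_info = assessments[0].lab_info

    wb = openpyxl.Workbook()
    ws = wb.active
    ws.title = TAB_NAMES[0]
    ws["A1"] = "Laboratory Safety & Biosecurity Assessment"
    ws["A3"] = (f"Instrument: {t.name} (version {t.version}) — "
                f"{len(t.areas)} areas, "
                f"{sum(1 for _ in t.iter_categories())} categories, "
                f"{t.n_subcategories} subcategories.")
    ws["A4"] = ("Each subcategory is scored 1-4 against its rubric; 'NA' "
                "removes an item from scoring; blanks lower the completion-"
                "based confidence band.")

    ws = wb.create_sheet(TAB_NAMES[1])
    ws["A1"] = "User guideline"
    ws["A3"] = ("Fill the Safety Module tab with one response per "
                "subcategory: a level 1-4, 'NA' for not applicable, or leave "
                "blank. Up to three assessment columns may be recorded for "
                "comparison over time or across assessors.")
    ws["A4"] = ("Scores are percentages of the optimum (level 4 on every "
                "applicable item). The Safety Summary tab is generated "
                "automatically.")

    ws = wb.create_sheet(TAB_NAMES[2])
    ws.append(["Field", "Value"])
    for k, v in lab_info.items():
        ws.append([str(k), str(v)])

    ws = wb.create_sheet(TAB_NAMES[3])
    header = list(_QUESTIONNAIRE_HEADER) + [
        f"Assessment {i + 1}" for i in range(MAX_WORKBOOK_ASSESSMENTS)]
    ws.append(header)
    for name, getter in (
            ("Label", lambda a: a.meta.label),
            ("Date", lambda a: a.meta.date),
            ("Assessor", lambda a: a.meta.assessor_role)):
        row = [name, "", "", ""]
        row += [getter(a) for a in assessments]
        row += [""] * (MAX_WORKBOOK_ASSESSMENTS - len(assessments))
        ws.append(row)
    for area in t.areas:
        for cid in area.category_ids:
            cat = t.category(cid)
            for sid in cat.subcategory_ids:
                sub = t.subcategory(sid)
                row: list = [sid, area.name, cat.name, sub.name]
                for a in assessments:
                    v = a.value_for(sid)
                    row.append("" if v is None else v)
                row += [""] * (MAX_WORKBOOK_ASSESSMENTS - len(assessments))
                ws.append(row)

    ws = wb.create_sheet(TAB_NAMES[4])
    ws.append(["Scope", "Name"] + [r.label for r in reports])
    ws.append(["overall", "Overall safety and biosecurity"]
              + [_fmt_percent(r.overall.percent) for r in reports])
    for i, area in enumerate(t.areas):
        ws.append([area.id, area.name]
                  + [_fmt_percent(r.per_area[i].percent) for r in reports])
    for i, cat in enumerate(t.iter_categories()):
        ws.append([cat.id, cat.name]
                  + [_fmt_percent(r.per_category[i].percent) for r in reports])
    ws.append([])
    ws.append(["completion", "Completion %"]
              + [f"{r.completion_percent:.1f}" for r in reports])
    ws.append(["confidence", "Confidence"]
              + [r.confidence_band for r in reports])

    ws = wb.create_sheet(TAB_NAMES[5])
    ws["A1"] = "Rights and attribution"
    ws["A3"] = ("Generated by labsafescore. Assessment content belongs to "
                "the assessed laboratory; handle as confidential.")

    _stable_save(wb, path)
    return Path(path)


def read_assessments_workbook(
        path: str | Path,
        t: Taxonomy) -> tuple[dict[str, str], list[Assessment]]:
    """Read lab info and up to 3 assessments back out of a workbook."""
    try:
        wb = openpyxl.load_workbook(path, data_only=True)
    except Exception as exc:  # openpyxl raises a mix of zipfile/xml errors
        raise FormatError(f"{path}: not a readable workbook: {exc}") from exc

    if tuple(wb.sheetnames) != TAB_NAMES:
        raise FormatError(
            f"workbook tabs {wb.sheetnames!r} do not match the required "
            f"layout {list(TAB_NAMES)!r}")

    ws = wb[TAB_NAMES[2]]
    lab_info: dict[str, str] = {}
    for row in ws.iter_rows(min_row=2, max_col=2, values_only=True):
        if row[0] is None:
            continue
        lab_info[str(row[0])] = "" if row[1] is None else str(row[1])

    ws = wb[TAB_NAMES[3]]
    sheet = TAB_NAMES[3]
    head = tuple(c.value for c in ws[1][:4])
    if head != _QUESTIONNAIRE_HEADER:
        raise FormatError(
            f"{sheet}!A1:D1: header {head!r} does not match "
            f"{_QUESTIONNAIRE_HEADER!r}")
    meta: list[dict[str, str]] = [
        {} for _ in range(MAX_WORKBOOK_ASSESSMENTS)]
    for offset, name in enumerate(_META_ROWS, start=2):
        row = ws[offset]
        if row[0].value != name:
            raise FormatError(
                f"{sheet}!A{offset}: expected metadata row {name!r}, "
                f"got {row[0].value!r}")
        for j in range(MAX_WORKBOOK_ASSESSMENTS):
            v = row[4 + j].value
            meta[j][name.lower()] = "" if v is None else str(v)

    known = set(t.subcategory_ids())
    responses: list[dict[str, Response]] = [
        {} for _ in range(MAX_WORKBOOK_ASSESSMENTS)]
    seen: set[str] = set()
    for r_idx, row in enumerate(ws.iter_rows(min_row=_DATA_START_ROW),
                                start=_DATA_START_ROW):
        sid = row[0].value
        if sid is None:
            continue
        sid = str(sid)
        if sid not in known:
            raise FormatError(
                f"{sheet}!A{r_idx}: unknown subcategory id {sid!r}")
        if sid in seen:
            raise FormatError(
                f"{sheet}!A{r_idx}: duplicate subcategory row {sid!r}")
        seen.add(sid)
        for j in range(MAX_WORKBOOK_ASSESSMENTS):
            cell = row[4 + j]
            where = f"{sheet}!{get_column_letter(5 + j)}{r_idx}"
            v = _parse_marker(cell.value, where)
            if v is not None:
                responses[j][sid] = Response(sid, v)
    missing = known - seen
    if missing:
        raise FormatError(
            f"{sheet}: missing rows for subcategories: "
            + ", ".join(sorted(missing)[:5])
            + ("..." if len(missing) > 5 else ""))

    assessments: list[Assessment] = []
    for j in range(MAX_WORKBOOK_ASSESSMENTS):
        if not responses[j] and not meta[j]["label"]:
            continue
        assessments.append(Assessment(
            responses=responses[j],
            meta=AssessmentMeta(
                label=meta[j]["label"] or f"Assessment {j + 1}",
                date=meta[j]["date"],
                assessor_role=meta[j]["assessor"]),
            lab_info=dict(lab_info)))
    return lab_info, assessments


# ---------------------------------------------------------------------------
# format dispatch


def _format_of(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix == ".csv":
        return "csv"
    if suffix in (".xlsx", ".xlsm"):
        return "workbook"
    raise FormatError(f"cannot infer format from {path!r} "
                      "(expected .json, .csv, or .xlsx)")


def read_any(path: str | Path, t: Taxonomy) -> list[Assessment]:
    """Read one or more assessments from a file, dispatching on extension.

    A JSON file may hold a single assessment envelope or a cohort document.
    """
    fmt = _format_of(path)
    if fmt == "csv":
        return [read_assessment_csv(path, t, label=Path(path).stem)]
    if fmt == "workbook":
        return read_assessments_workbook(path, t)[1]
    text = Path(path).read_text(encoding="utf-8")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    if isinstance(doc, dict) and doc.get("format") == COHORT_FORMAT:
        return read_cohort_json(io.StringIO(text), t)
    return [read_assessment_json(io.StringIO(text), t)]


def write_any(path: str | Path, assessments: Sequence[Assessment],
              t: Taxonomy, fmt: str | None = None,
              policy: str = "exclude", truncate: bool = False) -> Path:
    """Write assessments to ``path`` in ``fmt`` (inferred when omitted)."""
    fmt = fmt or _format_of(path)
    assessments = list(assessments)
    if fmt == "json":
        if len(assessments) == 1:
            write_assessment_json(assessments[0], t, path)
        else:
            write_cohort_json(assessments, t, path)
    elif fmt == "csv":
        if len(assessments) != 1:
            raise FormatError(
                f"CSV holds exactly one assessment, got {len(assessments)}")
        write_assessment_csv(assessments[0], t, path)
    elif fmt == "workbook":
        write_assessments_workbook(path, assessments, t, policy=policy,
                                   truncate=truncate)
    else:
        raise FormatError(f"unknown format {fmt!r}")
    return Path(path)
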