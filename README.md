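# labsafescore

A schema-driven library and CLI for scoring laboratory safety & biosecurity
capacity assessments built on rubric questionnaires.

The built-in instrument ("LMT-S") has **4 areas → 20 categories → 98
subcategories**; each subcategory is a question scored 1–4 against a
four-level practice rubric (4 = optimal), may be marked **N/A** (removed from
scoring), or left **blank**. The package provides:

- **Taxonomy model** (`labsafescore.taxonomy`) — load/validate instruments
  from a versioned YAML dialect; the built-in instrument ships as
  `src/labsafescore/data/lmt_s.yaml` (regenerable with
  `scripts/build_builtin_taxonomy.py`). Only the "Disposable glove usage"
  subcategory carries real rubric text; the other 97 rubrics are labelled
  placeholders, since the full instrument wording is not published.
- **Scoring engine** (`labsafescore.scoring`) — percentage-of-optimum scores
  (`100·Σlevels / (4·n_applicable)`) per category, per area and overall;
  two blank policies (`exclude`, default, and `blank_as_zero`); a completion
  percentage (N/A counts as completed) banded into **low** [0, 70) /
  **medium** [70, 90) / **reliable** [90, 100] confidence; and five 20-point
  radar bands (lower-inclusive, top band closed).
- **Comparison** (`labsafescore.comparison`) — align ≥2 assessments of one
  laboratory, deltas vs the baseline, plus an item-level assessor
  concordance summary.
- **Aggregation** (`labsafescore.aggregation`) — cohort mean (±sample SD)
  and range per scope, and a discrepancy ranking by inter-laboratory SD.
- **Gap analysis** (`labsafescore.gap_analysis`) — for every item below
  level 4, the next level's practice text, ordered weakest category first;
  blanks surfaced separately as "unassessed".
- **I/O** (`labsafescore.io_formats`) — canonical JSON envelope, flat CSV
  (`subcategory_id,response`), and a 6-tab spreadsheet workbook (index,
  guideline, laboratory information, questionnaire with up to 3 assessment
  columns, auto-generated summary, rights). Workbook output is byte-stable.
- **Reporting** (`labsafescore.reporting`) — summary tables and color-coded
  radar charts (5 shaded bands, up to 3 overlaid polygons: blue/red/grey;
  undefined scopes break the polygon), deterministic SVG output.
- **Synthetic data** (`labsafescore.synthetic`) — seeded generator of
  assessments/cohorts with configurable level distributions (global or
  per-area), blank and N/A rates; lab *i* draws from
  `SeedSequence([seed, i])` so any lab is regenerable on its own.

## CLI

```sh
labsafescore validate builtin                    # check an instrument schema
labsafescore score lab.json --policy exclude     # ScoreReport JSON (--table for text)
labsafescore compare base.json follow.json --radar radar.svg
labsafescore aggregate labs/ --table             # cohort "mean (±sd); range lo–hi%"
labsafescore gaps lab.json --table               # improvement plan
labsafescore convert lab.json --to workbook --out lab.xlsx
labsafescore report lab.json --radar radar.svg --level category
labsafescore generate --seed 7 --n-labs 17 | labsafescore aggregate -
```

Results go to stdout or `--out`; diagnostics to stderr. Exit codes:
0 success, 1 user/validation error, 2 internal error. Assessment inputs may
be JSON, CSV, or `.xlsx`; `-` reads JSON from stdin.

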