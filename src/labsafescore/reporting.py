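"""Tables and color-coded radar charts for score reports and cohorts.

Radar charts draw one axis per scope in instrument order on a fixed 0-100
radial scale, with five shaded concentric bands at 20-point intervals and
one polygon per assessment (first series blue, second red, third grey).
Undefined scopes leave a gap in the polygon.  Rendering is deterministic:
identical inputs and style give identical vector-output bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .aggregation import CohortSummary  # noqa: E402
from .errors import LabSafeError  # noqa: E402
from .scoring import ScoreReport  # noqa: E402
from .taxonomy import Taxonomy  # noqa: E402

__all__ = ["RadarStyle", "render_radar", "render_summary_tables",
           "render_cohort_table", "format_cell"]

MAX_OVERLAYS = 3


@dataclass(frozen=True)
class RadarStyle:
    """Colors and line styling; bands run bottom (worst) to top (best)."""

    band_colors: tuple[str, ...] = (
        "#d73027", "#fc8d59", "#fee08b", "#d9ef8b", "#91cf60")
    series_colors: tuple[str, ...] = ("#1f77b4", "#d62728", "#7f7f7f")
    band_alpha: float = 0.35
    line_width: float = 2.0
    figsize: tuple[float, float] = (8.0, 8.0)


def _scope_axes(t: Taxonomy, level: str) -> list[tuple[str, str]]:
    if level == "area":
        return [(a.id, a.name) for a in t.areas]
    if level == "category":
        return [(c.id, c.name) for c in t.iter_categories()]
    raise LabSafeError(f"unknown radar level {level!r} "
                       "(expected 'area' or 'category')")


def build_radar_figure(reports: Sequence[ScoreReport], t: Taxonomy,
                       level: str = "category",
                       style: RadarStyle | None = None):
    """Build (figure, axes) for a radar chart; exposed for inspection."""
    if not reports:
        raise LabSafeError("radar chart needs at least 1 report")
    if len(reports) > MAX_OVERLAYS:
        raise LabSafeError(
            f"radar chart overlays at most {MAX_OVERLAYS} reports, "
            f"got {len(reports)}")
    style = style or RadarStyle()
    axes_spec = _scope_axes(t, level)
    n = len(axes_spec)
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)

    fig, ax = plt.subplots(figsize=style.figsize,
                           subplot_kw={"projection": "polar"})
    ax.set_theta_offset(np.pi / 2)
    ax.set_theta_direction(-1)
    ax.set_ylim(0, 100)
    ax.set_yticks([20, 40, 60, 80, 100])

    theta_fill = np.linspace(0, 2 * np.pi, 256)
    for b, color in enumerate(style.band_colors):
        ax.fill_between(theta_fill, 20 * b, 20 * (b + 1),
                        color=color, alpha=style.band_alpha, zorder=0)

    for i, report in enumerate(reports):
        pm = report.scope_percent_map()
        values = np.array(
            [np.nan if pm[sid] is None else pm[sid] for sid, _ in axes_spec],
            dtype=float)
        # close the polygon only if the first axis is defined
        th = np.concatenate([angles, angles[:1]])
        vals = np.concatenate([values, values[:1]])
        color = style.series_colors[i % len(style.series_colors)]
        ax.plot(th, vals, color=color, linewidth=style.line_width,
                label=report.label, zorder=2 + i)
        ax.fill(th[~np.isnan(vals)], vals[~np.isnan(vals)],
                color=color, alpha=0.08, zorder=1)

    ax.set_xticks(angles)
    ax.set_xticklabels([name for _, name in axes_spec], fontsize=8)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1))
    return fig, ax


def render_radar(reports: Sequence[ScoreReport], t: Taxonomy,
                 out: str | Path, level: str = "category",
                 style: RadarStyle | None = None) -> Path:
    """Render the radar chart to ``out`` (format from the extension)."""
    fig, _ = build_radar_figure(reports, t, level=level, style=style)
    out = Path(out)
    try:
        # hashsalt + stripped date metadata keep vector output byte-stable
        with plt.rc_context({"svg.hashsalt": "labsafescore"}):
            metadata = {"Date": None} if out.suffix == ".svg" else None
            fig.savefig(out, bbox_inches="tight", metadata=metadata)
    finally:
        plt.close(fig)
    return out


def format_cell(percent: float | None) -> str:
    """Presentation rounding: one decimal; Undefined renders as N/A."""
    return "N/A" if percent is None else f"{percent:.1f}"


def render_summary_tables(reports: Sequence[ScoreReport],
                          t: Taxonomy) -> str:
    """Tabulate overall/area/category scores, one column per assessment."""
    if not reports:
        raise LabSafeError("summary table needs at least 1 report")
    labels = [r.label for r in reports]

    rows: list[tuple[str, list[str]]] = []
    rows.append(("Overall", [format_cell(r.overall.percent)
                             for r in reports]))
    for i, area in enumerate(t.areas):
        rows.append((area.name,
                     [format_cell(r.per_area[i].percent) for r in reports]))
    for i, cat in enumerate(t.iter_categories()):
        rows.append(("  " + cat.name,
                     [format_cell(r.per_category[i].percent)
                      for r in reports]))
    rows.append(("Completion %",
                 [f"{r.completion_percent:.1f}" for r in reports]))
    rows.append(("Confidence", [r.confidence_band for r in reports]))

    name_w = max(len("Scope"), *(len(name) for name, _ in rows))
    col_ws = [max(len(lbl), 8) for lbl in labels]
    out = [" | ".join(["Scope".ljust(name_w)]
                      + [lbl.rjust(w) for lbl, w in zip(labels, col_ws)])]
    out.append("-+-".join(["-" * name_w] + ["-" * w for w in col_ws]))
    for name, cells in rows:
        out.append(" | ".join([name.ljust(name_w)]
                              + [c.rjust(w) for c, w in zip(cells, col_ws)]))
    return "\n".join(out) + "\n"


def _cohort_cell(stats) -> str:
    if stats.n_defined == 0:
        return "N/A"
    if stats.sd is None:
        return f"{stats.mean:.1f}; range {stats.min:.1f}-{stats.max:.1f}%"
    return (f"{stats.mean:.1f} (±{stats.sd:.1f}); "
            f"range {stats.min:.1f}-{stats.max:.1f}%")


def render_cohort_table(summary: CohortSummary, t: Taxonomy) -> str:
    """Cohort table in "mean (±sd); range min-max%" cell grammar."""
    rows: list[tuple[str, str]] = []
    rows.append((f"Overall ({summary.n_labs} laboratories)",
                 _cohort_cell(summary.per_scope["overall"])))
    for area in t.areas:
        rows.append((area.name, _cohort_cell(summary.per_scope[area.id])))
    for cat in t.iter_categories():
        rows.append(("  " + cat.name,
                     _cohort_cell(summary.per_scope[cat.id])))
    name_w = max(len(name) for name, _ in rows)
    lines = [f"{name.ljust(name_w)}  {cell}" for name, cell in rows]
    lines.append("")
    lines.append(f"Largest discrepancies ({summary.discrepancy_metric}):")
    for scope, sd in summary.discrepancy_ranking[:5]:
        cat_name = t.category(scope).name
        sd_txt = "N/A" if sd is None else f"{sd:.1f}"
        lines.append(f"  {cat_name}: SD {sd_txt}")
    return "\n".join(lines) + "\n"
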