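"""Figure assembly: step curves, censor ticks, at-risk tables, test boxes.

Rendering is split in two stages.  :func:`build_render_plan` turns a
:class:`~survfig.plotspec.PlotSpec` plus computed curves and test results
into a :class:`RenderPlan` — a structured list of drawable elements with
final coordinates and styles.  :func:`render_figure` draws that plan with
matplotlib onto any of the supported backends (png, pdf, svg, eps, jpg,
tif).  Tests assert against the plan, not pixels, and vector output is
deterministic: identical spec + data give byte-identical svg.

Axis handling follows a simple contract: explicit settings with
``max > min`` and ``step > 0`` produce the exact tick sequence
``min, min+step, ..., max``; anything degenerate falls back to automatic
"nice" ticks over the data range.  A y-axis maximum above 1 switches the
display to percent — curve values are scaled by 100 for drawing only,
statistics are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib
matplotlib.use("Agg")

import numpy as np
from matplotlib import ticker
from matplotlib.figure import Figure
from matplotlib.lines import Line2D

from .kmcore import KMCurve, at_risk_counts, survival_at
from .logrank import LogrankResult, format_p
from .plotspec import AxisSpec, PlotSpec

__all__ = ["FORMATS", "ResolvedAxes", "RenderPlan", "resolve_axis",
           "percent_mode", "build_render_plan", "render_figure"]

FORMATS = ("png", "pdf", "svg", "eps", "jpg", "tif")

_LINESTYLES = {"solid": "-", "dashed": "--", "dotted": ":"}
_SVG_HASHSALT = "survfig"


def resolve_axis(spec: AxisSpec, data_range: tuple[float, float]
                 ) -> tuple[np.ndarray, tuple[float, float]]:
    """Tick positions and effective limits for one axis.

    Explicit scaling applies when ``spec.max > spec.min`` and
    ``spec.step > 0``; then ticks run ``min, min+step, ..., max`` and the
    limits are exactly (min, max).  Otherwise automatic nice ticks cover
    ``data_range``.
    """
    if spec.max > spec.min and spec.step > 0:
        n = int(round((spec.max - spec.min) / spec.step))
        ticks = spec.min + spec.step * np.arange(n + 1)
        ticks = ticks[ticks <= spec.max + 1e-9 * max(1.0, abs(spec.max))]
        return ticks, (spec.min, spec.max)
    lo, hi = float(data_range[0]), float(data_range[1])
    if not np.isfinite([lo, hi]).all() or hi <= lo:
        lo, hi = 0.0, max(hi, 1.0) if np.isfinite(hi) else 1.0
    ticks = ticker.MaxNLocator(nbins="auto").tick_values(lo, hi)
    return np.asarray(ticks, dtype=float), (float(ticks[0]), float(ticks[-1]))


def percent_mode(y_axis: AxisSpec) -> bool:
    """True when the y maximum exceeds 1: the axis is read as percent."""
    return y_axis.max > 1


@dataclass(frozen=True)
class ResolvedAxes:
    x_ticks: np.ndarray
    x_limits: tuple[float, float]
    y_ticks: np.ndarray
    y_limits: tuple[float, float]
    x_label: str
    y_label: str
    percent_mode: bool


@dataclass(frozen=True)
class PlanCurve:
    label: str
    x: np.ndarray
    y: np.ndarray
    color: str
    line_width: float
    line_type: str


@dataclass(frozen=True)
class PlanCensorMarks:
    label: str
    times: np.ndarray
    values: np.ndarray
    color: str


@dataclass(frozen=True)
class PlanAtRiskRow:
    label: str
    color: str
    counts: np.ndarray


@dataclass(frozen=True)
class PlanAtRisk:
    grid: np.ndarray
    rows: tuple[PlanAtRiskRow, ...]


@dataclass(frozen=True)
class PlanLegend:
    pos: tuple[float, float]
    entries: tuple[tuple[str, str, float, str], ...]  # (text, color, lw, ls)
    framed: bool


@dataclass(frozen=True)
class PlanTestBox:
    pos: tuple[float, float]
    lines: tuple[str, ...]
    framed: bool


@dataclass(frozen=True)
class PlanInfoText:
    pos: tuple[float, float]
    text: str


@dataclass(frozen=True)
class RenderPlan:
    """Everything :func:`render_figure` draws, in draw order."""

    axes: ResolvedAxes
    curves: tuple[PlanCurve, ...]
    censor_marks: tuple[PlanCensorMarks, ...]
    at_risk: PlanAtRisk | None
    legend: PlanLegend | None
    test_box: PlanTestBox | None
    info_text: PlanInfoText | None


def _display_value(v: np.ndarray, invert: bool, percent: bool) -> np.ndarray:
    out = np.asarray(v, dtype=float)
    if invert:
        out = 1.0 - out
    if percent:
        out = 100.0 * out
    return out


def _step_xy(curve: KMCurve, x_max: float, invert: bool, percent: bool
             ) -> tuple[np.ndarray, np.ndarray]:
    """Step-function polyline from t=0 out to the x-axis maximum."""
    xs = [0.0]
    ys = [1.0]
    for t, s in zip(curve.event_times, curve.survival):
        xs.extend([t, t])
        ys.extend([ys[-1], s])
    tail = max(x_max, curve.max_time)
    xs.append(tail)
    ys.append(ys[-1])
    return np.asarray(xs), _display_value(np.asarray(ys), invert, percent)


def build_render_plan(spec: PlotSpec, curves: Sequence[KMCurve],
                      tests: Sequence[LogrankResult] | None = None
                      ) -> RenderPlan:
    """Resolve a spec + computed results into concrete drawables."""
    if not curves:
        raise ValueError("at least one curve is required")
    styles = list(spec.level_styles)
    if len(styles) < len(curves):
        raise ValueError(
            f"spec has {len(styles)} level styles but {len(curves)} curves"
        )

    data_t_max = max(c.max_time for c in curves)
    x_ticks, x_lim = resolve_axis(spec.x_axis, (0.0, data_t_max))
    pct = percent_mode(spec.y_axis)
    y_hi = 100.0 if pct else 1.0
    y_ticks, y_lim = resolve_axis(spec.y_axis, (0.0, y_hi))
    axes = ResolvedAxes(x_ticks=x_ticks, x_limits=x_lim, y_ticks=y_ticks,
                        y_limits=y_lim, x_label=spec.x_axis.label,
                        y_label=spec.y_axis.label, percent_mode=pct)

    plan_curves = []
    censor_marks = []
    for curve, style in zip(curves, styles):
        x, y = _step_xy(curve, x_lim[1], spec.invert, pct)
        plan_curves.append(PlanCurve(
            label=style.legend_text or curve.group_label,
            x=x, y=y, color=style.color, line_width=style.line_width,
            line_type=style.line_type))
        if spec.show_censor_marks and curve.censor_times.size:
            vals = _display_value(survival_at(curve, curve.censor_times),
                                  spec.invert, pct)
            censor_marks.append(PlanCensorMarks(
                label=style.legend_text or curve.group_label,
                times=curve.censor_times, values=vals, color=style.color))

    at_risk = None
    if spec.show_at_risk:
        grid_ticks = x_ticks[(x_ticks >= x_lim[0]) & (x_ticks <= x_lim[1])]
        table = at_risk_counts(
            {c.group_label: np.concatenate([
                np.repeat(c.event_times, c.n_events), c.censor_times])
             for c in curves},
            grid_ticks)
        rows = tuple(
            PlanAtRiskRow(label=style.legend_text or curve.group_label,
                          color=style.color,
                          counts=table.counts[curve.group_label])
            for curve, style in zip(curves, styles))
        at_risk = PlanAtRisk(grid=table.grid, rows=rows)

    legend = None
    if spec.show_legend:
        entries = tuple(
            (style.legend_text or curve.group_label, style.color,
             style.line_width, style.line_type)
            for curve, style in zip(curves, styles))
        legend = PlanLegend(pos=spec.legend_pos, entries=entries,
                            framed=spec.preferences.legend.box_type == "closed")

    test_box = None
    if tests and spec.test_mode != "none":
        lines = tuple(
            f"{r.description or 'Logrank'}: p = {format_p(r.p_value, spec.p_digits)}"
            for r in tests)
        test_box = PlanTestBox(pos=spec.test_box_pos, lines=lines,
                               framed=spec.preferences.logrank.box_type == "closed")

    info = None
    if spec.info_text:
        info = PlanInfoText(pos=spec.info_pos, text=spec.info_text)

    return RenderPlan(axes=axes, curves=tuple(plan_curves),
                      censor_marks=tuple(censor_marks), at_risk=at_risk,
                      legend=legend, test_box=test_box, info_text=info)


def _fmt_tick(v: float) -> str:
    return f"{v:g}"


def _draw_plan(plan: RenderPlan, spec: PlotSpec, fig: Figure) -> None:
    prefs = spec.preferences
    ax = fig.add_axes((0.12, 0.12, 0.83, 0.83))
    axes = plan.axes

    for pc in plan.curves:
        ax.plot(pc.x, pc.y, color=pc.color, linewidth=pc.line_width,
                linestyle=_LINESTYLES[pc.line_type],
                solid_joinstyle="miter", label=pc.label)
    for cm in plan.censor_marks:
        ax.plot(cm.times, cm.values, linestyle="none", marker="|",
                markersize=8, markeredgewidth=1.2, color=cm.color)

    ax.set_xlim(axes.x_limits)
    ax.set_ylim(axes.y_limits)
    ax.set_xticks(axes.x_ticks)
    ax.set_yticks(axes.y_ticks)
    ax.set_xticklabels([_fmt_tick(v) for v in axes.x_ticks])
    ax.set_yticklabels([_fmt_tick(v) for v in axes.y_ticks])
    scale = prefs.label.scale_factor
    ax.set_xlabel(axes.x_label, fontsize=10 * scale, color=prefs.label.color)
    ax.set_ylabel(axes.y_label, fontsize=10 * scale, color=prefs.label.color)
    for spine in ax.spines.values():
        spine.set_color(prefs.axes.color)
    ax.tick_params(colors=prefs.axes.color)
    ax.set_facecolor(prefs.plain.background)

    if plan.at_risk is not None:
        rows = plan.at_risk.rows
        rs = prefs.under_risk.scale_factor
        for r, row in enumerate(rows):
            y_frac = 0.02 + 0.04 * (len(rows) - 1 - r)
            for x, count in zip(plan.at_risk.grid, row.counts):
                ax.text(x, y_frac, str(int(count)), color=row.color,
                        fontsize=8 * rs, ha="center", va="bottom",
                        transform=ax.get_xaxis_transform())

    if plan.legend is not None:
        handles = [Line2D([], [], color=c, linewidth=lw,
                          linestyle=_LINESTYLES[ls], label=text)
                   for text, c, lw, ls in plan.legend.entries]
        leg = ax.legend(handles=handles, loc="lower left",
                        bbox_to_anchor=plan.legend.pos,
                        bbox_transform=ax.transData,
                        frameon=plan.legend.framed,
                        fontsize=9 * prefs.legend.scale_factor,
                        labelcolor=prefs.legend.color)
        if plan.legend.framed:
            leg.get_frame().set_facecolor(prefs.legend.background)

    if plan.test_box is not None:
        bbox = (dict(facecolor=prefs.logrank.background,
                     edgecolor=prefs.logrank.color, boxstyle="square")
                if plan.test_box.framed else None)
        ax.text(plan.test_box.pos[0], plan.test_box.pos[1],
                "\n".join(plan.test_box.lines),
                fontsize=9 * prefs.logrank.scale_factor,
                color=prefs.logrank.color, ha="left", va="bottom", bbox=bbox)

    if plan.info_text is not None:
        ax.text(plan.info_text.pos[0], plan.info_text.pos[1],
                plan.info_text.text, fontsize=9 * prefs.plain.scale_factor,
                color=prefs.plain.color, ha="left", va="bottom")


def render_figure(spec: PlotSpec, curves: Sequence[KMCurve],
                  tests: Sequence[LogrankResult] | None,
                  out_path: str | Path, format: str | None = None) -> Path:
    """Draw a spec into a figure file.

    ``format`` defaults to the output suffix; one of png, pdf, svg, eps,
    jpg, tif.  SVG output is byte-identical across runs for identical
    inputs (fixed hash salt, no embedded date).
    """
    out_path = Path(out_path)
    fmt = (format or out_path.suffix.lstrip(".")).lower()
    if fmt not in FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; choose from {FORMATS}")
    plan = build_render_plan(spec, curves, tests)
    with matplotlib.rc_context({"svg.hashsalt": _SVG_HASHSALT}):
        fig = Figure(figsize=(8.0, 6.0), dpi=100)
        fig.patch.set_facecolor(spec.preferences.plain.background)
        _draw_plan(plan, spec, fig)
        save_kwargs: dict = {}
        if fmt == "svg":
            save_kwargs["metadata"] = {"Date": None}
        fig.savefig(out_path, format="tiff" if fmt == "tif" else fmt,
                    **save_kwargs)
    return out_path
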