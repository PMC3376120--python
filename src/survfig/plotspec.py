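"""Declarative, persistable plot specifications.

A :class:`PlotSpec` is the complete recipe for one survival figure: where
the data live (never the data themselves), the role assignment, an optional
filter string, per-level curve styles, axis settings, legend/test-box
placement and styling preferences.  Specs serialize to a human-readable
JSON document (extension ``.kmspec.json``) carrying a ``format_version``
field; saved specs are diffable, re-renderable in batch and safe to keep in
version control.

Loading is strict: unknown fields are rejected with the offending field
path, so typos surface immediately instead of being silently dropped.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from matplotlib import colors as mcolors

from .dataio import AnalysisInput, RoleAssignment, SurvivalDataset

__all__ = [
    "FORMAT_VERSION", "DEFAULT_PALETTE", "SpecError",
    "LevelStyle", "AxisSpec", "ItemStyle", "Preferences", "PlotSpec",
    "parse_color", "default_spec", "save_spec", "load_spec",
]

FORMAT_VERSION = 1

#: Fixed default palette for up to eight factor levels, starting with black.
DEFAULT_PALETTE = (
    "#000000",  # black
    "#E41A1C",  # red
    "#377EB8",  # blue
    "#4DAF4A",  # green
    "#984EA3",  # purple
    "#FF7F00",  # orange
    "#A65628",  # brown
    "#F781BF",  # pink
)

LINE_TYPES = ("solid", "dashed", "dotted")
TEST_MODES = ("none", "global", "pairwise")
BOX_TYPES = ("open", "closed")

_HEX_RE = re.compile(r"#[0-9A-F]{6}\Z")


class SpecError(ValueError):
    """Malformed plot specification (file or field values)."""


def parse_color(value: str | tuple[int, int, int] | list[int]) -> str:
    """Normalize a color to canonical uppercase ``#RRGGBB``.

    Accepts a named color (matplotlib's name vocabulary, e.g. ``"black"``), a
    hex string in either case, or an RGB triple of 0-255 integers:
    ``(128, 128, 128)`` becomes ``"#808080"``.
    """
    if isinstance(value, (tuple, list)):
        if len(value) != 3:
            raise SpecError(f"RGB triple must have 3 channels, got {len(value)}")
        for c in value:
            if not (isinstance(c, (int,)) and 0 <= c <= 255):
                raise SpecError(f"RGB channel out of range 0-255: {c!r}")
        return "#{:02X}{:02X}{:02X}".format(*value)
    if isinstance(value, str):
        text = value.strip()
        if text.startswith("#"):
            if not re.fullmatch(r"#[0-9A-Fa-f]{6}", text):
                raise SpecError(f"malformed hex color {value!r}")
            return text.upper()
        try:
            rgb = mcolors.to_rgb(text)
        except ValueError:
            raise SpecError(f"unknown color name {value!r}") from None
        return "#{:02X}{:02X}{:02X}".format(*(round(255 * c) for c in rgb))
    raise SpecError(f"cannot interpret color {value!r}")


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise SpecError(msg)


@dataclass(frozen=True)
class LevelStyle:
    """Drawing style and legend text for one factor level's curve."""

    level: float
    color: str = "#000000"
    line_width: float = 1.5
    line_type: str = "solid"
    legend_text: str = ""

    def __post_init__(self) -> None:
        _check(bool(_HEX_RE.match(self.color)),
               f"color must be canonical #RRGGBB, got {self.color!r}")
        _check(self.line_width > 0, f"line_width must be > 0, got {self.line_width}")
        _check(self.line_type in LINE_TYPES,
               f"line_type must be one of {LINE_TYPES}, got {self.line_type!r}")


@dataclass(frozen=True)
class AxisSpec:
    """Axis limits, step and label.

    Degenerate settings (max <= min, or step <= 0) are legal and mean
    "autoscale": the renderer falls back to automatic nice ticks over the
    data range.
    """

    min: float = 0.0
    max: float = 0.0
    step: float = 0.0
    label: str = ""


@dataclass(frozen=True)
class ItemStyle:
    """Styling of one figure component (legend box, test box, ...)."""

    color: str = "#000000"
    background: str = "#FFFFFF"
    box_type: str = "open"
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        for c in (self.color, self.background):
            _check(bool(_HEX_RE.match(c)), f"color must be #RRGGBB, got {c!r}")
        _check(self.box_type in BOX_TYPES,
               f"box_type must be one of {BOX_TYPES}, got {self.box_type!r}")
        _check(self.scale_factor > 0, "scale_factor must be > 0")


@dataclass(frozen=True)
class Preferences:
    """Per-item styles plus figure-global line width and margins."""

    plain: ItemStyle = field(default_factory=ItemStyle)
    axes: ItemStyle = field(default_factory=ItemStyle)
    label: ItemStyle = field(default_factory=ItemStyle)
    legend: ItemStyle = field(default_factory=ItemStyle)
    logrank: ItemStyle = field(default_factory=ItemStyle)
    under_risk: ItemStyle = field(default_factory=ItemStyle)
    line_width: float = 1.5
    margins: float = 0.05

    def __post_init__(self) -> None:
        _check(self.line_width > 0, "line_width must be > 0")
        _check(self.margins >= 0, "margins must be >= 0")


@dataclass(frozen=True)
class PlotSpec:
    """Everything needed to re-render one figure, except the data rows.

    A spec stores only the *location* of its data source; serialized spec
    files therefore contain no survival observations.
    """

    data_path: str
    dialect: str = "dat"
    roles: RoleAssignment = field(default_factory=lambda: RoleAssignment("timevar", "statusvar"))
    filter_string: str | None = None
    level_styles: tuple[LevelStyle, ...] = ()
    x_axis: AxisSpec = field(default_factory=AxisSpec)
    y_axis: AxisSpec = field(default_factory=AxisSpec)
    show_censor_marks: bool = False
    show_at_risk: bool = False
    invert: bool = False
    show_legend: bool = False
    legend_pos: tuple[float, float] = (0.0, 0.0)
    test_mode: str = "none"
    p_digits: int = 4
    test_box_pos: tuple[float, float] = (0.0, 0.0)
    pair_descriptions: tuple[str, ...] | None = None
    info_text: str | None = None
    info_pos: tuple[float, float] = (0.0, 0.0)
    preferences: Preferences = field(default_factory=Preferences)

    def __post_init__(self) -> None:
        _check(self.test_mode in TEST_MODES,
               f"test_mode must be one of {TEST_MODES}, got {self.test_mode!r}")
        _check(1 <= self.p_digits <= 10,
               f"p_digits must be in 1..10, got {self.p_digits}")
        _check(self.dialect in ("dat", "csv"),
               f"dialect must be 'dat' or 'csv', got {self.dialect!r}")


def _fmt_level(level: float) -> str:
    return str(int(level)) if float(level).is_integer() else str(level)


def default_spec(source: AnalysisInput | SurvivalDataset,
                 roles: RoleAssignment | None = None,
                 data_path: str | None = None,
                 dialect: str = "dat") -> PlotSpec:
    """Build the default spec for a dataset and role assignment.

    One :class:`LevelStyle` per factor level, colored from
    :data:`DEFAULT_PALETTE` (cycled past eight levels), legend text
    ``"<factor> = <level>"``; p-value precision 4; no tests, legend hidden
    when there is no factor variable.
    """
    if isinstance(source, AnalysisInput):
        ai = source
        if roles is not None and roles != ai.roles:
            raise ValueError("roles argument conflicts with the AnalysisInput roles")
    else:
        from .dataio import assign_roles
        if roles is None:
            raise ValueError("roles are required when passing a raw dataset")
        ai = assign_roles(source, roles)
    roles = ai.roles
    path = data_path or ai.dataset.source_path or ""
    has_factor = roles.factor_var is not None
    levels = ai.factor_levels if has_factor else [1.0]
    styles = tuple(
        LevelStyle(
            level=lv,
            color=DEFAULT_PALETTE[i % len(DEFAULT_PALETTE)],
            legend_text=(f"{roles.factor_var} = {_fmt_level(lv)}" if has_factor
                         else "all subjects"),
        )
        for i, lv in enumerate(levels)
    )
    return PlotSpec(
        data_path=str(path),
        dialect=dialect,
        roles=roles,
        level_styles=styles,
        x_axis=AxisSpec(label=roles.time_var),
        y_axis=AxisSpec(label="Survival"),
        show_legend=has_factor,
    )


# --- JSON (de)serialization ------------------------------------------------

def _style_to_dict(s: LevelStyle) -> dict:
    return {"level": s.level, "color": s.color, "line_width": s.line_width,
            "line_type": s.line_type, "legend_text": s.legend_text}


def spec_to_dict(spec: PlotSpec) -> dict:
    """Plain-dict form of ``spec`` (what :func:`save_spec` writes)."""
    return {
        "format_version": FORMAT_VERSION,
        "data_path": spec.data_path,
        "dialect": spec.dialect,
        "roles": {
            "time_var": spec.roles.time_var,
            "status_var": spec.roles.status_var,
            "factor_var": spec.roles.factor_var,
            "event_code": spec.roles.event_code,
        },
        "filter_string": spec.filter_string,
        "level_styles": [_style_to_dict(s) for s in spec.level_styles],
        "x_axis": dataclasses.asdict(spec.x_axis),
        "y_axis": dataclasses.asdict(spec.y_axis),
        "show_censor_marks": spec.show_censor_marks,
        "show_at_risk": spec.show_at_risk,
        "invert": spec.invert,
        "show_legend": spec.show_legend,
        "legend_pos": list(spec.legend_pos),
        "test_mode": spec.test_mode,
        "p_digits": spec.p_digits,
        "test_box_pos": list(spec.test_box_pos),
        "pair_descriptions": (list(spec.pair_descriptions)
                              if spec.pair_descriptions is not None else None),
        "info_text": spec.info_text,
        "info_pos": list(spec.info_pos),
        "preferences": {
            **{name: dataclasses.asdict(getattr(spec.preferences, name))
               for name in ("plain", "axes", "label", "legend", "logrank",
                            "under_risk")},
            "line_width": spec.preferences.line_width,
            "margins": spec.preferences.margins,
        },
    }


def _build(cls, data: dict, path: str):
    """Construct dataclass ``cls`` from ``data``, rejecting unknown fields."""
    if not isinstance(data, dict):
        raise SpecError(f"{path}: expected an object, got {type(data).__name__}")
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise SpecError(f"{path}: unknown field {sorted(unknown)[0]!r}")
    try:
        return cls(**data)
    except (TypeError, SpecError) as exc:
        raise SpecError(f"{path}: {exc}") from None


def spec_from_dict(doc: dict) -> PlotSpec:
    """Inverse of :func:`spec_to_dict`; strict about versions and fields."""
    if not isinstance(doc, dict):
        raise SpecError("spec document must be a JSON object")
    version = doc.get("format_version")
    if version is None:
        raise SpecError("missing 'format_version' field")
    if version != FORMAT_VERSION:
        raise SpecError(
            f"unsupported format_version {version!r}; this build reads version "
            f"{FORMAT_VERSION}"
        )
    d = dict(doc)
    d.pop("format_version")
    known = {
        "data_path", "dialect", "roles", "filter_string", "level_styles",
        "x_axis", "y_axis", "show_censor_marks", "show_at_risk", "invert",
        "show_legend", "legend_pos", "test_mode", "p_digits", "test_box_pos",
        "pair_descriptions", "info_text", "info_pos", "preferences",
    }
    unknown = set(d) - known
    if unknown:
        raise SpecError(f"unknown field {sorted(unknown)[0]!r}")

    def pop(key, default=None):
        return d.pop(key, default)

    roles_d = pop("roles", {})
    roles = _build(RoleAssignment, roles_d, "roles")
    styles_d = pop("level_styles", [])
    if not isinstance(styles_d, list):
        raise SpecError("level_styles: expected a list")
    styles = tuple(_build(LevelStyle, s, f"level_styles[{i}]")
                   for i, s in enumerate(styles_d))
    x_axis = _build(AxisSpec, pop("x_axis", {}), "x_axis")
    y_axis = _build(AxisSpec, pop("y_axis", {}), "y_axis")
    prefs_d = pop("preferences", {})
    if not isinstance(prefs_d, dict):
        raise SpecError("preferences: expected an object")
    prefs_d = dict(prefs_d)
    item_styles = {}
    for name in ("plain", "axes", "label", "legend", "logrank", "under_risk"):
        if name in prefs_d:
            item_styles[name] = _build(ItemStyle, prefs_d.pop(name),
                                       f"preferences.{name}")
    prefs = _build(Preferences, {**prefs_d, **item_styles}, "preferences")

    def pair(key, default=(0.0, 0.0)):
        v = pop(key, list(default))
        if not (isinstance(v, (list, tuple)) and len(v) == 2):
            raise SpecError(f"{key}: expected [x, y]")
        return (float(v[0]), float(v[1]))

    legend_pos = pair("legend_pos")
    test_box_pos = pair("test_box_pos")
    info_pos = pair("info_pos")
    pair_desc = pop("pair_descriptions")
    if pair_desc is not None:
        pair_desc = tuple(str(s) for s in pair_desc)

    kwargs = dict(
        data_path=pop("data_path", ""),
        dialect=pop("dialect", "dat"),
        roles=roles,
        filter_string=pop("filter_string"),
        level_styles=styles,
        x_axis=x_axis,
        y_axis=y_axis,
        show_censor_marks=bool(pop("show_censor_marks", False)),
        show_at_risk=bool(pop("show_at_risk", False)),
        invert=bool(pop("invert", False)),
        show_legend=bool(pop("show_legend", False)),
        legend_pos=legend_pos,
        test_mode=pop("test_mode", "none"),
        p_digits=int(pop("p_digits", 4)),
        test_box_pos=test_box_pos,
        pair_descriptions=pair_desc,
        info_text=pop("info_text"),
        info_pos=info_pos,
        preferences=prefs,
    )
    try:
        return PlotSpec(**kwargs)
    except SpecError:
        raise
    except (TypeError, ValueError) as exc:
        raise SpecError(str(exc)) from None


def save_spec(spec: PlotSpec, path: str | Path) -> Path:
    """Write ``spec`` as versioned JSON; ``load_spec`` round-trips it."""
    path = Path(path)
    path.write_text(json.dumps(spec_to_dict(spec), indent=2) + "\n",
                    encoding="utf-8")
    return path


def load_spec(path: str | Path) -> PlotSpec:
    """Read a spec file, validating version and every field name."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SpecError(f"{path}: not valid JSON ({exc})") from None
    return spec_from_dict(doc)
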