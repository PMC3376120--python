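"""Plot specifications: color parsing, defaults, strict JSON round-trips."""

import dataclasses
import json

import pytest
from hypothesis import given, strategies as st

import survfig as sf
from survfig.plotspec import (DEFAULT_PALETTE, ItemStyle, Preferences,
                              SpecError, spec_from_dict, spec_to_dict)


class TestParseColor:
    @pytest.mark.parametrize("value,expected", [
        ((128, 128, 128), "#808080"),   # "dark grey" of the worked example
        ((192, 192, 192), "#C0C0C0"),   # "light grey"
        ("black", "#000000"),
        ("#ff0000", "#FF0000"),
        ((0, 0, 0), "#000000"),
        ("white", "#FFFFFF"),
    ])
    def test_canonical_hex(self, value, expected):
        assert sf.parse_color(value) == expected

    @pytest.mark.parametrize("bad", [
        (256, 0, 0), (0, -1, 0), (1, 2), "no-such-color", "#12345", "#12345G",
    ])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(SpecError):
            sf.parse_color(bad)


class TestDefaultSpec:
    def test_legend_defaults_follow_factor_levels(self, default_analysis,
                                                  example_dat):
        spec = sf.default_spec(default_analysis, data_path=str(example_dat))
        assert [s.legend_text for s in spec.level_styles] == [
            "factorvar = 1", "factorvar = 2", "factorvar = 3"]
        assert spec.level_styles[0].color == "#000000"
        assert spec.show_legend

    def test_no_factor_hides_legend(self):
        import pandas as pd
        ds = sf.SurvivalDataset(pd.DataFrame({"t": [1.0, 2.0], "s": [1.0, 0.0]}))
        ai = sf.assign_roles(ds, sf.RoleAssignment("t", "s"))
        spec = sf.default_spec(ai, data_path="x.dat")
        assert len(spec.level_styles) == 1
        assert not spec.show_legend

    def test_p_digits_default_is_four(self, default_analysis):
        spec = sf.default_spec(default_analysis, data_path="x.dat")
        assert spec.p_digits == 4
        assert spec.test_mode == "none"


class TestSaveLoad:
    def test_worked_example_round_trip(self, worked_example):
        p1, p2, spec, spec_filtered = worked_example
        assert sf.load_spec(p1) == spec
        assert sf.load_spec(p2) == spec_filtered

    def test_default_spec_round_trip(self, tmp_path, default_analysis):
        spec = sf.default_spec(default_analysis, data_path="example.dat")
        path = sf.save_spec(spec, tmp_path / "d.kmspec.json")
        assert sf.load_spec(path) == spec

    def test_unknown_field_named_in_error(self, tmp_path, default_analysis):
        spec = sf.default_spec(default_analysis, data_path="e.dat")
        doc = spec_to_dict(spec)
        doc["level_styles"][0]["linewidht"] = 3
        path = tmp_path / "bad.kmspec.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(SpecError, match="linewidht"):
            sf.load_spec(path)

    def test_version_mismatch_is_explicit(self, tmp_path, default_analysis):
        doc = spec_to_dict(sf.default_spec(default_analysis, data_path="e.dat"))
        doc["format_version"] = 99
        path = tmp_path / "v.kmspec.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(SpecError, match="format_version"):
            sf.load_spec(path)

    def test_not_json_is_a_parse_error(self, tmp_path):
        path = tmp_path / "x.kmspec.json"
        path.write_text("{not json")
        with pytest.raises(SpecError, match="JSON"):
            sf.load_spec(path)

    def test_spec_file_contains_no_observations(self, worked_example,
                                                default_ds):
        p1, *_ = worked_example
        text = p1.read_text()
        times = default_ds.column("timevar")
        assert repr(float(times[0])) not in text
        assert "rows" not in json.loads(text)


# -- randomized specs -------------------------------------------------------

_hex = st.integers(0, 0xFFFFFF).map(lambda v: f"#{v:06X}")
_pos = st.tuples(st.floats(-100, 100, allow_nan=False),
                 st.floats(-100, 100, allow_nan=False))
_style = st.builds(
    sf.LevelStyle,
    level=st.integers(1, 9).map(float),
    color=_hex,
    line_width=st.floats(0.5, 5, allow_nan=False),
    line_type=st.sampled_from(["solid", "dashed", "dotted"]),
    legend_text=st.text(alphabet=st.characters(codec="ascii",
                                               categories=["L", "N", "Zs"]),
                        max_size=12),
)
_axis = st.builds(sf.AxisSpec,
                  min=st.floats(-10, 10, allow_nan=False),
                  max=st.floats(-10, 110, allow_nan=False),
                  step=st.floats(0, 30, allow_nan=False),
                  label=st.text(max_size=10))
_item = st.builds(ItemStyle, color=_hex, background=_hex,
                  box_type=st.sampled_from(["open", "closed"]),
                  scale_factor=st.floats(0.5, 2, allow_nan=False))
_spec = st.builds(
    sf.PlotSpec,
    data_path=st.just("data.dat"),
    dialect=st.sampled_from(["dat", "csv"]),
    roles=st.builds(sf.RoleAssignment, time_var=st.just("t"),
                    status_var=st.just("s"),
                    factor_var=st.none() | st.just("f"),
                    event_code=st.sampled_from([1.0, 2.0])),
    filter_string=st.none() | st.just("f<2"),
    level_styles=st.lists(_style, max_size=4).map(tuple),
    x_axis=_axis, y_axis=_axis,
    show_censor_marks=st.booleans(), show_at_risk=st.booleans(),
    invert=st.booleans(), show_legend=st.booleans(),
    legend_pos=_pos, test_mode=st.sampled_from(["none", "global", "pairwise"]),
    p_digits=st.integers(1, 10), test_box_pos=_pos,
    pair_descriptions=st.none() | st.lists(st.text(max_size=8), min_size=3,
                                           max_size=3).map(tuple),
    info_text=st.none() | st.text(max_size=12), info_pos=_pos,
    preferences=st.builds(Preferences, plain=_item, axes=_item, label=_item,
                          legend=_item, logrank=_item, under_risk=_item,
                          line_width=st.floats(0.5, 5, allow_nan=False),
                          margins=st.floats(0, 0.2, allow_nan=False)),
)


@given(spec=_spec)
def test_random_spec_survives_json_round_trip(spec):
    assert spec_from_dict(json.loads(json.dumps(spec_to_dict(spec)))) == spec
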