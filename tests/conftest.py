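"""Shared fixtures: the reference simulated dataset and worked-example specs."""

from __future__ import annotations

import dataclasses

import pytest
from hypothesis import settings

import survfig as sf

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_ds() -> sf.SurvivalDataset:
    """One draw of the default four-entity design (430 subjects)."""
    return sf.simulate_dataset(dataclasses.replace(sf.DEFAULT_CONFIG, seed=7))


@pytest.fixture(scope="session")
def default_analysis(default_ds) -> sf.AnalysisInput:
    roles = sf.RoleAssignment("timevar", "statusvar", "factorvar")
    return sf.assign_roles(default_ds, roles)


@pytest.fixture()
def example_dat(tmp_path, default_ds):
    """The reference dataset written as a whitespace-delimited .dat file."""
    path = tmp_path / "example.dat"
    sf.write_table(default_ds, path, dialect="dat")
    return path


def make_worked_example_specs(tmp_path, ds):
    """Build the two publication-style spec files of the worked example.

    Greyscale curves (#000000 / #808080 / #C0C0C0), line width 3, x axis
    0..100 step 20, legend at data coordinates (70, 0.5), pairwise logrank
    tests at 4 decimals; the second spec filters out the high-risk subset
    with "filtervar<2" and switches the y axis to percent (max 100).
    """
    data_path = tmp_path / "example.dat"
    sf.write_table(ds, data_path, dialect="dat")
    roles = sf.RoleAssignment("timevar", "statusvar", "factorvar")
    base = sf.default_spec(sf.assign_roles(ds, roles), data_path="example.dat")
    styles = tuple(
        dataclasses.replace(s, color=c, line_width=3.0, legend_text=t)
        for s, c, t in zip(base.level_styles,
                           ("#000000", "#808080", "#C0C0C0"),
                           ("Group 1", "Group 2", "Group 3")))
    spec = dataclasses.replace(
        base, level_styles=styles,
        x_axis=sf.AxisSpec(0, 100, 20, "Time"),
        y_axis=sf.AxisSpec(0, 1, 0.2, "Proportion event-free"),
        show_censor_marks=True, show_at_risk=True, show_legend=True,
        legend_pos=(70.0, 0.5), test_mode="pairwise", p_digits=4,
        test_box_pos=(1.0, 0.01),
        pair_descriptions=("Group 1 vs 2", "Group 1 vs 3", "Group 2 vs 3"))
    spec_filtered = dataclasses.replace(
        spec, filter_string="filtervar<2",
        y_axis=sf.AxisSpec(0, 100, 20, "Percent event-free"),
        test_box_pos=(1.0, 1.0))
    p1 = tmp_path / "example.kmspec.json"
    p2 = tmp_path / "example_filtered.kmspec.json"
    sf.save_spec(spec, p1)
    sf.save_spec(spec_filtered, p2)
    return p1, p2, spec, spec_filtered


@pytest.fixture()
def worked_example(tmp_path, default_ds):
    return make_worked_example_specs(tmp_path, default_ds)
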