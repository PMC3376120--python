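"""Execute a plot spec end to end: load, filter, estimate, test.

This is the shared engine behind the ``draw`` command and the batch queue.
Every stage can be tracked through a :class:`StepLog`, the textual analogue
of an analysis audit trail: one entry per executed stage, in order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import dataio, filterdsl, kmcore, logrank
from .kmcore import KMCurve
from .logrank import LogrankResult
from .plotspec import LevelStyle, PlotSpec, DEFAULT_PALETTE

__all__ = ["StepLog", "PipelineResult", "execute_spec", "curves_for",
           "tests_for"]


@dataclass
class StepLog:
    """Ordered record of pipeline stages: (stage, detail) pairs."""

    entries: list[tuple[str, str]] = field(default_factory=list)

    def add(self, stage: str, detail: str) -> None:
        self.entries.append((stage, detail))

    def lines(self) -> list[str]:
        return [f"{stage}: {detail}" for stage, detail in self.entries]


@dataclass(frozen=True)
class PipelineResult:
    analysis: dataio.AnalysisInput
    curves: tuple[KMCurve, ...]
    tests: tuple[LogrankResult, ...]
    n_filtered: int


def _fmt_level(level: float) -> str:
    return str(int(level)) if float(level).is_integer() else str(level)


def curves_for(analysis: dataio.AnalysisInput) -> tuple[KMCurve, ...]:
    """One product-limit curve per factor level (level order)."""
    return tuple(
        kmcore.km_estimate(t, s, group_label=_fmt_level(lv))
        for lv, t, s in analysis.groups()
    )


def tests_for(analysis: dataio.AnalysisInput, mode: str,
              pair_descriptions: Sequence[str] | None = None
              ) -> tuple[LogrankResult, ...]:
    """Logrank results for ``mode`` in {none, global, pairwise}.

    Pairwise default descriptions follow the ``"<factor> = i, j"``
    convention; explicit ``pair_descriptions`` override them pair by pair.
    """
    if mode == "none":
        return ()
    groups = [(t, s) for _, t, s in analysis.groups()]
    labels = [_fmt_level(lv) for lv in analysis.factor_levels]
    if len(groups) < 2:
        raise ValueError("tests require a factor variable with >= 2 levels")
    if mode == "global":
        res = logrank.logrank_global(groups, labels=labels,
                                     description="Logrank (global)")
        return (res,)
    if mode == "pairwise":
        factor = analysis.roles.factor_var or "group"
        defaults = None
        if pair_descriptions is None:
            import itertools
            defaults = [f"{factor} = {labels[i]}, {labels[j]}"
                        for i, j in itertools.combinations(range(len(groups)), 2)]
        return tuple(logrank.logrank_pairwise(
            groups, labels=labels,
            descriptions=list(pair_descriptions) if pair_descriptions else defaults))
    raise ValueError(f"unknown test mode {mode!r}")


def execute_spec(spec: PlotSpec, base_dir: str | Path | None = None,
                 log: StepLog | None = None) -> PipelineResult:
    """Run the full analysis a spec describes (everything but drawing).

    ``base_dir`` anchors a relative ``data_path`` (typically the directory
    of the spec file).  Raises the underlying I/O, filter or validation
    errors unchanged; the queue layer turns them into log entries.
    """
    log = log if log is not None else StepLog()
    data_path = Path(spec.data_path)
    if base_dir is not None and not data_path.is_absolute():
        data_path = Path(base_dir) / data_path

    ds = dataio.read_table(data_path, dialect=spec.dialect)
    log.add("load", f"{data_path} ({ds.n_rows} rows, "
                    f"{len(ds.variable_names)} variables)")

    n_filtered = 0
    if spec.filter_string:
        expr = filterdsl.parse_filter(spec.filter_string)
        ds, n_filtered = filterdsl.apply_filter(ds, expr)
        log.add("filter", f"{spec.filter_string!r} removed {n_filtered} rows, "
                          f"{ds.n_rows} remain")

    analysis = dataio.assign_roles(ds, spec.roles)
    log.add("roles", f"time={spec.roles.time_var} status={spec.roles.status_var} "
                     f"factor={spec.roles.factor_var} "
                     f"(dropped {analysis.n_dropped} incomplete rows)")

    curves = curves_for(analysis)
    log.add("estimate", f"{len(curves)} survival curve(s): "
                        + ", ".join(f"{c.group_label} (n={c.n_total})"
                                    for c in curves))

    tests = tests_for(analysis, spec.test_mode, spec.pair_descriptions)
    if tests:
        log.add("test", "; ".join(
            f"{r.description}: p = {logrank.format_p(r.p_value, spec.p_digits)}"
            for r in tests))

    return PipelineResult(analysis=analysis, curves=curves, tests=tests,
                          n_filtered=n_filtered)
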