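"""Batch re-processing of saved plot specs.

A queue run renders every spec file in order into one output directory,
one figure per spec, named ``<spec stem>.<format>``.  Failures are logged
and processing continues (use ``fail_fast`` to stop at the first error);
the log always ends with the sentinel line ``Finished``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

from . import plotspec, render
from .pipeline import execute_spec

__all__ = ["QueueJob", "QueueEntry", "QueueLog", "run_queue", "SENTINEL"]

SENTINEL = "Finished"


@dataclass(frozen=True)
class QueueJob:
    """A batch: spec files, output directory, output format."""

    spec_paths: tuple[str, ...]
    out_dir: str
    format: str = "svg"


@dataclass(frozen=True)
class QueueEntry:
    spec_path: str
    status: str  # "ok" | "error"
    message: str
    output_file: str | None


@dataclass(frozen=True)
class QueueLog:
    """One entry per input spec, in input order, plus the sentinel."""

    entries: tuple[QueueEntry, ...]

    @property
    def n_ok(self) -> int:
        return sum(e.status == "ok" for e in self.entries)

    def lines(self) -> list[str]:
        out = []
        for e in self.entries:
            if e.status == "ok":
                out.append(f"{e.spec_path}: ok -> {e.output_file}")
            else:
                out.append(f"{e.spec_path}: error: {e.message}")
        out.append(SENTINEL)
        return out

    def tsv_lines(self) -> list[str]:
        out = ["spec\tstatus\tmessage\toutput"]
        for e in self.entries:
            out.append(f"{e.spec_path}\t{e.status}\t{e.message}\t"
                       f"{e.output_file or ''}")
        out.append(SENTINEL)
        return out


def run_queue(job: QueueJob, fail_fast: bool = False,
              echo: Callable[[str], None] | None = None) -> QueueLog:
    """Process the queue; returns the log (also streamed via ``echo``).

    An empty queue, an unsupported format or an uncreatable output
    directory abort before any processing.  Re-running the same job
    overwrites its outputs deterministically.
    """
    if not job.spec_paths:
        raise ValueError("empty queue: no spec files to process")
    if job.format not in render.FORMATS:
        raise ValueError(f"unsupported format {job.format!r}; "
                         f"choose from {render.FORMATS}")
    out_dir = Path(job.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not out_dir.is_dir():
        raise NotADirectoryError(f"cannot use output directory {out_dir}")

    say = echo or (lambda _line: None)
    entries: list[QueueEntry] = []
    for spec_path in job.spec_paths:
        sp = Path(spec_path)
        try:
            spec = plotspec.load_spec(sp)
            result = execute_spec(spec, base_dir=sp.parent)
            stem = sp.name
            if stem.endswith(".kmspec.json"):
                stem = stem[: -len(".kmspec.json")]
            else:
                stem = sp.stem
            out_file = out_dir / f"{stem}.{job.format}"
            render.render_figure(spec, result.curves, result.tests, out_file,
                                 format=job.format)
            entry = QueueEntry(str(spec_path), "ok", "", str(out_file))
        except Exception as exc:  # continue-on-error contract
            entry = QueueEntry(str(spec_path), "error",
                               f"{type(exc).__name__}: {exc}", None)
        entries.append(entry)
        say(QueueLog((entry,)).lines()[0])
        if fail_fast and entry.status == "error":
            break
    log = QueueLog(tuple(entries))
    say(SENTINEL)
    return log
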