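"""Product-limit (Kaplan-Meier) estimation and at-risk bookkeeping.

The survival function of right-censored data is estimated as

    S(t) = prod_{t_i <= t} (1 - d_i / n_i)

over the distinct event times t_i, with d_i events among the n_i subjects
still at risk.  Ties between an event and a censoring at the same time are
resolved the standard way: the event is counted first, so the censored
subject is still in the risk set at that time.

No confidence intervals are computed here; the curves are point estimates
intended for figures with at-risk tables, and the companion logrank module
supplies the inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = ["KMCurve", "AtRiskTable", "km_estimate", "survival_at",
           "at_risk_counts", "transform_for_display"]


@dataclass(frozen=True)
class KMCurve:
    """One group's product-limit estimate with event/censoring bookkeeping.

    ``event_times`` are the strictly increasing distinct times with at least
    one event; ``n_at_risk``, ``n_events`` and ``survival`` are aligned with
    them.  ``censor_times`` holds every censored observation time (with
    multiplicity), for drawing censor marks.
    """

    group_label: str
    n_total: int
    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray

    @property
    def total_events(self) -> int:
        return int(self.n_events.sum())

    @property
    def max_time(self) -> float:
        """Largest observed time (event or censoring); 0 for empty curves."""
        candidates = [self.event_times.max(initial=0.0),
                      self.censor_times.max(initial=0.0)]
        return float(max(candidates))


@dataclass(frozen=True)
class AtRiskTable:
    """Numbers at risk on a common time grid, per group.

    ``counts[label][j]`` is the number of subjects in the group whose
    observed time is >= ``grid[j]``; the count at t=0 equals the group size.
    """

    grid: np.ndarray
    counts: dict[str, np.ndarray]


def _clean_inputs(times, status) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    s = np.asarray(status, dtype=bool)
    if t.ndim != 1 or t.shape != s.shape:
        raise ValueError("times and status must be 1-d arrays of equal length")
    if t.size == 0:
        raise ValueError("cannot estimate a survival curve from zero subjects")
    if not np.isfinite(t).all() or (t < 0).any():
        raise ValueError("times must be finite and non-negative")
    return t, s


def km_estimate(times: Sequence[float], status: Sequence[bool | int],
                group_label: str = "all") -> KMCurve:
    """Estimate the survival function of one group.

    Parameters
    ----------
    times
        Observed times, one per subject (finite, >= 0).
    status
        Event indicator per subject; truthy = event, falsy = censored.
    group_label
        Name carried onto the curve (legend text, table rows).

    With no events at all the estimate is identically 1 and ``event_times``
    is empty — a valid curve, not an error.
    """
    t, s = _clean_inputs(times, status)
    n = t.size

    event_t = np.unique(t[s])
    # at risk at u: observed time >= u (events-first tie rule keeps subjects
    # censored exactly at u in the risk set)
    t_sorted = np.sort(t)
    n_at_risk = n - np.searchsorted(t_sorted, event_t, side="left")
    d = np.array([(t[s] == u).sum() for u in event_t], dtype=int)
    with np.errstate(invalid="ignore"):
        survival = np.cumprod(1.0 - d / n_at_risk)
    return KMCurve(
        group_label=str(group_label),
        n_total=int(n),
        event_times=event_t,
        n_at_risk=n_at_risk.astype(int),
        n_events=d,
        survival=survival,
        censor_times=np.sort(t[~s]),
    )


def survival_at(curve: KMCurve, t: float | Sequence[float]) -> float | np.ndarray:
    """Right-continuous step lookup: S at the largest event time <= ``t``.

    Before the first event the estimate is 1.  Scalars in, scalar out.
    """
    tt = np.asarray(t, dtype=float)
    if (tt < 0).any():
        raise ValueError("time must be non-negative")
    idx = np.searchsorted(curve.event_times, tt, side="right")
    padded = np.concatenate(([1.0], curve.survival))
    out = padded[idx]
    return float(out) if np.isscalar(t) or tt.ndim == 0 else out


def at_risk_counts(group_times: Mapping[str, Sequence[float]],
                   grid: Sequence[float]) -> AtRiskTable:
    """Count subjects still at risk at each grid time, per group.

    A subject counts as at risk at t when their observed time is >= t, so a
    subject exiting exactly at a tick is still counted there — consistent
    with the n_i bookkeeping of :func:`km_estimate`.
    """
    g = np.asarray(grid, dtype=float)
    if g.size == 0 or (np.diff(g) <= 0).any():
        raise ValueError("grid must be non-empty and strictly increasing")
    counts = {}
    for label, times in group_times.items():
        t_sorted = np.sort(np.asarray(times, dtype=float))
        counts[str(label)] = (t_sorted.size
                              - np.searchsorted(t_sorted, g, side="left")).astype(int)
    return AtRiskTable(grid=g, counts=counts)


def transform_for_display(curve: KMCurve, invert: bool = False,
                          percent: bool = False) -> np.ndarray:
    """Survival values transformed for plotting.

    ``invert`` plots the cumulative event probability 1 - S(t); ``percent``
    scales to 0-100.  The step structure (event times) is unchanged, and the
    underlying statistics never see these transforms.
    """
    v = curve.survival.copy()
    if invert:
        v = 1.0 - v
    if percent:
        v = 100.0 * v
    return v
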