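"""Logrank tests across survival strata, global and pairwise.

At each distinct event time t with d events among N at-risk subjects, group
g (n_g at risk, d_g events) contributes observed d_g and expectation
E_g = d * n_g / N under the hypergeometric null of equal hazards.  The
covariance of the observed counts uses the tie-corrected hypergeometric
form

    V_gh = d * (N - d) / (N - 1) * (n_g / N) * (delta_gh - n_h / N),

summed over event times.  The statistic is the quadratic form of the first
k-1 components of O - E against the corresponding covariance block (a
generalized inverse covers degenerate strata), compared to chi-square with
k - 1 degrees of freedom.

Pairwise comparisons report the plain two-group test per unordered pair,
unadjusted for multiplicity — the conventional presentation inside a
figure; apply a multiple-testing correction downstream when the pairwise
family matters inferentially.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["LogrankResult", "logrank_global", "logrank_pairwise", "format_p"]

GroupData = tuple[np.ndarray, np.ndarray]  # (times, event indicator)


@dataclass(frozen=True)
class LogrankResult:
    """Outcome of one logrank test.

    ``observed``/``expected`` are per-group event totals O_g and E_g (their
    sums agree up to rounding); ``df`` is the group count minus one.
    """

    group_labels: list[str]
    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    df: int
    p_value: float
    description: str = ""


def _as_groups(groups: Sequence[GroupData]) -> list[tuple[np.ndarray, np.ndarray]]:
    out = []
    for times, status in groups:
        t = np.asarray(times, dtype=float)
        s = np.asarray(status, dtype=bool)
        if t.size == 0:
            raise ValueError("every group must contain at least one subject")
        out.append((t, s))
    return out


def logrank_global(groups: Sequence[GroupData],
                   labels: Sequence[str] | None = None,
                   description: str = "") -> LogrankResult:
    """Global k-sample logrank test of equal survival distributions.

    ``groups`` is a sequence of ``(times, status)`` pairs, one per stratum.
    Requires at least two groups and at least one event overall (the test is
    undefined on fully censored data).
    """
    gs = _as_groups(groups)
    k = len(gs)
    if k < 2:
        raise ValueError("logrank test needs at least two groups")
    if labels is None:
        labels = [str(i + 1) for i in range(k)]
    labels = [str(l) for l in labels]

    all_t = np.concatenate([t for t, _ in gs])
    all_s = np.concatenate([s for _, s in gs])
    if not all_s.any():
        raise ValueError("logrank test undefined: no events in any group")

    event_times = np.unique(all_t[all_s])
    sorted_t = [np.sort(t) for t, _ in gs]

    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for u in event_times:
        n_g = np.array([t.size - np.searchsorted(t, u, side="left")
                        for t in sorted_t], dtype=float)
        d_g = np.array([((t == u) & s).sum() for t, s in gs], dtype=float)
        N = n_g.sum()
        d = d_g.sum()
        O += d_g
        E += d * n_g / N
        if N > 1:
            p = n_g / N
            V += d * (N - d) / (N - 1) * (np.diag(p) - np.outer(p, p))

    diff = (O - E)[:-1]
    cov = V[:-1, :-1]
    stat = float(diff @ np.linalg.pinv(cov) @ diff)
    stat = max(stat, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(stat, df))
    return LogrankResult(group_labels=list(labels), observed=O, expected=E,
                         statistic=stat, df=df, p_value=p,
                         description=description)


def logrank_pairwise(groups: Sequence[GroupData],
                     labels: Sequence[str] | None = None,
                     descriptions: Sequence[str] | None = None
                     ) -> list[LogrankResult]:
    """Two-group logrank tests for every unordered pair, in lexicographic
    pair order ((1,2), (1,3), ..., (2,3), ...).

    Default descriptions are ``"<label i>, <label j>"``; pass
    ``descriptions`` (length k*(k-1)/2, pair order) to override, e.g.
    ``"Group 1 vs 2"``.  P-values are unadjusted.
    """
    gs = _as_groups(groups)
    k = len(gs)
    if k < 2:
        raise ValueError("pairwise tests need at least two groups")
    if labels is None:
        labels = [str(i + 1) for i in range(k)]
    pairs = list(itertools.combinations(range(k), 2))
    if descriptions is not None and len(descriptions) != len(pairs):
        raise ValueError(f"expected {len(pairs)} descriptions, got {len(descriptions)}")
    results = []
    for idx, (i, j) in enumerate(pairs):
        desc = (descriptions[idx] if descriptions is not None
                else f"{labels[i]}, {labels[j]}")
        res = logrank_global([gs[i], gs[j]], labels=[labels[i], labels[j]],
                             description=desc)
        results.append(res)
    return results


def format_p(p: float, digits: int = 4) -> str:
    """Fixed-point p-value with ``digits`` decimals (default 4).

    Values that would round to zero — below half the resolution
    10^-digits — are clipped to ``"<0.0...01"`` rather than printed as an
    impossible exact zero.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value out of [0, 1]: {p!r}")
    if not 1 <= int(digits) <= 10:
        raise ValueError(f"digits must be in 1..10, got {digits!r}")
    digits = int(digits)
    resolution = 10.0 ** (-digits)
    if p < resolution / 2:
        return f"<{resolution:.{digits}f}"
    return f"{p:.{digits}f}"
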