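"""Right-censored survival primitives: Kaplan-Meier curves, the two-group
log-rank test, and objective response rates.

The log-rank statistic is computed from an explicit risk table using the
hypergeometric variance for tied event times.  :func:`batched_logrank`
evaluates the statistic simultaneously for many candidate group assignments
and (bootstrap) case weightings; the cut-point optimizer and the repeated
cross-validation machinery are built on top of it, which is why the test is
implemented here rather than delegated per-call to an external routine.
Kaplan-Meier estimation itself is delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

RESPONDERS = frozenset({"CR", "PR"})
#: All valid RECIST-style categories; NE counts as a non-responder but stays
#: in the denominator.
RESPONSE_CATEGORIES = frozenset({"CR", "PR", "SD", "PD", "NE"})


def _as_survival_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be 1-D arrays of equal length")
    if t.size == 0:
        raise ValueError("need at least one subject")
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise ValueError("survival times must be finite and >= 0")
    return t, e


def batched_logrank(
    times,
    events,
    groups,
    weights=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-group log-rank chi-square for many groupings/weightings at once.

    Parameters
    ----------
    times, events
        Survival times and event indicators, length ``n``.
    groups
        Boolean array ``(n, C)``; each column is one candidate assignment to
        the "group 1" arm (e.g. one candidate cut point).
    weights
        Optional float array ``(W, n)`` of non-negative case multiplicities
        (bootstrap counts).  ``None`` means a single unit-weight row.
        Integer-valued weights reproduce exactly the statistic of the
        corresponding resampled data set.

    Returns
    -------
    chi2, o_minus_e, variance : ndarray of shape ``(W, C)``
        ``chi2`` is 0 where the variance vanishes (degenerate risk table).
        ``o_minus_e`` is observed-minus-expected events in group 1; negative
        values mean group 1 experiences fewer events (longer survival).
    """
    t, e = _as_survival_arrays(times, events)
    G = np.asarray(groups)
    if G.ndim != 2 or G.shape[0] != t.size:
        raise ValueError("groups must have shape (n, C)")
    n = t.size
    W = np.ones((1, n)) if weights is None else np.asarray(weights, dtype=float)
    if W.ndim != 2 or W.shape[1] != n:
        raise ValueError("weights must have shape (W, n)")

    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    Gs = G[order].astype(float)  # (n, C)
    Ws = W[:, order]  # (B, n)
    starts = np.flatnonzero(np.r_[True, ts[1:] != ts[:-1]])

    c1 = Ws[:, :, None] * Gs[None, :, :]  # (B, n, C)
    # at-risk counts: suffix sums evaluated at each distinct time
    Y1 = np.cumsum(c1[:, ::-1, :], axis=1)[:, ::-1, :][:, starts, :]
    Y = np.cumsum(Ws[:, ::-1], axis=1)[:, ::-1][:, starts]
    d1 = np.add.reduceat(c1 * es[None, :, None], starts, axis=1)
    d = np.add.reduceat(Ws * es[None, :], starts, axis=1)

    Yd = Y[:, :, None]
    frac = np.divide(Y1, Yd, out=np.zeros_like(Y1), where=Yd > 0)
    o1 = d1.sum(axis=1)
    e1 = (d[:, :, None] * frac).sum(axis=1)
    denom = Y - 1.0
    vt = np.divide(d * (Y - d), denom, out=np.zeros_like(d), where=denom > 0)
    v = (vt[:, :, None] * frac * (1.0 - frac)).sum(axis=1)
    ome = o1 - e1
    chi2 = np.divide(ome * ome, v, out=np.zeros_like(v), where=v > 0)
    return chi2, ome, v


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float
    observed_minus_expected: float
    variance: float


def logrank_test(times, events, groups) -> LogrankResult:
    """Standard two-group log-rank test (1 df, hypergeometric tie variance).

    ``groups`` is a boolean/0-1 vector; both groups must be non-empty.
    Identical event patterns yield statistic 0 and p = 1.
    """
    t, e = _as_survival_arrays(times, events)
    g = np.asarray(groups).astype(bool)
    if g.shape != t.shape:
        raise ValueError("groups must align with times")
    if g.all() or (~g).all():
        raise ValueError("both groups must be non-empty")
    chi2, ome, v = batched_logrank(t, e, g[:, None])
    stat = float(chi2[0, 0])
    return LogrankResult(
        statistic=stat,
        p_value=float(stats.chi2.sf(stat, 1)) if stat > 0 else 1.0,
        observed_minus_expected=float(ome[0, 0]),
        variance=float(v[0, 0]),
    )


@dataclass
class KMCurve:
    """Product-limit survival curve.  ``median`` is the first time at which
    S(t) drops to <= 0.5, ``inf`` when the curve never reaches it."""

    timeline: np.ndarray
    survival: np.ndarray
    median: float
    n: int
    n_events: int

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMCurve:
    from lifelines import KaplanMeierFitter

    t, e = _as_survival_arrays(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    return KMCurve(
        timeline=timeline,
        survival=surv,
        median=float(kmf.median_survival_time_),
        n=int(t.size),
        n_events=int(e.sum()),
    )


def orr(best_response) -> float:
    """Objective response rate in percent: CR+PR over all patients.

    NE cases count as non-responders and remain in the denominator.
    Returns NaN for an empty input.
    """
    arr = np.asarray(list(best_response), dtype=object)
    if arr.size == 0:
        return float("nan")
    bad = set(map(str, arr)) - RESPONSE_CATEGORIES
    if bad:
        raise ValueError(f"unknown response categories {sorted(bad)}")
    return 100.0 * float(np.mean([str(x) in RESPONDERS for x in arr]))
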