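"""Cut-point optimization and patient stratification.

Every observed readout value is a candidate binary cut point; patients with
a value >= the cut form the biomarker-positive ("high") group.  Two target
functions are supported: maximizing the objective response rate of the
positive group, and maximizing the log-rank chi-square between the groups
(equivalently minimizing the log-rank p, but immune to p-value underflow
ties).  The prevalence of both groups is constrained to be >= 20% of the
training set by default.  Optimized cuts are stabilized by a bootstrap: the
modal optimal cut over B resamples is recorded.

Ties (equal target values, or equal bootstrap modal counts) resolve to the
smallest cut, which favors a larger positive group under the inclusive >=
convention and keeps every routine deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import KMCurve, batched_logrank, km_estimate, orr, RESPONDERS

TARGETS = ("orr", "logrank")


class CutpointError(ValueError):
    """No admissible cut point under the prevalence constraint."""


@dataclass(frozen=True)
class CutpointModel:
    readout: str
    cut: float
    target: str = "logrank"
    min_prevalence: float = 0.2


def _clinical_arrays(clinical: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    times = clinical["pfs_months"].to_numpy(float)
    events = clinical["pfs_event"].to_numpy().astype(bool)
    resp = np.array([str(x) in RESPONDERS for x in clinical["best_response"]], dtype=float)
    return times, events, resp


class CutScanContext:
    """Precomputed candidate-cut structures for one readout vector.

    ``member[i, c]`` is 1.0 when patient ``i`` falls in the positive group
    under candidate cut ``cuts[c]``; reused across bootstrap resamples,
    cross-validation splits, and permutations.
    """

    def __init__(self, values, min_prevalence: float = 0.2):
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("readout values must be 1-D")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("readout values must be finite")
        self.min_prevalence = float(min_prevalence)
        self.cuts = np.unique(self.values)  # ascending
        self.member = (self.values[:, None] >= self.cuts[None, :]).astype(float)
        self.equal = (self.values[:, None] == self.cuts[None, :]).astype(float)

    def scan(
        self,
        times: np.ndarray,
        events: np.ndarray,
        responders: np.ndarray,
        weights: np.ndarray,
        target: str,
    ) -> np.ndarray:
        """Best admissible cut index per weight row; -1 where none exists."""
        if target not in TARGETS:
            raise ValueError(f"target must be one of {TARGETS}")
        W = np.asarray(weights, dtype=float)
        total = W.sum(axis=1)
        n_pos = W @ self.member  # (B, C)
        prev = n_pos / total[:, None]
        present = ((W > 0).astype(float) @ self.equal) > 0
        admissible = (
            present
            & (prev >= self.min_prevalence)
            & (1.0 - prev >= self.min_prevalence)
        )
        if target == "orr":
            pos_resp = (W * responders[None, :]) @ self.member
            score = np.divide(pos_resp, n_pos, out=np.zeros_like(n_pos), where=n_pos > 0)
        else:
            score, _, _ = batched_logrank(times, events, self.member.astype(bool), W)
        score = np.where(admissible, score, -np.inf)
        best = np.argmax(score, axis=1)  # first max -> smallest cut on ties
        best[~admissible.any(axis=1)] = -1
        return best


def optimize_cutpoint(
    values,
    clinical: pd.DataFrame,
    target: str = "logrank",
    min_prevalence: float = 0.2,
) -> float:
    """Exhaustive scan over observed values for the best admissible cut."""
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError("need at least five patients")
    times, events, resp = _clinical_arrays(clinical)
    if times.size != values.size:
        raise ValueError("readout and clinical tables must align")
    ctx = CutScanContext(values, min_prevalence)
    best = ctx.scan(times, events, resp, np.ones((1, values.size)), target)
    if best[0] < 0:
        raise CutpointError(
            f"no admissible cut at min_prevalence={min_prevalence} "
            f"({ctx.cuts.size} candidate values, n={values.size})"
        )
    return float(ctx.cuts[best[0]])


def bootstrap_cutpoint(
    values,
    clinical: pd.DataFrame,
    target: str = "logrank",
    n_bootstrap: int = 50,
    min_prevalence: float = 0.2,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Modal optimal cut over ``n_bootstrap`` resamples (with replacement)."""
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError("need at least five patients")
    times, events, resp = _clinical_arrays(clinical)
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = values.size
    ctx = CutScanContext(values, min_prevalence)
    idx = rng.integers(0, n, size=(n_bootstrap, n))
    W = np.zeros((n_bootstrap, n))
    for b in range(n_bootstrap):
        W[b] = np.bincount(idx[b], minlength=n)
    best = ctx.scan(times, events, resp, W, target)
    ok = best >= 0
    if not ok.any():
        raise CutpointError("cut-point optimization failed on every bootstrap sample")
    counts = np.bincount(best[ok])
    modal = int(np.argmax(counts))  # first max -> smallest cut on modal ties
    return float(ctx.cuts[modal])


@dataclass
class GroupSummary:
    n: int
    prevalence_pct: float
    orr_pct: float
    km: KMCurve | None


@dataclass
class StratificationResult:
    model: CutpointModel
    high: GroupSummary
    low: GroupSummary
    logrank_statistic: float
    logrank_p: float
    warnings: list[str] = field(default_factory=list)


def stratify(values, cut: float, clinical: pd.DataFrame, readout: str = "readout") -> StratificationResult:
    """Group patients by the >= convention and summarize outcome per group."""
    values = np.asarray(values, dtype=float)
    if not np.isfinite(cut):
        raise ValueError("cut must be finite")
    times, events, _ = _clinical_arrays(clinical)
    labels = values >= cut
    notes: list[str] = []
    groups = {}
    for name, mask in (("high", labels), ("low", ~labels)):
        n = int(mask.sum())
        if n == 0:
            notes.append(f"{name} group is empty at cut {cut}")
            groups[name] = GroupSummary(0, 0.0, float("nan"), None)
            continue
        groups[name] = GroupSummary(
            n=n,
            prevalence_pct=100.0 * n / values.size,
            orr_pct=orr(clinical["best_response"].to_numpy()[mask]),
            km=km_estimate(times[mask], events[mask]),
        )
    if groups["high"].n and groups["low"].n:
        from .survival import logrank_test

        res = logrank_test(times, events, labels)
        stat, p = res.statistic, res.p_value
    else:
        stat, p = float("nan"), float("nan")
        warnings.warn("one stratum is empty; log-rank test not computed", stacklevel=2)
    return StratificationResult(
        model=CutpointModel(readout=readout, cut=float(cut)),
        high=groups["high"],
        low=groups["low"],
        logrank_statistic=stat,
        logrank_p=p,
        warnings=notes,
    )
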