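"""n-times repeated k-fold cross-validation of cut-point stratification with
permutation-based empirical p-values.

For each of ``n_repeats`` random splits the cohort is partitioned into
``k`` equally sized folds; a bootstrap-stabilized cut point is trained on
the union of k-1 folds and applied to the held-out fold, so every patient
is labeled exactly once per split by a model not trained on it.  High/low
labels are pooled across the k test folds of one split and the pooled
two-group log-rank chi-square is recorded.  A standard log-rank p on pooled
curves would be invalid (pooled cases are not independent observations), so
significance comes from a permutation test: clinical rows (PFS time, event,
response) are permuted jointly against the fixed readout and the identical
cross-validation pipeline is re-run for each of ``m_permutations``
permutations.

The permutation test statistic is the mean pooled chi-square over the first
``perm_repeats`` splits, computed identically for observed and permuted
data; fold partitions and bootstrap draws are re-derived from the same
per-split seeds in both arms.  This exact symmetry makes the add-one
empirical p-value ``(1 + #{null >= observed}) / (m + 1)`` valid at any
``perm_repeats``, which defaults to ``max(1, n_repeats // 30)`` to keep the
permutation schedule affordable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cutpoint import CutScanContext, _clinical_arrays
from .survival import KMCurve, batched_logrank, km_estimate


@dataclass
class CrossValConfig:
    k: int = 5
    n_repeats: int = 300
    m_permutations: int = 1200
    n_bootstrap: int = 50
    target: str = "logrank"
    min_prevalence: float = 0.2
    perm_repeats: int | None = None  # None -> max(1, n_repeats // 30)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_repeats < 1 or self.m_permutations < 1:
            raise ValueError("n_repeats and m_permutations must be >= 1")
        if self.perm_repeats is not None and not 1 <= self.perm_repeats <= self.n_repeats:
            raise ValueError("perm_repeats must be in [1, n_repeats]")

    @property
    def effective_perm_repeats(self) -> int:
        return self.perm_repeats if self.perm_repeats is not None else max(1, self.n_repeats // 30)


@dataclass
class SplitOutcome:
    chi2: float
    o_minus_e: float  # negative: high group has fewer events (longer PFS)
    labels: np.ndarray  # pooled high/low labels, one per patient
    fold_prevalence_pct: np.ndarray  # (k,) test-fold prevalence of high group
    fold_orr_high_pct: np.ndarray
    fold_orr_low_pct: np.ndarray
    cuts: np.ndarray  # (k,) trained cut per fold
    failed: bool = False


@dataclass
class CrossValResult:
    config: CrossValConfig
    n_patients: int
    splits: list[SplitOutcome]
    statistic: float  # mean pooled chi-square over successful splits
    prevalence_mean_pct: float
    prevalence_sd_pct: float
    orr_high_mean_pct: float
    orr_low_mean_pct: float
    n_failed_splits: int

    def split_chi2(self) -> np.ndarray:
        return np.array([s.chi2 if not s.failed else np.nan for s in self.splits])

    def pooled_km(self, split_index: int, times, events) -> tuple[KMCurve, KMCurve]:
        """Cross-validated KM curves (high, low) for one split."""
        labels = self.splits[split_index].labels
        t = np.asarray(times, float)
        e = np.asarray(events).astype(bool)
        return km_estimate(t[labels], e[labels]), km_estimate(t[~labels], e[~labels])


@dataclass
class PermutationResult:
    p_value: float
    observed_statistic: float  # statistic over the first perm_repeats splits
    null_statistics: np.ndarray
    cross_validation: CrossValResult


def _fold_assignment(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    start = 0
    for f, size in enumerate(sizes):
        fold_of[perm[start : start + size]] = f
        start += size
    return fold_of


def _run_split(
    ctx: CutScanContext,
    times: np.ndarray,
    events: np.ndarray,
    resp: np.ndarray,
    fold_of: np.ndarray,
    boot_idx: list[np.ndarray],
    cfg: CrossValConfig,
) -> SplitOutcome:
    n = times.size
    k, B = cfg.k, cfg.n_bootstrap
    W = np.zeros((k * B, n))
    brow = np.arange(B)[:, None]
    for f in range(k):
        train = np.flatnonzero(fold_of != f)
        draws = boot_idx[f]  # (B, len(train)) indices into train
        counts = np.zeros((B, train.size))
        np.add.at(counts, (brow, draws), 1.0)
        W[f * B : (f + 1) * B, train] = counts
    best = ctx.scan(times, events, resp, W, cfg.target).reshape(k, B)
    cuts = np.full(k, np.nan)
    for f in range(k):
        ok = best[f] >= 0
        if not ok.any():
            return SplitOutcome(
                np.nan, np.nan, np.zeros(n, bool), np.full(k, np.nan), np.full(k, np.nan),
                np.full(k, np.nan), cuts, failed=True,
            )
        counts = np.bincount(best[f][ok])
        cuts[f] = ctx.cuts[int(np.argmax(counts))]
    labels = ctx.values >= cuts[fold_of]
    if labels.all() or (~labels).all():
        chi2, ome = 0.0, 0.0
    else:
        c, o, _ = batched_logrank(times, events, labels[:, None])
        chi2, ome = float(c[0, 0]), float(o[0, 0])
    prev = np.empty(k)
    orr_hi = np.full(k, np.nan)
    orr_lo = np.full(k, np.nan)
    for f in range(k):
        test = fold_of == f
        lab_t = labels[test]
        prev[f] = 100.0 * lab_t.mean()
        if lab_t.any():
            orr_hi[f] = 100.0 * resp[test][lab_t].mean()
        if (~lab_t).any():
            orr_lo[f] = 100.0 * resp[test][~lab_t].mean()
    return SplitOutcome(chi2, ome, labels, prev, orr_hi, orr_lo, cuts)


def _split_streams(cfg: CrossValConfig) -> tuple[list[np.random.SeedSequence], np.random.SeedSequence]:
    root = np.random.SeedSequence(cfg.seed)
    split_root, perm_root = root.spawn(2)
    return split_root.spawn(cfg.n_repeats), perm_root


def _run_all_splits(
    ctx: CutScanContext,
    times: np.ndarray,
    events: np.ndarray,
    resp: np.ndarray,
    split_seeds: list[np.random.SeedSequence],
    cfg: CrossValConfig,
    n_splits: int,
) -> list[SplitOutcome]:
    n = times.size
    outcomes = []
    for s in range(n_splits):
        rng = np.random.default_rng(split_seeds[s])
        fold_of = _fold_assignment(n, cfg.k, rng)
        boot_idx = []
        for f in range(cfg.k):
            train_size = int((fold_of != f).sum())
            boot_idx.append(rng.integers(0, train_size, size=(cfg.n_bootstrap, train_size)))
        outcomes.append(_run_split(ctx, times, events, resp, fold_of, boot_idx, cfg))
    return outcomes


def repeated_cv(values, clinical: pd.DataFrame, config: CrossValConfig | None = None) -> CrossValResult:
    """Run the full n-times repeated k-fold cross-validation for one readout."""
    cfg = config or CrossValConfig()
    values = np.asarray(values, dtype=float)
    times, events, resp = _clinical_arrays(clinical)
    if values.size != times.size:
        raise ValueError("readout and clinical tables must align")
    if values.size < 2 * cfg.k:
        raise ValueError(f"cohort of {values.size} too small for k={cfg.k} folds")
    ctx = CutScanContext(values, cfg.min_prevalence)
    split_seeds, _ = _split_streams(cfg)
    outcomes = _run_all_splits(ctx, times, events, resp, split_seeds, cfg, cfg.n_repeats)
    ok = [o for o in outcomes if not o.failed]
    n_failed = len(outcomes) - len(ok)
    if n_failed:
        warnings.warn(f"{n_failed} of {len(outcomes)} splits failed cut-point optimization", stacklevel=2)
    prev = np.concatenate([o.fold_prevalence_pct for o in ok]) if ok else np.array([np.nan])
    orr_hi = np.concatenate([o.fold_orr_high_pct for o in ok]) if ok else np.array([np.nan])
    orr_lo = np.concatenate([o.fold_orr_low_pct for o in ok]) if ok else np.array([np.nan])
    return CrossValResult(
        config=cfg,
        n_patients=values.size,
        splits=outcomes,
        statistic=float(np.mean([o.chi2 for o in ok])) if ok else float("nan"),
        prevalence_mean_pct=float(np.nanmean(prev)),
        prevalence_sd_pct=float(np.nanstd(prev)),
        orr_high_mean_pct=float(np.nanmean(orr_hi)) if np.any(~np.isnan(orr_hi)) else float("nan"),
        orr_low_mean_pct=float(np.nanmean(orr_lo)) if np.any(~np.isnan(orr_lo)) else float("nan"),
        n_failed_splits=n_failed,
    )


def _statistic_over(outcomes: list[SplitOutcome]) -> float:
    vals = [o.chi2 for o in outcomes if not o.failed]
    return float(np.mean(vals)) if vals else float("nan")


def permutation_pvalue(
    values, clinical: pd.DataFrame, config: CrossValConfig | None = None
) -> PermutationResult:
    """Empirical p for the cross-validated pooled log-rank statistic.

    PFS time, event flag, and response move together in every permutation;
    fold partitions and bootstrap draws are identical across the observed
    and permuted arms.
    """
    cfg = config or CrossValConfig()
    if cfg.m_permutations < 19:
        warnings.warn("fewer than 19 permutations: p resolution is coarser than 0.05", stacklevel=2)
    values = np.asarray(values, dtype=float)
    times, events, resp = _clinical_arrays(clinical)
    observed = repeated_cv(values, clinical, cfg)
    R = cfg.effective_perm_repeats
    obs_stat = _statistic_over(observed.splits[:R])
    ctx = CutScanContext(values, cfg.min_prevalence)
    split_seeds, perm_root = _split_streams(cfg)
    perm_rng = np.random.default_rng(perm_root)
    null_stats = np.empty(cfg.m_permutations)
    n = values.size
    for j in range(cfg.m_permutations):
        perm = perm_rng.permutation(n)
        outcomes = _run_all_splits(ctx, times[perm], events[perm], resp[perm], split_seeds, cfg, R)
        null_stats[j] = _statistic_over(outcomes)
    # a null run that fails everywhere counts as >= observed (conservative)
    exceed = np.isnan(null_stats) | (null_stats >= obs_stat)
    p = (1.0 + int(exceed.sum())) / (cfg.m_permutations + 1.0)
    return PermutationResult(
        p_value=float(p),
        observed_statistic=obs_stat,
        null_statistics=null_stats,
        cross_validation=observed,
    )
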