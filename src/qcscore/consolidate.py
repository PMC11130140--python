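"""Readout consolidation: remove non-informative and redundant columns.

Two filters run in sequence.  The first drops columns with zero variance
(one unique value) or near-zero variance (unique-count fraction < 0.1 AND
most-common : second-most-common frequency ratio > 95:5).  The second
iteratively prunes one member of every column pair whose absolute Spearman
correlation is >= a threshold (0.99 by default), discarding the member with
the larger mean absolute correlation against all remaining columns and
re-evaluating after each removal.

Tie handling is fully deterministic and name-based, so the surviving set is
independent of the input column order: pairs are processed in order of
decreasing |rho| (ties by the lexicographically smallest name pair), and
mean-|rho| ties discard the lexicographically larger name.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

NEAR_ZERO_UNIQUE_FRACTION = 0.1
NEAR_ZERO_FREQ_RATIO = 95.0 / 5.0


def drop_non_informative(
    matrix: pd.DataFrame, return_report: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, list[dict]]:
    """Drop zero-variance and near-zero-variance columns; order preserved."""
    if len(matrix) < 2:
        raise ValueError("need at least two patients")
    report: list[dict] = []
    keep: list[str] = []
    n = len(matrix)
    for col in matrix.columns:
        values = matrix[col].dropna()
        counts = values.value_counts()
        n_unique = len(counts)
        if n_unique <= 1:
            report.append({"column": col, "rule": "zero_variance"})
            continue
        freq_ratio = counts.iloc[0] / counts.iloc[1]
        if n_unique / n < NEAR_ZERO_UNIQUE_FRACTION and freq_ratio > NEAR_ZERO_FREQ_RATIO:
            report.append(
                {
                    "column": col,
                    "rule": "near_zero_variance",
                    "unique_fraction": n_unique / n,
                    "freq_ratio": float(freq_ratio),
                }
            )
            continue
        keep.append(col)
    result = matrix.loc[:, keep]
    return (result, report) if return_report else result


def _spearman_abs(matrix: pd.DataFrame) -> pd.DataFrame:
    # average ranks for ties, pairwise complete observations
    return matrix.corr(method="spearman").abs()


def drop_correlated(
    matrix: pd.DataFrame, rho: float = 0.99, return_report: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, list[dict]]:
    """Iteratively prune redundant columns with |Spearman rho| >= ``rho``."""
    if matrix.shape[1] < 2:
        return (matrix, []) if return_report else matrix
    if len(matrix) < 3:
        raise ValueError("need at least three patients for rank correlations")
    nunique = matrix.nunique(dropna=True)
    constant = list(nunique[nunique <= 1].index)
    if constant:
        raise ValueError(f"zero-variance columns must be pre-filtered: {constant}")

    corr = _spearman_abs(matrix)
    alive = list(matrix.columns)
    report: list[dict] = []
    while True:
        sub = corr.loc[alive, alive]
        tri = sub.where(np.triu(np.ones(sub.shape, dtype=bool), k=1))
        pairs = tri.stack()
        pairs = pairs[pairs >= rho]
        if pairs.empty:
            break
        # highest |rho| first; ties by lexicographically smallest name pair
        best = sorted(pairs.items(), key=lambda kv: (-kv[1], tuple(sorted(map(str, kv[0])))))[0]
        (a, b), rho_ab = best
        others = [c for c in alive]
        mean_abs = {
            c: float((sub.loc[c, others].sum() - 1.0) / max(len(others) - 1, 1)) for c in (a, b)
        }
        if mean_abs[a] > mean_abs[b]:
            drop = a
        elif mean_abs[b] > mean_abs[a]:
            drop = b
        else:
            drop = max((a, b), key=str)
        report.append(
            {
                "column": drop,
                "rule": "correlated",
                "with": b if drop == a else a,
                "rho": float(rho_ab),
                "mean_abs_corr": mean_abs[drop],
            }
        )
        alive.remove(drop)
        if len(alive) < 2:
            break
    result = matrix.loc[:, [c for c in matrix.columns if c in set(alive)]]
    return (result, report) if return_report else result


def consolidate(
    matrix: pd.DataFrame, rho: float = 0.99, return_report: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, list[dict]]:
    """Full consolidation: non-informative filter, then redundancy pruning."""
    step1, rep1 = drop_non_informative(matrix, return_report=True)
    step2, rep2 = drop_correlated(step1, rho=rho, return_report=True)
    return (step2, rep1 + rep2) if return_report else step2
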