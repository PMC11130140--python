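"""Analytical-validation metrics for segmentation and OD measurement:
Dice overlap, center-detection F1, average symmetric surface distance
(ASSD), and Pearson correlation of paired OD values."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import pearsonr


def eval_dice(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Dice = 2|A∩B| / (|A|+|B|); both empty -> 1.0, one empty -> 0.0."""
    a = np.asarray(pred_mask).astype(bool)
    b = np.asarray(true_mask).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    if na == 0 or nb == 0:
        return 0.0
    return 2.0 * int((a & b).sum()) / (na + nb)


@dataclass(frozen=True)
class CenterMatchResult:
    precision: float
    recall: float
    f1: float
    n_matched: int


def eval_f1_centers(pred_centers, true_centers, match_radius_um: float) -> CenterMatchResult:
    """Greedy nearest-neighbor one-to-one matching within ``match_radius_um``.

    Candidate pairs are ranked by distance; each predicted and each true
    center matches at most once.
    """
    pred = np.atleast_2d(np.asarray(pred_centers, dtype=float)) if np.size(pred_centers) else np.empty((0, 2))
    true = np.atleast_2d(np.asarray(true_centers, dtype=float)) if np.size(true_centers) else np.empty((0, 2))
    if pred.shape[0] == 0 or true.shape[0] == 0:
        n = 0
    else:
        d = np.hypot(
            pred[:, None, 0] - true[None, :, 0], pred[:, None, 1] - true[None, :, 1]
        )
        pairs = [(d[i, j], i, j) for i in range(pred.shape[0]) for j in range(true.shape[0]) if d[i, j] <= match_radius_um]
        pairs.sort()
        used_p: set[int] = set()
        used_t: set[int] = set()
        n = 0
        for _, i, j in pairs:
            if i not in used_p and j not in used_t:
                used_p.add(i)
                used_t.add(j)
                n += 1
    precision = n / pred.shape[0] if pred.shape[0] else 0.0
    recall = n / true.shape[0] if true.shape[0] else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return CenterMatchResult(precision=precision, recall=recall, f1=f1, n_matched=n)


def _boundary_coords(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    m = np.asarray(mask).astype(bool)
    eroded = ndimage.binary_erosion(m, border_value=0)
    return np.argwhere(m & ~eroded).astype(float)


def eval_assd(pred_mask: np.ndarray, true_mask: np.ndarray, pixel_size_um: float = 1.0) -> float:
    """Average symmetric surface distance between two mask contours.

    Pooled average: (sum of nearest distances from pred boundary to true
    boundary + vice versa) / (total boundary pixel count), in µm.
    """
    p = _boundary_coords(pred_mask)
    t = _boundary_coords(true_mask)
    if p.shape[0] == 0 or t.shape[0] == 0:
        raise ValueError("ASSD requires non-empty contours")
    d_pt, _ = cKDTree(t).query(p)
    d_tp, _ = cKDTree(p).query(t)
    return pixel_size_um * float((d_pt.sum() + d_tp.sum()) / (len(p) + len(t)))


def eval_od_correlation(pred_ods, true_ods) -> float:
    """Pearson correlation between paired predicted and reference ODs."""
    a = np.asarray(pred_ods, dtype=float)
    b = np.asarray(true_ods, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two aligned vectors of length >= 2")
    return float(pearsonr(a, b).statistic)
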