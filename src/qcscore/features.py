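"""Per-patient readouts from cell tables: membrane-OD quantiles, percentage
and density of OD-positive cells, binary and continuous spatial proximity
scores (SPS), and stromal-TIL density.

The spatial proximity scores model bystander killing by antibody-drug
conjugates: a tumor cell is likely to be hit if it expresses the target
itself or sits within payload-diffusion range ``r`` of a cell that does.
The binary score (bSPS) is the percentage of cells that are OD-positive or
have an OD-positive neighbor within ``r``; the continuous score (cSPS)
replaces the hard threshold with a distance-weighted neighborhood mean of
membrane OD, with linearly decreasing weights ``w_ij = 1 - d_ij / r`` and
self-weight 1.  Both reduce to their non-spatial counterparts as ``r -> 0``.

cSPS normalization: the weighted neighborhood aggregate is normalized by the
sum of weights (a convex combination), so the ``r -> 0`` limit equals the
per-cell OD exactly; an unnormalized weighted-sum variant is available via
``normalize=False``.

Neighborhoods use the Euclidean distance between cell centroids with an
inclusive boundary ``d <= r`` and exclude the cell itself.  A k-d tree
accelerates neighbor queries; a brute-force all-pairs path is provided and
both paths are bit-identical by construction (identical candidate filtering
and summation order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .tables import SampleCellTable

#: Preselected membrane-OD positivity thresholds, spanning faint (6) to very
#: strong (120) staining as perceived by eye.
OD_THRESHOLDS: tuple[float, ...] = (6, 8, 10, 12, 15, 20, 25, 30, 40, 50, 60, 70, 80, 90, 100, 110, 120)
#: Neighborhood radii in µm for the spatial proximity scores.
SPS_RADII: tuple[float, ...] = (10.0, 25.0, 50.0, 75.0)
#: Aggregation quantiles (percent): 5th to 95th in steps of 5.
QUANTILES: tuple[int, ...] = tuple(range(5, 100, 5))

_FAMILIES = ("od_quantile", "od_mean", "pct_positive", "positive_density", "bsps", "csps", "stil_density")


@dataclass(frozen=True)
class FeatureSpec:
    """Fully parameterized descriptor of one patient-level readout."""

    family: str
    od_threshold: float | None = None
    radius_um: float | None = None
    aggregation: str | int | None = None  # "mean" or a percent in 5..95
    til_region: str = "tumor_center"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown feature family {self.family!r}")
        if self.family in ("pct_positive", "positive_density", "bsps") and self.od_threshold is None:
            raise ValueError(f"{self.family} requires od_threshold")
        if self.family in ("bsps", "csps") and self.radius_um is None:
            raise ValueError(f"{self.family} requires radius_um")
        if self.family in ("od_quantile", "csps"):
            agg = self.aggregation
            if self.family == "od_quantile" and not isinstance(agg, (int, np.integer)):
                raise ValueError("od_quantile requires an integer percent aggregation")
            if self.family == "csps" and not (agg == "mean" or isinstance(agg, (int, np.integer))):
                raise ValueError("csps requires aggregation 'mean' or an integer percent")

    @property
    def name(self) -> str:
        f = self.family
        if f == "od_quantile":
            return f"od_q{int(self.aggregation):02d}"
        if f == "od_mean":
            return "od_mean"
        if f == "pct_positive":
            return f"pctpos_od{self.od_threshold:g}"
        if f == "positive_density":
            return f"density_od{self.od_threshold:g}"
        if f == "bsps":
            return f"bsps_r{self.radius_um:g}_od{self.od_threshold:g}"
        if f == "csps":
            agg = "mean" if self.aggregation == "mean" else f"q{int(self.aggregation):02d}"
            return f"csps_r{self.radius_um:g}_{agg}"
        return f"stil_density_{self.til_region}"


# ---------------------------------------------------------------------------
# neighbor machinery

def _neighbor_lists(
    xy: np.ndarray, r: float, method: str = "kdtree"
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-cell sorted neighbor indices and distances with ``0 < rank, d <= r``.

    Candidate pairs come either from a k-d tree or from the full distance
    matrix; both candidate sets are filtered through the identical
    ``hypot(dx, dy) <= r`` test and sorted by index, so downstream weighted
    sums are bit-identical between the two methods.
    """
    n = len(xy)
    out: list[tuple[np.ndarray, np.ndarray]] = []
    if r <= 0 or n == 0:
        empty = (np.empty(0, dtype=int), np.empty(0))
        return [empty] * n
    r_pad = r * (1.0 + 1e-9)
    if method == "kdtree":
        tree = cKDTree(xy)
        candidates = tree.query_ball_point(xy, r_pad)
    elif method == "brute":
        diff = xy[:, None, :] - xy[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        candidates = [np.flatnonzero(d2[i] <= r_pad * r_pad) for i in range(n)]
    else:
        raise ValueError(f"unknown neighbor method {method!r}")
    for i in range(n):
        idx = np.asarray(sorted(j for j in candidates[i] if j != i), dtype=int)
        d = np.hypot(xy[idx, 0] - xy[i, 0], xy[idx, 1] - xy[i, 1])
        keep = d <= r
        out.append((idx[keep], d[keep]))
    return out


# ---------------------------------------------------------------------------
# readout operations

def od_quantile(sample: SampleCellTable, q: int | str) -> float:
    """q-th percentile (linear interpolation) of per-cell membrane ODs;
    ``q="mean"`` returns the arithmetic mean.  NaN on an empty cell table."""
    od = sample.membrane_od()
    if od.size == 0:
        return float("nan")
    if q == "mean":
        return float(np.mean(od))
    return float(np.percentile(od, float(q)))


def pct_od_positive(sample: SampleCellTable, od_threshold: float) -> float:
    """Percentage of tumor cells with membrane OD >= threshold (inclusive)."""
    od = sample.membrane_od()
    if od.size == 0:
        return float("nan")
    return 100.0 * float(np.mean(od >= od_threshold))


def positive_density(sample: SampleCellTable, od_threshold: float) -> float:
    """OD-positive cells per mm² of analyzed epithelium."""
    if not sample.epithelium_area_mm2 or sample.epithelium_area_mm2 <= 0:
        raise ValueError("positive_density requires epithelium_area_mm2 > 0")
    count = int(np.sum(sample.membrane_od() >= od_threshold))
    return count / sample.epithelium_area_mm2


def bsps(
    sample: SampleCellTable,
    radius_um: float,
    od_threshold: float,
    method: str = "kdtree",
    _neighbors: list | None = None,
) -> float:
    """Binary spatial proximity score in percent.

    A cell counts if (a) it is OD-positive itself or (b) any neighboring
    cell within ``radius_um`` is OD-positive.  ``r = 0`` reduces to
    :func:`pct_od_positive`.
    """
    if radius_um < 0:
        raise ValueError("radius must be >= 0")
    od = sample.membrane_od()
    if od.size == 0:
        return float("nan")
    positive = od >= od_threshold
    if radius_um == 0:
        return 100.0 * float(np.mean(positive))
    nbrs = _neighbors if _neighbors is not None else _neighbor_lists(sample.coordinates(), radius_um, method)
    hit = positive.copy()
    for i in range(od.size):
        if not hit[i]:
            idx, _ = nbrs[i]
            hit[i] = bool(np.any(positive[idx]))
    return 100.0 * float(np.mean(hit))


def csps_cell_values(
    sample: SampleCellTable,
    radius_um: float,
    method: str = "kdtree",
    normalize: bool = True,
    _neighbors: list | None = None,
) -> np.ndarray:
    """Per-cell continuous spatial proximity values (OD-like units).

    Each cell's value is the weight-normalized mean of membrane ODs over
    itself (weight 1) and its neighbors (weights ``1 - d/r``); with
    ``normalize=False`` the raw weighted sum is returned instead.  ``r = 0``
    returns the raw membrane ODs.
    """
    if radius_um < 0:
        raise ValueError("radius must be >= 0")
    od = sample.membrane_od()
    if od.size == 0 or radius_um == 0:
        return od.copy()
    nbrs = _neighbors if _neighbors is not None else _neighbor_lists(sample.coordinates(), radius_um, method)
    out = np.empty_like(od)
    for i in range(od.size):
        idx, d = nbrs[i]
        w = 1.0 - d / radius_um
        num = od[i] + float(w @ od[idx])
        out[i] = num / (1.0 + float(w.sum())) if normalize else num
    return out


def csps(
    sample: SampleCellTable,
    radius_um: float,
    aggregation: str | int = "mean",
    method: str = "kdtree",
    normalize: bool = True,
) -> float:
    values = csps_cell_values(sample, radius_um, method=method, normalize=normalize)
    if values.size == 0:
        return float("nan")
    if aggregation == "mean":
        return float(np.mean(values))
    return float(np.percentile(values, float(aggregation)))


def stil_density(sample: SampleCellTable, denominator: str = "tumor_center") -> float:
    """Stromal TILs per mm² inside the tumor center."""
    if denominator != "tumor_center":
        raise ValueError("only the tumor-center denominator is supported")
    if not sample.tumor_center_area_mm2 or sample.tumor_center_area_mm2 <= 0:
        raise ValueError("stil_density requires tumor_center_area_mm2 > 0")
    if len(sample.tils) == 0:
        return 0.0
    count = int((sample.tils["compartment"].astype(str) == "stromal").sum())
    return count / sample.tumor_center_area_mm2


# ---------------------------------------------------------------------------
# grid expansion and the readout matrix

@dataclass(frozen=True)
class FeatureGrid:
    """Deterministic enumeration of the full readout grid.

    The default grid yields 19 OD quantiles + mean OD + 17 %-positive
    thresholds + 17 density thresholds + 4x17 bSPS + 4x20 cSPS + 1 sTIL
    density = 203 readouts, in that stable order.
    """

    od_thresholds: tuple[float, ...] = OD_THRESHOLDS
    radii_um: tuple[float, ...] = SPS_RADII
    quantiles: tuple[int, ...] = QUANTILES
    include_mean: bool = True
    families: tuple[str, ...] = _FAMILIES


def expand_feature_grid(grid: FeatureGrid | None = None) -> list[FeatureSpec]:
    grid = grid or FeatureGrid()
    specs: list[FeatureSpec] = []
    fams = grid.families
    if "od_quantile" in fams:
        specs += [FeatureSpec("od_quantile", aggregation=q) for q in grid.quantiles]
    if "od_mean" in fams and grid.include_mean:
        specs.append(FeatureSpec("od_mean"))
    if "pct_positive" in fams:
        specs += [FeatureSpec("pct_positive", od_threshold=t) for t in grid.od_thresholds]
    if "positive_density" in fams:
        specs += [FeatureSpec("positive_density", od_threshold=t) for t in grid.od_thresholds]
    if "bsps" in fams:
        specs += [
            FeatureSpec("bsps", od_threshold=t, radius_um=r)
            for r in grid.radii_um
            for t in grid.od_thresholds
        ]
    if "csps" in fams:
        for r in grid.radii_um:
            aggs: list[str | int] = (["mean"] if grid.include_mean else []) + list(grid.quantiles)
            specs += [FeatureSpec("csps", radius_um=r, aggregation=a) for a in aggs]
    if "stil_density" in fams:
        specs.append(FeatureSpec("stil_density"))
    return specs


@dataclass
class ReadoutMatrix:
    """Patients x readouts matrix with the generating :class:`FeatureSpec`s."""

    values: pd.DataFrame  # index: patient_id; columns: readout names
    specs: list[FeatureSpec]
    failures: dict[str, list[str]] = field(default_factory=dict)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.index)

    def column(self, name: str) -> np.ndarray:
        return self.values[name].to_numpy(float)


def compute_feature(
    sample: SampleCellTable,
    spec: FeatureSpec,
    method: str = "kdtree",
    _neighbors: dict[float, list] | None = None,
    _csps_cache: dict[float, np.ndarray] | None = None,
) -> float:
    f = spec.family
    if f == "od_quantile":
        return od_quantile(sample, int(spec.aggregation))
    if f == "od_mean":
        return od_quantile(sample, "mean")
    if f == "pct_positive":
        return pct_od_positive(sample, spec.od_threshold)
    if f == "positive_density":
        return positive_density(sample, spec.od_threshold)
    if f == "bsps":
        nb = _neighbors.get(spec.radius_um) if _neighbors is not None else None
        return bsps(sample, spec.radius_um, spec.od_threshold, method=method, _neighbors=nb)
    if f == "csps":
        if _csps_cache is not None and spec.radius_um in _csps_cache:
            values = _csps_cache[spec.radius_um]
        else:
            nb = _neighbors.get(spec.radius_um) if _neighbors is not None else None
            values = csps_cell_values(sample, spec.radius_um, method=method, _neighbors=nb)
            if _csps_cache is not None:
                _csps_cache[spec.radius_um] = values
        if values.size == 0:
            return float("nan")
        if spec.aggregation == "mean":
            return float(np.mean(values))
        return float(np.percentile(values, float(spec.aggregation)))
    return stil_density(sample, spec.til_region)


def compute_readout_matrix(
    samples: Sequence[SampleCellTable],
    specs: Iterable[FeatureSpec],
    method: str = "kdtree",
) -> ReadoutMatrix:
    """Evaluate every spec on every sample.

    Per-sample neighbor lists and cSPS cell values are cached per radius;
    cached and uncached paths are numerically identical.  Per-sample feature
    failures are recorded as NaN with the reason logged in ``failures``.
    """
    specs = list(specs)
    if not samples:
        raise ValueError("need at least one sample")
    radii = sorted({s.radius_um for s in specs if s.family in ("bsps", "csps") and s.radius_um})
    rows: list[list[float]] = []
    failures: dict[str, list[str]] = {}
    for sample in samples:
        neighbors = {r: _neighbor_lists(sample.coordinates(), r, method) for r in radii}
        csps_cache: dict[float, np.ndarray] = {}
        row = []
        for spec in specs:
            try:
                row.append(
                    compute_feature(sample, spec, method=method, _neighbors=neighbors, _csps_cache=csps_cache)
                )
            except ValueError as exc:
                row.append(float("nan"))
                failures.setdefault(sample.patient_id, []).append(f"{spec.name}: {exc}")
        rows.append(row)
    df = pd.DataFrame(rows, index=[s.patient_id for s in samples], columns=[s.name for s in specs])
    df.index.name = "patient_id"
    return ReadoutMatrix(values=df, specs=specs, failures=failures)
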