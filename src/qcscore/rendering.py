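"""Synthetic ROI rendering with pixel-level ground truth.

Cells are laid out as non-overlapping disks (jittered hexagonal packing of
the sample's cells), clipped against their neighbors' Voronoi boundaries so
touching cells remain disjoint.  The RGB image is rendered through
Beer-Lambert mixing of a hematoxylin stain (nuclei plus a faint tissue
background) and a DAB stain whose per-pixel absorbance on the membrane band
carries the cell's membrane OD; a small multiplicative dither decorrelates
8-bit quantization errors across pixels.  Ground truth carries instance and
compartment masks, cell centers, smoothed-indicator posterior maps, and the
per-cell true compartment ODs measured on the continuous (pre-quantization)
OD field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .imaging import CYTOPLASM, DEFAULT_STAIN_BASIS, MEMBRANE, NUCLEUS, OD_SCALE
from .tables import SampleCellTable


@dataclass
class ImagingParams:
    pixel_size_um: float = 0.5
    roi_shape: tuple[int, int] = (256, 256)
    cell_radius_um: float = 4.5
    spacing_factor: float = 2.8  # center spacing in units of cell radius
    band_px: int = 3
    nucleus_radius_frac: float = 0.45
    od_scale: float = OD_SCALE
    od_dither: float = 0.03  # relative sd of the per-pixel OD dither
    hematoxylin_nucleus: float = 0.6
    hematoxylin_background: float = 0.05
    posterior_sigma_px: float = 0.7
    stain_basis: np.ndarray = field(default_factory=lambda: DEFAULT_STAIN_BASIS.copy())
    jitter_frac: float = 0.08  # positional jitter, fraction of spacing
    min_center_distance_factor: float = 1.2  # packing tolerance, units of radius
    on_overlap: str = "error"  # or "drop"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")
        if self.spacing_factor <= 0 or self.cell_radius_um <= 0:
            raise ValueError("cell geometry parameters must be > 0")


@dataclass
class GroundTruthROI:
    rgb: np.ndarray  # uint8 (H, W, 3)
    epithelium_mask: np.ndarray
    instance_labels: np.ndarray
    compartment_labels: np.ndarray  # 1 membrane / 2 nucleus / 3 cytoplasm
    cell_centers_px: np.ndarray  # (n, 2) row, col
    membrane_posterior: np.ndarray
    nuclei_posterior: np.ndarray
    true_ods: pd.DataFrame  # cell_id, od_membrane, od_cytoplasm, od_nucleus
    pixel_size_um: float

    def __post_init__(self) -> None:
        for post in (self.membrane_posterior, self.nuclei_posterior):
            if post.min() < 0 or post.max() > 1:
                raise ValueError("posteriors must lie in [0, 1]")


def _hex_positions(shape: tuple[int, int], spacing_px: float, margin_px: float) -> np.ndarray:
    rows = []
    y = margin_px
    row_i = 0
    dy = spacing_px * np.sqrt(3) / 2
    while y < shape[0] - margin_px:
        x0 = margin_px + (spacing_px / 2 if row_i % 2 else 0.0)
        x = x0
        while x < shape[1] - margin_px:
            rows.append((y, x))
            x += spacing_px
        y += dy
        row_i += 1
    return np.asarray(rows, dtype=float)


def render_cells(
    centers_px: np.ndarray,
    od_membrane: np.ndarray,
    od_cytoplasm: np.ndarray,
    od_nucleus: np.ndarray,
    params: ImagingParams,
    rng: np.random.Generator,
) -> GroundTruthROI:
    """Render explicitly placed cells; the low-level work-horse of
    :func:`render_roi`.  Centers closer than the packing tolerance raise or
    are dropped according to ``params.on_overlap``."""
    shape = params.roi_shape
    centers = np.atleast_2d(np.asarray(centers_px, dtype=float))
    radius_px = params.cell_radius_um / params.pixel_size_um
    min_d = params.min_center_distance_factor * radius_px
    if len(centers) > 1:
        tree = cKDTree(centers)
        close = sorted({j for i, j in tree.query_pairs(min_d) for j in (i, j)})
        if close:
            if params.on_overlap == "error":
                raise ValueError(f"{len(close)} cells violate the packing tolerance")
            keep = np.setdiff1d(np.arange(len(centers)), np.array(close))
            centers = centers[keep]
            od_membrane, od_cytoplasm, od_nucleus = (
                np.asarray(od_membrane)[keep],
                np.asarray(od_cytoplasm)[keep],
                np.asarray(od_nucleus)[keep],
            )
    od_membrane = np.asarray(od_membrane, dtype=float)
    od_cytoplasm = np.asarray(od_cytoplasm, dtype=float)
    od_nucleus = np.asarray(od_nucleus, dtype=float)
    n = len(centers)

    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    grid = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    labels = np.zeros(shape, dtype=np.int32)
    if n:
        dist, nearest = cKDTree(centers).query(grid)
        inside = dist <= radius_px
        labels.ravel()[inside] = nearest[inside] + 1

    compartments = np.zeros(shape, dtype=np.uint8)
    od_field = np.zeros(shape)  # working OD units, continuous
    hem_field = np.full(shape, params.hematoxylin_background)
    objects = ndimage.find_objects(labels)
    nuc_r = params.nucleus_radius_frac * radius_px
    rows = []
    for cid in range(1, n + 1):
        sl = objects[cid - 1]
        if sl is None:
            continue
        mask = labels[sl] == cid
        padded = np.pad(mask, 1)
        depth = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
        band = mask & (depth <= params.band_px)
        cy, cx = centers[cid - 1]
        sub_y = yy[sl] - cy
        sub_x = xx[sl] - cx
        nucleus = mask & ~band & (np.hypot(sub_y, sub_x) <= nuc_r)
        cyto = mask & ~band & ~nucleus
        sub_c = compartments[sl]
        sub_c[band] = MEMBRANE
        sub_c[nucleus] = NUCLEUS
        sub_c[cyto] = CYTOPLASM
        sub_od = od_field[sl]
        dither = lambda size: 1.0 + params.od_dither * rng.standard_normal(size)  # noqa: E731
        sub_od[band] = np.clip(od_membrane[cid - 1] * dither(int(band.sum())), 0, None)
        sub_od[cyto] = np.clip(od_cytoplasm[cid - 1] * dither(int(cyto.sum())), 0, None)
        sub_od[nucleus] = np.clip(od_nucleus[cid - 1] * dither(int(nucleus.sum())), 0, None)
        hem_field[sl][nucleus] = params.hematoxylin_nucleus
        rows.append(
            {
                "cell_id": cid,
                "od_membrane": float(sub_od[band].mean()) if band.any() else float("nan"),
                "od_cytoplasm": float(sub_od[cyto].mean()) if cyto.any() else float("nan"),
                "od_nucleus": float(sub_od[nucleus].mean()) if nucleus.any() else float("nan"),
            }
        )

    hem_vec = params.stain_basis[0]
    dab_vec = params.stain_basis[1]
    absorbance = (
        (od_field / params.od_scale)[..., None] * dab_vec[None, None, :]
        + hem_field[..., None] * hem_vec[None, None, :]
    )
    rgb = np.clip(np.rint(255.0 * 10.0 ** (-absorbance)), 0, 255).astype(np.uint8)

    def _posterior(mask: np.ndarray) -> np.ndarray:
        smoothed = ndimage.gaussian_filter(mask.astype(float), params.posterior_sigma_px)
        peak = smoothed.max()
        return np.clip(smoothed / peak if peak > 0 else smoothed, 0.0, 1.0)

    epithelium = labels > 0
    roi = GroundTruthROI(
        rgb=rgb,
        epithelium_mask=epithelium,
        instance_labels=labels,
        compartment_labels=compartments,
        cell_centers_px=centers,
        membrane_posterior=_posterior(compartments == MEMBRANE),
        nuclei_posterior=_posterior(compartments == NUCLEUS),
        true_ods=pd.DataFrame(rows, columns=["cell_id", "od_membrane", "od_cytoplasm", "od_nucleus"]),
        pixel_size_um=params.pixel_size_um,
    )
    return roi


def render_roi(
    sample: SampleCellTable,
    params: ImagingParams | None = None,
    seed: int | None = None,
    max_cells: int | None = None,
) -> GroundTruthROI:
    """Render a ground-truth ROI carrying (a subset of) the sample's cells.

    Cell ODs come from the sample's cell table; positions are re-laid on a
    jittered hexagonal grid inside the ROI so that the packing tolerance is
    honored by construction.
    """
    params = params or ImagingParams()
    rng = np.random.default_rng(seed)
    radius_px = params.cell_radius_um / params.pixel_size_um
    spacing = params.spacing_factor * radius_px
    positions = _hex_positions(params.roi_shape, spacing, margin_px=radius_px + 2)
    # bounded jitter keeps the packing tolerance satisfiable by construction
    jitter = params.jitter_frac * spacing
    positions = positions + rng.uniform(-jitter, jitter, size=positions.shape)
    capacity = len(positions)
    n = min(capacity, sample.n_cells if max_cells is None else min(max_cells, sample.n_cells))
    if n == 0:
        raise ValueError("sample has no cells to render")
    order = rng.permutation(sample.n_cells)[:n]
    cells = sample.cells.iloc[np.sort(order)]
    chosen = positions[rng.permutation(capacity)[:n]]
    od_nuc = (
        cells["od_nucleus"].to_numpy(float)
        if "od_nucleus" in cells.columns
        else np.full(n, 0.5)
    )
    od_nuc = np.where(np.isfinite(od_nuc), od_nuc, 0.5)
    return render_cells(
        chosen,
        cells["od_membrane"].to_numpy(float),
        cells["od_cytoplasm"].to_numpy(float),
        od_nuc,
        params,
        rng,
    )
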