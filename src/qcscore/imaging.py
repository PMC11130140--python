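"""Classical image-analysis steps for DAB-stained IHC regions of interest.

The chain reimplemented here starts where a trained detection model stops:
given an RGB ROI, membrane/nuclei posterior probability maps, cell-center
seed points, and an epithelium mask, it (1) converts the image to per-pixel
DAB optical density by color deconvolution, (2) segments cell instances
with a seeded watershed using the membrane posterior as energy, (3) assigns
subcellular compartments (a 2-4 px membrane band along the instance
boundary, nuclei at posterior >= 0.5, cytoplasm as the remainder), and
(4) measures the mean OD of each compartment per cell.

OD unit: reported OD values are ``od_scale`` (default 100) times the
base-10 absorbance of the DAB channel, so the working positivity thresholds
6-120 span faint to very strong staining.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import rgb_from_hdx
from skimage.segmentation import watershed

#: Default Ruifrok-Johnston style H-DAB stain basis (rows: hematoxylin, DAB,
#: residual; unit absorbance vectors in RGB).
DEFAULT_STAIN_BASIS = np.asarray(rgb_from_hdx)
DAB_INDEX = 1
OD_SCALE = 100.0

MEMBRANE, NUCLEUS, CYTOPLASM = 1, 2, 3


@dataclass
class ODMap:
    """Per-pixel DAB optical density in working OD units (>= 0, finite)."""

    values: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("OD map must be finite and non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")


@dataclass
class CellSegmentation:
    """Instance labels (0 = background), per-pixel compartment codes
    (1 membrane / 2 nucleus / 3 cytoplasm within each instance), per-cell
    centroids in pixel coordinates (row, col)."""

    labels: np.ndarray
    compartments: np.ndarray
    centroids_px: np.ndarray  # (n_cells, 2) row, col
    cell_ids: np.ndarray
    pixel_size_um: float
    n_seeds_dropped: int = 0


def deconvolve_dab(
    rgb: np.ndarray,
    stain_basis: np.ndarray | None = None,
    od_scale: float = OD_SCALE,
    pixel_size_um: float = 1.0,
    max_od: float | None = 300.0,
) -> ODMap:
    """Color-deconvolve an RGB image into a DAB optical-density map.

    Per-channel absorbance ``A_c = -log10(I_c / I0)`` is projected onto the
    DAB stain vector (row ``DAB_INDEX`` of the basis) and scaled to working
    OD units.  Saturated black pixels are clipped at ``max_od``.
    """
    basis = DEFAULT_STAIN_BASIS if stain_basis is None else np.asarray(stain_basis, dtype=float)
    if basis.ndim != 2 or basis.shape[1] != 3 or basis.shape[0] not in (2, 3):
        raise ValueError("stain basis must be a 2x3 or 3x3 matrix of RGB absorbance rows")
    if np.linalg.matrix_rank(basis) < basis.shape[0]:
        raise ValueError("stain basis is singular")
    img = np.asarray(rgb)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    i0 = float(np.iinfo(img.dtype).max) if np.issubdtype(img.dtype, np.integer) else 1.0
    transmittance = np.clip(img.astype(float), 1.0, i0) / i0
    absorbance = -np.log10(transmittance)
    concentrations = absorbance @ np.linalg.pinv(basis)
    od = np.clip(concentrations[..., DAB_INDEX], 0.0, None) * od_scale
    if max_od is not None:
        od = np.minimum(od, max_od)
    return ODMap(values=od, pixel_size_um=pixel_size_um)


def _membrane_band(mask: np.ndarray, band_px: int) -> np.ndarray:
    """Pixels of ``mask`` within ``band_px`` (Euclidean depth) of its exterior."""
    padded = np.pad(mask, 1)
    depth = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    return mask & (depth <= band_px)


def segment_cells(
    membrane_posterior: np.ndarray,
    nuclei_posterior: np.ndarray,
    seeds_px: np.ndarray,
    epithelium_mask: np.ndarray,
    band_px: int = 3,
    pixel_size_um: float = 1.0,
) -> CellSegmentation:
    """Seeded-watershed instance segmentation with compartment assignment.

    Cell centers act as watershed seeds and the membrane posterior as the
    energy image; region growing stops on membrane ridges.  Seeds outside
    the epithelium mask are dropped (counted in ``n_seeds_dropped``), and no
    instance extends beyond the epithelium.  The membrane band is a 2-4 px
    deep rim of each instance (``band_px`` total depth, default 3); nuclei
    are pixels with nuclei posterior >= 0.5 not claimed by the membrane;
    cytoplasm is the remainder of the cell.

    Zero admissible seeds yield an empty segmentation, not an error.
    """
    mem = np.asarray(membrane_posterior, dtype=float)
    nuc = np.asarray(nuclei_posterior, dtype=float)
    for name, post in (("membrane", mem), ("nuclei", nuc)):
        if post.min() < 0 or post.max() > 1:
            raise ValueError(f"{name} posterior must lie in [0, 1]")
    if mem.shape != nuc.shape:
        raise ValueError("posterior maps must share a shape")
    if not 2 <= band_px <= 4:
        raise ValueError("membrane band depth must be 2 to 4 pixels")
    epi = np.asarray(epithelium_mask).astype(bool)
    seeds = np.atleast_2d(np.asarray(seeds_px, dtype=float)) if np.size(seeds_px) else np.empty((0, 2))

    markers = np.zeros(mem.shape, dtype=np.int32)
    kept_ids = []
    dropped = 0
    for i, (r, c) in enumerate(np.round(seeds).astype(int)):
        if 0 <= r < mem.shape[0] and 0 <= c < mem.shape[1] and epi[r, c]:
            markers[r, c] = i + 1
            kept_ids.append(i + 1)
        else:
            dropped += 1
    if kept_ids:
        labels = watershed(mem, markers=markers, mask=epi)
    else:
        labels = np.zeros(mem.shape, dtype=np.int32)

    compartments = np.zeros(mem.shape, dtype=np.uint8)
    centroids = []
    ids = []
    objects = ndimage.find_objects(labels)
    for cell_id in kept_ids:
        sl = objects[cell_id - 1] if cell_id - 1 < len(objects) else None
        if sl is None:
            continue
        mask = labels[sl] == cell_id
        band = _membrane_band(mask, band_px)
        nucleus = mask & (nuc[sl] >= 0.5) & ~band
        cyto = mask & ~band & ~nucleus
        sub = compartments[sl]
        sub[band] = MEMBRANE
        sub[nucleus] = NUCLEUS
        sub[cyto] = CYTOPLASM
        rr, cc = np.nonzero(mask)
        centroids.append((rr.mean() + sl[0].start, cc.mean() + sl[1].start))
        ids.append(cell_id)
    return CellSegmentation(
        labels=labels,
        compartments=compartments,
        centroids_px=np.asarray(centroids, dtype=float).reshape(-1, 2),
        cell_ids=np.asarray(ids, dtype=int),
        pixel_size_um=pixel_size_um,
        n_seeds_dropped=dropped,
    )


def measure_compartment_od(odmap: ODMap, seg: CellSegmentation) -> pd.DataFrame:
    """Arithmetic mean OD per non-empty compartment of each cell.

    Returns a cell table (cell_id, x_um, y_um, od_membrane, od_cytoplasm,
    od_nucleus); empty compartments yield NaN.
    """
    od = odmap.values
    if od.shape != seg.labels.shape:
        raise ValueError("OD map and segmentation shapes differ")
    rows = []
    objects = ndimage.find_objects(seg.labels)
    for cell_id, centroid in zip(seg.cell_ids, seg.centroids_px):
        sl = objects[cell_id - 1]
        mask = seg.labels[sl] == cell_id
        comp = seg.compartments[sl]
        sub_od = od[sl]
        means = {}
        for name, code in (("od_membrane", MEMBRANE), ("od_nucleus", NUCLEUS), ("od_cytoplasm", CYTOPLASM)):
            sel = mask & (comp == code)
            means[name] = float(sub_od[sel].mean()) if sel.any() else float("nan")
        rows.append(
            {
                "cell_id": int(cell_id),
                "x_um": centroid[1] * seg.pixel_size_um,
                "y_um": centroid[0] * seg.pixel_size_um,
                "od_membrane": means["od_membrane"],
                "od_cytoplasm": means["od_cytoplasm"],
                "od_nucleus": means["od_nucleus"],
            }
        )
    return pd.DataFrame(rows, columns=["cell_id", "x_um", "y_um", "od_membrane", "od_cytoplasm", "od_nucleus"])
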