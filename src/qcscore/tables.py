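"""Tabular containers for per-sample cell data and cohort IO.

The canonical on-disk schema is a flat cell table (one row per tumor cell),
a TIL table (one row per lymphocyte), a per-patient area table, and a
clinical table.  CSV and Parquet are supported interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CELL_COLUMNS = ["patient_id", "cell_id", "x_um", "y_um", "od_membrane", "od_cytoplasm", "od_nucleus"]
TIL_COLUMNS = ["patient_id", "x_um", "y_um", "compartment"]
AREA_COLUMNS = ["patient_id", "epithelium_area_mm2", "tumor_center_area_mm2"]
CLINICAL_COLUMNS = ["patient_id", "pfs_months", "pfs_event", "best_response"]

TIL_COMPARTMENTS = ("stromal", "intraepithelial")
RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD", "NE")


@dataclass
class SampleCellTable:
    """All measurements for one patient sample.

    ``cells`` holds tumor-cell centroids (µm) and per-compartment mean ODs;
    ``tils`` holds lymphocyte coordinates with a stromal/intraepithelial
    label; areas are in mm² and may be ``None`` when the corresponding
    density readouts are not requested.
    """

    patient_id: str
    cells: pd.DataFrame
    tils: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=TIL_COLUMNS[1:]))
    epithelium_area_mm2: float | None = None
    tumor_center_area_mm2: float | None = None

    def __post_init__(self) -> None:
        for col in ("x_um", "y_um", "od_membrane", "od_cytoplasm"):
            if col not in self.cells.columns:
                raise ValueError(f"cell table for {self.patient_id!r} lacks column {col!r}")
        xy = self.cells[["x_um", "y_um"]].to_numpy(float)
        if xy.size and not np.all(np.isfinite(xy)):
            raise ValueError("cell coordinates must be finite")
        for col in ("od_membrane", "od_cytoplasm", "od_nucleus"):
            if col in self.cells.columns:
                od = self.cells[col].to_numpy(float)
                od = od[~np.isnan(od)]
                if od.size and (np.any(od < 0) or not np.all(np.isfinite(od))):
                    raise ValueError(f"{col} values must be finite and >= 0")
        for area_name in ("epithelium_area_mm2", "tumor_center_area_mm2"):
            area = getattr(self, area_name)
            if area is not None and not area > 0:
                raise ValueError(f"{area_name} must be > 0 when given")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def membrane_od(self) -> np.ndarray:
        return self.cells["od_membrane"].to_numpy(float)

    def coordinates(self) -> np.ndarray:
        return self.cells[["x_um", "y_um"]].to_numpy(float)


def _read_table(path: Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix in (".parquet", ".pq"):
        return pd.read_parquet(path)
    return pd.read_csv(path)


def _write_table(df: pd.DataFrame, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix in (".parquet", ".pq"):
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def samples_to_frames(samples: list[SampleCellTable]) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Concatenate per-sample tables into cohort-level cell/TIL/area frames."""
    cell_frames, til_frames, areas = [], [], []
    for s in samples:
        cf = s.cells.copy()
        cf.insert(0, "patient_id", s.patient_id)
        cell_frames.append(cf)
        tf = s.tils.copy()
        tf.insert(0, "patient_id", s.patient_id)
        til_frames.append(tf)
        areas.append(
            {
                "patient_id": s.patient_id,
                "epithelium_area_mm2": s.epithelium_area_mm2,
                "tumor_center_area_mm2": s.tumor_center_area_mm2,
            }
        )
    cells = pd.concat(cell_frames, ignore_index=True) if cell_frames else pd.DataFrame(columns=CELL_COLUMNS)
    tils = pd.concat(til_frames, ignore_index=True) if til_frames else pd.DataFrame(columns=TIL_COLUMNS)
    return cells, tils, pd.DataFrame(areas, columns=AREA_COLUMNS)


def frames_to_samples(
    cells: pd.DataFrame,
    tils: pd.DataFrame | None = None,
    areas: pd.DataFrame | None = None,
) -> list[SampleCellTable]:
    """Split cohort-level frames back into per-patient :class:`SampleCellTable`."""
    if tils is None:
        tils = pd.DataFrame(columns=TIL_COLUMNS)
    area_map: dict[str, tuple[float | None, float | None]] = {}
    if areas is not None:
        for row in areas.itertuples(index=False):
            epi = getattr(row, "epithelium_area_mm2", None)
            tc = getattr(row, "tumor_center_area_mm2", None)
            area_map[str(row.patient_id)] = (
                None if pd.isna(epi) else float(epi),
                None if pd.isna(tc) else float(tc),
            )
    samples = []
    til_groups = {str(k): g for k, g in tils.groupby("patient_id")} if len(tils) else {}
    for pid, group in cells.groupby("patient_id", sort=True):
        pid = str(pid)
        epi, tc = area_map.get(pid, (None, None))
        samples.append(
            SampleCellTable(
                patient_id=pid,
                cells=group.drop(columns=["patient_id"]).reset_index(drop=True),
                tils=til_groups.get(pid, pd.DataFrame(columns=TIL_COLUMNS[1:]))
                .drop(columns=["patient_id"], errors="ignore")
                .reset_index(drop=True),
                epithelium_area_mm2=epi,
                tumor_center_area_mm2=tc,
            )
        )
    return samples


def write_cohort(
    samples: list[SampleCellTable],
    clinical: pd.DataFrame | None,
    outdir: str | Path,
    fmt: str = "parquet",
) -> dict[str, str]:
    """Write a cohort to ``outdir``; returns the mapping of artifact names to paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = "parquet" if fmt == "parquet" else "csv"
    cells, tils, areas = samples_to_frames(samples)
    paths = {
        "cells": outdir / f"cells.{ext}",
        "tils": outdir / f"tils.{ext}",
        "areas": outdir / "areas.csv",
    }
    _write_table(cells, paths["cells"])
    _write_table(tils, paths["tils"])
    _write_table(areas, paths["areas"])
    if clinical is not None:
        paths["clinical"] = outdir / "clinical.csv"
        _write_table(clinical, paths["clinical"])
    return {k: str(v) for k, v in paths.items()}


def read_cohort(directory: str | Path) -> tuple[list[SampleCellTable], pd.DataFrame | None]:
    directory = Path(directory)
    cells_path = next((p for p in (directory / "cells.parquet", directory / "cells.csv") if p.exists()), None)
    if cells_path is None:
        raise FileNotFoundError(f"no cell table found in {directory}")
    tils_path = next((p for p in (directory / "tils.parquet", directory / "tils.csv") if p.exists()), None)
    areas_path = directory / "areas.csv"
    cells = _read_table(cells_path)
    tils = _read_table(tils_path) if tils_path else None
    areas = _read_table(areas_path) if areas_path.exists() else None
    clinical_path = directory / "clinical.csv"
    clinical = _read_table(clinical_path) if clinical_path.exists() else None
    return frames_to_samples(cells, tils, areas), clinical


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = _read_table(Path(path))
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table lacks columns {missing}")
    bad = set(df["best_response"].astype(str)) - set(RESPONSE_CATEGORIES)
    if bad:
        raise ValueError(f"unknown response categories {sorted(bad)}")
    if (df["pfs_months"].to_numpy(float) < 0).any():
        raise ValueError("pfs_months must be >= 0")
    return df
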