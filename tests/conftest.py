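import numpy as np
import pandas as pd
import pytest

from qcscore.tables import SampleCellTable


def make_sample(
    xy=None,
    od_membrane=None,
    od_cytoplasm=None,
    tils=None,
    epithelium_area_mm2=2.0,
    tumor_center_area_mm2=2.0,
    patient_id="P1",
) -> SampleCellTable:
    """Build a SampleCellTable from plain arrays for unit tests."""
    xy = np.zeros((0, 2)) if xy is None else np.atleast_2d(np.asarray(xy, float))
    n = len(xy)
    od_membrane = np.zeros(n) if od_membrane is None else np.asarray(od_membrane, float)
    od_cytoplasm = 0.5 * od_membrane if od_cytoplasm is None else np.asarray(od_cytoplasm, float)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "x_um": xy[:, 0] if n else [],
            "y_um": xy[:, 1] if n else [],
            "od_membrane": od_membrane,
            "od_cytoplasm": od_cytoplasm,
            "od_nucleus": np.ones(n),
        }
    )
    if tils is None:
        til_df = pd.DataFrame(columns=["x_um", "y_um", "compartment"])
    else:
        til_xy, comp = tils
        til_df = pd.DataFrame(
            {"x_um": np.asarray(til_xy)[:, 0], "y_um": np.asarray(til_xy)[:, 1], "compartment": comp}
        )
    return SampleCellTable(
        patient_id=patient_id,
        cells=cells,
        tils=til_df,
        epithelium_area_mm2=epithelium_area_mm2,
        tumor_center_area_mm2=tumor_center_area_mm2,
    )


def random_sample(rng, n_cells=50, extent=500.0, od_scale_range=(0.5, 40.0), patient_id="P1"):
    """A random cell table with a lognormal OD mix, for property tests."""
    xy = rng.uniform(0, extent, size=(n_cells, 2))
    od = rng.lognormal(np.log(rng.uniform(*od_scale_range)), 0.8, n_cells)
    return make_sample(xy, od, patient_id=patient_id)


def random_clinical(rng, n, orr_rate=0.4, event_rate=0.7):
    responders = rng.random(n) < orr_rate
    resp = np.where(responders, rng.choice(["CR", "PR"], n), rng.choice(["SD", "PD", "NE"], n))
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "pfs_months": rng.exponential(10.0, n),
            "pfs_event": (rng.random(n) < event_rate).astype(int),
            "best_response": resp,
        }
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
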