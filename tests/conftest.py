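import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from tlsquant import CellTable, RegionSet


def make_cell_table(coords, panel=("CD20", "CD4", "CD8", "CD21", "CD23"), markers=None):
    """Hand-built cell table from an (n, 2) coordinate array.

    ``markers``: optional dict marker -> boolean/0-1 vector of length n.
    """
    coords = np.asarray(coords, dtype=float)
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i:04d}" for i in range(len(coords))],
            "x_um": coords[:, 0] if len(coords) else [],
            "y_um": coords[:, 1] if len(coords) else [],
        }
    )
    for m in panel:
        vec = (markers or {}).get(m, np.zeros(len(coords), dtype=int))
        df[m] = np.asarray(vec, dtype=int)
    return CellTable(panel=tuple(panel), df=df)


def line_aggregate_markers(n, n_cd20, n_fdc=0, with_cd4=True, with_cd8=True):
    """Marker vectors for n cells: CD20s first, then fDCs, then CD4/CD8."""
    cd20 = np.zeros(n, dtype=int)
    cd20[:n_cd20] = 1
    fdc = np.zeros(n, dtype=int)
    fdc[n_cd20 : n_cd20 + n_fdc] = 1
    rest = np.arange(n) >= n_cd20 + n_fdc
    rest_idx = np.flatnonzero(rest)
    cd4 = np.zeros(n, dtype=int)
    cd8 = np.zeros(n, dtype=int)
    if with_cd4 and len(rest_idx):
        cd4[rest_idx[: max(1, len(rest_idx) // 2)]] = 1
    if with_cd8 and len(rest_idx):
        cd8[rest_idx[max(1, len(rest_idx) // 2) :]] = 1
        if cd8.sum() == 0:
            cd8[rest_idx[-1]] = 1
    return {"CD20": cd20, "CD21": fdc, "CD23": fdc, "CD4": cd4, "CD8": cd8}


@pytest.fixture
def square_regions():
    tissue = box(0, 0, 3000, 3000)
    core = Polygon([(1000, 1000), (2000, 1000), (2000, 2000), (1000, 2000)])
    return RegionSet(
        tissue=tissue, core=core, stroma=tissue.difference(core), margin_band_um=400.0
    )
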