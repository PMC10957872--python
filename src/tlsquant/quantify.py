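"""Phenotype resolution, compartmental cell densities and patient clusters.

Densities are reported in cells/mm² for six compartments: the whole tumor
microenvironment (TME, the tissue polygon with TLSs included), the tissue
outside any TLS (nTLS), the union of early-TLS hulls (eTLS), the union of
mature-TLS hulls (mTLS), and the tumor core / stroma region polygons.

TLS compartment membership is by aggregate membership, not point-in-hull,
so for every phenotype the counts satisfy the exact partition identity
``count(TME) = count(nTLS) + count(eTLS) + count(mTLS)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.ops import unary_union

from .tls import CellTable, RegionSet, TlsCall, tls_hull_union

__all__ = [
    "PhenotypeDef",
    "resolve_phenotype",
    "phenotype_mask",
    "compute_compartment_densities",
    "assign_patient_cluster",
    "PatientProfile",
]

UM2_PER_MM2 = 1e6


@dataclass(frozen=True)
class PhenotypeDef:
    """A cell phenotype as marker logic, e.g. TIM3+PD1+CD8+ T cells."""

    name: str
    required_positive: tuple[str, ...]
    required_negative: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        overlap = set(self.required_positive) & set(self.required_negative)
        if overlap:
            raise ValueError(f"markers both required and excluded: {sorted(overlap)}")


def phenotype_mask(cells: CellTable, ph: PhenotypeDef) -> np.ndarray:
    """Boolean vector over the cell table: which cells match the phenotype."""
    for m in (*ph.required_positive, *ph.required_negative):
        if m not in cells.panel:
            raise KeyError(f"marker {m!r} (phenotype {ph.name!r}) not in panel")
    mask = np.ones(cells.n_cells, dtype=bool)
    for m in ph.required_positive:
        mask &= cells.marker(m)
    for m in ph.required_negative:
        mask &= ~cells.marker(m)
    return mask


def resolve_phenotype(cell_markers: dict, ph: PhenotypeDef) -> bool:
    """True iff a single cell's marker map satisfies the phenotype logic."""
    for m in (*ph.required_positive, *ph.required_negative):
        if m not in cell_markers:
            raise KeyError(f"marker {m!r} (phenotype {ph.name!r}) absent from cell")
    return all(bool(cell_markers[m]) for m in ph.required_positive) and not any(
        bool(cell_markers[m]) for m in ph.required_negative
    )


def compute_compartment_densities(
    cells: CellTable,
    calls: list[TlsCall],
    regions: RegionSet,
    defs: list[PhenotypeDef],
) -> pd.DataFrame:
    """Tidy density table: one row per (compartment, phenotype).

    Columns: compartment, phenotype, count, area_mm2, density.  Compartments
    with zero area are omitted with a warning.  Core/stroma counts use
    point-in-polygon on cell centroids (boundary inclusive) and do not enter
    the TME = nTLS + eTLS + mTLS partition.
    """
    tls_calls = [c for c in calls if c.tls_class in ("eTLS", "mTLS")]
    e_members = np.concatenate(
        [c.aggregate.member_index for c in tls_calls if c.tls_class == "eTLS"]
        or [np.empty(0, dtype=int)]
    )
    m_members = np.concatenate(
        [c.aggregate.member_index for c in tls_calls if c.tls_class == "mTLS"]
        or [np.empty(0, dtype=int)]
    )

    tissue_area = regions.tissue.area / UM2_PER_MM2
    e_hull = tls_hull_union(tls_calls, cells, "eTLS")
    m_hull = tls_hull_union(tls_calls, cells, "mTLS")
    all_hull = unary_union([e_hull, m_hull])
    areas = {
        "TME": tissue_area,
        "nTLS": (regions.tissue.area - regions.tissue.intersection(all_hull).area)
        / UM2_PER_MM2,
        "eTLS": e_hull.area / UM2_PER_MM2,
        "mTLS": m_hull.area / UM2_PER_MM2,
        "core": (regions.core.area / UM2_PER_MM2) if regions.core is not None else 0.0,
        "stroma": (regions.stroma.area / UM2_PER_MM2)
        if regions.stroma is not None
        else 0.0,
    }

    pts = [Point(x, y) for x, y in cells.coords()]
    in_core = (
        np.array([regions.core.covers(p) for p in pts])
        if regions.core is not None
        else np.zeros(cells.n_cells, dtype=bool)
    )
    in_stroma = (
        np.array([regions.stroma.covers(p) for p in pts])
        if regions.stroma is not None
        else np.zeros(cells.n_cells, dtype=bool)
    )

    rows = []
    for ph in defs:
        mask = phenotype_mask(cells, ph)
        n_e = int(mask[e_members].sum()) if e_members.size else 0
        n_m = int(mask[m_members].sum()) if m_members.size else 0
        counts = {
            "TME": int(mask.sum()),
            "eTLS": n_e,
            "mTLS": n_m,
            "nTLS": int(mask.sum()) - n_e - n_m,
            "core": int(mask[in_core].sum()),
            "stroma": int(mask[in_stroma].sum()),
        }
        for comp in ("TME", "nTLS", "eTLS", "mTLS", "core", "stroma"):
            area = areas[comp]
            if area <= 0:
                if counts[comp]:
                    warnings.warn(
                        f"compartment {comp} has zero area; entry omitted",
                        stacklevel=2,
                    )
                continue
            rows.append(
                {
                    "compartment": comp,
                    "phenotype": ph.name,
                    "count": counts[comp],
                    "area_mm2": area,
                    "density": counts[comp] / area,
                }
            )
    return pd.DataFrame(rows, columns=["compartment", "phenotype", "count", "area_mm2", "density"])


def assign_patient_cluster(n_etls: int, n_mtls: int) -> str:
    """TLS cluster: CL1 no TLS, CL2 eTLS only, CL3 any mTLS present."""
    if n_etls < 0 or n_mtls < 0:
        raise ValueError("TLS counts must be non-negative")
    if n_mtls > 0:
        return "CL3"
    return "CL2" if n_etls > 0 else "CL1"


@dataclass
class PatientProfile:
    """Per-patient roll-up across pipeline stages."""

    patient_id: str
    n_etls: int = 0
    n_mtls: int = 0
    cluster: str = "CL1"
    densities: pd.DataFrame | None = None
    tmb: float | None = None
    signature_scores: dict = field(default_factory=dict)
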