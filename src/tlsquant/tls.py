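"""Detection, measurement and maturity classification of lymphoid aggregates.

Cells enter as centroids with boolean marker calls (CD20, CD4, CD8, CD21,
CD23, ...).  Aggregates are the connected components of the proximity graph
joining cell pairs whose centroid distance is at most a contact threshold.
Each aggregate is measured (maximum Feret diameter, convex-hull area,
marker composition) and classified:

* early TLS (eTLS): more than ``min_cells`` cells, maximum Feret diameter of
  at least ``min_size_um``, a strict majority of CD20+ B cells, and at least
  one CD4+ and one CD8+ T cell;
* mature TLS (mTLS): an eTLS that additionally contains at least
  ``min_fdc_for_mature`` follicular dendritic cells (CD21+ and CD23+);
* anything else is ``not_tls``.

Localization relative to the tumor core / stroma geometry distinguishes
aggregates at the invasive margin (within a configurable band around the
core boundary) from those deep in the core or in the stroma.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.spatial.distance import pdist
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import unary_union

__all__ = [
    "CellTable",
    "RegionSet",
    "Aggregate",
    "TlsThresholds",
    "TlsCall",
    "detect_aggregates",
    "measure_aggregate",
    "classify_aggregate",
    "localize_tls",
]

#: markers used by the maturity rules; FDC is the CD21+CD23+ conjunction
CORE_MARKERS = ("CD20", "CD4", "CD8")


@dataclass(frozen=True)
class CellTable:
    """Per-cell centroids (µm) plus boolean marker positivity.

    ``df`` must carry columns ``cell_id``, ``x_um``, ``y_um`` and one boolean
    (0/1) column per marker in ``panel``.
    """

    panel: tuple[str, ...]
    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["cell_id", "x_um", "y_um", *self.panel]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"cell table missing columns: {missing}")
        if self.df["cell_id"].duplicated().any():
            dup = self.df.loc[self.df["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise ValueError(f"duplicate cell_id {dup!r}")
        xy = self.df[["x_um", "y_um"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise ValueError("non-finite cell coordinates")

    @property
    def n_cells(self) -> int:
        return len(self.df)

    def coords(self) -> np.ndarray:
        return self.df[["x_um", "y_um"]].to_numpy(dtype=float)

    def marker(self, name: str) -> np.ndarray:
        if name not in self.panel:
            raise KeyError(f"marker {name!r} not in panel {list(self.panel)}")
        return self.df[name].to_numpy(dtype=bool)


@dataclass
class RegionSet:
    """Tissue geometry in µm: whole-tissue polygon, tumor core and stroma.

    ``margin_band_um`` is the half-width of the invasive-margin band drawn
    symmetrically around the core boundary.
    """

    tissue: Polygon
    core: Polygon | None = None
    stroma: Polygon | None = None
    margin_band_um: float = 500.0

    def __post_init__(self) -> None:
        if self.tissue is None or self.tissue.area <= 0:
            raise ValueError("tissue polygon must have positive area")
        if self.margin_band_um <= 0:
            raise ValueError("margin_band_um must be positive")


@dataclass
class Aggregate:
    """A connected cluster of cells with its spatial metrics.

    ``member_index`` holds integer row positions into the originating
    :class:`CellTable`; ``member_ids`` the corresponding cell ids.
    """

    member_index: np.ndarray
    member_ids: tuple
    n_cells: int
    max_feret_um: float = float("nan")
    hull_area_mm2: float = float("nan")
    degenerate_hull: bool = False
    centroid: tuple[float, float] = (float("nan"), float("nan"))
    composition: dict = field(default_factory=dict)

    def hull_polygon(self, cells: CellTable) -> Polygon:
        """Convex hull of member centroids as a shapely geometry (µm)."""
        pts = cells.coords()[self.member_index]
        return MultiPoint([tuple(p) for p in pts]).convex_hull


@dataclass(frozen=True)
class TlsThresholds:
    """Rule thresholds for aggregate classification.

    ``min_cells`` is exclusive (an aggregate needs *more than* 50 cells) and
    ``cd20_majority`` is a strict majority; ``min_size_um`` is inclusive.
    ``contact_distance_um`` defaults to a 3 µm membrane gap plus two nominal
    6 µm cell radii, because inputs are centroids rather than membranes.
    """

    min_cells: int = 50
    min_size_um: float = 250.0
    contact_distance_um: float = 15.0
    cd20_majority: float = 0.5
    require_cd4: bool = True
    require_cd8: bool = True
    min_fdc_for_mature: int = 1

    def __post_init__(self) -> None:
        if min(self.min_cells, self.min_size_um, self.contact_distance_um,
               self.cd20_majority, self.min_fdc_for_mature) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass
class TlsCall:
    aggregate: Aggregate
    tls_class: str  # not_tls | eTLS | mTLS
    rule_trace: dict[str, bool]
    localization: str = "unassigned"  # margin | stroma | core | unassigned


def detect_aggregates(
    cells: CellTable,
    contact_distance_um: float = 15.0,
    min_component_size: int = 2,
) -> list[Aggregate]:
    """Connected components of the cell proximity graph.

    Two cells are in contact when their centroid distance is at most
    ``contact_distance_um`` (the boundary is inclusive).  Components with
    fewer than ``min_component_size`` members are dropped.  Components are
    returned sorted by their smallest member cell id, so output order is
    deterministic.
    """
    if contact_distance_um <= 0:
        raise ValueError("contact_distance_um must be positive")
    n = cells.n_cells
    if n == 0:
        return []
    xy = cells.coords()
    tree = cKDTree(xy)
    pairs = tree.query_pairs(contact_distance_um, output_type="ndarray")
    if len(pairs):
        data = np.ones(len(pairs), dtype=np.int8)
        adj = sparse.coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        adj = sparse.coo_matrix((n, n), dtype=np.int8)
    _, labels = connected_components(adj, directed=False)

    ids = cells.df["cell_id"].to_numpy()
    out: list[Aggregate] = []
    order = np.argsort(labels, kind="stable")
    boundaries = np.flatnonzero(np.diff(labels[order])) + 1
    for comp in np.split(order, boundaries):
        if len(comp) < min_component_size:
            continue
        comp = np.sort(comp)
        out.append(
            Aggregate(
                member_index=comp,
                member_ids=tuple(ids[comp]),
                n_cells=len(comp),
            )
        )
    out.sort(key=lambda a: min(a.member_ids))
    return out


def measure_aggregate(
    agg: Aggregate,
    cells: CellTable,
    phenotypes: list | None = None,
) -> Aggregate:
    """Fill spatial metrics and marker composition of an aggregate.

    ``max_feret_um`` is the largest pairwise centroid distance;
    ``hull_area_mm2`` the convex-hull area of the member centroids.  Fewer
    than three non-collinear members yield a zero-area hull flagged as
    degenerate.  Composition always includes the counts the maturity rules
    need (CD20, CD4, CD8 and CD21+CD23+ follicular DCs) when those markers
    are on the panel; additional :class:`~tlsquant.quantify.PhenotypeDef`
    entries are counted on request.
    """
    idx = np.asarray(agg.member_index)
    if idx.size == 0 or idx.max() >= cells.n_cells:
        raise ValueError("aggregate members out of range for cell table")
    pts = cells.coords()[idx]

    feret = float(pdist(pts).max()) if len(pts) > 1 else 0.0
    degenerate = False
    if len(pts) < 3:
        area_mm2, degenerate = 0.0, True
    else:
        try:
            area_mm2 = ConvexHull(pts).volume * 1e-6  # µm² -> mm²
        except QhullError:  # collinear members
            area_mm2, degenerate = 0.0, True

    comp: dict[str, int] = {}
    for m in CORE_MARKERS:
        if m in cells.panel:
            comp[m] = int(cells.marker(m)[idx].sum())
    if "CD21" in cells.panel and "CD23" in cells.panel:
        comp["FDC"] = int((cells.marker("CD21")[idx] & cells.marker("CD23")[idx]).sum())
    for ph in phenotypes or []:
        mask = np.ones(len(idx), dtype=bool)
        for m in ph.required_positive:
            mask &= cells.marker(m)[idx]
        for m in ph.required_negative:
            mask &= ~cells.marker(m)[idx]
        comp[ph.name] = int(mask.sum())

    return replace(
        agg,
        max_feret_um=feret,
        hull_area_mm2=float(area_mm2),
        degenerate_hull=degenerate,
        centroid=(float(pts[:, 0].mean()), float(pts[:, 1].mean())),
        composition=comp,
    )


def classify_aggregate(agg: Aggregate, thresholds: TlsThresholds | None = None) -> TlsCall:
    """Apply the eTLS/mTLS rules to a measured aggregate.

    All structural criteria must pass for TLS status; the CD21+CD23+
    follicular-DC count then separates mature from early TLS.  The full
    per-criterion outcome is recorded in ``rule_trace``.
    """
    t = thresholds or TlsThresholds()
    if not math.isfinite(agg.max_feret_um):
        raise ValueError("aggregate metrics not filled; call measure_aggregate first")
    comp = agg.composition
    cd20_frac = comp.get("CD20", 0) / agg.n_cells
    trace = {
        "min_cells": agg.n_cells > t.min_cells,
        "min_size": agg.max_feret_um >= t.min_size_um,
        "cd20_majority": cd20_frac > t.cd20_majority,
        "has_cd4": (not t.require_cd4) or comp.get("CD4", 0) >= 1,
        "has_cd8": (not t.require_cd8) or comp.get("CD8", 0) >= 1,
    }
    is_tls = all(trace.values())
    trace["fdc_mature"] = comp.get("FDC", 0) >= t.min_fdc_for_mature
    if not is_tls:
        cls = "not_tls"
    elif trace["fdc_mature"]:
        cls = "mTLS"
    else:
        cls = "eTLS"
    return TlsCall(aggregate=agg, tls_class=cls, rule_trace=trace)


def localize_tls(call: TlsCall, regions: RegionSet) -> TlsCall:
    """Assign margin / core / stroma localization by aggregate centroid.

    Margin wins on both sides of the core boundary: any centroid within
    ``margin_band_um`` of the core outline is at the invasive margin,
    whether it sits inside the core or in the stroma.
    """
    c = Point(*call.aggregate.centroid)
    if not regions.tissue.covers(c):
        warnings.warn(
            f"aggregate centroid {call.aggregate.centroid} outside tissue polygon",
            stacklevel=2,
        )
        call.localization = "unassigned"
        return call
    loc = "unassigned"
    if regions.core is not None and not regions.core.is_empty:
        if regions.core.boundary.distance(c) <= regions.margin_band_um:
            loc = "margin"
        elif regions.core.covers(c):
            loc = "core"
    if loc == "unassigned" and regions.stroma is not None and regions.stroma.covers(c):
        loc = "stroma"
    call.localization = loc
    return call


def tls_hull_union(calls: list[TlsCall], cells: CellTable, which: str | None = None):
    """Union of convex hulls of the given TLS calls (shapely, µm units).

    ``which`` restricts to one class (``"eTLS"`` or ``"mTLS"``).
    Degenerate hulls contribute no area.
    """
    polys = [
        c.aggregate.hull_polygon(cells)
        for c in calls
        if (which is None or c.tls_class == which) and not c.aggregate.degenerate_hull
    ]
    return unary_union(polys) if polys else Polygon()
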