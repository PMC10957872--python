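"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates one input kind and records what a correct analysis
must recover:

* :func:`generate_tissue` — a cell table with background cells scattered
  uniformly over a tissue polygon plus planted lymphoid aggregates of
  controlled size, extent and marker composition.  Aggregate cells sit on a
  jittered hexagonal lattice clipped to a disc and filled row-by-row from
  the central row outward, which guarantees (a) the aggregate is one
  connected component at the declared contact distance and (b) its maximum
  Feret diameter reaches the requested disc diameter as soon as the central
  row is full.  The intended class of every aggregate is recorded by
  applying the classification rules to the planted composition.
* :func:`generate_variant_table` — variants constructed to be removed by
  exactly one named filter of the TMB cascade, or to be eligible.
* :func:`generate_expression` — negative-binomial counts with the signature
  genes elevated by a known log-fold effect in a "Hi" subset of samples.
* :func:`generate_survival` — exponential event times under proportional
  hazards with a known log hazard ratio and independent exponential
  censoring calibrated to the requested censoring fraction.

All randomness flows from one integer seed per call; identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from shapely.geometry import Point, Polygon

from .quantify import PhenotypeDef
from .signatures import ExpressionMatrix, GeneSignature
from .stats import SurvivalRecord
from .tls import (
    Aggregate,
    CellTable,
    RegionSet,
    TlsThresholds,
    classify_aggregate,
    localize_tls,
    measure_aggregate,
)
from .tmb import PanelRegions, TmbConfig, VariantRecord

__all__ = [
    "AggregateSpec",
    "TissueSimSpec",
    "GroundTruth",
    "generate_tissue",
    "generate_variant_table",
    "generate_panel",
    "generate_expression",
    "generate_survival",
    "DEFAULT_PANEL",
    "BACKGROUND_PHENOTYPE_MARKERS",
]

DEFAULT_PANEL = ("CD20", "CD4", "CD8", "CD21", "CD23", "CD68")

#: marker positivity implied by each background phenotype name
BACKGROUND_PHENOTYPE_MARKERS: dict[str, tuple[str, ...]] = {
    "B": ("CD20",),
    "CD4_T": ("CD4",),
    "CD8_T": ("CD8",),
    "macrophage": ("CD68",),
}


@dataclass(frozen=True)
class AggregateSpec:
    """One planted aggregate: geometry plus marker composition."""

    center: tuple[float, float]
    n_cells: int
    diameter_um: float
    frac_cd20: float
    include_cd4: bool = True
    include_cd8: bool = True
    n_fdc: int = 0
    intra_spacing_um: float = 12.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.diameter_um <= 0 or self.intra_spacing_um <= 0:
            raise ValueError("diameter_um and intra_spacing_um must be positive")
        if not 0.0 <= self.frac_cd20 <= 1.0:
            raise ValueError("frac_cd20 must lie in [0, 1]")
        if self.n_fdc < 0:
            raise ValueError("n_fdc must be >= 0")


@dataclass
class TissueSimSpec:
    seed: int
    tissue_polygon: Polygon
    core_polygon: Polygon | None = None
    stroma_polygon: Polygon | None = None
    margin_band_um: float = 500.0
    n_background_cells: int = 0
    background_phenotype_freqs: dict[str, float] = field(default_factory=dict)
    aggregates: list[AggregateSpec] = field(default_factory=list)
    contact_distance_um: float = 15.0
    panel: tuple[str, ...] = DEFAULT_PANEL

    def __post_init__(self) -> None:
        if sum(self.background_phenotype_freqs.values()) > 1.0 + 1e-12:
            raise ValueError("background phenotype probabilities sum to > 1")
        for a in self.aggregates:
            if not self.tissue_polygon.covers(Point(*a.center)):
                raise ValueError(f"aggregate center {a.center} outside tissue polygon")


@dataclass
class GroundTruth:
    """Construction record of what a correct analysis must recover."""

    planted_aggregates: list[dict] = field(default_factory=list)
    variant_truth: list[dict] = field(default_factory=list)
    expected_eligible: int | None = None
    signature_truth: dict[str, str] = field(default_factory=dict)
    survival_truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------- tissue --

def _hex_disc_points(center, n_cells, diameter_um, spacing):
    """Lattice points filling a disc row-by-row from the central row out.

    Returned in fill order so that any prefix is connected at the lattice
    spacing and the first full central row spans the disc diameter.
    """
    radius = diameter_um / 2.0
    row_h = spacing * math.sqrt(3) / 2.0
    max_row = int(radius // row_h)
    rows = sorted(range(-max_row, max_row + 1), key=lambda j: (abs(j), j < 0))
    pts = []
    for j in rows:
        y = j * row_h
        half_w = math.sqrt(max(radius**2 - y**2, 0.0))
        x_off = (spacing / 2.0) if j % 2 else 0.0
        k_max = int((half_w - x_off) // spacing) if half_w >= x_off else -1
        k_min = -int((half_w + x_off) // spacing)
        xs = [x_off + k * spacing for k in range(k_min, k_max + 1)]
        pts.extend((x, y) for x in sorted(xs))
    if len(pts) < n_cells:
        raise ValueError(
            f"aggregate of {n_cells} cells does not fit in a {diameter_um} µm "
            f"disc at {spacing} µm spacing ({len(pts)} lattice sites)"
        )
    arr = np.array(pts[:n_cells])
    return arr + np.asarray(center)


def _aggregate_markers(rng, spec: AggregateSpec, panel) -> np.ndarray:
    """0/1 marker matrix (n_cells × panel) honouring the requested mix."""
    n = spec.n_cells
    n_cd20 = int(round(spec.frac_cd20 * n))
    n_rest = n - n_cd20 - spec.n_fdc
    need = int(spec.include_cd4) + int(spec.include_cd8)
    if n_rest < need or n_rest < 0:
        raise ValueError(
            "aggregate composition infeasible: not enough non-B, non-fDC cells "
            "for the requested CD4/CD8 presence"
        )
    roles = ["B"] * n_cd20 + ["FDC"] * spec.n_fdc
    if spec.include_cd4 and spec.include_cd8:
        n_cd4 = max(1, n_rest // 2)
        roles += ["CD4"] * n_cd4 + ["CD8"] * (n_rest - n_cd4)
    elif spec.include_cd4:
        roles += ["CD4"] * n_rest
    elif spec.include_cd8:
        roles += ["CD8"] * n_rest
    else:
        roles += ["none"] * n_rest
    roles = np.array(roles)[rng.permutation(n)]

    markers = np.zeros((n, len(panel)), dtype=np.int8)
    col = {m: i for i, m in enumerate(panel)}
    role_markers = {"B": ("CD20",), "FDC": ("CD21", "CD23"), "CD4": ("CD4",), "CD8": ("CD8",)}
    for i, role in enumerate(roles):
        for m in role_markers.get(role, ()):
            if m in col:
                markers[i, col[m]] = 1
    return markers


def _background_markers(rng, spec: TissueSimSpec, n: int) -> np.ndarray:
    names = list(spec.background_phenotype_freqs)
    probs = [spec.background_phenotype_freqs[k] for k in names]
    p_none = 1.0 - sum(probs)
    choice = rng.choice(len(names) + 1, size=n, p=[*probs, p_none])
    markers = np.zeros((n, len(spec.panel)), dtype=np.int8)
    col = {m: i for i, m in enumerate(spec.panel)}
    for i, c in enumerate(choice):
        if c == len(names):
            continue
        for m in BACKGROUND_PHENOTYPE_MARKERS.get(names[c], (names[c],)):
            if m in col:
                markers[i, col[m]] = 1
    return markers


def _uniform_in_polygon(rng, polygon: Polygon, n: int, exclusion=None) -> np.ndarray:
    minx, miny, maxx, maxy = polygon.bounds
    pts = np.empty((n, 2))
    filled = 0
    while filled < n:
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(max(4 * (n - filled), 64), 2))
        for x, y in cand:
            p = Point(x, y)
            if not polygon.covers(p):
                continue
            if exclusion is not None and exclusion.covers(p):
                continue
            pts[filled] = (x, y)
            filled += 1
            if filled == n:
                break
    return pts


def generate_tissue(
    spec: TissueSimSpec,
    thresholds: TlsThresholds | None = None,
) -> tuple[CellTable, RegionSet, GroundTruth]:
    """Simulate a tissue section with planted aggregates.

    Background cells are uniform over the tissue polygon outside an
    exclusion halo (two contact distances) around each planted disc, so
    that planted aggregates never merge with chance background clusters
    and the recorded ground truth stays unambiguous.  Planted discs must
    fit inside the tissue polygon and be separated by at least two contact
    distances from one another.
    """
    thresholds = thresholds or TlsThresholds(contact_distance_um=spec.contact_distance_um)
    rng = np.random.default_rng(spec.seed)

    for a in spec.aggregates:
        disc = Point(*a.center).buffer(a.diameter_um / 2.0, quad_segs=32)
        if not spec.tissue_polygon.covers(disc):
            raise ValueError(f"aggregate at {a.center} exceeds the tissue polygon")
    for i, a in enumerate(spec.aggregates):
        for b in spec.aggregates[i + 1:]:
            gap = (
                math.dist(a.center, b.center)
                - a.diameter_um / 2.0
                - b.diameter_um / 2.0
            )
            if gap < 2.0 * spec.contact_distance_um:
                raise ValueError(
                    f"aggregates at {a.center} and {b.center} are closer than "
                    "2x the contact distance; ground truth would be ambiguous"
                )

    coords_parts, marker_parts, planted_slices = [], [], []
    n_so_far = 0
    for a in spec.aggregates:
        spacing = min(a.intra_spacing_um, spec.contact_distance_um)
        jitter = max(0.0, (spec.contact_distance_um - spacing) / 4.0)
        pts = _hex_disc_points(a.center, a.n_cells, a.diameter_um, spacing)
        pts = pts + rng.uniform(-jitter, jitter, size=pts.shape)
        coords_parts.append(pts)
        marker_parts.append(_aggregate_markers(rng, a, spec.panel))
        planted_slices.append((n_so_far, n_so_far + a.n_cells))
        n_so_far += a.n_cells

    if spec.n_background_cells:
        halos = [
            Point(*a.center).buffer(
                a.diameter_um / 2.0 + 2.0 * spec.contact_distance_um, quad_segs=32
            )
            for a in spec.aggregates
        ]
        from shapely.ops import unary_union

        exclusion = unary_union(halos) if halos else None
        bg = _uniform_in_polygon(rng, spec.tissue_polygon, spec.n_background_cells, exclusion)
        coords_parts.append(bg)
        marker_parts.append(_background_markers(rng, spec, spec.n_background_cells))

    if coords_parts:
        coords = np.vstack(coords_parts)
        markers = np.vstack(marker_parts)
    else:
        coords = np.empty((0, 2))
        markers = np.empty((0, len(spec.panel)), dtype=np.int8)

    df = pd.DataFrame(
        {
            "cell_id": [f"C{i:06d}" for i in range(len(coords))],
            "x_um": coords[:, 0],
            "y_um": coords[:, 1],
        }
    )
    for j, m in enumerate(spec.panel):
        df[m] = markers[:, j].astype(np.int64)
    cells = CellTable(panel=spec.panel, df=df)
    regions = RegionSet(
        tissue=spec.tissue_polygon,
        core=spec.core_polygon,
        stroma=spec.stroma_polygon,
        margin_band_um=spec.margin_band_um,
    )

    truth = GroundTruth()
    for lo, hi in planted_slices:
        idx = np.arange(lo, hi)
        agg = measure_aggregate(
            Aggregate(member_index=idx, member_ids=tuple(df["cell_id"].iloc[lo:hi]), n_cells=hi - lo),
            cells,
        )
        call = localize_tls(classify_aggregate(agg, thresholds), regions)
        truth.planted_aggregates.append(
            {
                "member_ids": list(call.aggregate.member_ids),
                "intended_class": call.tls_class,
                "localization": call.localization,
                "n_cells": call.aggregate.n_cells,
                "composition": dict(call.aggregate.composition),
            }
        )
    return cells, regions, truth


# -------------------------------------------------------------- variants --

#: construction recipes per requested truth category (chromosome, VAF range)
_CATEGORIES = (
    "eligible", "db", "proximity", "high_af", "mnv",
    "noncoding", "low_vaf", "low_depth", "cosmic",
)


def generate_variant_table(
    seed: int,
    n_variants: int,
    panel: PanelRegions,
    truth_mix: dict[str, int],
    cfg: TmbConfig | None = None,
) -> tuple[list[VariantRecord], GroundTruth]:
    """Variants constructed so each is resolved by exactly one named rule.

    ``truth_mix`` maps category → count over: eligible, db, proximity,
    high_af, mnv, noncoding, low_vaf, low_depth, cosmic.  Database-removed
    decoys live on their own chromosome near VAF 0.5, and proximity victims
    are placed among them; every other category is isolated on other
    chromosomes so no rule fires by accident.
    """
    cfg = cfg or TmbConfig()
    unknown = set(truth_mix) - set(_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown truth categories: {sorted(unknown)}")
    if any(c < 0 for c in truth_mix.values()):
        raise ValueError("truth_mix counts must be non-negative")
    if sum(truth_mix.values()) != n_variants:
        raise ValueError("truth_mix counts must sum to n_variants")
    if truth_mix.get("proximity", 0) > 0 and truth_mix.get("db", 0) < cfg.proximity_group_min:
        raise ValueError(
            f"proximity removals need at least {cfg.proximity_group_min} "
            "database-removed variants on the same chromosome"
        )

    rng = np.random.default_rng(seed)
    pos_counter: dict[str, int] = {}

    def next_pos(chrom: str) -> int:
        pos_counter[chrom] = pos_counter.get(chrom, 0) + 1000
        return pos_counter[chrom]

    def base(chrom, vaf, **kw) -> dict:
        d = dict(
            chrom=chrom,
            pos=next_pos(chrom),
            ref="A",
            alt="T",
            variant_type="SNV",
            vaf=float(vaf),
            depth=int(rng.integers(cfg.min_depth, 500)),
            consequence="nonsynonymous" if rng.random() < 0.7 else "synonymous",
            in_coding=True,
            gnomad_exome=int(rng.integers(0, cfg.db_count_threshold)),
            gnomad_genome=int(rng.integers(0, cfg.db_count_threshold)),
            kg1000=int(rng.integers(0, cfg.db_count_threshold)),
            cosmic_count=int(rng.integers(0, cfg.cosmic_exclude_threshold)),
        )
        d.update(kw)
        return d

    makers = {
        "eligible": lambda: base("chr1", rng.uniform(cfg.min_vaf, 0.45)),
        "db": lambda: base(
            "chr9",
            0.5 + rng.uniform(-0.4, 0.4) * cfg.proximity_af_tol,
            gnomad_exome=int(rng.integers(cfg.db_count_threshold, 500)),
        ),
        "proximity": lambda: base(
            "chr9", 0.5 + rng.uniform(-0.2, 0.2) * cfg.proximity_af_tol
        ),
        "high_af": lambda: base("chr2", rng.uniform(cfg.high_af_threshold, 1.0)),
        "mnv": lambda: base("chr3", 0.3, variant_type="MNV", ref="AC", alt="TG"),
        "noncoding": lambda: base("chr3", 0.3, in_coding=False, consequence="noncoding"),
        "low_vaf": lambda: base("chr4", rng.uniform(0.005, cfg.min_vaf * 0.9)),
        "low_depth": lambda: base("chr4", 0.3, depth=int(rng.integers(0, cfg.min_depth))),
        "cosmic": lambda: base(
            "chr5", 0.3, cosmic_count=int(rng.integers(cfg.cosmic_exclude_threshold, 2000))
        ),
    }
    verdict_of = {
        "eligible": "eligible",
        "db": "removed_db",
        "proximity": "removed_proximity",
        "high_af": "removed_high_af",
        "mnv": "not_eligible:mnv",
        "noncoding": "not_eligible:not_coding",
        "low_vaf": "not_eligible:low_vaf",
        "low_depth": "not_eligible:low_depth",
        "cosmic": "not_eligible:cosmic",
    }

    variants, truth_rows = [], []
    for cat in _CATEGORIES:  # fixed order keeps output deterministic
        for _ in range(truth_mix.get(cat, 0)):
            variants.append(VariantRecord(**makers[cat]()))
            truth_rows.append({"category": cat, "expected_verdict": verdict_of[cat]})
    order = rng.permutation(len(variants))
    variants = [variants[i] for i in order]
    truth_rows = [truth_rows[i] for i in order]
    for i, row in enumerate(truth_rows):
        row["index"] = i

    truth = GroundTruth(
        variant_truth=truth_rows,
        expected_eligible=truth_mix.get("eligible", 0),
    )
    return variants, truth


def generate_panel(
    seed: int,
    n_intervals: int = 20,
    mean_length: int = 50_000,
    coverage_range: tuple[float, float] = (10.0, 200.0),
    frac_low_confidence: float = 0.1,
) -> PanelRegions:
    """Random non-overlapping panel intervals with mean coverage."""
    rng = np.random.default_rng(seed)
    intervals = []
    pos = 0
    for _ in range(n_intervals):
        pos += int(rng.integers(1, 10_000))
        length = max(1, int(rng.exponential(mean_length)))
        cov = float(rng.uniform(*coverage_range))
        low_conf = bool(rng.random() < frac_low_confidence)
        intervals.append(("chr1", pos, pos + length, cov, low_conf))
        pos += length
    # a usable panel needs at least one confidently covered interval
    if not any(cov > 50.0 and not lc for _c, _s, _e, cov, lc in intervals):
        chrom, start, end, _cov, _lc = intervals[0]
        intervals[0] = (chrom, start, end, 100.0, False)
    return PanelRegions(intervals=intervals)


# ------------------------------------------------------------ expression --

def generate_expression(
    seed: int,
    n_genes: int,
    n_samples: int,
    signature: GeneSignature,
    effect: float,
    frac_hi: float,
    baseline_mean: float = 10.0,
    dispersion: float = 0.5,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Negative-binomial counts with the signature elevated in Hi samples.

    The baseline is NB with mean ``baseline_mean`` and dispersion
    ``dispersion`` (variance = µ + φµ²); in the Hi fraction of samples the
    signature genes' mean is multiplied by exp(effect).
    """
    if effect < 0:
        raise ValueError("effect must be >= 0")
    if not 0.0 < frac_hi < 1.0:
        raise ValueError("frac_hi must lie in (0, 1)")
    if n_genes < len(signature.genes):
        raise ValueError("n_genes smaller than the signature")
    rng = np.random.default_rng(seed)

    gene_ids = list(signature.genes) + [
        f"G{i:05d}" for i in range(n_genes - len(signature.genes))
    ]
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    n_hi = max(1, int(round(frac_hi * n_samples)))
    hi_idx = np.sort(rng.choice(n_samples, size=n_hi, replace=False))

    mu = np.full((n_genes, n_samples), baseline_mean)
    mu[: len(signature.genes), hi_idx] *= math.exp(effect)
    size = 1.0 / dispersion
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p)

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    )
    labels = {
        s: ("Hi" if i in set(hi_idx) else "Lo") for i, s in enumerate(sample_ids)
    }
    return matrix, GroundTruth(signature_truth=labels)


# -------------------------------------------------------------- survival --

def generate_survival(
    seed: int,
    n: int,
    true_log_hr: float,
    censor_rate: float,
    baseline_hazard: float = math.log(2) / 24.0,
    covariate_name: str = "group",
) -> tuple[list[SurvivalRecord], GroundTruth]:
    """Proportional-hazards survival data with a balanced binary covariate.

    Event times are exponential with hazard ``baseline_hazard`` (default:
    24-month median survival in the reference group) multiplied by
    exp(true_log_hr) when the covariate is 1.  Censoring is an independent
    exponential time whose rate is solved so the expected fraction censored
    equals ``censor_rate``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    x = np.zeros(n, dtype=int)
    x[: n // 2] = 1
    x = x[rng.permutation(n)]
    lam = baseline_hazard * np.exp(true_log_hr * x)
    t_event = rng.exponential(1.0 / lam)

    if censor_rate > 0:
        lams = np.unique(lam)

        def frac_censored(lc):
            return float(np.mean(lc / (lam + lc))) - censor_rate

        lc = brentq(frac_censored, 1e-12 * lams.min(), 1e12 * lams.max())
        t_cens = rng.exponential(1.0 / lc, size=n)
    else:
        t_cens = np.full(n, np.inf)

    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    records = [
        SurvivalRecord(
            subject_id=f"P{i:05d}",
            time=float(time[i]),
            event=int(event[i]),
            covariates=((covariate_name, int(x[i])),),
        )
        for i in range(n)
    ]
    truth = GroundTruth(
        survival_truth={
            "true_log_hr": true_log_hr,
            "censor_rate": censor_rate,
            "covariate": covariate_name,
        }
    )
    return records, truth
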