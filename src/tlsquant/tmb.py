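"""Panel tumor-mutational-burden with a tumor-only germline filter cascade.

Variants from a targeted panel are filtered in four ordered steps:

1. **database** — remove any variant with an observed allele count of 10 or
   more in any of gnomAD exomes, gnomAD genomes or 1000 Genomes;
2. **proximity** — remove a surviving variant when 5 or more of the
   database-removed variants share its chromosome and have a variant allele
   frequency within ±``proximity_af_tol`` of it (decisions are made against
   the frozen database-removed set, never against each other);
3. **high allele frequency** — remove variants with VAF ≥ 90%, likely
   germline homozygous;
4. **eligibility** — of the survivors, count coding SNVs and indels
   (MNVs excluded), synonymous or nonsynonymous, with VAF ≥ 5%,
   coverage ≥ 50× and a COSMIC count below 50.

TMB = eligible variants / effective panel size, in mutations per megabase.
The effective panel size is the coding territory with coverage strictly
above 50×, excluding low-confidence regions.  Note the deliberate
asymmetry: the numerator's coverage rule is inclusive (≥ 50×) while the
denominator's is strict (> 50×).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "VariantRecord",
    "TmbConfig",
    "PanelRegions",
    "TmbResult",
    "filter_database",
    "filter_proximity",
    "filter_high_af",
    "select_eligible",
    "effective_panel_size",
    "compute_tmb",
]

VARIANT_TYPES = ("SNV", "indel", "MNV")
CONSEQUENCES = ("synonymous", "nonsynonymous", "noncoding")


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    variant_type: str
    vaf: float
    depth: int
    consequence: str
    in_coding: bool
    gnomad_exome: int = 0
    gnomad_genome: int = 0
    kg1000: int = 0
    cosmic_count: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.variant_type not in VARIANT_TYPES:
            raise ValueError(f"variant_type must be one of {VARIANT_TYPES}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"consequence must be one of {CONSEQUENCES}")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


@dataclass(frozen=True)
class TmbConfig:
    db_count_threshold: int = 10
    proximity_af_tol: float = 0.05
    proximity_group_min: int = 5
    high_af_threshold: float = 0.90
    min_vaf: float = 0.05
    min_depth: int = 50
    cosmic_exclude_threshold: int = 50
    denominator_min_coverage: float = 50.0


@dataclass
class PanelRegions:
    """Coding panel intervals (0-based half-open) with mean coverage."""

    intervals: list[tuple[str, int, int, float, bool]]  # chrom, start, end, coverage, low_confidence

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, _cov, _lc in self.intervals:
            if end <= start:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, _e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping panel intervals on {chrom}")


@dataclass
class TmbResult:
    eligible_count: int
    effective_size_mb: float
    tmb: float
    trace: list[dict] = field(default_factory=list)


def _max_db_count(v: VariantRecord) -> int:
    counts = []
    for name in ("gnomad_exome", "gnomad_genome", "kg1000"):
        c = getattr(v, name)
        if c is None:
            warnings.warn(f"missing {name} count treated as 0", stacklevel=3)
            c = 0
        counts.append(c)
    return max(counts)


def filter_database(
    variants: list[VariantRecord], cfg: TmbConfig | None = None
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split into (removed, retained) by population-database allele counts."""
    cfg = cfg or TmbConfig()
    removed = [v for v in variants if _max_db_count(v) >= cfg.db_count_threshold]
    retained = [v for v in variants if _max_db_count(v) < cfg.db_count_threshold]
    return removed, retained


def filter_proximity(
    retained: list[VariantRecord],
    removed_by_db: list[VariantRecord],
    cfg: TmbConfig | None = None,
) -> list[VariantRecord]:
    """Variants that cluster with the database-removed germline background.

    Returns the subset of ``retained`` to remove: those with at least
    ``proximity_group_min`` database-removed variants on the same chromosome
    whose VAF lies within ``proximity_af_tol``.
    """
    cfg = cfg or TmbConfig()
    by_chrom: dict[str, list[float]] = {}
    for v in removed_by_db:
        by_chrom.setdefault(v.chrom, []).append(v.vaf)
    out = []
    for v in retained:
        vafs = by_chrom.get(v.chrom, ())
        n_similar = sum(1 for f in vafs if abs(f - v.vaf) <= cfg.proximity_af_tol)
        if n_similar >= cfg.proximity_group_min:
            out.append(v)
    return out


def filter_high_af(
    variants: list[VariantRecord], cfg: TmbConfig | None = None
) -> list[VariantRecord]:
    """Likely homozygous germline: VAF at or above the high-AF threshold."""
    cfg = cfg or TmbConfig()
    return [v for v in variants if v.vaf >= cfg.high_af_threshold]


def _ineligibility_reason(v: VariantRecord, cfg: TmbConfig) -> str | None:
    if not v.in_coding:
        return "not_coding"
    if v.variant_type == "MNV":
        return "mnv"
    if v.consequence == "noncoding":
        return "noncoding_consequence"
    if v.vaf < cfg.min_vaf:
        return "low_vaf"
    if v.depth < cfg.min_depth:
        return "low_depth"
    if v.cosmic_count >= cfg.cosmic_exclude_threshold:
        return "cosmic"
    return None


def select_eligible(
    variants: list[VariantRecord], cfg: TmbConfig | None = None
) -> list[VariantRecord]:
    """Numerator selection among variants that survived the germline filters."""
    cfg = cfg or TmbConfig()
    return [v for v in variants if _ineligibility_reason(v, cfg) is None]


def effective_panel_size(panel: PanelRegions, cfg: TmbConfig | None = None) -> float:
    """Denominator in megabases: bases covered strictly above the coverage
    floor, excluding low-confidence intervals."""
    cfg = cfg or TmbConfig()
    bases = sum(
        end - start
        for _chrom, start, end, cov, low_conf in panel.intervals
        if cov > cfg.denominator_min_coverage and not low_conf
    )
    if bases == 0:
        raise ValueError("no panel bases pass the coverage/confidence gates")
    return bases / 1e6


def compute_tmb(
    variants: list[VariantRecord],
    panel: PanelRegions,
    cfg: TmbConfig | None = None,
) -> TmbResult:
    """Run the full cascade and form the TMB quotient.

    The trace records, for every input variant in order, the single rule
    that removed it ("removed_db", "removed_proximity", "removed_high_af",
    "not_eligible:<reason>") or "eligible".
    """
    cfg = cfg or TmbConfig()
    removed_db, retained = filter_database(variants, cfg)
    removed_db_set = {id(v) for v in removed_db}
    removed_prox = {id(v) for v in filter_proximity(retained, removed_db, cfg)}
    survivors = [v for v in retained if id(v) not in removed_prox]
    removed_high = {id(v) for v in filter_high_af(survivors, cfg)}
    survivors = [v for v in survivors if id(v) not in removed_high]
    eligible = {id(v) for v in select_eligible(survivors, cfg)}

    trace = []
    for i, v in enumerate(variants):
        if id(v) in removed_db_set:
            verdict = "removed_db"
        elif id(v) in removed_prox:
            verdict = "removed_proximity"
        elif id(v) in removed_high:
            verdict = "removed_high_af"
        elif id(v) in eligible:
            verdict = "eligible"
        else:
            verdict = f"not_eligible:{_ineligibility_reason(v, cfg)}"
        trace.append({"index": i, "chrom": v.chrom, "pos": v.pos, "verdict": verdict})

    size_mb = effective_panel_size(panel, cfg)
    n_eligible = len(eligible)
    return TmbResult(
        eligible_count=n_eligible,
        effective_size_mb=size_mb,
        tmb=n_eligible / size_mb,
        trace=trace,
    )
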