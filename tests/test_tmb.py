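"""Panel TMB filter cascade against boundaries and a brute-force oracle."""

import numpy as np
import pytest

from tlsquant import (
    PanelRegions,
    TmbConfig,
    VariantRecord,
    compute_tmb,
    effective_panel_size,
)
from tlsquant.tmb import (
    filter_database,
    filter_high_af,
    filter_proximity,
    select_eligible,
)


def V(**kw):
    base = dict(
        chrom="chr1", pos=100, ref="A", alt="T", variant_type="SNV",
        vaf=0.3, depth=100, consequence="nonsynonymous", in_coding=True,
        gnomad_exome=0, gnomad_genome=0, kg1000=0, cosmic_count=0,
    )
    base.update(kw)
    return VariantRecord(**base)


PANEL_2MB = PanelRegions([("chr1", 0, 2_000_000, 60.0, False),
                          ("chr2", 0, 500_000, 50.0, False)])


def brute_force_tmb(variants, panel, cfg):
    """Independent single-pass evaluator of the whole cascade."""
    verdicts = {}
    db_removed = []
    for i, v in enumerate(variants):
        if max(v.gnomad_exome, v.gnomad_genome, v.kg1000) >= cfg.db_count_threshold:
            verdicts[i] = "removed_db"
            db_removed.append(v)
    for i, v in enumerate(variants):
        if i in verdicts:
            continue
        similar = [
            u for u in db_removed
            if u.chrom == v.chrom and abs(u.vaf - v.vaf) <= cfg.proximity_af_tol
        ]
        if len(similar) >= cfg.proximity_group_min:
            verdicts[i] = "removed_proximity"
    for i, v in enumerate(variants):
        if i in verdicts:
            continue
        if v.vaf >= cfg.high_af_threshold:
            verdicts[i] = "removed_high_af"
    n_eligible = 0
    for i, v in enumerate(variants):
        if i in verdicts:
            continue
        ok = (
            v.in_coding
            and v.variant_type in ("SNV", "indel")
            and v.consequence in ("synonymous", "nonsynonymous")
            and v.vaf >= cfg.min_vaf
            and v.depth >= cfg.min_depth
            and v.cosmic_count < cfg.cosmic_exclude_threshold
        )
        verdicts[i] = "eligible" if ok else "not_eligible"
        n_eligible += ok
    mb = sum(
        e - s for _c, s, e, cov, lc in panel.intervals
        if cov > cfg.denominator_min_coverage and not lc
    ) / 1e6
    return verdicts, n_eligible, n_eligible / mb


class TestFilters:
    def test_db_count_10_removed_9_retained(self):
        removed, retained = filter_database(
            [V(gnomad_exome=10), V(gnomad_exome=9, gnomad_genome=9, kg1000=9)]
        )
        assert len(removed) == 1 and removed[0].gnomad_exome == 10
        assert len(retained) == 1

    def test_db_any_of_three_sources(self):
        for kw in ({"gnomad_exome": 10}, {"gnomad_genome": 11}, {"kg1000": 400}):
            removed, _ = filter_database([V(**kw)])
            assert len(removed) == 1

    def test_proximity_five_similar_removes(self):
        db = [V(chrom="chr1", vaf=f, gnomad_exome=50) for f in (0.45, 0.47, 0.49, 0.51, 0.52)]
        victim = V(chrom="chr1", vaf=0.48)
        assert filter_proximity([victim], db) == [victim]

    def test_proximity_four_similar_retains(self):
        db = [V(chrom="chr1", vaf=f, gnomad_exome=50) for f in (0.45, 0.47, 0.49, 0.51)]
        assert filter_proximity([V(chrom="chr1", vaf=0.48)], db) == []

    def test_proximity_needs_same_chromosome(self):
        db = [V(chrom="chr2", vaf=0.48, gnomad_exome=50) for _ in range(6)]
        assert filter_proximity([V(chrom="chr1", vaf=0.48)], db) == []

    @pytest.mark.parametrize("vaf,removed", [(0.90, True), (0.899, False), (1.0, True)])
    def test_high_af_boundary(self, vaf, removed):
        got = filter_high_af([V(vaf=vaf)])
        assert (len(got) == 1) is removed

    def test_eligibility_inclusive_boundaries(self):
        assert select_eligible([V(vaf=0.05, depth=50)]) != []
        assert select_eligible([V(vaf=0.049, depth=50)]) == []
        assert select_eligible([V(vaf=0.05, depth=49)]) == []

    def test_mnv_excluded(self):
        assert select_eligible([V(variant_type="MNV", ref="AC", alt="TG")]) == []

    def test_cosmic_boundary(self):
        assert select_eligible([V(cosmic_count=50)]) == []
        assert select_eligible([V(cosmic_count=49)]) != []

    def test_synonymous_counts_noncoding_does_not(self):
        assert select_eligible([V(consequence="synonymous")]) != []
        assert select_eligible([V(in_coding=False, consequence="noncoding")]) == []


class TestEffectivePanelSize:
    def test_strict_coverage_boundary(self):
        assert effective_panel_size(PANEL_2MB) == pytest.approx(2.0)

    def test_all_low_confidence_errors(self):
        panel = PanelRegions([("chr1", 0, 1000, 100.0, True)])
        with pytest.raises(ValueError, match="no panel bases"):
            effective_panel_size(panel)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_base_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        intervals, pos = [], 0
        for _ in range(10):
            pos += int(rng.integers(1, 100))
            end = pos + int(rng.integers(1, 2000))
            intervals.append(
                ("chr1", pos, end, float(rng.uniform(10, 100)), bool(rng.random() < 0.2))
            )
            pos = end
        if not any(c > 50 and not l for _x, _s, _e, c, l in intervals):
            intervals[0] = ("chr1", *intervals[0][1:3], 60.0, False)
        panel = PanelRegions(intervals)
        per_base = sum(
            1
            for _c, s, e, cov, lc in intervals
            for _b in range(s, e)
            if cov > 50 and not lc
        )
        assert effective_panel_size(panel) == pytest.approx(per_base / 1e6)

    def test_denominator_monotone_in_coverage_floor(self):
        sizes = [
            effective_panel_size(PANEL_2MB, TmbConfig(denominator_min_coverage=c))
            for c in (10, 49.9, 55)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            PanelRegions([("chr1", 0, 100, 60.0, False), ("chr1", 50, 150, 60.0, False)])


def _random_variants(rng, n):
    out = []
    for _ in range(n):
        vt = rng.choice(["SNV", "indel", "MNV"], p=[0.7, 0.2, 0.1])
        out.append(
            V(
                chrom=f"chr{int(rng.integers(1, 4))}",
                pos=int(rng.integers(1, 10**6)),
                variant_type=str(vt),
                vaf=float(np.round(rng.uniform(0, 1), 3)),
                depth=int(rng.integers(0, 300)),
                consequence=str(rng.choice(["synonymous", "nonsynonymous", "noncoding"])),
                in_coding=bool(rng.random() < 0.8),
                gnomad_exome=int(rng.integers(0, 20)),
                gnomad_genome=int(rng.integers(0, 20)),
                kg1000=int(rng.integers(0, 20)),
                cosmic_count=int(rng.integers(0, 100)),
            )
        )
    return out


class TestComputeTmb:
    def test_quotient_example(self):
        variants = [V(pos=1000 * (i + 1)) for i in range(10)]
        res = compute_tmb(variants, PANEL_2MB)
        assert res.eligible_count == 10
        assert res.effective_size_mb == pytest.approx(2.0)
        assert res.tmb == pytest.approx(5.0)

    def test_zero_eligible(self):
        res = compute_tmb([V(vaf=0.95)], PANEL_2MB)
        assert res.eligible_count == 0 and res.tmb == 0.0

    def test_trace_partitions_input(self):
        rng = np.random.default_rng(0)
        variants = _random_variants(rng, 80)
        res = compute_tmb(variants, PANEL_2MB)
        assert len(res.trace) == len(variants)
        assert {t["index"] for t in res.trace} == set(range(len(variants)))

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        variants = _random_variants(rng, int(rng.integers(1, 100)))
        res = compute_tmb(variants, PANEL_2MB)
        expected, n_elig, tmb = brute_force_tmb(variants, PANEL_2MB, TmbConfig())
        got = {
            t["index"]: t["verdict"].split(":")[0] for t in res.trace
        }
        assert got == expected
        assert res.eligible_count == n_elig
        assert res.tmb == tmb

    def test_appending_filtered_variant_keeps_tmb(self):
        variants = [V(pos=1000 * (i + 1)) for i in range(5)]
        base = compute_tmb(variants, PANEL_2MB).tmb
        assert compute_tmb(variants + [V(vaf=0.95)], PANEL_2MB).tmb == base
        assert compute_tmb(variants + [V()], PANEL_2MB).eligible_count == 6

    def test_infinite_proximity_group_reduces_to_independent_predicates(self):
        rng = np.random.default_rng(1)
        variants = _random_variants(rng, 60)
        cfg = TmbConfig(proximity_group_min=10**9)
        res = compute_tmb(variants, PANEL_2MB, cfg)
        for t, v in zip(res.trace, variants):
            if max(v.gnomad_exome, v.gnomad_genome, v.kg1000) >= 10:
                assert t["verdict"] == "removed_db"
            else:
                assert t["verdict"] != "removed_proximity"
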