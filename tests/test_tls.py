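"""Aggregate detection, measurement, classification and localization."""

import numpy as np
import pytest
from shapely.geometry import MultiPoint

from tlsquant import (
    TlsThresholds,
    classify_aggregate,
    detect_aggregates,
    localize_tls,
    measure_aggregate,
)

from conftest import line_aggregate_markers, make_cell_table


def brute_force_components(coords, threshold):
    """Oracle: BFS over the full pairwise distance matrix."""
    n = len(coords)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    adj = d <= threshold
    seen = np.zeros(n, dtype=bool)
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in np.flatnonzero(adj[i] & ~seen):
                seen[j] = True
                stack.append(j)
        comps.append(frozenset(comp))
    return set(comps)


class TestDetect:
    def test_two_separated_clusters(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 50, (60, 2))
        b = rng.uniform(0, 50, (60, 2)) + 1500.0
        cells = make_cell_table(np.vstack([a, b]))
        aggs = detect_aggregates(cells, contact_distance_um=15.0, min_component_size=2)
        assert sorted(a.n_cells for a in aggs) == [60, 60]

    def test_chain_at_exact_threshold_is_one_component(self):
        coords = [(15.0 * i, 0.0) for i in range(10)]
        cells = make_cell_table(coords)
        aggs = detect_aggregates(cells, contact_distance_um=15.0, min_component_size=2)
        assert len(aggs) == 1 and aggs[0].n_cells == 10

    def test_empty_table(self):
        cells = make_cell_table(np.empty((0, 2)))
        assert detect_aggregates(cells, 15.0, 2) == []

    def test_members_are_disjoint_and_ordered(self):
        rng = np.random.default_rng(3)
        cells = make_cell_table(rng.uniform(0, 500, (200, 2)))
        aggs = detect_aggregates(cells, 30.0, 1)
        all_ids = [i for a in aggs for i in a.member_ids]
        assert len(all_ids) == len(set(all_ids)) == 200
        assert [min(a.member_ids) for a in aggs] == sorted(min(a.member_ids) for a in aggs)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_bfs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 300))
        coords = rng.uniform(0, 400, (n, 2))
        cells = make_cell_table(coords)
        got = {frozenset(a.member_index) for a in detect_aggregates(cells, 25.0, 1)}
        assert got == brute_force_components(coords, 25.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_component_count_monotone_in_contact_distance(self, seed):
        rng = np.random.default_rng(seed)
        cells = make_cell_table(rng.uniform(0, 300, (150, 2)))
        counts = [
            len(detect_aggregates(cells, r, 1)) for r in (5.0, 10.0, 20.0, 40.0, 80.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            make_cell_table([(0.0, 0.0), (np.nan, 1.0)])


class TestMeasure:
    def _measured(self, coords, **markers):
        cells = make_cell_table(coords, markers=markers)
        (agg,) = detect_aggregates(cells, 1e9, 1)
        return measure_aggregate(agg, cells), cells

    def test_right_triangle_geometry(self):
        agg, _ = self._measured([(0, 0), (100, 0), (0, 100)])
        assert agg.hull_area_mm2 == pytest.approx(0.005)
        assert agg.max_feret_um == pytest.approx(141.4213562)
        assert not agg.degenerate_hull

    def test_two_members_degenerate(self):
        agg, _ = self._measured([(0, 0), (50, 0)])
        assert agg.hull_area_mm2 == 0.0 and agg.degenerate_hull
        assert agg.max_feret_um == pytest.approx(50.0)

    def test_collinear_members_degenerate(self):
        agg, _ = self._measured([(0, 0), (10, 0), (20, 0), (30, 0)])
        assert agg.hull_area_mm2 == 0.0 and agg.degenerate_hull

    @pytest.mark.parametrize("seed", range(10))
    def test_hull_area_matches_shoelace(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 1000, (int(rng.integers(4, 60)), 2))
        agg, _ = self._measured(coords)
        # oracle: shoelace formula over the hull vertex cycle
        ring = np.array(MultiPoint([tuple(p) for p in coords]).convex_hull.exterior.coords)
        x, y = ring[:-1, 0], ring[:-1, 1]
        shoelace = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
        assert agg.hull_area_mm2 == pytest.approx(shoelace * 1e-6, rel=1e-12)

    def test_composition_counts(self):
        markers = line_aggregate_markers(60, n_cd20=40, n_fdc=2)
        agg, _ = self._measured([(5.0 * i, 0.0) for i in range(60)], **markers)
        assert agg.composition["CD20"] == 40
        assert agg.composition["FDC"] == 2
        assert agg.composition["CD4"] >= 1 and agg.composition["CD8"] >= 1


def _line_cells(n, length, n_cd20, n_fdc=0, **kw):
    """n cells evenly spread along a line of exact `length` µm."""
    markers = line_aggregate_markers(n, n_cd20=n_cd20, n_fdc=n_fdc, **kw)
    xs = np.linspace(0.0, length, n)
    cells = make_cell_table(np.column_stack([xs, np.zeros(n)]), markers=markers)
    (agg,) = detect_aggregates(cells, max(length / (n - 1) + 1, 15.0), 1)
    return measure_aggregate(agg, cells)


class TestClassify:
    def test_standard_etls(self):
        agg = _line_cells(120, 300.0, n_cd20=72)  # feret 300, CD20 60%
        call = classify_aggregate(agg)
        assert call.tls_class == "eTLS"
        assert all(call.rule_trace[k] for k in
                   ("min_cells", "min_size", "cd20_majority", "has_cd4", "has_cd8"))

    def test_single_fdc_makes_mature(self):
        agg = _line_cells(120, 300.0, n_cd20=72, n_fdc=1)
        assert classify_aggregate(agg).tls_class == "mTLS"

    def test_50_cells_rejected_51_accepted(self):
        rejected = classify_aggregate(_line_cells(50, 260.0, n_cd20=30))
        assert rejected.tls_class == "not_tls" and not rejected.rule_trace["min_cells"]
        accepted = classify_aggregate(_line_cells(51, 260.0, n_cd20=30))
        assert accepted.tls_class != "not_tls" and accepted.rule_trace["min_cells"]

    def test_feret_boundary_250um(self):
        small = classify_aggregate(_line_cells(60, 249.9, n_cd20=36))
        assert small.tls_class == "not_tls" and not small.rule_trace["min_size"]
        exact = classify_aggregate(_line_cells(60, 250.0, n_cd20=36))
        assert exact.rule_trace["min_size"] and exact.tls_class == "eTLS"

    def test_cd20_majority_is_strict(self):
        half = classify_aggregate(_line_cells(100, 297.0, n_cd20=50))
        assert half.tls_class == "not_tls" and not half.rule_trace["cd20_majority"]
        over = classify_aggregate(_line_cells(100, 297.0, n_cd20=51))
        assert over.rule_trace["cd20_majority"] and over.tls_class == "eTLS"

    def test_missing_cd4_or_cd8_rejects(self):
        no_cd4 = _line_cells(100, 297.0, n_cd20=60, with_cd4=False)
        assert classify_aggregate(no_cd4).tls_class == "not_tls"
        no_cd8 = _line_cells(100, 297.0, n_cd20=60, with_cd8=False)
        assert classify_aggregate(no_cd8).tls_class == "not_tls"

    def test_mtls_implies_all_etls_criteria(self):
        agg = _line_cells(120, 300.0, n_cd20=72, n_fdc=3)
        call = classify_aggregate(agg)
        assert call.tls_class == "mTLS"
        assert all(call.rule_trace[k] for k in
                   ("min_cells", "min_size", "cd20_majority", "has_cd4", "has_cd8"))

    def test_unmeasured_aggregate_rejected(self):
        cells = make_cell_table([(0, 0), (5, 0)])
        (agg,) = detect_aggregates(cells, 15.0, 1)
        with pytest.raises(ValueError, match="measure_aggregate"):
            classify_aggregate(agg)


class TestLocalize:
    def _call_at(self, center, square_regions):
        agg = _line_cells(60, 250.0, n_cd20=36)
        # move the aggregate so its centroid sits at `center`
        dx = center[0] - agg.centroid[0]
        dy = center[1] - agg.centroid[1]
        import dataclasses

        agg = dataclasses.replace(agg, centroid=(agg.centroid[0] + dx, agg.centroid[1] + dy))
        return localize_tls(classify_aggregate(agg), square_regions)

    def test_deep_core(self, square_regions):
        assert self._call_at((1500, 1500), square_regions).localization == "core"

    def test_margin_outside_core(self, square_regions):
        # 100 µm outside the core boundary, band 400 µm
        assert self._call_at((900, 1500), square_regions).localization == "margin"

    def test_stroma_beyond_band(self, square_regions):
        assert self._call_at((200, 200), square_regions).localization == "stroma"

    def test_outside_tissue_warns_unassigned(self, square_regions):
        with pytest.warns(UserWarning, match="outside tissue"):
            call = self._call_at((-500, -500), square_regions)
        assert call.localization == "unassigned"
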