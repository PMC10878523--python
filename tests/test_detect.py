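"""The fire rule, spatial grouping, area filter, perimeter refinement."""

import numpy as np
import pytest

from firehist.breaks import PixelSeries, TrendBreak
from firehist.detect import (FireEvent, detect_fires, filter_min_area,
                             group_to_polygons, match_break_with_dnbr,
                             refine_perimeter)
from firehist.raster import GeoRef, RasterGrid

GEO = GeoRef(0, 3000, 30)


def make_break(month=100, magnitude=-0.4, ci=None):
    return TrendBreak(month=month, magnitude=magnitude,
                      ci=ci or (month, month), obs_index=month - 1,
                      rss=0.0, n_segments=2)


def dnbr_series(months, values, loc=(0, 0)):
    return PixelSeries(np.asarray(months), np.asarray(values, float),
                       index_name="dNBR", location=loc)


class TestFireRule:
    def test_negative_break_with_spike_is_candidate(self):
        brk = make_break(ci=(99, 101))
        s = dnbr_series([98, 99, 100, 101], [0.0, 0.05, 0.35, 0.1])
        cand = match_break_with_dnbr(brk, s, threshold=0.2)
        assert cand is not None
        assert cand.fire_month == 100
        assert cand.max_dnbr == pytest.approx(0.35)

    def test_below_threshold_is_none(self):
        brk = make_break(ci=(99, 101))
        s = dnbr_series([99, 100, 101], [0.05, 0.15, 0.1])
        assert match_break_with_dnbr(brk, s, threshold=0.2) is None

    def test_positive_break_is_gated_out(self):
        brk = make_break(magnitude=0.4)
        s = dnbr_series([100], [0.5])
        assert match_break_with_dnbr(brk, s) is None

    def test_tie_takes_earliest_month(self):
        brk = make_break(ci=(99, 101))
        s = dnbr_series([99, 100, 101], [0.3, 0.3, 0.3])
        assert match_break_with_dnbr(brk, s).fire_month == 99

    def test_ci_outside_series_span_raises(self):
        brk = make_break(month=10, ci=(9, 11))
        s = dnbr_series([100, 101], [0.5, 0.5])
        with pytest.raises(ValueError):
            match_break_with_dnbr(brk, s)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        months = np.arange(50)
        counts = []
        for thr in (0.2, 0.3, 0.4, 0.5):
            n = 0
            for s in range(50):
                vals = rng.normal(0.2, 0.15, 50)
                brk = make_break(month=25, ci=(20, 30))
                if match_break_with_dnbr(
                        brk, dnbr_series(months, vals), threshold=thr):
                    n += 1
            counts.append(n)
            rng = np.random.default_rng(0)  # same draws per threshold
        assert counts == sorted(counts, reverse=True)


class TestGrouping:
    def _cands(self, pixels, month=100):
        out = []
        for p in pixels:
            brk = make_break(month=month, ci=(month, month))
            s = dnbr_series([month], [0.5], loc=p)
            out.append(match_break_with_dnbr(brk, s))
        return out

    def test_edge_sharing_pixels_one_component(self):
        evs = group_to_polygons(self._cands([(5, 5), (5, 6)]), (10, 10), GEO)
        assert len(evs) == 1 and evs[0].n_pixels == 2

    def test_diagonal_pixels_two_components_rook(self):
        evs = group_to_polygons(self._cands([(5, 5), (6, 6)]), (10, 10), GEO,
                                connectivity=1)
        assert len(evs) == 2

    def test_diagonal_pixels_one_component_queen(self):
        evs = group_to_polygons(self._cands([(5, 5), (6, 6)]), (10, 10), GEO,
                                connectivity=2)
        assert len(evs) == 1

    def test_different_months_never_grouped(self):
        cands = self._cands([(5, 5)], month=100) + self._cands([(5, 6)], month=101)
        evs = group_to_polygons(cands, (10, 10), GEO)
        assert len(evs) == 2

    def test_polygon_area_matches_pixel_set(self):
        evs = group_to_polygons(self._cands([(5, 5), (5, 6), (6, 5)]),
                                (10, 10), GEO)
        assert evs[0].polygon.area == pytest.approx(3 * 900.0)


class TestMinAreaFilter:
    @pytest.mark.parametrize("n_px,kept", [(56, True), (55, False)])
    def test_minimum_mapping_unit_boundary(self, n_px, kept):
        mask = np.zeros((60, 60), dtype=bool)
        mask[0, :n_px] = True
        ev = FireEvent(event_id=0, month=100, pixel_mask=mask, georef=GEO)
        out = filter_min_area([ev], min_area_ha=5.0)
        assert (len(out) == 1) is kept

    def test_zero_minimum_is_identity(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0, 0] = True
        ev = FireEvent(event_id=0, month=1, pixel_mask=mask, georef=GEO)
        assert filter_min_area([ev], min_area_ha=0.0) == [ev]


class TestRefinement:
    def _event_and_grids(self, drop=0.35, noise=0.0, seed=0, speckle=0.0):
        rng = np.random.default_rng(seed)
        H = W = 50
        truth = np.zeros((H, W), dtype=bool)
        truth[15:35, 15:35] = True
        pre = np.full((H, W), 0.7) + rng.normal(0, noise, (H, W))
        post = np.full((H, W), 0.7) + rng.normal(0, noise, (H, W))
        post[truth] -= drop
        cand = truth.copy()
        if speckle > 0:
            # corrupt the candidate boundary
            edge = truth & ~np.roll(truth, 2, axis=0)
            flip = rng.random((H, W)) < speckle
            cand[edge & flip] = False
        ev = FireEvent(event_id=0, month=100, pixel_mask=cand, georef=GEO)
        return ev, truth, RasterGrid(pre, band="NDVI"), RasterGrid(post, band="NDVI")

    def test_noiseless_event_pixel_set_unchanged(self):
        ev, truth, pre, post = self._event_and_grids()
        out = refine_perimeter(ev, pre, post)
        assert out is not None
        assert np.array_equal(out.pixel_mask, truth)

    def test_uniform_dndvi_artifact_dropped(self):
        ev, truth, pre, post = self._event_and_grids(drop=0.0)
        assert refine_perimeter(ev, pre, post) is None

    def test_noisy_speckled_boundary_f1(self):
        scores = []
        for s in range(5):
            ev, truth, pre, post = self._event_and_grids(
                noise=0.03, seed=s, speckle=0.5)
            out = refine_perimeter(ev, pre, post, seed=s)
            assert out is not None
            tp = (out.pixel_mask & truth).sum()
            f1 = 2 * tp / (out.pixel_mask.sum() + truth.sum())
            scores.append(f1)
        assert np.mean(scores) >= 0.9

    def test_provenance_flags_added_pixels(self):
        from firehist.detect import PROV_REFINED, PROV_RULE
        ev, truth, pre, post = self._event_and_grids(noise=0.02, speckle=0.8,
                                                     seed=3)
        out = refine_perimeter(ev, pre, post)
        assert set(np.unique(out.provenance[out.pixel_mask])) <= {PROV_RULE,
                                                                  PROV_REFINED}
        added = out.pixel_mask & ~ev.pixel_mask
        if added.any():
            assert np.all(out.provenance[added] == PROV_REFINED)


class TestEndToEnd:
    def test_benchmark_detection_matches_truth(self, benchmark_ctx):
        ev = benchmark_ctx["evaluation"]
        assert ev["precision"] >= 0.9
        assert ev["recall"] >= 0.9
        assert all(abs(e) <= 1 for e in ev["month_errors"])

    def test_every_pixel_has_provenance(self, benchmark_ctx):
        for e in benchmark_ctx["events"]:
            assert np.all(e.provenance[e.pixel_mask] > 0)
            assert np.all(e.provenance[~e.pixel_mask] == 0)

    def test_event_invariants(self, benchmark_ctx):
        for e in benchmark_ctx["events"]:
            assert e.area_ha == pytest.approx(e.n_pixels * 0.09)
            assert e.area_ha >= 5.0 or np.any(e.provenance == 2)
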