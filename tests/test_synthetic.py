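"""Generator contracts: landscape, archive, fires, footprints, truth."""

import numpy as np
import pandas as pd
import pytest

from firehist.raster import ym_to_index
from firehist.synthetic import (FireSpec, SceneConfig, generate_landscape,
                                simulate_archive, simulate_footprints)
from conftest import small_scene_config


class TestLandscape:
    def test_degenerate_fraction_all_forest(self):
        cfg = small_scene_config(forest_fraction=1.0)
        land, _ = generate_landscape(cfg)
        assert np.all(land == 1)

    def test_same_seed_identical_maps(self):
        cfg = small_scene_config()
        a = generate_landscape(cfg)
        b = generate_landscape(cfg)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_forest_share_matches_requested_fraction(self):
        cfg = SceneConfig(rows=100, cols=100, forest_fraction=0.7, seed=3)
        land, _ = generate_landscape(cfg)
        assert abs((land == 1).mean() - 0.7) <= 0.05 * 0.7

    def test_forest_is_patchy_not_salt_and_pepper(self):
        from scipy import ndimage
        cfg = small_scene_config(forest_fraction=0.5)
        land, _ = generate_landscape(cfg)
        _, n = ndimage.label(land == 1)
        assert n < 20  # a few contiguous patches, not thousands of specks

    def test_all_five_zones_present(self):
        cfg = small_scene_config()
        _, zones = generate_landscape(cfg)
        assert set(np.unique(zones)) == set(range(5))

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            generate_landscape(small_scene_config(rows=0))

    def test_fire_outside_dry_season_rejected(self):
        with pytest.raises(ValueError):
            small_scene_config(fires=(FireSpec(2015, 2, 10.0),)).validate()

    def test_fire_outside_time_span_rejected(self):
        with pytest.raises(ValueError):
            small_scene_config(fires=(FireSpec(1990, 9, 10.0),)).validate()


class TestArchive:
    def test_no_fire_null_has_empty_catalog_and_no_steps(self):
        cfg = small_scene_config(fires=(), noise_sd=0.0, missing_prob=0.0)
        bands, truth = simulate_archive(cfg)
        assert truth.fires == []
        # NDVI of every pixel repeats with a 12-month period: no steps
        red, nir = bands["red"].values, bands["nir"].values
        ndvi = (nir - red) / (nir + red)
        assert np.allclose(ndvi[:12], ndvi[12:24], atol=1e-6)

    def test_noiseless_dnbr_equals_configured_magnitude(self, small_scene):
        cfg, bands, truth = small_scene
        f = truth.fires[0]
        t = f.month_index
        nir, sw = bands["nir"].values, bands["swir2"].values
        nbr = (nir - sw) / (nir + sw)
        d = nbr[t - 1] - nbr[t]
        assert np.allclose(d[f.mask], cfg.dnbr_first, atol=1e-5)

    def test_area_bookkeeping_50ha(self):
        cfg = small_scene_config(fires=(FireSpec(2019, 10, 50.0),))
        _, truth = simulate_archive(cfg)
        n_px = truth.fires[0].mask.sum()
        assert abs(n_px * 0.09 - 50.0) <= 0.09  # one pixel rounding
        assert truth.fires[0].area_ha == pytest.approx(n_px * 0.09)

    def test_fire_larger_than_forest_rejected(self):
        cfg = small_scene_config(forest_fraction=0.05,
                                 fires=(FireSpec(2019, 10, 300.0),))
        with pytest.raises(ValueError):
            simulate_archive(cfg)

    def test_bitwise_reproducibility(self):
        cfg = small_scene_config()
        a, _ = simulate_archive(cfg)
        b, _ = simulate_archive(cfg)
        for band in a:
            assert np.array_equal(a[band].values, b[band].values,
                                  equal_nan=True)

    def test_postfire_ndvi_never_recovers_past_half_drop(self, small_scene):
        # zero recovery: after its first burn every pixel's mean NDVI stays
        # at least half the configured drop below its pre-fire mean
        cfg, bands, truth = small_scene
        red, nir = bands["red"].values, bands["nir"].values
        ndvi = (nir - red) / (nir + red)
        first = truth.burn_months[0]
        rows, cols = np.nonzero(first >= 0)
        for r, c in zip(rows[::7], cols[::7]):
            t0 = first[r, c]
            pre = ndvi[:t0, r, c].mean()
            post = ndvi[t0:, r, c].mean()
            assert post <= pre - 0.5 * cfg.ndvi_drop_first

    def test_truth_counts_equal_catalog_membership(self, small_scene):
        _, _, truth = small_scene
        counts = np.zeros_like(truth.burn_counts)
        for f in truth.fires:
            counts += f.mask
        assert np.array_equal(counts, truth.burn_counts)

    def test_missing_mask_rate_close_to_requested(self):
        cfg = small_scene_config(missing_prob=0.2)
        bands, _ = simulate_archive(cfg)
        rate = bands["nir"].mask.mean()
        assert abs(rate - 0.2) < 0.01


class TestFootprints:
    def test_null_model_identical_forest_metrics(self):
        cfg = small_scene_config(
            noise_sd=0.0, missing_prob=0.0, fires=(),
            fp_coef_nfires={"pai": 0.0, "cc": 0.0, "ch": 0.0},
            fp_coef_months={"pai": 0.0, "cc": 0.0, "ch": 0.0},
            fp_noise_sd={"pai": 0.0, "cc": 0.0, "ch": 0.0},
            fp_zone_sd={"pai": 0.0, "cc": 0.0, "ch": 0.0},
            fp_season_sd={"pai": 0.0, "cc": 0.0, "ch": 0.0})
        _, truth = simulate_archive(cfg)
        fp = simulate_footprints(cfg, truth)
        forest = fp[fp.cover == "forest"]
        for m in ("pai", "cc", "ch"):
            assert forest[m].nunique() == 1

    def test_degenerate_quality_rate_all_fail(self):
        cfg = small_scene_config(fp_quality_fail_rate=1.0)
        _, truth = simulate_archive(cfg)
        fp = simulate_footprints(cfg, truth)
        assert not fp.quality_ok.any()

    def test_zero_footprints_rejected(self):
        cfg = small_scene_config(n_footprints=0)
        _, truth = simulate_archive(small_scene_config())
        with pytest.raises(ValueError):
            simulate_footprints(cfg, truth)

    def test_group_means_ordered_by_burn_count(self):
        cfg = SceneConfig(seed=5, n_footprints=1500)
        _, truth = simulate_archive(cfg)
        fp = simulate_footprints(cfg, truth)
        means = fp.groupby("n_fires_true")["pai"].mean()
        assert means[0] > means[1] > means[2]

    def test_metric_ranges_respected(self):
        cfg = small_scene_config()
        _, truth = simulate_archive(cfg)
        fp = simulate_footprints(cfg, truth)
        assert fp.cc.between(0, 1).all()
        assert (fp.pai >= 0).all() and (fp.ch >= 0).all()

    def test_covariates_match_truth_at_acquisition(self):
        cfg = small_scene_config()
        _, truth = simulate_archive(cfg)
        fp = simulate_footprints(cfg, truth)
        for row in fp.sample(50, random_state=0).itertuples():
            assert truth.n_fires_at(row.row, row.col, row.month_index) \
                == row.n_fires_true
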