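"""Rank tests, mixed models, covariate attachment, recovery labels."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from firehist.history import NEVER, accumulate_history
from firehist.stats import (dunn_posthoc, filter_and_attach,
                            fit_structure_model, kruskal_wallis,
                            recovery_assessment)


def brute_force_kw(groups):
    """Independent H computation straight from ranks, for small tables."""
    values = np.concatenate(groups)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    # average ranks for ties, computed naively
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j < len(values) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = np.mean(np.arange(i + 1, j + 1))
        i = j
    n = len(values)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    ties = np.sum(counts**3 - counts)
    if ties:
        h /= 1 - ties / (n**3 - n)
    return h


class TestKruskalWallis:
    def test_hand_computed_example(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)
        assert 0 < p < 0.05

    def test_label_permutation_symmetry(self):
        groups = [[1.0, 5.0, 3.2], [2.2, 8.8], [0.5, 4.4, 9.1]]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis(groups[::-1])
        assert h1 == pytest.approx(h2)

    def test_matches_brute_force_on_random_small_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            k = int(rng.integers(2, 5))
            sizes = rng.integers(3, 50 // k + 1, size=k)
            groups = [np.round(rng.normal(0, 1, s), 1) for s in sizes]
            h, _ = kruskal_wallis(groups)
            assert h == pytest.approx(brute_force_kw(groups), rel=1e-10)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(i * 0.3, 1, 20) for i in range(3)]
        h, p = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert h == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(2)
        rejections = 0
        reps = 400
        for _ in range(reps):
            a = rng.normal(0, 1, 30)
            b = rng.normal(0, 1, 30)
            _, p = kruskal_wallis([a, b])
            rejections += p < 0.05
        assert abs(rejections / reps - 0.05) <= 0.03

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestDunn:
    def test_two_groups_bonferroni_factor_one(self):
        d = dunn_posthoc([[1, 2, 3, 7], [4, 5, 6, 8]])
        assert len(d) == 1
        assert d.p_adj.iloc[0] == pytest.approx(d.p.iloc[0])

    def test_four_groups_factor_six(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(i, 0.1, 10) for i in range(4)]
        d = dunn_posthoc(groups)
        assert len(d) == 6
        unadj = d.p.to_numpy()
        assert np.allclose(d.p_adj, np.minimum(1.0, unadj * 6))

    def test_well_separated_groups_all_significant(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(mu, 0.2, 25) for mu in (0.0, 3.0, 6.0)]
        d = dunn_posthoc(groups)
        assert (d.p_adj < 0.05).all()

    def test_two_group_z_consistent_with_h(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 18), rng.normal(0.8, 1, 14)
        h, _ = kruskal_wallis([a, b])
        z = dunn_posthoc([a, b]).z.iloc[0]
        assert z**2 == pytest.approx(h, rel=1e-9)


class TestMixedModel:
    def _table(self, n=800, coef_nf=-0.2, coef_m=0.0, noise=0.0, seed=0,
               zone_sd=0.0, season_sd=0.0):
        rng = np.random.default_rng(seed)
        nf = rng.integers(1, 4, n)
        months = rng.integers(0, 60, n)
        zone = rng.choice(["service", "buffer", "community"], n)
        season = rng.choice(["dry", "wet"], n)
        zoff = dict(zip(["service", "buffer", "community"],
                        rng.normal(0, zone_sd, 3)))
        soff = dict(zip(["dry", "wet"], rng.normal(0, season_sd, 2)))
        y = (3.0 + coef_nf * nf + coef_m * months
             + np.array([zoff[z] for z in zone])
             + np.array([soff[s] for s in season])
             + rng.normal(0, noise, n))
        return pd.DataFrame({"pai": y, "n_fires": nf, "months_since": months,
                             "zone": zone, "season": season})

    def test_noiseless_recovery_exact(self):
        res = fit_structure_model(self._table(), "pai")
        assert res.coef("n_fires") == pytest.approx(-0.2, abs=1e-6)
        assert res.coef("n_months") == pytest.approx(0.0, abs=1e-8)
        res.validate()

    def test_zone_label_renaming_invariance(self):
        t = self._table(noise=0.3, zone_sd=0.2, season_sd=0.1, seed=2)
        r1 = fit_structure_model(t, "pai")
        t2 = t.replace({"zone": {"service": "Z1", "buffer": "Z2",
                                 "community": "Z3"}})
        r2 = fit_structure_model(t2, "pai")
        assert r1.coef("n_fires") == pytest.approx(r2.coef("n_fires"), rel=1e-6)

    def test_large_zone_variance_dominates_season(self):
        wins = 0
        for s in range(10):
            t = self._table(noise=0.2, zone_sd=1.0, season_sd=0.02, seed=10 + s)
            res = fit_structure_model(t, "pai")
            if res.variance_components["zone"] > res.variance_components["season"]:
                wins += 1
        assert wins >= 9

    def test_singular_fit_reported_not_hidden(self):
        # a degenerate (noise-free) response drives the variance components
        # to the boundary; the result must say so rather than hide it
        res = fit_structure_model(self._table(noise=0.0, seed=3), "pai")
        assert res.singular
        assert "singular" in res.notes

    def test_single_level_grouping_rejected(self):
        t = self._table(noise=0.1)
        t["season"] = "dry"
        with pytest.raises(ValueError):
            fit_structure_model(t, "pai")


class TestFilterAndAttach:
    def _setup(self):
        from firehist.detect import FireEvent
        from firehist.raster import GeoRef
        shape = (10, 10)
        forest = np.ones(shape, dtype=bool)
        mask = np.zeros(shape, dtype=bool)
        mask[2:5, 2:5] = True
        ev = FireEvent(event_id=0, month=100, pixel_mask=mask,
                       georef=GeoRef(0, 300, 30))
        hist = accumulate_history([ev], forest)
        fp = pd.DataFrame({
            "row": [3, 3, 0, 3], "col": [3, 3, 0, 3],
            "month_index": [90, 110, 110, 110],
            "month": [7, 3, 3, 3],
            "quality_ok": [True, True, True, False],
            "zone": ["buffer", "buffer", "peripheral", "buffer"],
            "pai": [3.0, 2.0, 3.1, 2.5], "cc": [0.8, 0.6, 0.8, 0.7],
            "ch": [18, 15, 18, 16],
        })
        return fp, hist, forest

    def test_temporal_causality(self):
        fp, hist, forest = self._setup()
        out = filter_and_attach(fp, hist, forest)
        before = out[out.month_index == 90]
        assert (before.n_fires == 0).all()
        after = out[out.month_index == 110]
        assert (after.n_fires == 1).all()
        assert (after.months_since == 10).all()

    def test_quality_and_peripheral_exclusion(self):
        fp, hist, forest = self._setup()
        out = filter_and_attach(fp, hist, forest)
        assert len(out) == 2  # peripheral row and failing-quality row dropped
        assert not (out.zone == "peripheral").any()

    def test_footprint_outside_grid_rejected(self):
        fp, hist, forest = self._setup()
        fp.loc[0, "row"] = 99
        with pytest.raises(ValueError):
            filter_and_attach(fp, hist, forest)

    def test_benchmark_attachment_matches_generator_truth(self, benchmark_ctx):
        table = benchmark_ctx["analysis_table"]
        agree = (table.n_fires == table.n_fires_true).mean()
        assert agree >= 0.95


class TestRecovery:
    def test_strong_positive_slope_labelled_recovering(self):
        rng = np.random.default_rng(6)
        n = 600
        nf = rng.integers(1, 4, n)
        months = rng.integers(0, 60, n)
        base = {"pai": 3.0, "cc": 0.7, "ch": 15.0}
        t = pd.DataFrame({"n_fires": nf, "months_since": months,
                          "zone": rng.choice(["a", "b"], n),
                          "season": rng.choice(["dry", "wet"], n)})
        for m in ("pai", "cc", "ch"):
            t[m] = base[m] - 0.05 * nf + 0.01 * months + rng.normal(0, 0.05, n)
        rep = recovery_assessment(t)
        assert (rep.n_months_effect == "recovering").all()

    def test_all_zero_effects_mostly_flat(self):
        rng = np.random.default_rng(7)
        flats = 0
        for s in range(10):
            n = 400
            t = pd.DataFrame({
                "n_fires": rng.integers(1, 4, n),
                "months_since": rng.integers(0, 60, n),
                "zone": rng.choice(["a", "b"], n),
                "season": rng.choice(["dry", "wet"], n),
                "pai": rng.normal(3, 0.3, n)})
            rep = recovery_assessment(t, responses=("pai",))
            flats += (rep.n_months_effect == "flat").all()
        assert flats >= 8

    def test_benchmark_reproduces_study_pattern(self, benchmark_ctx):
        rep = benchmark_ctx["recovery"].set_index("response")
        assert (rep.n_fires_effect.loc[["pai", "cc", "ch"]] == "declining").all()
        assert rep.n_months_effect.loc["pai"] == "flat"
        assert rep.n_months_effect.loc["cc"] == "flat"
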