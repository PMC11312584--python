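"""Screen-stage inference: normalization, concordance, inert circle,
classification and hit calling."""

import numpy as np
import pandas as pd
import pytest

import luxscreen as lx
from luxscreen.screen import CLASSES, classify_strains

SEED = 0


def make_points(rows):
    """Points frame from (strain, ff_fold, ren_fold, q_ff, q_ren) tuples."""
    recs = {}
    for strain, ff, ren, q_ff, q_ren in rows:
        recs[strain] = {
            "ff_fold": ff,
            "ren_fold": ren,
            "distance": float(np.hypot(ff - 1, ren - 1)),
            "p_ff": q_ff,
            "p_ren": q_ren,
            "q_ff": q_ff,
            "q_ren": q_ren,
        }
    return pd.DataFrame.from_dict(recs, orient="index")


class TestNormalization:
    def test_zero_noise_folds_are_exact(self, small_manifest):
        cfg = lx.SimConfig.screen(seed=1, cv_total=0.0)
        t = lx.simulate_screen(small_manifest, [lx.EffectSpec("G1", 2.7, 1.0)], cfg)
        points, excluded = lx.summarize_and_normalize(t, "WT")
        assert excluded == []
        assert points.loc["G1", "ff_fold"] == pytest.approx(2.7)
        assert points.loc["G1", "ren_fold"] == pytest.approx(1.0)
        assert points.loc["G2", "ff_fold"] == pytest.approx(1.0)

    def test_distance_hand_example(self):
        # folds (1.6, 1.8): sqrt(0.36 + 0.64) = 1.0
        pts = make_points([("S", 1.6, 1.8, 0.5, 0.5)])
        assert pts.loc["S", "distance"] == pytest.approx(1.0)

    def test_missing_wildtype_rejected(self, small_manifest):
        t = lx.simulate_screen(small_manifest, [], lx.SimConfig.screen(seed=2))
        sub = lx.ReadoutTable(df=t.df[t.df["group_id"] != "WT"].reset_index(drop=True))
        with pytest.raises(ValueError, match="WT"):
            lx.summarize_and_normalize(sub, "WT")


class TestPearson:
    def test_identical_vectors(self):
        pts = make_points([(f"S{i}", f, f, 0.5, 0.5) for i, f in enumerate([1, 2, 3])])
        assert lx.pearson_across_strains(pts) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        folds = [(1, 1), (2, 2), (3, 4)]
        pts = make_points([(f"S{i}", x, y, 0.5, 0.5) for i, (x, y) in enumerate(folds)])
        assert lx.pearson_across_strains(pts) == pytest.approx(0.982, abs=1e-3)

    def test_anticorrelated_vectors(self):
        pts = make_points(
            [(f"S{i}", x, -x + 4, 0.5, 0.5) for i, x in enumerate([1, 2, 3])]
        )
        assert lx.pearson_across_strains(pts) == pytest.approx(-1.0)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(SEED)
        x, y = rng.lognormal(size=20), rng.lognormal(size=20)
        fwd = make_points([(f"S{i}", a, b, 0.5, 0.5) for i, (a, b) in enumerate(zip(x, y))])
        rev = make_points([(f"S{i}", b, a, 0.5, 0.5) for i, (a, b) in enumerate(zip(x, y))])
        r = lx.pearson_across_strains(fwd)
        assert r == pytest.approx(lx.pearson_across_strains(rev))
        assert -1.0 <= r <= 1.0

    def test_degenerate_folds_reported_undefined(self):
        pts = make_points([(f"S{i}", 1.0, y, 0.5, 0.5) for i, y in enumerate([1, 2, 3])])
        assert np.isnan(lx.pearson_across_strains(pts))


class TestInertRadius:
    def test_constant_measurements_give_zero(self):
        assert lx.inert_radius([5.0, 5.0, 5.0, 5.0]) == 0.0

    def test_cv_024_gives_048(self):
        rng = np.random.default_rng(SEED)
        sigma = np.sqrt(np.log1p(0.24**2))
        vals = 1e4 * rng.lognormal(-(sigma**2) / 2, sigma, size=10_000)
        assert lx.inert_radius(vals) == pytest.approx(0.48, abs=0.02)

    def test_scale_invariance(self):
        rng = np.random.default_rng(SEED)
        vals = rng.lognormal(0, 0.2, size=50)
        assert lx.inert_radius(2 * vals) == pytest.approx(lx.inert_radius(vals))

    def test_too_few_measurements_rejected(self):
        with pytest.raises(ValueError):
            lx.inert_radius([1.0, 2.0])


class TestClassifyStrains:
    def test_planted_selective_hit_geometry(self):
        pts = make_points([("HIT", 2.7, 1.0, 1e-6, 0.8)])
        classes = classify_strains(pts, radius=0.48, wt_ren_band=0.48)
        assert classes["HIT"] == "selective_hit"

    def test_wildtype_like_point_is_inert(self):
        pts = make_points([("S", 1.0, 1.0, 0.9, 0.9)])
        assert classify_strains(pts, 0.48, 0.48)["S"] == "inert"

    def test_both_down_quadrant(self):
        pts = make_points([("S", 0.4, 0.45, 1e-6, 1e-6)])
        assert classify_strains(pts, 0.48, 0.48)["S"] == "q4_both_down"

    def test_both_up_is_not_selective(self):
        """A strain shifting both reporters equally is never a hit."""
        pts = make_points([("S", 2.7, 2.7, 1e-6, 1e-6)])
        assert classify_strains(pts, 0.48, 0.48)["S"] == "q2_both_up"

    def test_ren_only_quadrant(self):
        pts = make_points([("S", 0.9, 1.8, 0.5, 1e-6)])
        assert classify_strains(pts, 0.48, 0.48)["S"] == "q1_ren_up"

    def test_ff_up_but_insignificant_is_quadrant_not_hit(self):
        pts = make_points([("S", 2.0, 1.0, 0.4, 0.8)])
        assert classify_strains(pts, 0.48, 0.48)["S"] == "q3_ff_up"

    def test_totality_and_exclusivity(self, full_manifest, screen_table):
        res = lx.run_screen(screen_table, full_manifest)
        assert set(res.classes.index) == set(res.points.index)
        assert res.classes.isin(CLASSES).all()
        inert = (res.classes == "inert").sum()
        outside = (res.classes != "inert").sum()
        assert inert + outside == len(res.points)


class TestRunScreen:
    def test_planted_strain_is_sole_hit(self, full_manifest, screen_table):
        res = lx.run_screen(screen_table, full_manifest)
        assert res.hits == ["RPL40A"]
        assert res.classes["RPL40A"] == "selective_hit"

    def test_wildtype_excluded_from_points(self, full_manifest, screen_table):
        res = lx.run_screen(screen_table, full_manifest)
        assert "WT" not in res.points.index
        assert len(res.points) == 128

    def test_radius_near_calibration(self, full_manifest, screen_table):
        res = lx.run_screen(screen_table, full_manifest)
        assert 0.35 < res.radius < 0.6

    def test_equal_shift_strain_not_hit(self, full_manifest):
        t = lx.simulate_screen(
            full_manifest,
            [lx.EffectSpec("RPL40A", 2.7, 2.7)],
            lx.SimConfig.screen(seed=SEED),
        )
        res = lx.run_screen(t, full_manifest)
        assert res.classes["RPL40A"] == "q2_both_up"
        assert "RPL40A" not in res.hits

    def test_null_screens_rarely_call_hits(self, full_manifest):
        """Under the null the hit list is empty in at least 95% of seeds."""
        empty = 0
        n_runs = 60
        for s in range(n_runs):
            t = lx.simulate_screen(full_manifest, [], lx.SimConfig.screen(seed=s))
            empty += len(lx.run_screen(t, full_manifest).hits) == 0
        assert empty / n_runs >= 0.95

    def test_radius_override(self, full_manifest, screen_table):
        cfg = lx.ScreenConfig(radius_override=0.5, ren_band_override=0.5)
        res = lx.run_screen(screen_table, full_manifest, cfg)
        assert res.radius == 0.5
        assert res.ren_band == 0.5

    def test_summary_is_json_shaped(self, full_manifest, screen_table):
        summary = lx.run_screen(screen_table, full_manifest).summary()
        assert summary["n_strains"] == 128
        assert set(summary["class_counts"]) == set(CLASSES)
        assert summary["hits"] == ["RPL40A"]
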