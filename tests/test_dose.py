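"""Compound-stage analysis: control normalization, dose trend, triage."""

import numpy as np
import pandas as pd
import pytest

import luxscreen as lx
from luxscreen.dose import EFFECT_COLUMNS, DoseResponseResult, PanelConfig
from conftest import paper_panel_specs

SEED = 0


def make_effects(doses, ff_folds, ren_folds, p_ff=None, p_ren=None):
    n = len(doses)
    df = pd.DataFrame(
        {
            "ff_fold": ff_folds,
            "ren_fold": ren_folds,
            "p_ff": p_ff if p_ff is not None else [0.5] * n,
            "p_ren": p_ren if p_ren is not None else [0.5] * n,
            "n_used_ff": [3] * n,
            "n_used_ren": [3] * n,
        },
        index=pd.Index(doses, name="dose"),
    )
    return df.loc[:, EFFECT_COLUMNS]


class TestNormalizeToControl:
    def test_zero_noise_null_folds_are_one(self):
        cfg = lx.SimConfig.dual_glo(seed=1, cv_total=0.0)
        t = lx.simulate_dose_panel([lx.EffectSpec("C1")], cfg)
        eff = lx.normalize_to_control(t, "C1")
        assert (eff["ff_fold"] == 1.0).all()
        assert (eff["ren_fold"] == 1.0).all()

    def test_zero_noise_top_dose_fold(self):
        cfg = lx.SimConfig.dual_glo(seed=1, cv_total=0.0)
        t = lx.simulate_dose_panel([lx.EffectSpec("C17", 1.7, 1.0)], cfg)
        eff = lx.normalize_to_control(t, "C17")
        assert eff["ff_fold"].iloc[-1] == pytest.approx(1.7)
        assert eff.index[-1] == pytest.approx(1e-4)

    def test_doses_ascending(self, panel_table):
        eff = lx.normalize_to_control(panel_table, "C17")
        assert (np.diff(eff.index.to_numpy()) > 0).all()

    def test_missing_control_rejected(self):
        cfg = lx.SimConfig.dual_glo(seed=1)
        t = lx.simulate_dose_panel([lx.EffectSpec("C1")], cfg)
        sub = lx.ReadoutTable(
            df=t.df[t.df["group_id"] != "control"].reset_index(drop=True),
            assay_variant="dual_glo_compound",
        )
        with pytest.raises(ValueError, match="control.*FF"):
            lx.normalize_to_control(sub, "C1")

    def test_unknown_compound_rejected(self, panel_table):
        with pytest.raises(ValueError, match="C99"):
            lx.normalize_to_control(panel_table, "C99")


class TestTrendTest:
    def test_flat_folds_give_no_trend(self):
        eff = make_effects(list(lx.DEFAULT_DOSES), [1.0] * 6, [1.0] * 6)
        assert lx.trend_test(eff, "FF") >= 0.5

    def test_increasing_folds_detected(self):
        folds = [1.0, 1.01, 1.05, 1.1, 1.35, 1.7]
        eff = make_effects(list(lx.DEFAULT_DOSES), folds, [1.0] * 6)
        assert lx.trend_test(eff, "FF") < 0.05

    def test_decreasing_folds_one_sided(self):
        folds = [1.7, 1.35, 1.1, 1.05, 1.01, 1.0]
        eff = make_effects(list(lx.DEFAULT_DOSES), folds, [1.0] * 6)
        assert lx.trend_test(eff, "FF") > 0.5

    def test_too_few_doses_rejected(self):
        eff = make_effects([1e-9, 1e-8], [1.0, 1.2], [1.0, 1.0])
        with pytest.raises(ValueError, match="3 doses"):
            lx.trend_test(eff, "FF")

    def test_trend_power_at_printed_effect(self):
        """A planted 1.7x top-dose effect is detected (p < 0.05) in well
        over 90% of panels at the assay's noise level."""
        detected = 0
        n_runs = 100
        for s in range(n_runs):
            t = lx.simulate_dose_panel(
                [lx.EffectSpec("C17", 1.7, 1.0)], lx.SimConfig.dual_glo(seed=s)
            )
            r = lx.run_compound_panel(t)
            detected += r.results[0].trend_p_ff < 0.05
        assert detected / n_runs > 0.9


class TestClassifyCompound:
    def c17_like(self, trend_q=1e-4, top_p_ff=0.01, p_ren=0.6):
        eff = make_effects(
            list(lx.DEFAULT_DOSES),
            [1.0, 1.0, 1.01, 1.05, 1.2, 1.7],
            [1.0] * 6,
            p_ff=[0.6, 0.6, 0.5, 0.4, 0.2, top_p_ff],
            p_ren=[p_ren] * 6,
        )
        return DoseResponseResult(
            "C17", eff, trend_p_ff=trend_q, trend_p_ren=0.5, trend_q_ff=trend_q
        )

    def test_selective_hit(self):
        assert lx.classify_compound(self.c17_like()) == "selective_hit"

    def test_inactive_when_flat(self):
        eff = make_effects(list(lx.DEFAULT_DOSES), [1.0] * 6, [1.0] * 6)
        r = DoseResponseResult("C22", eff, trend_p_ff=0.7, trend_p_ren=0.5, trend_q_ff=0.9)
        assert lx.classify_compound(r) == "inactive"

    def test_minor_when_both_reporters_shift(self):
        eff = make_effects(
            list(lx.DEFAULT_DOSES),
            [1.0, 1.0, 1.1, 1.3, 1.6, 2.0],
            [1.0, 1.0, 1.1, 1.3, 1.6, 2.0],
            p_ff=[0.5, 0.5, 0.4, 0.2, 0.05, 0.001],
            p_ren=[0.5, 0.5, 0.4, 0.2, 0.04, 0.002],
        )
        r = DoseResponseResult("C07", eff, trend_p_ff=1e-5, trend_p_ren=1e-5, trend_q_ff=1e-4)
        assert lx.classify_compound(r) == "minor_active"

    def test_no_trend_means_inactive(self):
        r = self.c17_like(trend_q=0.4)
        assert lx.classify_compound(r) == "inactive"

    def test_deterministic_in_alpha(self):
        r = self.c17_like(top_p_ff=0.03)
        assert lx.classify_compound(r, alpha=0.05) == "selective_hit"
        assert lx.classify_compound(r, alpha=0.01) == "minor_active"


class TestRunCompoundPanel:
    def test_empty_panel(self):
        cfg = lx.SimConfig.dual_glo(seed=1)
        t = lx.simulate_dose_panel([lx.EffectSpec("C1")], cfg)
        sub = lx.ReadoutTable(
            df=t.df[t.df["group_id"] == "control"].reset_index(drop=True),
            assay_variant="dual_glo_compound",
        )
        res = lx.run_compound_panel(sub)
        assert res.results == []
        assert res.actives() == []

    def test_planted_composition_seeded_run(self, panel_table):
        res = lx.run_compound_panel(panel_table)
        assert len(res.results) == 29
        actives = set(res.actives())
        assert "C17" in actives
        assert actives <= {"C17", "C07", "C25"}

    def test_classes_exhaustive(self, panel_table):
        res = lx.run_compound_panel(panel_table)
        assert all(r.cls in ("selective_hit", "minor_active", "inactive")
                   for r in res.results)

    def test_all_null_panel_false_actives_alpha_governed(self):
        """BH across compounds keeps false actives near zero on null panels."""
        total = 0
        n_runs = 40
        specs = [lx.EffectSpec(f"C{i + 1:02d}") for i in range(29)]
        for s in range(n_runs):
            t = lx.simulate_dose_panel(specs, lx.SimConfig.dual_glo(seed=1000 + s))
            total += len(lx.run_compound_panel(t).actives())
        assert total / n_runs <= 0.3

    def test_report_shape(self, panel_table):
        rep = lx.run_compound_panel(panel_table).report()
        assert len(rep) == 29 * 6
        assert {"compound_id", "dose", "ff_fold", "class"} <= set(rep.columns)

    def test_seeded_determinism(self):
        specs = paper_panel_specs()
        t1 = lx.simulate_dose_panel(specs, lx.SimConfig.dual_glo(seed=4))
        t2 = lx.simulate_dose_panel(specs, lx.SimConfig.dual_glo(seed=4))
        r1 = lx.run_compound_panel(t1)
        r2 = lx.run_compound_panel(t2)
        assert r1.classes() == r2.classes()
        assert [r.trend_p_ff for r in r1.results] == [r.trend_p_ff for r in r2.results]
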