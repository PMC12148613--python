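"""Scenario runners: protection, crosstalk sweep, combination grids."""

import numpy as np
import pytest

import endosig as es
from endosig.experiments import (percent_change, run_ang1_protection,
                                 run_combination_grid, run_crosstalk_sweep,
                                 ScenarioSpec, sequestration_timecourse)
from endosig.simulate import StimulusProtocol


class TestPercentChange:
    def test_equal_values_give_zero(self):
        assert percent_change(2.0, 2.0) == 0.0

    def test_eighty_percent_drop(self):
        assert percent_change(0.2 * 5.0, 5.0) == pytest.approx(-80.0)

    def test_matches_independent_hand_computation(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a, b = rng.uniform(0.1, 10, 2)
            assert percent_change(a, b) == pytest.approx(100 * (a - b) / b)

    def test_zero_baseline_rejected(self):
        with pytest.raises(es.ModelError):
            percent_change(1.0, 0.0)


class TestScenarioSpec:
    def test_requires_at_least_one_variant(self):
        with pytest.raises(es.ModelError):
            ScenarioSpec(name="s", variants={})

    def test_comparison_requires_named_baseline(self):
        with pytest.raises(es.ModelError):
            ScenarioSpec(name="s",
                         variants={"a": StimulusProtocol(events=[])},
                         comparison="percent_change_vs_baseline",
                         baseline_variant="missing")


class TestProtection:
    def test_reduction_nondecreasing_in_ang1_dose(self, compiled,
                                                  rest_state):
        reductions = []
        for dose in (12.5, 50.0, 200.0):
            rep = run_ang1_protection(compiled, mode="pre_25min",
                                      ang1_dose=dose, x0=rest_state,
                                      t_post=40.0)
            reductions.append(rep.psrc_reduction_percent)
        assert reductions[0] < reductions[1] < reductions[2]

    def test_unknown_mode_rejected(self, compiled, rest_state):
        with pytest.raises(es.ModelError):
            run_ang1_protection(compiled, mode="overnight", x0=rest_state)

    def test_baseline_hash_identical_across_runs(self, compiled, rest_state):
        r1 = run_ang1_protection(compiled, mode="simultaneous",
                                 ang1_dose=50.0, x0=rest_state, t_post=20.0)
        r2 = run_ang1_protection(compiled, mode="simultaneous",
                                 ang1_dose=200.0, x0=rest_state, t_post=20.0)
        assert r1.baseline_hash == r2.baseline_hash

    def test_sequestration_timecourse_reports_t95(self, compiled,
                                                  rest_state):
        times, seq, plateau, t95 = sequestration_timecourse(
            compiled, ang1_dose=50.0, x0=rest_state, t_end=60.0)
        assert 0.0 < plateau <= 1.0
        assert 0.0 <= t95 <= 60.0
        assert np.interp(t95, times, seq) >= 0.95 * plateau - 1e-9


class TestCombinationGrid:
    @pytest.fixture(scope="class")
    def src_grid(self, compiled, rest_state):
        return run_combination_grid(compiled, "Src", levels=(0.0, 0.8),
                                    ang1_doses=(0.0, 500.0), x0=rest_state)

    def test_level_zero_ang1_zero_equals_vegf_baseline(self, compiled,
                                                       rest_state, src_grid):
        from endosig.simulate import StimulusEvent, simulate
        proto = StimulusProtocol(
            events=[StimulusEvent(0.0, "VEGF", 50.0)], t_end=20.0)
        base = simulate(compiled, proto, x0=rest_state)
        ref = float(np.interp(15.0, base.times, base.observable("pSrc")))
        cell = src_grid.query(
            "level == 0 and ang1_dose == 0 and readout == 'pSrc'")
        assert cell["value"].iloc[0] == pytest.approx(ref, rel=1e-6)

    def test_src_inhibition_akt_rescued_by_ang1(self, src_grid):
        akt = src_grid.query("level == 0.8 and readout == 'ppAkt'")
        a0 = akt.query("ang1_dose == 0")["value"].iloc[0]
        a500 = akt.query("ang1_dose == 500")["value"].iloc[0]
        assert a500 > a0

    def test_vegfr2_inhibition_erk_not_rescued_by_ang1(self, compiled,
                                                       rest_state):
        grid = run_combination_grid(compiled, "VEGFR2", levels=(0.0, 0.9),
                                    ang1_doses=(0.0, 500.0), x0=rest_state)
        erk = grid.query("readout == 'pErk'")
        base = erk.query("level == 0 and ang1_dose == 0")["value"].iloc[0]
        inhibited = erk.query("level == 0.9 and ang1_dose == 500")["value"]
        assert inhibited.iloc[0] < 0.6 * base

    def test_unknown_target_rejected(self, compiled, rest_state):
        with pytest.raises(es.ModelError):
            run_combination_grid(compiled, "Raf", x0=rest_state)

    def test_psrc_monotone_in_inhibition_level(self, compiled, rest_state):
        grid = run_combination_grid(compiled, "Src",
                                    levels=(0.0, 0.4, 0.8),
                                    ang1_doses=(0.0,), x0=rest_state)
        psrc = grid.query("readout == 'pSrc'").sort_values("level")
        vals = psrc["value"].to_numpy()
        assert vals[0] > vals[1] > vals[2]


class TestCrosstalkSweep:
    @pytest.fixture(scope="class")
    def sweep(self, compiled, rest_state):
        return run_crosstalk_sweep(compiled,
                                   doses=np.linspace(0, 20, 11),
                                   x0=rest_state)

    def test_anchors_at_zero_dose(self, sweep):
        assert sweep.shedding_fold.values[0] == pytest.approx(1.0, abs=1e-6)
        assert sweep.ptie2_inhibition.values[0] == pytest.approx(0.0,
                                                                 abs=1e-9)
        assert sweep.ang2_release.values[0] == pytest.approx(0.0, abs=1e-9)

    def test_shedding_fold_monotone_with_plateau_near_two(self, sweep):
        vals = sweep.shedding_fold.values
        assert np.all(np.diff(vals) >= -1e-9)
        assert 1.6 <= sweep.shedding_fold.plateau <= 2.4

    def test_summary_reports_saturation_doses(self, sweep):
        s = sweep.summary
        assert np.isfinite(s["shedding_saturation_dose_ng_ml"])
        assert np.isfinite(s["ang2_saturation_dose_ng_ml"])
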