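"""Simulator behaviour: equilibria, events, peaks, dose-response."""

import numpy as np
import pytest

import endosig as es
from endosig.simulate import (SimulationError, apply_dose, dose_response,
                              refined_peak, summarize_peak, vegf_protocol)
from conftest import make_binding_toy


class TestPreEquilibration:
    def test_toy_binding_equilibrium_matches_kd(self):
        # A + B <-> C, Kd = koff/kon = 0.5: C*(Kd) = A*B at equilibrium
        model, params = make_binding_toy(kon=2.0, koff=1.0)
        cm = es.compile_rhs(model, params)
        y = es.pre_equilibrate(cm, tol=1e-10)
        A, B, C = (y[cm.species_index(s)] for s in "ABC")
        assert A * B / C == pytest.approx(0.5, rel=1e-6)

    def test_idempotent_on_its_own_output(self, compiled, rest_state):
        again = es.pre_equilibrate(compiled, x0=rest_state)
        np.testing.assert_allclose(again, rest_state, rtol=1e-9, atol=1e-15)

    def test_constitutive_shedding_at_flux_balance(self, compiled, params,
                                                   rest_state):
        # soluble-Tie2 clearance flux equals total shedding flux at rest
        idx = compiled.species_index
        shed_cols = [j for j, (r, d) in enumerate(compiled.reactions)
                     if d > 0 and (r.name.startswith("tie2_shed")
                                   or r.name.startswith("shed_"))]
        rates = compiled.rates(rest_state)
        shed_flux = rates[shed_cols].sum()
        clear_flux = params["kclrstie2"] * (
            rest_state[idx("sTie2")] + rest_state[idx("sTie2_Ang1")]
            + rest_state[idx("sTie2_Ang2")])
        assert shed_flux == pytest.approx(clear_flux, rel=1e-6)

    def test_nonconvergence_raises_naming_species(self):
        # pure zero-order synthesis never settles
        from endosig.network import (NetworkModel, ParameterSet,
                                     ReactionRule, SpeciesDef)
        model = NetworkModel(
            species=[SpeciesDef("X", "cytosol", {})],
            rules=[ReactionRule("syn", (), ("X",), "mass_action", "k",
                                non_conserving=True)],
            observables={})
        cm = es.compile_rhs(model, ParameterSet({"k": 1.0}))
        with pytest.raises(SimulationError, match="X"):
            es.pre_equilibrate(cm, max_time=20.0, chunk=10.0)


class TestSimulate:
    def test_zero_ligand_baseline_is_flat(self, compiled, rest_state):
        proto = es.StimulusProtocol(events=[], t_end=120.0)
        res = es.simulate(compiled, proto, x0=rest_state)
        for obs in ("pVEGFR2", "pTie2", "pSrc", "ppAkt", "pErk"):
            series = res.observable(obs)
            ref = max(series.max(), 1e-9)
            assert np.ptp(series) <= 1e-3 * ref + 1e-12

    def test_event_leaves_pre_state_and_jumps_ligand(self, compiled,
                                                     rest_state, params):
        proto = es.StimulusProtocol(
            events=[es.StimulusEvent(30.0, "VEGF", 45.0)], t_end=60.0)
        res = es.simulate(compiled, proto, x0=rest_state)
        base = es.simulate(compiled,
                           es.StimulusProtocol(events=[], t_end=60.0),
                           x0=rest_state)
        pre_mask = res.times < 30.0
        np.testing.assert_allclose(res.states[pre_mask],
                                   base.states[pre_mask], rtol=1e-7,
                                   atol=1e-12)
        pre, post = res.event_jumps[30.0]
        jump = post - pre
        iv = compiled.species_index("VEGF")
        # 45 ng/mL of a 45 kDa dimer is exactly 1 nM
        assert jump[iv] == pytest.approx(1.0)
        jump[iv] = 0.0
        assert np.all(jump == 0.0)

    def test_negative_dose_rejected(self, compiled):
        with pytest.raises(es.ModelError):
            es.StimulusEvent(0.0, "VEGF", -1.0)
        with pytest.raises(es.ModelError):
            apply_dose(compiled, np.zeros(compiled.n_species), "VEGF", -2.0)

    def test_deterministic_repeat(self, compiled, rest_state):
        proto = vegf_protocol(50.0, t_end=30.0)
        r1 = es.simulate(compiled, proto, x0=rest_state)
        r2 = es.simulate(compiled, proto, x0=rest_state)
        assert r1.params_hash == r2.params_hash
        np.testing.assert_array_equal(r1.states, r2.states)

    def test_tightening_rtol_changes_little(self, compiled, rest_state):
        proto = vegf_protocol(50.0, t_end=60.0)
        loose = es.simulate(compiled, proto, x0=rest_state, rtol=1e-8)
        tight = es.simulate(compiled, proto, x0=rest_state, rtol=1e-9)
        for obs in ("pVEGFR2", "pSrc", "ppAkt"):
            a, b = loose.observable(obs), tight.observable(obs)
            denom = np.maximum(np.abs(b), 1e-9 * b.max())
            assert np.max(np.abs(a - b) / denom) < 1e-3

    def test_grid_refinement_stability_of_peaks(self, compiled, rest_state):
        for dt in (0.5, 0.25):
            proto = es.StimulusProtocol(
                events=[es.StimulusEvent(0.0, "VEGF", 50.0)], t_end=30.0,
                output_grid=np.arange(0, 30 + 1e-9, dt))
            res = es.simulate(compiled, proto, x0=rest_state)
            pk, _ = summarize_peak(res.times, res.observable("pSrc"))
            if dt == 0.5:
                coarse = pk
        assert abs(pk - coarse) / coarse < 0.005


class TestPeaks:
    def test_constant_series_peaks_at_first_point(self):
        v, t = summarize_peak([0, 1, 2], [3.0, 3.0, 3.0])
        assert (v, t) == (3.0, 0.0)

    def test_monotone_series_peaks_at_last_point(self):
        v, t = summarize_peak([0, 1, 2], [0.0, 1.0, 2.0])
        assert (v, t) == (2.0, 2.0)

    def test_all_nan_rejected(self):
        with pytest.raises(es.ModelError):
            summarize_peak([0, 1], [np.nan, np.nan])

    def test_refined_peak_recovers_analytic_pulse_maximum(self):
        # A -> B -> sink: B(t) = (k1 A0/(k2-k1)) (e^-k1 t - e^-k2 t),
        # maximum at t* = ln(k2/k1)/(k2-k1)
        from endosig.network import (NetworkModel, ParameterSet,
                                     ReactionRule, SpeciesDef)
        k1, k2 = 0.8, 0.25
        model = NetworkModel(
            species=[SpeciesDef("A", "cytosol", {}, initial_value_key="A_0"),
                     SpeciesDef("B", "cytosol", {})],
            rules=[ReactionRule("a2b", ("A",), ("B",), "mass_action", "k1",
                                non_conserving=True),
                   ReactionRule("bdecay", ("B",), (), "mass_action", "k2",
                                non_conserving=True)],
            observables={"B": {"B": 1}})
        cm = es.compile_rhs(model, ParameterSet(
            {"k1": k1, "k2": k2, "A_0": 1.0}))
        proto = es.StimulusProtocol(events=[], t_end=20.0)
        peak, t_peak = refined_peak(cm, proto, "B",
                                    x0=np.array([1.0, 0.0]))
        t_star = np.log(k2 / k1) / (k2 - k1)
        assert t_peak == pytest.approx(t_star, abs=0.1)


class TestDoseResponse:
    def test_zero_dose_anchors_at_baseline_fold(self, compiled, rest_state):
        curve = dose_response(compiled, "VEGF", [0.0, 10.0],
                              "tie2_shedding_fold", summary="steady",
                              t_end=60.0, x0=rest_state)
        assert curve.values[0] == pytest.approx(1.0, abs=1e-6)

    def test_ang1_ptie2_monotone_nondecreasing_below_hook(self, compiled,
                                                          rest_state):
        # monotone over the agonist range; supersaturating doses show a
        # mild hook (seed excess outcompetes cluster completion)
        curve = dose_response(compiled, "Ang1", [0, 12.5, 25, 50, 100, 200],
                              "pTie2", summary="at_time", at_time=30.0,
                              t_end=30.0, x0=rest_state)
        assert np.all(np.diff(curve.values) >= -1e-12)

    def test_unknown_readout_rejected(self, compiled, rest_state):
        with pytest.raises(es.ModelError, match="unknown readout"):
            dose_response(compiled, "VEGF", [0, 1], "nonsense",
                          summary="steady", t_end=10.0, x0=rest_state)
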