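"""Compiled RHS against closed forms and an independent brute-force oracle."""

import numpy as np
import pytest

import endosig as es
from endosig.compile import validate_state
from endosig.network import (Gate, NetworkModel, ParameterSet, ReactionRule,
                             SpeciesDef)
from conftest import make_binding_toy


def naive_rhs(model, params, y):
    """Independent per-reaction summation, straight from the rule list."""
    idx = {s.name: i for i, s in enumerate(model.species)}
    c = np.maximum(np.asarray(y, float), 0.0)
    dy = np.zeros(len(y))
    for rule, direction in model.expanded_reactions():
        if direction > 0:
            k = params[rule.rate_constant_key]
            if rule.rate_law == "mass_action":
                v = k
                for r in rule.reactants:
                    v *= c[idx[r]]
            elif rule.rate_law == "michaelis_menten":
                S = c[idx[rule.reactants[0]]]
                Km = params[rule.km_key]
                v = k * S / (Km + S)
                if rule.modifier:
                    v *= c[idx[rule.modifier]]
            else:  # saturating_hill
                M = c[idx[rule.modifier]]
                v = k * M / (params[rule.km_key] + M)
                for r in rule.reactants:
                    v *= c[idx[r]]
            for g in rule.gates:
                G = c[idx[g.species]]
                Kg = params[g.k_key]
                v *= G / (Kg + G) if g.sign > 0 else Kg / (Kg + G)
            st = rule.stoichiometry()
        else:
            v = params[rule.reverse_key]
            for prod in rule.products:
                v *= c[idx[prod]]
            st = {s: -co for s, co in rule.stoichiometry().items()}
        for s, co in st.items():
            dy[idx[s]] += co * v
    return dy


def random_network(rng, n_species=6):
    names = [f"S{i}" for i in range(n_species)]
    species = [SpeciesDef(n, "cytosol", {}, initial_value_key=None)
               for n in names]
    laws = ["mass_action", "michaelis_menten", "saturating_hill"]
    rules, values = [], {}
    for j in range(rng.integers(4, 9)):
        law = laws[rng.integers(0, 3)]
        k = f"k{j}"
        values[k] = float(rng.uniform(0.1, 5.0))
        if law == "mass_action":
            nre = rng.integers(0, 3)
            reactants = tuple(rng.choice(names, nre, replace=True))
            products = tuple(rng.choice(names, rng.integers(0, 3),
                                        replace=True))
            rule = ReactionRule(f"r{j}", reactants, products, law, k,
                                non_conserving=True)
        else:
            sub, mod = rng.choice(names, 2, replace=False)
            km = f"Km{j}"
            values[km] = float(rng.uniform(0.2, 2.0))
            gates = ()
            if rng.random() < 0.4:
                gk = f"Kg{j}"
                values[gk] = float(rng.uniform(0.2, 2.0))
                gates = (Gate(str(rng.choice(names)), gk,
                              1 if rng.random() < 0.5 else -1),)
            reactants = (str(sub),) if law == "michaelis_menten" else \
                ((str(sub),) if rng.random() < 0.7 else ())
            rule = ReactionRule(f"r{j}", reactants, (str(mod),), law, k,
                                km_key=km, modifier=str(mod), gates=gates,
                                non_conserving=True)
        rules.append(rule)
    model = NetworkModel(species=species, rules=rules, observables={})
    return model, ParameterSet(values)


class TestCompiledDerivative:
    def test_all_zero_state_without_synthesis_gives_zero_derivative(self):
        model, params = make_binding_toy()
        cm = es.compile_rhs(model, params)
        dy = cm(np.zeros(3))
        assert np.all(dy == 0.0)

    def test_reversible_binding_closed_form(self):
        # A + B <-> C with kon=koff=1, A=B=1 nM, C=0: dC/dt = 1 nM/min
        model, params = make_binding_toy(kon=1.0, koff=1.0)
        cm = es.compile_rhs(model, params)
        dy = cm(np.array([1.0, 1.0, 0.0]))
        assert dy[cm.species_index("C")] == pytest.approx(1.0)
        assert dy[cm.species_index("A")] == pytest.approx(-1.0)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_bruteforce_oracle_on_random_networks(self, trial):
        rng = np.random.default_rng(1000 + trial)
        for _ in range(10):
            model, params = random_network(rng)
            cm = es.compile_rhs(model, params)
            y = rng.uniform(0.0, 3.0, len(model.species))
            np.testing.assert_allclose(cm(y), naive_rhs(model, params, y),
                                       rtol=1e-12, atol=1e-12)

    def test_negative_state_gives_finite_derivative_and_is_flagged(self,
                                                                   compiled):
        y = compiled.initial_state()
        y[0] = -1e-3
        dy = compiled(y)
        assert np.all(np.isfinite(dy))
        flagged = validate_state(y, compiled.species_names)
        assert flagged == [compiled.species_names[0]]

    def test_analytic_jacobian_matches_finite_differences(self, compiled,
                                                          rest_state):
        y = rest_state + 1e-4
        J = compiled.jac()(0.0, y)
        f = compiled.rhs()
        eps = 1e-8
        f0 = f(0.0, y)
        for j in range(0, compiled.n_species, 7):  # spot-check columns
            yp = y.copy()
            yp[j] += eps
            col = (f(0.0, yp) - f0) / eps
            np.testing.assert_allclose(J[:, j], col, rtol=2e-4, atol=1e-6)


class TestInhibitorScaling:
    def test_fraction_zero_is_identity(self, compiled, rest_state):
        proto = es.StimulusProtocol(
            events=[es.StimulusEvent(0.0, "VEGF", 50.0)],
            inhibitors=[es.InhibitorSpec("Src", 0.0, 0.0)], t_end=20.0)
        base_proto = es.StimulusProtocol(
            events=[es.StimulusEvent(0.0, "VEGF", 50.0)], t_end=20.0)
        r1 = es.simulate(compiled, proto, x0=rest_state)
        r0 = es.simulate(compiled, base_proto, x0=rest_state)
        np.testing.assert_allclose(r1.observable("pSrc"),
                                   r0.observable("pSrc"), rtol=1e-10)

    def test_full_src_block_keeps_psrc_at_baseline(self, compiled,
                                                   rest_state):
        proto = es.StimulusProtocol(
            events=[es.StimulusEvent(0.0, "VEGF", 50.0)],
            inhibitors=[es.InhibitorSpec("Src", 1.0, 0.0)], t_end=30.0)
        res = es.simulate(compiled, proto, x0=rest_state)
        uninhibited = es.simulate(
            compiled, es.StimulusProtocol(
                events=[es.StimulusEvent(0.0, "VEGF", 50.0)], t_end=30.0),
            x0=rest_state)
        peak = uninhibited.observable("pSrc").max()
        assert res.observable("pSrc").max() <= 0.01 * peak

    def test_vegfr2_peak_monotone_in_inhibition_fraction(self, compiled,
                                                         rest_state):
        peaks = []
        for f in (0.0, 0.5, 1.0):
            proto = es.StimulusProtocol(
                events=[es.StimulusEvent(0.0, "VEGF", 50.0)],
                inhibitors=[es.InhibitorSpec("VEGFR2", f, 0.0)], t_end=30.0)
            res = es.simulate(compiled, proto, x0=rest_state)
            peaks.append(res.observable("pVEGFR2").max())
        assert peaks[0] > peaks[1] > peaks[2]
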