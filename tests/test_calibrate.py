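"""Normalization, SSE objective and the generalized pattern search."""

import numpy as np
import pytest

import endosig as es
from endosig.calibrate import (CalibrationDataset, FitConfig,
                               PatternSearchOptions, fit, normalize_prediction,
                               objective_sse, pattern_search)
from endosig.simulate import StimulusEvent, StimulusProtocol
from endosig.synthetic import NoiseModel, generate_timecourse_dataset


def _dataset(points, normalization="percent_of_max", **kw):
    return CalibrationDataset(
        id=kw.pop("id", "d"), protocol=StimulusProtocol(events=[], t_end=60.0),
        observable="pSrc", abscissa_kind="time", points=points,
        normalization=normalization, **kw)


class TestNormalization:
    def test_constant_curve_percent_of_max_is_all_100(self):
        ds = _dataset([(0, 0, 1), (1, 0, 1)])
        out = normalize_prediction([2.0, 2.0], ds)
        np.testing.assert_allclose(out, [100.0, 100.0])

    def test_scale_invariance_of_percent_of_max(self):
        ds = _dataset([(0, 0, 1), (1, 0, 1), (2, 0, 1)])
        a = normalize_prediction([1.0, 3.0, 2.0], ds)
        b = normalize_prediction([2.0, 6.0, 4.0], ds)
        np.testing.assert_allclose(a, b)

    def test_pulse_normalization_matches_hand_computation(self):
        ds = _dataset([(0, 0, 1)] * 4)
        curve = np.array([0.5, 2.0, 1.0, 0.25])
        np.testing.assert_allclose(normalize_prediction(curve, ds),
                                   100.0 * curve / 2.0)

    def test_fold_of_baseline_with_zero_baseline_errors(self):
        ds = _dataset([(0, 0, 1), (1, 0, 1)],
                      normalization="fold_of_baseline")
        with pytest.raises(es.ModelError, match="zero baseline"):
            normalize_prediction([0.0, 1.0], ds)


class TestObjective:
    @pytest.fixture(scope="class")
    def noise_free_dataset(self, compiled, rest_state):
        proto = StimulusProtocol(
            events=[StimulusEvent(0.0, "VEGF", 50.0)], t_end=30.0)
        return generate_timecourse_dataset(
            compiled, proto, "pSrc", [0, 2, 5, 10, 20, 30],
            NoiseModel(scale=0.0), x0=rest_state)

    def test_zero_at_truth(self, compiled, rest_state, noise_free_dataset):
        obj = objective_sse(compiled, [noise_free_dataset], x0=rest_state)
        assert obj < 1e-10

    def test_positive_when_parameter_perturbed(self, compiled, rest_state,
                                               noise_free_dataset):
        pvec = compiled.params.with_updates(
            {"kactivesrc": 2 * compiled.params["kactivesrc"]}).vector()
        obj = objective_sse(compiled, [noise_free_dataset], pvec=pvec,
                            x0=rest_state)
        assert obj > 1e-4

    def test_additive_over_datasets(self, compiled, rest_state,
                                    noise_free_dataset):
        ds2 = CalibrationDataset(
            id="shifted", protocol=noise_free_dataset.protocol,
            observable="pSrc", abscissa_kind="time",
            points=[(a, v * 0.9, w) for a, v, w in noise_free_dataset.points],
            normalization="percent_of_max")
        o1 = objective_sse(compiled, [noise_free_dataset], x0=rest_state)
        o2 = objective_sse(compiled, [ds2], x0=rest_state)
        o12 = objective_sse(compiled, [noise_free_dataset, ds2],
                            x0=rest_state)
        assert o12 == pytest.approx(o1 + o2, rel=1e-12)

    def test_doubling_weights_doubles_objective(self, compiled, rest_state,
                                                noise_free_dataset):
        doubled = CalibrationDataset(
            id="w2", protocol=noise_free_dataset.protocol, observable="pSrc",
            abscissa_kind="time",
            points=[(a, v * 0.8, 2 * w)
                    for a, v, w in noise_free_dataset.points],
            normalization="percent_of_max")
        single = CalibrationDataset(
            id="w1", protocol=noise_free_dataset.protocol, observable="pSrc",
            abscissa_kind="time",
            points=[(a, v * 0.8, w)
                    for a, v, w in noise_free_dataset.points],
            normalization="percent_of_max")
        assert objective_sse(compiled, [doubled], x0=rest_state) == \
            pytest.approx(2 * objective_sse(compiled, [single],
                                            x0=rest_state), rel=1e-12)

    def test_empty_dataset_list_rejected(self, compiled):
        with pytest.raises(es.ModelError):
            objective_sse(compiled, [])


class TestPatternSearch:
    def test_quadratic_bowl_converges(self):
        f = lambda x: (x[0] - 0.7) ** 2 + (x[1] + 0.3) ** 2
        x, fb, trace, conv, _ = pattern_search(
            f, [(-5, 5), (-5, 5)], [0.0, 0.0],
            PatternSearchOptions(space="linear", initial_mesh=0.5))
        assert conv
        np.testing.assert_allclose(x, [0.7, -0.3], atol=1e-4)

    def test_rosenbrock_reaches_low_objective(self):
        ros = lambda x: (1 - x[0]) ** 2 + 100 * (x[1] - x[0] ** 2) ** 2
        _, fb, *_ = pattern_search(
            ros, [(-5, 5), (-5, 5)], [-1.2, 1.0],
            PatternSearchOptions(space="linear", initial_mesh=0.25))
        assert fb < 1e-3

    def test_returns_init_when_already_optimal(self):
        f = lambda x: 0.0
        x, fb, trace, conv, n_eval = pattern_search(
            f, [(0.1, 10)], [1.0], PatternSearchOptions())
        assert conv and x[0] == 1.0 and fb == 0.0

    def test_incumbent_never_increases(self):
        rng_like = lambda x: np.sin(5 * x[0]) + (x[0] - 2) ** 2
        _, _, trace, _, _ = pattern_search(
            rng_like, [(0.01, 100)], [10.0], PatternSearchOptions())
        objs = [t[2] for t in trace]
        assert all(a >= b for a, b in zip(objs, objs[1:]))

    def test_bounds_respected_at_every_evaluation(self):
        seen = []
        f = lambda x: (seen.append(x.copy()), float((x[0] - 3) ** 2))[1]
        pattern_search(f, [(0.5, 2.0)], [1.0],
                       PatternSearchOptions(space="linear"))
        arr = np.array(seen)
        assert arr.min() >= 0.5 and arr.max() <= 2.0

    def test_invalid_bounds_rejected(self):
        with pytest.raises(es.ModelError):
            pattern_search(lambda x: 0.0, [(2.0, 1.0)], [1.5],
                           PatternSearchOptions(space="linear"))

    def test_log_space_requires_positive_bounds(self):
        with pytest.raises(es.ModelError):
            pattern_search(lambda x: 0.0, [(-1.0, 1.0)], [0.5],
                           PatternSearchOptions())


class TestFit:
    def test_fitting_zero_parameters_returns_initial_objective(
            self, compiled, rest_state):
        proto = StimulusProtocol(
            events=[StimulusEvent(0.0, "VEGF", 50.0)], t_end=20.0)
        ds = generate_timecourse_dataset(
            compiled, proto, "pSrc", [0, 5, 10, 20], NoiseModel(scale=0.0),
            x0=rest_state)
        res = fit(compiled, [ds], FitConfig(fitted_keys=[]))
        assert res.converged and res.n_evaluations == 1
        assert res.objective < 1e-10

    def test_single_parameter_recovery_noise_free(self, tie_compiled):
        # perturb one Tie-axis constant and recover it from a pTie2 curve
        proto = StimulusProtocol(
            events=[StimulusEvent(0.0, "Ang1", 100.0)], t_end=40.0)
        x0 = es.pre_equilibrate(tie_compiled)
        ds = generate_timecourse_dataset(
            tie_compiled, proto, "pTie2", [0, 5, 10, 20, 30, 40],
            NoiseModel(scale=0.0), x0=x0)
        truth = tie_compiled.params["konang1tie2"]
        res = fit(tie_compiled, [ds],
                  FitConfig(fitted_keys=["konang1tie2"],
                            init={"konang1tie2": truth * 2.0},
                            options=PatternSearchOptions(
                                initial_mesh=0.35, mesh_tolerance=1e-5,
                                max_evaluations=300)))
        assert res.best_params["konang1tie2"] == pytest.approx(truth,
                                                               rel=0.1)
        assert res.objective < 1e-6
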