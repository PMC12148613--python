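"""Parameter estimation against normalized datasets.

The experimental observations this model is calibrated to are relative
signals (densitometry / ELISA time-courses and dose-responses), so every
dataset declares a normalization mode and the objective compares the
identically-normalized model prediction by weighted sum of squared errors.
The optimizer is a generalized pattern search in log10-parameter space:
2n coordinate polling directions, opportunistic (first-improvement)
polling in lexicographic key order, mesh expansion x2 on success and
contraction x0.5 on failure, stopping when the mesh falls below 1e-6
log10 units or an evaluation budget is exhausted.  Deterministic given the
initial point and options.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import pathlib

import numpy as np
import pandas as pd

from .compile import CompiledModel
from .network import ModelError, ParameterSet
from .simulate import (SimulationError, StimulusProtocol, dose_response,
                       pre_equilibrate, readout_series, simulate)

NORMALIZATIONS = ("percent_of_max", "fold_of_baseline", "absolute")

#: objective value substituted when a candidate parameter vector makes the
#: integration fail (large finite penalty, logged on the result)
PENALTY = 1e9


@dataclass
class CalibrationDataset:
    """Normalized measurements mapped to one model readout.

    ``abscissa`` is time (minutes) for time-courses or dose (ng/mL) for
    dose-responses; ``points`` are (abscissa, value, weight) triples.
    """

    id: str
    protocol: StimulusProtocol
    observable: str
    abscissa_kind: str                     # "time" | "dose"
    points: list
    normalization: str = "percent_of_max"
    source: str = "synthetic"
    dose_ligand: str | None = None         # for abscissa_kind == "dose"
    dose_summary: str = "steady"
    dose_time: float | None = None
    truth_fingerprint: str = ""
    extrapolation_flag: bool = False

    def __post_init__(self):
        if len(self.points) < 2:
            raise ModelError(f"dataset {self.id}: need at least 2 points")
        if self.normalization not in NORMALIZATIONS:
            raise ModelError(f"dataset {self.id}: unknown normalization "
                             f"{self.normalization!r}")
        if self.abscissa_kind not in ("time", "dose"):
            raise ModelError(f"dataset {self.id}: bad abscissa kind")
        for a, v, w in self.points:
            if w <= 0:
                raise ModelError(f"dataset {self.id}: weights must be > 0")

    @property
    def abscissae(self):
        return np.array([p[0] for p in self.points], float)

    @property
    def values(self):
        return np.array([p[1] for p in self.points], float)

    @property
    def weights(self):
        return np.array([p[2] for p in self.points], float)


def normalize_prediction(curve, dataset: CalibrationDataset) -> np.ndarray:
    """Normalize a simulated curve the way the dataset is normalized.

    percent_of_max: 100 * y / max(y) over the dataset's abscissa range;
    fold_of_baseline: y / y[0] (the pre-stimulus / zero-dose anchor);
    absolute: unchanged.
    """
    y = np.asarray(curve, float)
    if dataset.normalization == "percent_of_max":
        m = np.max(y)
        if m <= 0:
            return np.zeros_like(y)
        return 100.0 * y / m
    if dataset.normalization == "fold_of_baseline":
        if y[0] == 0:
            raise ModelError(
                f"dataset {dataset.id}: zero baseline with fold normalization")
        return y / y[0]
    return y


def predict_dataset(compiled: CompiledModel, dataset: CalibrationDataset,
                    pvec=None, x0=None, rtol=1e-7, atol=1e-10,
                    _sim_cache=None) -> np.ndarray:
    """Model prediction at the dataset's abscissae, normalized.

    ``_sim_cache`` (dict) lets one objective evaluation share a single
    simulation across time-course datasets with an identical protocol.
    """
    if dataset.abscissa_kind == "time":
        key = dataset.protocol.describe()
        res = None if _sim_cache is None else _sim_cache.get(key)
        if res is None:
            res = simulate(compiled, dataset.protocol, pvec=pvec, x0=x0,
                           rtol=rtol, atol=atol)
            if _sim_cache is not None:
                _sim_cache[key] = res
        series = readout_series(compiled, res, dataset.observable, pvec)
        raw = np.interp(dataset.abscissae, res.times, series)
    else:
        curve = dose_response(
            compiled, dataset.dose_ligand, dataset.abscissae,
            dataset.observable, summary=dataset.dose_summary,
            at_time=dataset.dose_time, t_end=dataset.protocol.t_end,
            pvec=pvec, x0=x0, rtol=rtol, atol=atol)
        raw = curve.values
    return normalize_prediction(raw, dataset)


def objective_sse(compiled: CompiledModel, datasets, pvec=None, x0=None,
                  log=None, rtol=1e-7, atol=1e-10) -> float:
    """Weighted SSE between normalized predictions and dataset values;
    integration failures contribute the PENALTY value (and are logged)."""
    if not datasets:
        raise ModelError("empty dataset list")
    total = 0.0
    sim_cache = {}
    for ds in datasets:
        try:
            pred = predict_dataset(compiled, ds, pvec=pvec, x0=x0,
                                   rtol=rtol, atol=atol,
                                   _sim_cache=sim_cache)
            total += float(np.sum(ds.weights * (pred - ds.values) ** 2))
        except (SimulationError, ModelError) as err:
            if log is not None:
                log.append((ds.id, str(err)))
            total += PENALTY
    return total


@dataclass
class CalibrationResult:
    best_params: ParameterSet
    objective: float
    trace: list                       # (evaluations, mesh, incumbent)
    fitted_keys: list
    fixed_keys: list
    converged: bool
    n_evaluations: int
    penalty_log: list = field(default_factory=list)

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trace,
                            columns=["evaluations", "mesh", "objective"])

    def save(self, outdir):
        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.trace_frame().to_csv(outdir / "trace.csv", index=False)
        with open(outdir / "best_params.json", "w") as fh:
            json.dump({"objective": self.objective,
                       "converged": self.converged,
                       "n_evaluations": self.n_evaluations,
                       "fitted": {k: self.best_params[k]
                                  for k in self.fitted_keys},
                       "values": dict(self.best_params.values)}, fh, indent=1)


@dataclass
class PatternSearchOptions:
    initial_mesh: float = 0.25         # log10 units (or linear units)
    mesh_tolerance: float = 1e-6
    max_evaluations: int = 5000
    expansion: float = 2.0
    contraction: float = 0.5
    space: str = "log10"               # or "linear"
    #: optional Hooke-Jeeves-style search step before polling: after a
    #: successful iteration, first try repeating the last accepted move
    #: (doubling while it keeps paying off).  The poll step is untouched,
    #: so this remains a generalized pattern search; it accelerates
    #: convergence along curved valleys considerably.
    pattern_moves: bool = False


def pattern_search(objective, bounds, init, options=None):
    """Generalized pattern search; returns (x_best, f_best, trace, converged,
    n_eval).

    ``bounds`` is a list of (lo, hi) per coordinate (finite, lo < hi),
    ``init`` must lie inside.  In 'log10' space all coordinates must be
    positive and polling steps are taken in log10 units.  Polling is
    opportunistic over the 2n coordinate directions in a fixed order
    (+e1, -e1, +e2, ...), so runs are deterministic.
    """
    opts = options or PatternSearchOptions()
    x = np.asarray(init, float).copy()
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    for i, (lo, hi) in enumerate(bounds):
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ModelError(f"invalid bounds for coordinate {i}")
        if not (lo <= x[i] <= hi):
            raise ModelError(f"init coordinate {i} outside bounds")
        if opts.space == "log10" and lo <= 0:
            raise ModelError("log10 search needs positive bounds")

    if opts.space == "log10":
        enc = np.log10
        dec = lambda z: 10.0 ** z
    else:
        enc = lambda z: np.asarray(z, float)
        dec = lambda z: np.asarray(z, float)

    z = enc(x)
    zlo = enc(np.array([b[0] for b in bounds]))
    zhi = enc(np.array([b[1] for b in bounds]))
    n = len(z)
    mesh = opts.initial_mesh
    f_best = objective(dec(z))
    n_eval = 1
    trace = [(n_eval, mesh, f_best)]
    def exploratory_sweep(z0, f0, mesh):
        """Full coordinate sweep accumulating improvements (Hooke-Jeeves
        exploratory phase); returns updated point/value."""
        nonlocal n_eval
        zc = z0.copy()
        fc = f0
        for i in range(n):
            for sgn in (+1.0, -1.0):
                if n_eval >= opts.max_evaluations:
                    return zc, fc
                zt = zc.copy()
                zt[i] = np.clip(zt[i] + sgn * mesh, zlo[i], zhi[i])
                if zt[i] == zc[i]:
                    continue
                ft = objective(dec(zt))
                n_eval += 1
                if ft < fc:
                    zc, fc = zt, ft
                    break
        return zc, fc

    while mesh >= opts.mesh_tolerance and n_eval < opts.max_evaluations:
        if opts.pattern_moves:
            # Hooke-Jeeves: exploratory sweep, then pattern moves along the
            # net displacement while they keep paying off
            z_new, f_new = exploratory_sweep(z, f_best, mesh)
            improved = f_new < f_best
            if improved:
                d = z_new - z
                z, f_best = z_new, f_new
                while n_eval < opts.max_evaluations:
                    z_trial = np.clip(z + d, zlo, zhi)
                    if np.array_equal(z_trial, z):
                        break
                    f_probe = objective(dec(z_trial))
                    n_eval += 1
                    z_exp, f_exp = exploratory_sweep(
                        z_trial, f_probe, mesh)
                    if min(f_probe, f_exp) < f_best:
                        d = z_exp - z
                        z = z_exp
                        f_best = min(f_probe, f_exp)
                    else:
                        break
        else:
            improved = False
            for i in range(n):
                for sgn in (+1.0, -1.0):
                    zc = z.copy()
                    zc[i] = np.clip(zc[i] + sgn * mesh, zlo[i], zhi[i])
                    if zc[i] == z[i]:
                        continue
                    fc = objective(dec(zc))
                    n_eval += 1
                    if fc < f_best:
                        z, f_best = zc, fc
                        improved = True
                        break
                    if n_eval >= opts.max_evaluations:
                        break
                if improved or n_eval >= opts.max_evaluations:
                    break
        mesh = mesh * (opts.expansion if improved else opts.contraction)
        trace.append((n_eval, mesh, f_best))
    converged = mesh < opts.mesh_tolerance
    return dec(z), f_best, trace, converged, n_eval


@dataclass
class FitConfig:
    fitted_keys: list
    bounds: dict = field(default_factory=dict)   # key -> (lo, hi)
    init: dict = field(default_factory=dict)     # manual init overrides
    bound_factor: float = 100.0
    options: PatternSearchOptions = field(default_factory=PatternSearchOptions)


def fit(compiled: CompiledModel, datasets, config: FitConfig,
        outdir=None, rtol=1e-7, atol=1e-10) -> CalibrationResult:
    """Pattern-search minimisation of the weighted SSE over the configured
    fitted keys; everything else stays at the compiled baseline.

    The ligand-free steady state is recomputed once per candidate vector
    and shared across all datasets of that evaluation.
    """
    if not datasets:
        raise ModelError("empty dataset list")
    params = compiled.params
    keys = list(config.fitted_keys)
    for k in keys:
        if k not in params:
            raise ModelError(f"fitted key {k!r} not in ParameterSet")
    init = np.array([config.init.get(k, params[k]) for k in keys])
    bounds = [config.bounds.get(
        k, (init[i] / config.bound_factor, init[i] * config.bound_factor))
        for i, k in enumerate(keys)]
    kidx = np.array([params.index(k) for k in keys], int)
    base = params.vector()
    penalty_log = []
    rest_guess = pre_equilibrate(compiled, base, tol=1e-7) if keys else None

    def objective(x):
        pvec = base.copy()
        pvec[kidx] = x
        try:
            x0 = pre_equilibrate(compiled, pvec, tol=1e-7, x0=rest_guess,
                                 chunk=200.0)
        except SimulationError as err:
            penalty_log.append(("pre_equilibrate", str(err)))
            return PENALTY
        return objective_sse(compiled, datasets, pvec=pvec, x0=x0,
                             log=penalty_log, rtol=rtol, atol=atol)

    if keys:
        x, f_best, trace, converged, n_eval = pattern_search(
            objective, bounds, init, config.options)
    else:
        f_best = objective_sse(compiled, datasets, log=penalty_log,
                               rtol=rtol, atol=atol)
        x, trace, converged, n_eval = init, [(1, 0.0, f_best)], True, 1
    best = params.with_updates(dict(zip(keys, x)))
    result = CalibrationResult(
        best_params=best, objective=f_best, trace=trace, fitted_keys=keys,
        fixed_keys=[k for k in params.keys() if k not in keys],
        converged=converged, n_evaluations=n_eval, penalty_log=penalty_log)
    if outdir is not None:
        result.save(outdir)
    return result
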