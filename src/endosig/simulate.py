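"""Stimulation-protocol simulation on a compiled model.

A :class:`StimulusProtocol` is a list of timed ligand additions (ng/mL or
nM) plus optional inhibitor applications.  Simulation always starts from a
ligand-free steady state (:func:`pre_equilibrate`), integrates piecewise
between events with LSODA (analytic Jacobian, rtol 1e-8 / atol 1e-10 by
default), and treats ligand additions as instantaneous concentration jumps
against an infinite extracellular reservoir (binding depletion is
modeled; bath dilution is not).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import hashlib

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .compile import CompiledModel
from .network import InhibitorSpec, ModelError
from .params import MOLECULAR_WEIGHTS_KDA, ang2_dose_to_species_nM, ng_per_ml_to_nM


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class StimulusEvent:
    time: float            # minutes
    species: str           # "VEGF", "Ang1", "Ang2" or a raw species name
    amount: float          # dose
    units: str = "ng_per_mL"   # or "nM"

    def __post_init__(self):
        if self.amount < 0:
            raise ModelError("negative dose rejected")
        if self.time < 0:
            raise ModelError("event times must be >= 0")


@dataclass
class StimulusProtocol:
    """Timed ligand additions + inhibitors defining an in-silico experiment."""

    events: list = field(default_factory=list)
    inhibitors: list = field(default_factory=list)
    t_end: float = 120.0
    output_grid: np.ndarray | None = None

    def __post_init__(self):
        for e in self.events:
            if e.time > self.t_end:
                raise ModelError(f"event at t={e.time} beyond t_end={self.t_end}")
        if self.output_grid is None:
            self.output_grid = np.arange(0.0, self.t_end + 1e-9, 0.5)
        self.output_grid = np.asarray(self.output_grid, float)
        if np.any(np.diff(self.output_grid) <= 0):
            raise ModelError("output_grid must be strictly ascending")

    def describe(self) -> str:
        ev = ";".join(f"{e.time}:{e.species}:{e.amount}{e.units}" for e in self.events)
        inh = ";".join(f"{i.target}:{i.fraction}@{i.apply_time}" for i in self.inhibitors)
        return f"events[{ev}]|inh[{inh}]|t_end={self.t_end}"


def vegf_protocol(dose_ng_ml, t_end=120.0, t0=0.0, **kw):
    return StimulusProtocol(events=[StimulusEvent(t0, "VEGF", dose_ng_ml)],
                            t_end=t_end, **kw)


@dataclass
class SimulationResult:
    times: np.ndarray
    states: np.ndarray                 # time x species
    observables: pd.DataFrame          # time-indexed
    protocol: StimulusProtocol
    params_hash: str
    species_names: list
    event_jumps: dict = field(default_factory=dict)  # time -> (pre, post)

    def observable(self, name) -> np.ndarray:
        return self.observables[name].to_numpy()

    def species(self, name) -> np.ndarray:
        return self.states[:, self.species_names.index(name)]

    def to_tidy(self) -> pd.DataFrame:
        long = self.observables.reset_index().melt(
            id_vars="time", var_name="observable", value_name="value")
        return long.sort_values(["observable", "time"]).reset_index(drop=True)


def apply_dose(compiled: CompiledModel, y, species, amount, units="ng_per_mL"):
    """Return a state with the ligand dose added as a concentration jump."""
    if amount < 0:
        raise ModelError("negative dose rejected")
    y = np.array(y, float)

    def bump(name, nM):
        try:
            y[compiled.species_index(name)] += nM
        except KeyError:
            raise ModelError(f"ligand species {name!r} not in this model") from None

    if units == "nM":
        bump(species, amount)
        return y
    if units != "ng_per_mL":
        raise ModelError(f"unknown dose units {units!r}")
    if species == "VEGF":
        bump("VEGF", ng_per_ml_to_nM(amount, MOLECULAR_WEIGHTS_KDA["VEGF"]))
    elif species == "Ang1":
        bump("Ang1", ng_per_ml_to_nM(amount, MOLECULAR_WEIGHTS_KDA["Ang1"]))
    elif species == "Ang2":
        mix = dict(compiled.model.config.ang2_mixture) if compiled.model.config else None
        for name, nM in ang2_dose_to_species_nM(amount, mix).items():
            bump(name, nM)
    else:
        raise ModelError(f"no ng/mL conversion for species {species!r}")
    return y


def pre_equilibrate(compiled: CompiledModel, pvec=None, tol=1e-8,
                    max_time=5000.0, x0=None, rtol=1e-9, atol=1e-12,
                    chunk=500.0):
    """Integrate the ligand-free system to steady state.

    Convergence criterion: max_i |dx_i/dt| / (|x_i| + eps) < tol with
    eps = 1e-9 nM.  Raises SimulationError naming the worst species if the
    system has not settled within ``max_time`` simulated minutes.
    """
    y = compiled.initial_state(pvec) if x0 is None else np.array(x0, float)
    f = compiled.rhs(pvec)
    J = compiled.jac(pvec)
    t = 0.0
    while True:
        dy = f(0.0, y)
        rel = np.abs(dy) / (np.abs(y) + 1e-9)
        if rel.max() < tol:
            return y
        if t >= max_time:
            worst = compiled.species_names[int(np.argmax(rel))]
            raise SimulationError(
                f"pre-equilibration did not converge within {max_time} min; "
                f"worst species {worst} (rel. rate {rel.max():.2e})")
        sol = solve_ivp(f, (0.0, chunk), y, method="LSODA", jac=J,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise SimulationError(f"pre-equilibration integration failed: {sol.message}")
        y = sol.y[:, -1]
        t += chunk


def _params_hash(compiled, pvec, protocol):
    h = hashlib.sha256()
    p = compiled._pvec if pvec is None else np.asarray(pvec, float)
    h.update(p.tobytes())
    h.update(protocol.describe().encode())
    h.update(compiled.fingerprint().encode())
    return h.hexdigest()[:16]


def simulate(compiled: CompiledModel, protocol: StimulusProtocol, pvec=None,
             x0=None, rtol=1e-8, atol=1e-10, pre_eq_kwargs=None) -> SimulationResult:
    """Run a stimulation protocol; returns observables on the output grid.

    ``x0`` defaults to the ligand-free pre-equilibrated state.  Integration
    is split at every event and inhibitor application time; doses are
    applied as instantaneous jumps at the segment boundary.
    """
    if x0 is None:
        x0 = pre_equilibrate(compiled, pvec, **(pre_eq_kwargs or {}))
    y = np.array(x0, float)
    grid = protocol.output_grid
    t_end = float(protocol.t_end)

    cuts = {0.0, t_end}
    cuts.update(float(e.time) for e in protocol.events)
    cuts.update(float(i.apply_time) for i in protocol.inhibitors
                if 0.0 <= i.apply_time <= t_end)
    cuts.update(float(i.apply_time) for i in compiled.model.inhibitors
                if 0.0 <= i.apply_time <= t_end)
    cuts = sorted(cuts)

    times_out, states_out = [], []
    event_jumps = {}
    for a, b in zip(cuts[:-1], cuts[1:]):
        pre = y.copy()
        for e in protocol.events:
            if np.isclose(e.time, a):
                y = apply_dose(compiled, y, e.species, e.amount, e.units)
        if not np.allclose(pre, y):
            event_jumps[a] = (pre, y.copy())
        scale = compiled.inhibitor_scale(a + 1e-9, protocol.inhibitors)
        f = compiled.rhs(pvec, scale)
        J = compiled.jac(pvec, scale)
        mask = (grid >= a - 1e-12) & (grid <= b + 1e-12)
        t_eval = grid[mask]
        # drop grid points that belong to the next segment's t=a sample
        if len(t_eval) and not np.isclose(b, t_end) and np.isclose(t_eval[-1], b):
            t_eval = t_eval[:-1]
        if len(times_out) and len(t_eval) and np.isclose(t_eval[0], a):
            pass  # boundary point reported post-event
        sol = solve_ivp(f, (a, b), y, method="LSODA", jac=J, rtol=rtol,
                        atol=atol, t_eval=t_eval if len(t_eval) else None,
                        dense_output=False)
        if not sol.success:
            raise SimulationError(
                f"integration failed at t={sol.t[-1] if len(sol.t) else a:.3f} "
                f"min: {sol.message}; state snapshot: "
                f"{dict(zip(compiled.species_names, np.round(y, 6)))}")
        if len(t_eval):
            seg_states = sol.y.T
            if len(times_out) and np.isclose(t_eval[0], times_out[-1][-1] if len(times_out[-1]) else -1):
                t_eval = t_eval[1:]
                seg_states = seg_states[1:]
            times_out.append(t_eval)
            states_out.append(seg_states)
        # advance to segment end
        y = sol.y[:, -1] if sol.t[-1] == b else solve_ivp(
            f, (sol.t[-1], b), sol.y[:, -1], method="LSODA", jac=J,
            rtol=rtol, atol=atol).y[:, -1]

    times = np.concatenate(times_out) if times_out else np.array([])
    states = np.vstack(states_out) if states_out else np.zeros((0, compiled.n_species))
    if not np.all(np.isfinite(states)):
        raise SimulationError("non-finite states in trajectory")
    obs = np.maximum(compiled.observe(states), 0.0)
    df = pd.DataFrame(obs, columns=compiled.obs_names,
                      index=pd.Index(times, name="time"))
    return SimulationResult(times=times, states=states, observables=df,
                            protocol=protocol,
                            params_hash=_params_hash(compiled, pvec, protocol),
                            species_names=compiled.species_names,
                            event_jumps=event_jumps)


# ---------------------------------------------------------------------------
# readouts
# ---------------------------------------------------------------------------

def readout_series(compiled: CompiledModel, result: SimulationResult,
                   name: str, pvec=None) -> np.ndarray:
    """An observable column or one of the derived readouts.

    Derived readouts:

    ``tie2_shedding_fold``
        Instantaneous per-receptor Tie2 shedding rate relative to the
        constitutive rate: 1 + (kshedvegftie2/kshedtie2) * pV/(K + pV).
    ``ang2_released``
        Cumulative Ang2 released from Weibel-Palade bodies, in monomer nM.
    ``src_sequestration``
        Fraction of total Src held in RhoA-GTP/mDia complexes,
        1 - (free Src + pSrc)/total Src.
    """
    if name in result.observables.columns:
        return result.observable(name)
    p = compiled.params if pvec is None else compiled.params.from_vector(pvec)
    if name == "tie2_shedding_fold":
        pv = result.species("pVEGFR2d")
        k0, kv, K = p["kshedtie2"], p["kshedvegftie2"], p["Kshedvegf"]
        return 1.0 + (kv / k0) * pv / (K + pv)
    if name == "ang2_released":
        wpb = result.species("WPB_Ang2")
        return 12.0 * (wpb[0] - wpb)
    if name == "src_sequestration":
        free = result.species("Src") + result.species("pSrc")
        total = free + result.species("mDiaSrc")
        return 1.0 - free / np.maximum(total, 1e-12)
    if name == "stie2_accumulated":
        # cumulative Tie2 ectodomain release (integrated shedding flux, nM);
        # emulates soluble-Tie2 accumulation assays in fresh medium
        shed_cols = [j for j, (r, d) in enumerate(compiled.reactions)
                     if d > 0 and (r.name.startswith("tie2_shed")
                                   or r.name.startswith("shed_"))]
        pv = compiled._pvec if pvec is None else np.asarray(pvec, float)
        flux = np.array([
            compiled.rates(result.states[i], pv,
                           compiled.inhibitor_scale(
                               result.times[i], result.protocol.inhibitors)
                           )[shed_cols].sum()
            for i in range(len(result.times))])
        from scipy.integrate import cumulative_trapezoid
        out = np.zeros(len(result.times))
        out[1:] = cumulative_trapezoid(flux, result.times)
        return out
    raise ModelError(f"unknown readout {name!r}")


def summarize_peak(times, values):
    """(peak value, time of peak) of a timecourse on its grid.

    Constant series peak at the first grid point; monotone series at the
    last.  All-NaN input is an error.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if len(values) == 0 or np.all(np.isnan(values)):
        raise ModelError("cannot summarise an empty/all-NaN timecourse")
    i = int(np.nanargmax(values))
    return float(values[i]), float(times[i])


def refined_peak(compiled: CompiledModel, protocol: StimulusProtocol,
                 readout: str, pvec=None, x0=None, window=2.0, dt=0.1):
    """Peak of ``readout`` with local re-integration at ``dt``-min
    resolution around the coarse grid maximum."""
    coarse = simulate(compiled, protocol, pvec=pvec, x0=x0)
    series = readout_series(compiled, coarse, readout, pvec)
    _, t0 = summarize_peak(coarse.times, series)
    lo = max(0.0, t0 - window)
    hi = min(protocol.t_end, t0 + window)
    fine_grid = np.unique(np.concatenate([[0.0], np.arange(lo, hi + 1e-9, dt)]))
    fine_proto = StimulusProtocol(events=list(protocol.events),
                                  inhibitors=list(protocol.inhibitors),
                                  t_end=protocol.t_end, output_grid=fine_grid)
    fine = simulate(compiled, fine_proto, pvec=pvec, x0=x0)
    fseries = readout_series(compiled, fine, readout, pvec)
    mask = (fine.times >= lo) & (fine.times <= hi)
    return summarize_peak(fine.times[mask], fseries[mask])


@dataclass
class DoseResponseCurve:
    doses: np.ndarray
    values: np.ndarray
    readout: str
    summary: str
    normalization: str = "raw"
    plateau: float = float("nan")
    saturation_dose: float = float("nan")

    def __post_init__(self):
        self.doses = np.asarray(self.doses, float)
        self.values = np.asarray(self.values, float)
        if np.any(np.diff(self.doses) <= 0):
            raise ModelError("doses must be sorted ascending")
        if len(self.doses) != len(self.values):
            raise ModelError("doses and values length mismatch")


def dose_response(compiled: CompiledModel, ligand, doses, readout,
                  summary="steady", at_time=None, t_end=120.0, pvec=None,
                  co_stimulation=(), x0=None, rtol=1e-8, atol=1e-10) -> DoseResponseCurve:
    """One simulation per dose from a shared pre-equilibrated baseline.

    ``summary``: 'at_time' (requires ``at_time``), 'peak', or 'steady'
    (value at the final grid point).  The plateau is the value at the
    largest dose; the saturation dose is the smallest dose reaching 95 %
    of the plateau (measured from the zero-dose anchor).
    """
    doses = np.asarray(sorted(doses), float)
    if np.any(doses < 0):
        raise ModelError("doses must be >= 0")
    if x0 is None:
        x0 = pre_equilibrate(compiled, pvec)
    vals = []
    for d in doses:
        events = [StimulusEvent(0.0, ligand, float(d))]
        events += [StimulusEvent(0.0, sp, amt) for sp, amt in co_stimulation]
        proto = StimulusProtocol(events=events, t_end=t_end)
        res = simulate(compiled, proto, pvec=pvec, x0=x0, rtol=rtol, atol=atol)
        series = readout_series(compiled, res, readout, pvec)
        if summary == "at_time":
            if at_time is None:
                raise ModelError("summary 'at_time' needs at_time")
            vals.append(float(np.interp(at_time, res.times, series)))
        elif summary == "peak":
            vals.append(summarize_peak(res.times, series)[0])
        elif summary == "steady":
            vals.append(float(series[-1]))
        else:
            raise ModelError(f"unknown summary mode {summary!r}")
    vals = np.array(vals)
    plateau = float(vals[-1])
    v0 = float(vals[0]) if doses[0] == 0 else 0.0
    target = v0 + 0.95 * (plateau - v0)
    above = np.nonzero(vals >= target if plateau >= v0 else vals <= target)[0]
    sat = float(doses[above[0]]) if len(above) else float("nan")
    return DoseResponseCurve(doses=doses, values=vals, readout=readout,
                             summary=summary, plateau=plateau,
                             saturation_dose=sat)


def conservation_report(compiled: CompiledModel, result: SimulationResult,
                        pvec=None) -> pd.DataFrame:
    """Max relative drift of each conserved monomer pool along a trajectory.

    Flux through rules flagged ``non_conserving`` is integrated
    (trapezoidal) and credited back before measuring drift, so synthesis /
    degradation / clearance do not register as conservation errors.
    """
    if result.states.shape[1] != compiled.n_species:
        raise ModelError("trajectory does not match model species")
    M = compiled.monomer_matrix          # monomers x species
    totals = result.states @ M.T         # time x monomers
    # net monomer production rate of non-conserving reactions
    nc_cols = np.nonzero(compiled.nc_mask)[0]
    S = compiled.model.stoichiometry_matrix()          # species x reactions
    prod = M @ S[:, nc_cols]                           # monomers x nc-reactions
    n_t = len(result.times)
    credit = np.zeros((n_t, M.shape[0]))
    if len(nc_cols):
        rates = np.zeros((n_t, len(nc_cols)))
        for i in range(n_t):
            t = result.times[i]
            scale = compiled.inhibitor_scale(t, result.protocol.inhibitors)
            rates[i] = compiled.rates(result.states[i], pvec, scale)[nc_cols]
        flux = rates @ prod.T                          # time x monomers
        from scipy.integrate import cumulative_trapezoid
        credit[1:] = cumulative_trapezoid(flux, result.times, axis=0)
    # ligand additions legitimately change pool totals; credit the jumps
    # (the first grid point is recorded post-event, so t=0 additions are
    # already inside totals[0])
    for t_event, (pre, post) in result.event_jumps.items():
        if t_event <= result.times[0] + 1e-9:
            continue
        jump = (np.asarray(post) - np.asarray(pre)) @ M.T
        credit[result.times >= t_event - 1e-9] += jump
    drift = totals - totals[0] - credit
    denom = np.maximum(np.abs(totals).max(axis=0), 1e-9)
    rows = []
    for m_i, m in enumerate(compiled.monomers):
        rows.append({
            "pool": m,
            "initial_total": totals[0, m_i],
            "max_abs_drift": float(np.max(np.abs(drift[:, m_i]))),
            "max_rel_drift": float(np.max(np.abs(drift[:, m_i])) / denom[m_i]),
            "credited_flux": float(credit[-1, m_i]),
        })
    return pd.DataFrame(rows).set_index("pool")
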