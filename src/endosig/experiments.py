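"""The in-silico studies: crosstalk dose sweeps, chronic-vs-acute Ang1
protection, and inhibitor x Ang1 combination grids.

Each scenario runner pre-equilibrates once, reuses the same ligand-free
baseline for every variant (so the VEGF-only reference is bit-identical
across scenarios), and reports the headline percentages the study
quantifies: peak-pSrc / peak-pVEcad reduction under Ang1 pre-stimulation,
the Src-sequestration fraction, the Tie2-shedding fold and pTie2
inhibition plateaus with their 95 %-of-plateau saturation doses, and the
four 15-min readouts of the combination grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compile import CompiledModel
from .network import InhibitorSpec, ModelError
from .simulate import (DoseResponseCurve, StimulusEvent, StimulusProtocol,
                       dose_response, pre_equilibrate, readout_series,
                       refined_peak, simulate, summarize_peak)

#: Fig-7-style grids show "simultaneous stimulation with Ang1 and" an
#: inhibitor on VEGF-activated cells; the background VEGF dose is a package
#: default (matching the protection protocols) and is configurable.
DEFAULT_VEGF_BACKGROUND = 50.0
#: Ang1 co-stimulation dose for the pTie2-inhibition sweep
DEFAULT_ANG1_COSTIM = 200.0


def percent_change(perturbed, baseline) -> float:
    """Signed percent change, 100 * (perturbed - baseline) / baseline."""
    if baseline == 0:
        raise ModelError("zero baseline in percent_change")
    return 100.0 * (perturbed - baseline) / baseline


@dataclass
class ScenarioSpec:
    name: str
    variants: dict                      # name -> StimulusProtocol
    readouts: tuple = ()
    comparison: str = "raw"             # percent_change_vs_baseline | ...
    baseline_variant: str | None = None

    def __post_init__(self):
        if not self.variants:
            raise ModelError("scenario needs at least one variant")
        if (self.comparison != "raw"
                and self.baseline_variant not in self.variants):
            raise ModelError("comparison requires a named baseline variant")


@dataclass
class CrosstalkSweepResult:
    ang2_release: DoseResponseCurve
    shedding_fold: DoseResponseCurve
    ptie2_inhibition: DoseResponseCurve
    summary: dict


def run_crosstalk_sweep(compiled: CompiledModel, doses=None, pvec=None,
                        ang1_costim=DEFAULT_ANG1_COSTIM, t_end=180.0,
                        release_window=60.0, x0=None) -> CrosstalkSweepResult:
    """VEGF sweep (default 0-20 ng/mL, 41 points): cumulative Ang2 release,
    Tie2-shedding fold vs constitutive, and suppression of Ang1-induced
    Tie2 activation (% inhibition vs the VEGF=0 co-stimulated case)."""
    doses = np.linspace(0.0, 20.0, 41) if doses is None else np.asarray(doses)
    if x0 is None:
        x0 = pre_equilibrate(compiled, pvec)
    ang2 = dose_response(compiled, "VEGF", doses, "ang2_released",
                         summary="at_time", at_time=release_window,
                         t_end=release_window, pvec=pvec, x0=x0)
    shed = dose_response(compiled, "VEGF", doses, "tie2_shedding_fold",
                         summary="steady", t_end=t_end, pvec=pvec, x0=x0)
    ptie2 = dose_response(compiled, "VEGF", doses, "pTie2", summary="steady",
                          t_end=t_end, pvec=pvec,
                          co_stimulation=[("Ang1", ang1_costim)], x0=x0)
    inh_vals = 100.0 * (1.0 - ptie2.values / ptie2.values[0])
    inh = DoseResponseCurve(doses=ptie2.doses, values=inh_vals,
                            readout="pTie2_inhibition_percent",
                            summary="steady",
                            plateau=float(inh_vals[-1]))
    target = 0.95 * inh.plateau
    above = np.nonzero(inh_vals >= target)[0]
    inh.saturation_dose = float(doses[above[0]]) if len(above) else float("nan")
    summary = {
        "shedding_fold_plateau": shed.plateau,
        "shedding_saturation_dose_ng_ml": shed.saturation_dose,
        "ang2_release_plateau_nM": ang2.plateau,
        "ang2_saturation_dose_ng_ml": ang2.saturation_dose,
        "ptie2_inhibition_plateau_percent": inh.plateau,
        "ang1_costim_ng_ml": ang1_costim,
    }
    return CrosstalkSweepResult(ang2_release=ang2, shedding_fold=shed,
                                ptie2_inhibition=inh, summary=summary)


@dataclass
class ProtectionReport:
    mode: str
    max_psrc: float
    max_pvecad: float
    max_psrc_baseline: float
    max_pvecad_baseline: float
    psrc_reduction_percent: float
    pvecad_reduction_percent: float
    times: np.ndarray
    ptie2: np.ndarray
    src_sequestration: np.ndarray
    sequestration_at_25min: float
    baseline_hash: str = ""


def run_ang1_protection(compiled: CompiledModel, mode="pre_25min",
                        ang1_dose=50.0, vegf_dose=50.0, pvec=None,
                        x0=None, t_post=60.0) -> ProtectionReport:
    """Chronic vs acute Ang1 protection against VEGF-driven Src signaling.

    Modes: 'pre_25min' (Ang1 at t=0, VEGF at t=25), 'simultaneous' (both at
    t=0) and 'ang1_only'.  Peak reductions are measured on the post-VEGF
    window against a VEGF-only run from the same pre-equilibrated state.
    """
    if mode not in ("pre_25min", "simultaneous", "ang1_only"):
        raise ModelError(f"unknown mode {mode!r}")
    if ang1_dose < 0 or vegf_dose < 0:
        raise ModelError("doses must be >= 0")
    if x0 is None:
        x0 = pre_equilibrate(compiled, pvec)
    t_vegf = 25.0 if mode == "pre_25min" else 0.0
    t_end = t_vegf + t_post

    base_proto = StimulusProtocol(
        events=[StimulusEvent(t_vegf, "VEGF", vegf_dose)], t_end=t_end)
    base = simulate(compiled, base_proto, pvec=pvec, x0=x0)
    post = base.times >= t_vegf
    base_psrc = float(base.observable("pSrc")[post].max())
    base_pvec = float(base.observable("pVEcad")[post].max())

    events = [StimulusEvent(0.0, "Ang1", ang1_dose)]
    if mode != "ang1_only":
        events.append(StimulusEvent(t_vegf, "VEGF", vegf_dose))
    proto = StimulusProtocol(events=events, t_end=t_end)
    res = simulate(compiled, proto, pvec=pvec, x0=x0)
    psrc = float(res.observable("pSrc")[post].max())
    pvec_max = float(res.observable("pVEcad")[post].max())
    seq = readout_series(compiled, res, "src_sequestration", pvec)
    return ProtectionReport(
        mode=mode, max_psrc=psrc, max_pvecad=pvec_max,
        max_psrc_baseline=base_psrc, max_pvecad_baseline=base_pvec,
        psrc_reduction_percent=-percent_change(psrc, base_psrc),
        pvecad_reduction_percent=-percent_change(pvec_max, base_pvec),
        times=res.times, ptie2=res.observable("pTie2"),
        src_sequestration=seq,
        sequestration_at_25min=float(np.interp(25.0, res.times, seq)),
        baseline_hash=base.params_hash)


def sequestration_timecourse(compiled: CompiledModel, ang1_dose=50.0,
                             pvec=None, x0=None, t_end=120.0):
    """Src-sequestration trajectory under Ang1 alone, plus the earliest
    time at which it reaches 95 % of its plateau (end-of-run) value."""
    if x0 is None:
        x0 = pre_equilibrate(compiled, pvec)
    proto = StimulusProtocol(events=[StimulusEvent(0.0, "Ang1", ang1_dose)],
                             t_end=t_end)
    res = simulate(compiled, proto, pvec=pvec, x0=x0)
    seq = readout_series(compiled, res, "src_sequestration", pvec)
    plateau = float(seq[-1])
    idx = np.nonzero(seq >= 0.95 * plateau)[0]
    t95 = float(res.times[idx[0]]) if len(idx) else float("nan")
    return res.times, seq, plateau, t95


GRID_READOUTS = ("pTie2", "pSrc", "ppAkt", "pErk")


def run_combination_grid(compiled: CompiledModel, target,
                         levels=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
                         ang1_doses=(0.0, 50.0, 200.0, 500.0),
                         vegf_background=DEFAULT_VEGF_BACKGROUND,
                         readout_time=15.0, pvec=None,
                         x0=None) -> pd.DataFrame:
    """Inhibitor-level x Ang1-dose grid of the four readouts at 15 min.

    Simultaneous Ang1 + background VEGF at t=0, inhibitor applied at t=0.
    Returns a tidy frame (target, level, ang1_dose, readout, value).
    """
    if target not in ("Src", "Axl", "Akt", "VEGFR2"):
        raise ModelError(f"unknown target {target!r}")
    if any(not 0 <= l <= 1 for l in levels):
        raise ModelError("inhibition levels must lie in [0, 1]")
    if x0 is None:
        x0 = pre_equilibrate(compiled, pvec)
    rows = []
    for level in levels:
        for dose in ang1_doses:
            events = [StimulusEvent(0.0, "VEGF", vegf_background)]
            if dose > 0:
                events.append(StimulusEvent(0.0, "Ang1", float(dose)))
            inhibitors = ([InhibitorSpec(target, float(level), 0.0)]
                          if level > 0 else [])
            proto = StimulusProtocol(events=events, inhibitors=inhibitors,
                                     t_end=readout_time + 5.0)
            res = simulate(compiled, proto, pvec=pvec, x0=x0)
            for obs in GRID_READOUTS:
                val = float(np.interp(readout_time, res.times,
                                      res.observable(obs)))
                rows.append({"target": target, "level": level,
                             "ang1_dose": dose, "readout": obs,
                             "value": val})
    return pd.DataFrame(rows)
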