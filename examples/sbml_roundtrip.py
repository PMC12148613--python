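"""Export the expanded ODE model as SBML Level 3, validate it, re-import it
and check that the two simulators agree."""
import numpy as np
import endosig as es
from endosig.sbml import export_sbml, import_sbml, validate_sbml
from endosig.simulate import StimulusProtocol, apply_dose, simulate

compiled = es.compile_rhs(es.build_default_model(), es.baseline_parameters())
doc = export_sbml(compiled)
print(f"SBML document: {len(doc)/1024:.0f} kB, "
      f"validation errors: {validate_sbml(doc)}")
imported = import_sbml(doc)
rest = es.pre_equilibrate(compiled)
y0 = apply_dose(compiled, rest, "VEGF", 50.0)
grid = np.linspace(0, 20, 21)
native = simulate(compiled, StimulusProtocol(events=[], t_end=20.0,
                                             output_grid=grid), x0=y0)
_, traj = imported.simulate((0.0, 20.0), y0=y0, t_eval=grid)
err = np.max(np.abs(traj - native.states)
             / np.maximum(np.abs(native.states).max(axis=0), 1e-12))
print(f"max relative trajectory difference native vs re-imported: {err:.2e}")
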