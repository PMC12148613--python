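"""Chronic Ang1 pre-stimulation protects against VEGF-driven Src signaling;
acute Ang1 does not.

Builds the packaged model, pre-equilibrates it, and compares peak Src and
VE-cadherin phosphorylation after 50 ng/mL VEGF with and without 25 min of
Ang1 (50 ng/mL) pre-stimulation, plus the simultaneous-addition control.
"""
import endosig as es
from endosig.experiments import run_ang1_protection

compiled = es.compile_rhs(es.build_default_model(), es.baseline_parameters())
rest = es.pre_equilibrate(compiled)

chronic = run_ang1_protection(compiled, mode="pre_25min", ang1_dose=50.0,
                              vegf_dose=50.0, x0=rest)
print(f"chronic (25 min Ang1 then VEGF):")
print(f"  peak-pSrc reduction    {chronic.psrc_reduction_percent:6.1f} %")
print(f"  peak-pVEcad reduction  {chronic.pvecad_reduction_percent:6.1f} %")
print(f"  Src sequestered @25min {100*chronic.sequestration_at_25min:6.1f} %")

for dose in (200.0, 500.0):
    acute = run_ang1_protection(compiled, mode="simultaneous",
                                ang1_dose=dose, vegf_dose=50.0, x0=rest)
    print(f"acute Ang1 {dose:.0f} ng/mL with VEGF: peak-pSrc reduction "
          f"{acute.psrc_reduction_percent:.1f} % (protection fails)")
print("\nInterpretation: sequestration of Src by RhoA-GTP/mDia needs ~20 min"
      "\nto develop, but VEGF activates Src within ~4 min - only chronic"
      "\nAng1 wins that race.")
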