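"""Inhibitor x Ang1 combination grids: predicted pTie2, pSrc, ppAkt and
pErk at 15 min after simultaneous stimulation."""
import endosig as es
from endosig.experiments import run_combination_grid

compiled = es.compile_rhs(es.build_default_model(), es.baseline_parameters())
rest = es.pre_equilibrate(compiled)
for target in ("Src", "VEGFR2"):
    grid = run_combination_grid(compiled, target, levels=(0.0, 0.8),
                                ang1_doses=(0.0, 500.0), x0=rest)
    print(f"\n{target} inhibitor grid (readouts at 15 min):")
    print(grid.pivot_table(index=["level", "ang1_dose"], columns="readout",
                           values="value").round(4))
print("\nSrc inhibition suppresses pSrc and dents ppAkt; Ang1 rescues ppAkt"
      "\nthrough Tie2->PI3K. VEGFR2 inhibition suppresses pErk too, and that"
      "\nloss is NOT rescued by Ang1.")
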