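"""Reduced Sobol main-effect analysis of the packaged model.

Runs the Saltelli first-order design at a small base sample so it finishes
in about a minute; the packaged analysis uses n_base 256.
"""
import endosig as es
from endosig.params import sensitivity_parameter_keys
from endosig.sensitivity import (SensitivityConfig, make_model_evaluator,
                                 sobol_first_order, rank_top)

params = es.baseline_parameters()
compiled = es.compile_rhs(es.build_default_model(), params)
keys = sensitivity_parameter_keys(params)
cfg = SensitivityConfig(parameters=keys, n_base=32, bootstrap=100, seed=0)
evaluator = make_model_evaluator(compiled, cfg)
result = sobol_first_order(evaluator, cfg, {k: params[k] for k in keys})
print(f"model runs: {result.n_runs}  (N*(d+2) with N={cfg.n_base}, d={len(keys)})")
for output in ("ppAkt", "pSrc"):
    print(f"\ntop-5 main effects for {output}:")
    for k, (s, lo, hi) in rank_top(result, output, 5):
        print(f"  {k:20s} S={s:+.3f}  [{lo:+.3f}, {hi:+.3f}]")
print("\nIndices are noisy at this tiny N - mind the bootstrap intervals.")
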