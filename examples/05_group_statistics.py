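"""Full pipeline at the study's group sizes: simulate, ALPS, group statistics.

Simulates 79 PD / 57 iRBD / 48 HC subjects with group ALPS means
1.21 / 1.24 / 1.28 and an age decline of -0.008 per year, runs both ROI
methods, age-adjusts using the control-fitted slope, and prints the
ANCOVA (sex covariate) with LSD pairwise p-values and partial eta^2.
"""

from dtialps.pipeline import PipelineConfig, run_pipeline
from dtialps.synthetic import CohortConfig

cfg = PipelineConfig(
    output_dir="scratch/example_groups",
    seed=2024,
    cohort=CohortConfig(exclusion_rates={}, seed=2024),
)
_, res = run_pipeline(cfg)

model = res["stats"]["age_models"]["automatic_average"]
print(f"control-fitted age slope beta = {model['beta']:.4f} /yr "
      f"(configured -0.0080), control mean age {model['age_mean']:.1f} y")

entry = res["stats"]["ancova"]["automatic_average"]
print(f"\nautomatic average ALPS, age-adjusted (n = {entry['n']}):")
for g, (m, s) in sorted(entry["group_mean_sd"].items()):
    print(f"  {g:>4}: {m:.3f} +/- {s:.3f}")
print(f"  ANCOVA F({entry['df1']},{entry['df2']}) = {entry['f']:.3f}, "
      f"p = {entry['p']:.4f}, partial eta^2 = {entry['partial_eta_sq']:.3f}")
for pair, p in entry["pairwise_p"].items():
    print(f"  LSD {pair}: p = {p:.4f}")
print(
    "\nThe group ordering PD < iRBD < HC and the significant PD contrasts"
    "\nmirror the configured group means; the partial eta^2 sizes the group"
    "\neffect after the sex covariate."
)
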