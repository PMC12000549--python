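"""Manual-vs-automatic method agreement on a noisy simulated cohort.

Runs a 60-subject cohort through the DWI route (Rician noise, tensor fit),
computes both ROI methods' indices, and prints the reliability battery:
paired t with Cohen's d, Pearson r, and Bland-Altman limits of agreement.
"""

from dtialps.pipeline import PipelineConfig, run_pipeline
from dtialps.synthetic import CohortConfig

cfg = PipelineConfig(
    output_dir="scratch/example_agreement",
    seed=11,
    use_dwi=True,  # simulate raw DWI and fit tensors per subject
    cohort=CohortConfig(
        n_per_group={"PD": 20, "iRBD": 20, "HC": 20}, exclusion_rates={}, seed=11
    ),
)
_, res = run_pipeline(cfg)
rel = res["stats"]["reliability"]["average"]

t = rel["paired_t"]
print(f"paired t({t['df']}) = {t['t']:.3f}, p = {t['p']:.3g}, Cohen's d = {t['d']:.3f}")
r = rel["pearson"]
print(f"Pearson r({r['df']}) = {r['r']:.3f}, p = {r['p']:.3g}")
ba = rel["bland_altman_numeric"]
print(
    f"Bland-Altman: bias {ba['bias']:.4f}, limits [{ba['loa_low']:.4f}, "
    f"{ba['loa_high']:.4f}], {100 * ba['fraction_outside']:.1f}% outside"
)
print(
    "\nBoth methods sample the same homogeneous synthetic columns, so the"
    "\nbias is ~0 and the limits of agreement reflect only acquisition noise;"
    "\non real data a systematic manual/automatic offset would appear as bias."
)
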