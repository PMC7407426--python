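"""Full cohort analysis with the per-ROI statistical battery.

Runs the whole chain on a small synthetic cohort (analytic displacement
backend for speed) and prints, per group, the percentage of testable ROIs
flagged by each family: paired strain change (Wilcoxon signed-rank),
SPI vs 1.0 (one-sample signed-rank), and SHI change (Feltz-Miller CV
equality).  The SB group was generated with uniform strain amplification,
the MV group is a null.
"""

import json

from lungstrain import PhantomSpec, RunConfig, run_cohort

cfg = RunConfig(
    phantom=PhantomSpec(grid_shape=(48, 48, 48), lung_axes=(1.8, 1.5, 1.6)),
    n_per_group=5,
    backend="ground_truth",
    sample_cap=1000,
    seed=2,
)
result = run_cohort(cfg)
print(json.dumps(result.summary["families"], indent=2))
print("-> SB flags ~100 % for progression families; MV stays near the 5 % level.")
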