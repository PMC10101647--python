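"""Run the full configurable pipeline and correct a p-value family.

The pipeline simulates (or loads) axon series, runs all three analyses and
writes tidy CSVs plus a manifest — deterministic for a fixed seed.  The
two-stage linear step-up procedure then illustrates how a family of
post-hoc p-values from downstream group tests would be FDR-corrected.
"""

import numpy as np

from arbordyn.pipeline import RunConfig, run_pipeline
from arbordyn.stats import bky_adjust

cfg = RunConfig(seed=1, out_dir="arbordyn_demo_out", n_axons=3, n_reps=50)
tables = run_pipeline(cfg)
for name, df in tables.items():
    print(f"{name}.csv: {len(df)} rows, columns {list(df.columns)[:5]}...")

spatial = tables["spatial"]
sync = spatial[(spatial.kind == "elimination") & (spatial.epoch == "sync")]
print("\nsync elimination normalized ratios per axon:")
print(sync[["axon_id", "n_events", "normalized_ratio"]].to_string(index=False))

# a small illustrative p-value family (e.g. post-hoc comparisons)
pvals = np.array([0.001, 0.008, 0.021, 0.047, 0.12, 0.35, 0.80])
flags = bky_adjust(pvals, q=0.05)
print("\ntwo-stage step-up at q = 0.05:")
for p, f in zip(pvals, flags):
    print(f"  p = {p:5.3f}  ->  {'reject' if f else 'keep'}")
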