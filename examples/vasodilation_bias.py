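"""Quantify how tissue vasodilation biases breath-hold perfusion values.

Sweeps relative vasodilation over the typical 4-9% range for a
venous-dominated voxel with 4% baseline blood volume and prints the
recovered CBV and percentage error from the full pipeline.
"""

import numpy as np

from bhdsc import vasodilation_bias_experiment

table = vasodilation_bias_experiment(
    cbv_grid=[0.04],
    dcbv_grid=np.arange(0.0, 0.10, 0.01),
    compositions=("venous_dominated",),
)

print(table[["dcbv_rel", "cbv_recovered", "pct_error", "cbf_pct_error",
             "mtt_ratio"]].to_string(index=False,
                                     float_format=lambda v: f"{v:8.2f}"))
print(
    "\nA 4-9% vasodilation during the hold underestimates CBV by roughly"
    "\n20-40% (a true 4% reads ~2.8% at the midpoint); CBF shows the same"
    "\nbias, so MTT is nearly untouched (mtt_ratio ~ 1)."
)
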