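"""Simulate single-voxel breath-hold responses with the compartment model.

Builds three voxels -- a large vessel that only vasodilates, and
venous-dominated tissue that only oxygenates, at 3 T and 7 T -- and prints
the apparent relaxation-rate change each produces.  The signs are the core
of the breath-hold AIF idea: vasodilation makes a vessel voxel *darker*
(positive dR2*), oxygenation makes tissue *brighter* (negative dR2*), and
both effects are larger at 7 T.
"""

import numpy as np

from bhdsc import BolusDynamics, FieldParams, composition_preset, simulate_voxel_signal

no_oxy = {"arterial": 0.0, "capillary": 0.0, "venous": 0.0}
vaso_only = BolusDynamics(dY_peak=no_oxy, dcbv_rel_peak=0.065)
oxy_only = BolusDynamics(dcbv_rel_peak=0.0)

print(f"{'voxel':<28}{'field':>6}{'peak dS %':>12}{'dR2* AUC (1/s*s)':>18}")
for fp in (FieldParams.from_field(3), FieldParams.from_field(7)):
    for name, comp, dyn in [
        ("large vessel, vasodilation", composition_preset("large_vessel_csf"), vaso_only),
        ("venous tissue, oxygenation", composition_preset("venous_dominated"), oxy_only),
    ]:
        t, s = simulate_voxel_signal(comp, fp, dyn, total_s=120.0)
        s0 = s[:8].mean()
        ds = 100.0 * (s / s0 - 1.0)
        auc = np.trapezoid(-np.log(s / s0) / fp.TE, t)
        peak = ds[np.argmax(np.abs(ds))]
        print(f"{name:<28}{fp.field_strength:>4.0f} T{peak:>12.2f}{auc:>18.2f}")

print(
    "\nPositive AUC = signal dip (vasodilating vessel, the AIF signature);"
    "\nnegative AUC = signal rise (oxygenated tissue); |AUC| grows with field."
)
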