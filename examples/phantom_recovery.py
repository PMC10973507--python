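"""Generate a breath-hold phantom and recover its perfusion parameters.

Builds the default 16x16 phantom (GM CBV 4%, WM 2%, MTT 4 s, artery and
vein strips) at 7 T, runs the full pipeline -- bolus averaging, AIF/VOF
selection, VOF scaling, truncated-SVD deconvolution, delay mapping -- and
prints recovered vs true values per region.
"""

import warnings

import numpy as np

from bhdsc import BreathHoldProtocol, FieldParams, PipelineConfig, run_pipeline
from bhdsc.phantom import PhantomLayout, generate_phantom

protocol = BreathHoldProtocol()
fp = FieldParams.from_field(7)
layout = PhantomLayout.default()
ts, truth = generate_phantom(protocol, fp, noise_sd=0.0, seed=1)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    out = run_pipeline(ts, layout.mask("artery"), layout.mask("vein"),
                       PipelineConfig(detrend=False))

res = out.perfusion
print(f"{'region':<8}{'CBV true':>10}{'CBV rec':>10}{'MTT rec (s)':>12}"
      f"{'delay rec (s)':>14}{'delay true':>12}")
for region in ("gm", "wm"):
    m = layout.mask(region) & res.valid_mask
    print(f"{region:<8}{np.nanmean(truth.cbv[layout.mask(region)]):>10.3f}"
          f"{np.nanmean(res.CBV[m]):>10.4f}{np.nanmean(res.MTT[m]):>12.2f}"
          f"{np.nanmean(out.delay.delay[m]):>14.1f}"
          f"{np.nanmean(truth.delay[layout.mask(region)]):>12.1f}")

ratio = np.nanmean(res.CBV[layout.mask('gm') & res.valid_mask]) / \
    np.nanmean(res.CBV[layout.mask('wm') & res.valid_mask])
print(f"\nGM/WM CBV ratio: {ratio:.2f} (truth 2.0)")
print("MTT reads high because a ~35 s bolus is much longer than a contrast "
      "injection;\nthe GM/WM contrast and delays are preserved.")
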