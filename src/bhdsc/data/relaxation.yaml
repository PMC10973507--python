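# Field-strength-specific relaxation parameters for the multi-compartment
# GRE signal model.
#
# Intravascular model:  R2*_iv(Y) = iv_a + iv_b * (1 - Y)^2   [1/s]
# Extravascular model:  dR2*_ev  = r_ev * sum_p f_p * (1 - Y_p)  [1/s]
#
# Coefficients are calibrated so that (i) tissue/vein oxygenation responses
# are roughly twice as large at 7 T as at 3 T, and (ii) the intravascular
# share of the oxygenation-driven signal-change sensitivity of a tissue
# voxel falls in 10-40% at 3 T and 0-5% at 7 T.
"3":
  TE: 0.030          # s
  r2s_tissue: 20.0   # 1/s, baseline extravascular tissue R2*
  r2s_csf: 4.0       # 1/s
  iv_a: 12.0         # 1/s
  iv_b: 140.0        # 1/s
  r_ev: 150.0        # 1/s per unit (blood volume fraction * (1-Y))
"7":
  TE: 0.020
  r2s_tissue: 33.0
  r2s_csf: 5.0
  iv_a: 30.0
  iv_b: 2800.0
  r_ev: 275.0
TR: 2.0              # s
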