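# Methods

This note documents the models behind `bhdsc`, the parameter choices that
matter, what the synthetic data do and do not emulate, and the numerical
conventions.

## Signal model

Each voxel is a volume-fraction-weighted sum of mono-exponential
compartments sampled at echo time TE:

    S(t) = S0 · [ f_t(t) e^{−TE·R2*_ev(t)} + f_csf(t) e^{−TE·R2*_csf}
                  + Σ_p f_p(t) e^{−TE·R2*_iv(Y_p(t))} ]

with blood pools p ∈ {arterial, capillary, venous}. Two relaxation rules
carry the deoxyhemoglobin physics:

- **Intravascular:** R2\*_iv(Y) = a + b·(1−Y)², the standard quadratic
  dependence on deoxygenation, monotonically decreasing in oxygenation Y.
- **Extravascular:** R2\*_ev = R2\*_tissue + r_ev · Σ_p f_p·(1−Y_p),
  linear in deoxygenated blood volume (static-dephasing regime), with
  r_ev(7 T) > r_ev(3 T).

Coefficients live in `src/bhdsc/data/relaxation.yaml`, not in code:

| field | TE (s) | R2\*_t | R2\*_csf | a | b | r_ev |
|-------|--------|--------|----------|----|------|------|
| 3 T   | 0.030  | 20     | 4        | 12 | 140  | 150  |
| 7 T   | 0.020  | 33     | 5        | 30 | 2800 | 275  |

They were set so that (i) venous blood is essentially MR-invisible at 7 T
but not at 3 T, (ii) tissue/vein oxygenation responses are roughly 2–3×
larger at 7 T, and (iii) the intravascular share of the oxygenation-driven
signal-change sensitivity of a tissue voxel lands in the 10–40 % window at
3 T and 0–5 % at 7 T (the established field-dependence of the BOLD
intravascular contribution). That share is computed by
`intravascular_change_fraction` as the intravascular term of dS/dY at
baseline; a dedicated property test pins both windows.

**Vasodilation** multiplies all blood pools by (1 + ΔCBV_rel(t)); the
added volume displaces CSF first, then tissue, proportionally once CSF is
exhausted. Expanding a large vessel therefore swaps bright CSF for dark
blood — a signal *decrease* with no oxygenation change, which is the
breath-hold arterial input function. A `include_csf=False` preset variant
removes CSF from the voxel, which strongly weakens the 3 T dip (at 3 T
the effect rides almost entirely on CSF–blood contrast).

**Dynamics.** Oxygenation and vasodilation follow one raised-cosine pulse
(smooth, compactly supported; the functional form is a modelling choice),
duration 35 s at tissue for a 16 s hold, onset 12 s after the hold starts
(lung-to-brain CO₂ lag, 10–15 s physiologically). Baseline oxygenations:
arterial 0.98, capillary 0.65, venous 0.60. The oxygenation-bolus peak is
ΔY = 0.14 (venous saturation 0.60 → 0.74): ΔY sets the scale of the
oxygenation response against which the vasodilation dip competes, and this
value both lies within the hypercapnia literature and reproduces the
observed magnitude of vasodilation-induced CBV bias; it is the package's
study condition and is not a per-experiment dial. Simulation runs on an
internal 0.5 s grid, box-car resampled to TR = 2 s, to avoid aliasing the
16 s hold.

**Composition presets.** Exact per-voxel vascular compositions are not
observable; four canonical presets are shipped as stand-ins (blood split
arterial/capillary/venous): arterial-dominated 0.4/0.3/0.3, capillary
0.1/0.6/0.3, venous-dominated 0.1/0.2/0.7 (tissue presets: 4 % blood, 5 %
CSF by default) and large-vessel+CSF 0.9/0/0.1 (30 % blood, 25 % CSF).
Splits follow vascular anatomy: even an "arterial-dominated" tissue voxel
keeps most of its microvascular blood in capillaries and veins.

## Phantom with ground truth

`generate_phantom` couples two layers. Artery voxels use the biophysical
model above (vasodilation-only large vessel). Tissue and vein voxels are
built from indicator-dilution kinetics on a latent arterial concentration
train c_a(t): tissue ΔR2\*(t) = (ρ/k_H)·CBF·(c_a(·−d) ⊗ e^{−t/MTT}), vein
= delayed c_a convolved with a normalized exponential transport kernel
(τ = 5 s, integral preserved). This makes ground-truth CBV/CBF/MTT exact
by construction (MTT = CBV/CBF), so absolute parameter recovery is a
well-posed test. Defaults: GM CBV 4 %, WM 2 %, MTT 4 s, delays
artery 0 < GM 1 < WM 2 < vein 2.5 s; S0 500/450/700/300/600 for
GM/WM/artery/vein/CSF; additive Gaussian noise sd 0.5 (×3 in vessel
voxels, emulating pulsatility), which puts the preprocessed GM CNR near
the observed 7 T scale (~9) and WM near half of it. The latent input peak
is 3.0 s⁻¹ at 7 T and 1.0 s⁻¹ at 3 T.

What the phantom does **not** emulate: the phantom vein reports the latent
concentration faithfully, which is what makes recovery unbiased — real
veins under-report concentration at 7 T (intravascular signal is dead),
which is exactly why in-vivo DSC values are relative. Consequently the
phantom's tissue amplitudes are small relative to its vein (ratio fixed at
(ρ/k_H)·CBV), its signal amplitudes are not field-realistic, and there is
no motion, drift beyond the linear model, physiological noise structure,
or partial-volume mixing between regions. Passing recovery tests therefore
demonstrates correctness of the estimator chain, not in-vivo accuracy.

Ground-truth **delay** is defined as the correlation-delay observable
evaluated on the noise-free bolus-averaged curves, because the
shift-and-correlate estimator conflates arrival delay, transit and
dispersion (tissue reads arrival + ~MTT). Pure-shift constructions test
the estimator's exactness independently.

## Vasodilation-bias experiment

`vasodilation_bias_experiment` simulates a tissue voxel with the
oxygenation bolus plus vasodilation locked to the same time course, a
vasodilation-only large-vessel AIF, and an oxygenation-only venous VOF,
and runs the complete measurement chain (apparent ΔR2\*, truncation, VOF
scaling, truncated-SVD deconvolution). Because every recovered value is
relative, the error attributable to vasodilation is defined against the
identical pipeline with ΔCBV = 0:
pct_error = 100·(CBV_with − CBV_without)/CBV_without. Two mechanisms
drive the bias, both proportional to ΔCBV: blood displacing
brighter CSF/tissue, and the added deoxygenated blood volume raising
extravascular dephasing; the oxygenation response is proportional to ΔY,
so the relative error scales like ΔCBV/ΔY and is nearly independent of
baseline CBV and composition (spread < 10 percentage points across the
presets). CBF inherits the same scaling (the dip shares the tissue bolus
shape), leaving MTT within a few percent.

## Pipeline conventions and numerics

- **Bolus averaging:** block peaks are located on the brain-mean reference
  within [hold onset + 5 s, block end + 20 s] (the physiological lag makes
  earlier maxima noise), and one common 72 s window per block is applied
  to all voxels so inter-voxel delays survive averaging. Windows at the
  series edge are padded by edge value with a warning.
- **Baselines:** S0 and ε_t use ten volumes immediately before bolus onset
  plus ten after return to baseline, where onset/return are the last/first
  samples within one baseline SD of the pre-bolus mean; a `baseline_n`
  option switches to the stricter ten-total reading (5 + 5).
- **Smoothing:** length-5 normalized Gaussian, σ = 1 sample, reflection at
  the edges; detrending removes the per-voxel least-squares slope and
  preserves the mean.
- **Bolus edges:** first/last crossing of 10 % of the peak |ΔR2\*| with at
  least two consecutive supra-threshold samples.
- **Selection:** percentiles are computed within the candidate mask (and
  within the correct sign class), so the rule is invariant to global
  rescaling; "short delay" is ≤ 0.5 s on the delay grid, "low S0" is
  below the candidate median; the VOF delay window [1.5, 4.0] s is relaxed
  progressively (with a warning) when it empties — the shipped phantom
  exercises this path because its vein carries the full transit delay.
  Selections keep the top-|ΔS| 15–20 voxels, backfilling from the ranked
  candidate pool when the percentile cut leaves fewer than 15.
- **Deconvolution:** signed ΔR2\* curves are used throughout (the VOF
  scaling makes AIF, tissue and VOF share one sign); rectangle-rule
  Toeplitz discretization, non-circulant, no delay-insensitive variant —
  delay is estimated separately by shifting. Integrals are trapezoidal on
  the truncated window. Singular values below 20 % of the largest are
  zeroed; a zero convolution matrix is rejected.
- **Exclusions:** negative-CBV/CBF voxels are dropped from the validity
  mask and summaries but kept in the maps (negative values are meaningful
  in steal physiology). Zero-variance voxels get NaN delays; zero ε_t
  flags a voxel invalid rather than producing infinite CNR.
- **Radical fit:** in a·√(b·x)+c only a·√b is identifiable; the fit is an
  exact linear least-squares in √x, reported with b = 1.
- **ICC:** one-way random-effects single-measurement estimator
  ICC(1,1) = (MSB − MSW)/(MSB + (k−1)·MSW) over all 70 choose-4-of-8
  combinations; a `literal_within_total` flag returns the within/total
  reading instead.

## Problem sizes

The shipped phantom is a 16×16×1 grid (120 GM, 80 WM, 20 artery, 20 vein,
12 CSF voxels) over 310 volumes; the bias experiment uses single-voxel,
single-bolus simulations on a 120 s grid. These sizes keep every analysis
in this package deterministic and fast while leaving enough voxels for
stable region means (the GM region alone gives <2 % standard error on the
mean CNR).

## Known limitations

- The kinetic model assumes constant CBV/CBF during the bolus; the bias
  experiment quantifies, but the pipeline does not correct, the violation.
- MTT is systematically inflated for long boluses (a 35 s bolus roughly
  doubles it versus a 5 s bolus at MTT 4 s) — an inherent truncated-SVD
  property, reproduced and tested rather than corrected.
- Relaxation coefficients are plausible calibrations, not measurements;
  all recovered values are relative (a.u.), and cross-field comparisons
  inherit the intravascular-contribution asymmetry.
- No motion/distortion/slice-timing handling: inputs are assumed
  preprocessed (or synthetic).
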