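"""Synthetic breath-hold phantom with known perfusion ground truth.

The phantom couples two model layers:

* **Tissue and vein voxels** are built from indicator-dilution kinetics on
  a latent arterial concentration train ``c_a(t)`` (one raised-cosine
  bolus per breath-hold block, onset 12 s after each hold):
  ``dR2*_tis(t) = (rho/k_H) * CBF * (c_a(. - d) * e^{-t/MTT})`` and
  ``VOF(t) = (c_a(. - d_vein) * h)`` with a normalized exponential
  transport kernel (integral preserved).  This guarantees exact ground
  truth CBV/CBF/MTT under the central volume principle and makes absolute
  parameter recovery well-posed -- the phantom's vein reports the latent
  concentration faithfully, an idealization real veins do not satisfy.
* **Artery voxels** use the biophysical multi-compartment model: a large
  vessel adjacent to CSF that vasodilates with no oxygenation change,
  producing the negative-going signal that defines the breath-hold AIF.

Signals are ``S = S0 * exp(-TE * dR2*_app)`` per region baseline, with
additive Gaussian noise (vessel voxels noisier, emulating pulsatility).
Ground-truth delay is the correlation-delay observable evaluated on the
noise-free bolus-averaged curves, since arrival delay, transit and
dispersion are not separable in the delay maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import preprocess
from .delay import estimate_delay
from .params import (
    BolusDynamics,
    BreathHoldProtocol,
    FieldParams,
    composition_preset,
)
from .perfusion import KineticConstants
from .simulator import FINE_DT, boxcar_resample, fine_grid, simulate_voxel_signal

REGION_CODES = {"background": 0, "gm": 1, "wm": 2, "csf": 3, "artery": 4, "vein": 5}

#: Latent input peak amplitude (1/s of apparent dR2*), field dependent:
#: breath-hold relaxation responses are roughly 2-3x larger at 7 T.
DEFAULT_INPUT_PEAK = {3.0: 1.0, 7.0: 3.0}

VEIN_TRANSPORT_S = 5.0  # venous transport-kernel time constant
ARTERY_DCBV_REL = 0.065  # arterial vasodilation, middle of the 4-9% range


@dataclass(frozen=True)
class RegionSpec:
    name: str
    cbv: float = np.nan  # blood volume fraction (tissue regions)
    mtt_s: float = np.nan
    delay_s: float = 0.0
    S0: float = 500.0
    noise_factor: float = 1.0


DEFAULT_REGIONS = (
    RegionSpec("gm", cbv=0.04, mtt_s=4.0, delay_s=1.0, S0=500.0),
    RegionSpec("wm", cbv=0.02, mtt_s=4.0, delay_s=2.0, S0=450.0),
    RegionSpec("csf", S0=600.0),
    RegionSpec("artery", delay_s=0.0, S0=700.0, noise_factor=3.0),
    RegionSpec("vein", delay_s=2.5, S0=300.0, noise_factor=3.0),
)

DEFAULT_COUNTS = {"gm": 120, "wm": 80, "csf": 12, "artery": 20, "vein": 20}


@dataclass
class PhantomLayout:
    """Integer-labeled region geometry plus per-region specifications."""

    labels: np.ndarray
    regions: dict

    def mask(self, name: str) -> np.ndarray:
        return self.labels == REGION_CODES[name]

    @classmethod
    def default(cls, shape=(16, 16, 1), counts: dict | None = None,
                regions=DEFAULT_REGIONS) -> "PhantomLayout":
        counts = dict(DEFAULT_COUNTS if counts is None else counts)
        n = int(np.prod(shape))
        if sum(counts.values()) > n:
            raise ValueError("region counts exceed grid size")
        flat = np.zeros(n, dtype=np.int16)
        pos = 0
        for name in ("gm", "wm", "csf", "artery", "vein"):
            c = counts.get(name, 0)
            flat[pos : pos + c] = REGION_CODES[name]
            pos += c
        return cls(labels=flat.reshape(shape), regions={r.name: r for r in regions})


@dataclass
class PhantomGroundTruth:
    labels: np.ndarray
    cbv: np.ndarray
    cbf: np.ndarray
    mtt: np.ndarray
    delay: np.ndarray
    S0: np.ndarray
    pve_gm: np.ndarray
    pve_wm: np.ndarray
    region_curves: dict = field(default_factory=dict)  # clean windowed dR2*


def _exp_kernel(tau_s: float, dt: float, length_s: float = 60.0) -> np.ndarray:
    t = np.arange(0.0, length_s, dt)
    k = np.exp(-t / tau_s)
    return k


def _kinetic_curves(protocol, fp, regions, dyn, input_peak):
    """Fine-grid apparent dR2* curves for tissue and vein regions."""
    consts = KineticConstants()
    tf = fine_grid(protocol.total_s)
    curves = {}
    for name, spec in regions.items():
        if name in ("artery", "csf", "background"):
            continue
        d = BolusDynamics(
            onset_delay_s=dyn.onset_delay_s,
            duration_s=dyn.duration_s,
            delay_s=spec.delay_s,
        )
        c_in = input_peak * d.shape_train(tf, protocol)
        if name == "vein":
            h = _exp_kernel(VEIN_TRANSPORT_S, FINE_DT)
            h = h / (h.sum() * FINE_DT)  # normalized: integral preserved
            curve = -FINE_DT * np.convolve(c_in, h)[: tf.size]
        else:
            R = _exp_kernel(spec.mtt_s, FINE_DT)  # residue, integral = MTT
            cbf = spec.cbv / spec.mtt_s
            curve = -(1.0 / consts.scale) * cbf * FINE_DT * np.convolve(c_in, R)[: tf.size]
        curves[name] = boxcar_resample(curve, FINE_DT, fp.TR)
    return curves


def _artery_curve(protocol, fp, dyn, dcbv_rel):
    comp = composition_preset("large_vessel_csf")
    d = BolusDynamics(
        onset_delay_s=dyn.onset_delay_s,
        duration_s=dyn.duration_s,
        delay_s=0.0,
        dY_peak={"arterial": 0.0, "capillary": 0.0, "venous": 0.0},
        dcbv_rel_peak=dcbv_rel,
    )
    t, s = simulate_voxel_signal(comp, fp, d, protocol=protocol)
    return s / s[0]  # relative signal; baseline 1


def _ground_truth_delays(clean_ts, protocol, layout):
    """Correlation-delay observable on noise-free bolus-averaged curves."""
    bav = preprocess.average_boluses(clean_ts, protocol)
    rs = preprocess.bolus_average_to_relaxation(bav)
    ref = rs.dR2s[layout.mask("artery")].mean(axis=0)
    delays = {}
    curves = {}
    for name in layout.regions:
        m = layout.mask(name)
        if not m.any():
            continue
        curve = rs.dR2s[m].mean(axis=0)
        curves[name] = curve
        if name == "csf":
            delays[name] = np.nan
            continue
        d, _ = estimate_delay(-curve if name == "artery" else curve, -ref, rs.t)
        delays[name] = d
    return delays, curves


def generate_phantom(
    protocol: BreathHoldProtocol,
    fp: FieldParams,
    layout: PhantomLayout | None = None,
    noise_sd: float = 0.5,
    seed: int = 0,
    dyn: BolusDynamics | None = None,
    input_peak: float | None = None,
    artery_dcbv_rel: float = ARTERY_DCBV_REL,
):
    """Generate a 4D breath-hold phantom and its ground truth.

    Returns ``(TimeSeries4D, PhantomGroundTruth)``.  ``noise_sd`` is the
    additive Gaussian noise standard deviation in signal units (scaled by
    each region's ``noise_factor``); identical seeds give bit-identical
    phantoms.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if layout is None:
        layout = PhantomLayout.default()
    if dyn is None:
        dyn = BolusDynamics()
    if input_peak is None:
        input_peak = DEFAULT_INPUT_PEAK.get(fp.field_strength, 3.0)

    curves = _kinetic_curves(protocol, fp, layout.regions, dyn, input_peak)
    art_rel = _artery_curve(protocol, fp, dyn, artery_dcbv_rel)
    n_t = art_rel.size

    shape = layout.labels.shape
    data = np.zeros(shape + (n_t,), dtype=float)
    S0 = np.zeros(shape)
    cbv = np.full(shape, np.nan)
    cbf = np.full(shape, np.nan)
    mtt = np.full(shape, np.nan)
    for name, spec in layout.regions.items():
        m = layout.mask(name)
        if not m.any():
            continue
        S0[m] = spec.S0
        if name == "artery":
            data[m] = spec.S0 * art_rel
        elif name in curves:
            data[m] = spec.S0 * np.exp(-fp.TE * curves[name])
            if np.isfinite(spec.cbv):
                cbv[m] = spec.cbv
                mtt[m] = spec.mtt_s
                cbf[m] = spec.cbv / spec.mtt_s
        else:  # csf: flat baseline
            data[m] = spec.S0

    clean = preprocess.TimeSeries4D(
        data.copy(), TR=fp.TR, TE=fp.TE, field_strength=fp.field_strength,
        brain_mask=layout.labels > 0,
    )
    delays, clean_curves = _ground_truth_delays(clean, protocol, layout)
    delay_map_true = np.full(shape, np.nan)
    for name in delays:
        delay_map_true[layout.mask(name)] = delays[name]

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(data.shape)
    for name, spec in layout.regions.items():
        m = layout.mask(name)
        data[m] += noise_sd * spec.noise_factor * noise[m]

    ts = preprocess.TimeSeries4D(
        data, TR=fp.TR, TE=fp.TE, field_strength=fp.field_strength,
        brain_mask=layout.labels > 0,
    )
    gt = PhantomGroundTruth(
        labels=layout.labels.copy(),
        cbv=cbv, cbf=cbf, mtt=mtt, delay=delay_map_true, S0=S0,
        pve_gm=np.where(layout.mask("gm"), 0.95, 0.0),
        pve_wm=np.where(layout.mask("wm"), 0.95, 0.0),
        region_curves=clean_curves,
    )
    return ts, gt
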