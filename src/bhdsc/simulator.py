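"""Multi-compartment gradient-echo signal model.

A voxel's signal is the volume-fraction-weighted sum of mono-exponential
compartments,

    S(t) = S0 * [ f_t(t) e^{-TE R2*_ev(t)} + f_csf(t) e^{-TE R2*_csf}
                  + sum_p f_p(t) e^{-TE R2*_iv(Y_p(t))} ],

where the extravascular rate carries the linear deoxyhemoglobin
perturbation R2*_ev(t) = R2*_tissue + r_ev * sum_p f_p(t) (1 - Y_p(t)).
Vasodilation scales the blood pools by (1 + dCBV_rel(t)); the added blood
volume displaces CSF first and then tissue, so a large vessel expanding
into bright CSF produces a signal *decrease* (apparent relaxation-rate
increase) even with no oxygenation change -- the mechanism behind the
breath-hold arterial input function.

Time courses are evaluated on an internal fine grid (default 0.5 s) and
box-car resampled to the acquisition TR to avoid aliasing the 16 s hold.
"""

from __future__ import annotations

import numpy as np

from .params import (
    BLOOD_POOLS,
    BolusDynamics,
    BreathHoldProtocol,
    FieldParams,
    VoxelComposition,
)

FINE_DT = 0.5  # s, internal simulation grid


class CompositionOverflowError(ValueError):
    """Vasodilation would displace more volume than is available."""


def fine_grid(total_s: float, dt: float = FINE_DT) -> np.ndarray:
    n = int(round(total_s / dt))
    return (np.arange(n) + 0.5) * dt


def boxcar_resample(x: np.ndarray, dt_fine: float, TR: float) -> np.ndarray:
    """Average consecutive fine-grid samples into TR-length bins."""
    ratio = TR / dt_fine
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("TR must be an integer multiple of the fine grid step")
    r = int(round(ratio))
    n = (x.shape[-1] // r) * r
    return x[..., :n].reshape(*x.shape[:-1], -1, r).mean(axis=-1)


def _displaced_fractions(comp: VoxelComposition, dcbv_rel: np.ndarray):
    """Time-resolved compartment fractions under vasodilation.

    Blood pools scale by (1 + dcbv_rel); the extra volume comes out of CSF
    first, then tissue, keeping the fractions summing to one.
    """
    fb0 = comp.total_blood
    extra = fb0 * dcbv_rel
    # CSF absorbs displacement up to its own volume, remainder from tissue.
    from_csf = np.minimum(extra, comp.f_csf)
    from_tissue = extra - from_csf
    f_tissue = comp.f_tissue - from_tissue
    if np.any(f_tissue < -1e-12):
        raise CompositionOverflowError(
            "vasodilation displaces more volume than tissue+CSF provide"
        )
    f_csf = comp.f_csf - from_csf
    pools = {p: comp.f_blood.get(p, 0.0) * (1.0 + dcbv_rel) for p in BLOOD_POOLS}
    return f_tissue, f_csf, pools


def compartment_signal(
    comp: VoxelComposition,
    fp: FieldParams,
    dY: dict | None = None,
    dcbv_rel: float | np.ndarray = 0.0,
):
    """Normalized voxel signal for given oxygenation shifts and vasodilation.

    ``dY`` maps pool name -> oxygenation increment (scalar or array);
    ``dcbv_rel`` is the relative blood-volume increase. Returns the signal
    in absolute (S0-free) units.
    """
    dY = dY or {}
    dcbv_rel = np.asarray(dcbv_rel, dtype=float)
    f_tissue, f_csf, pools = _displaced_fractions(comp, dcbv_rel)
    r_ev = fp.ev_relaxivity(comp.vessel_class)

    dohb = np.zeros_like(dcbv_rel, dtype=float)
    s = np.zeros_like(dcbv_rel, dtype=float)
    for pool, f_p in pools.items():
        Y = np.clip(comp.Y_baseline.get(pool, 1.0) + np.asarray(dY.get(pool, 0.0)), 0.0, 1.0)
        dohb = dohb + f_p * (1.0 - Y)
        s = s + f_p * np.exp(-fp.TE * fp.r2s_iv(Y))
    r2_ev = fp.r2s_tissue + r_ev * dohb
    s = s + f_tissue * np.exp(-fp.TE * r2_ev)
    s = s + f_csf * np.exp(-fp.TE * fp.r2s_csf)
    return s


def simulate_voxel_signal(
    comp: VoxelComposition,
    fp: FieldParams,
    dyn: BolusDynamics,
    total_s: float = 120.0,
    protocol: BreathHoldProtocol | None = None,
    S0: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one voxel's signal time course S(t) at the acquisition TR.

    Returns ``(t, S)`` where ``t`` are TR-grid sample times (bin centers).
    With ``protocol`` given, the dynamics repeat over all breath-hold
    blocks; otherwise a single bolus is simulated over ``total_s``.
    """
    if protocol is not None:
        total_s = protocol.total_s
    tf = fine_grid(total_s)
    dY = {p: dyn.dY(tf, p, protocol) for p in BLOOD_POOLS}
    dcbv = dyn.dcbv_rel(tf, protocol)
    s = compartment_signal(comp, fp, dY, dcbv)
    s_tr = boxcar_resample(s, FINE_DT, fp.TR)
    n = s_tr.shape[-1]
    t_tr = (np.arange(n) + 0.5) * fp.TR
    return t_tr, S0 * s_tr


def intravascular_change_fraction(comp: VoxelComposition, fp: FieldParams) -> float:
    """Intravascular share of the oxygenation-driven signal-change sensitivity.

    Decomposes dS/dY at baseline into the intravascular term (blood signal
    brightening as Y rises) and the extravascular term (reduced dephasing
    around vessels).  At 3 T the intravascular term is a sizable share of
    the response; at 7 T deoxygenated blood signal is essentially dead and
    the response is extravascular.
    """
    r_ev = fp.ev_relaxivity(comp.vessel_class)
    iv = 0.0
    dohb = 0.0
    f_resp = 0.0
    for pool, f_p in comp.f_blood.items():
        Y = comp.Y_baseline[pool]
        dohb += f_p * (1.0 - Y)
        if pool == "arterial":
            continue  # near-saturated pool does not carry the bolus
        iv += f_p * np.exp(-fp.TE * float(fp.r2s_iv(Y))) * 2.0 * fp.iv_b * (1.0 - Y)
        f_resp += f_p
    e_t = np.exp(-fp.TE * (fp.r2s_tissue + r_ev * dohb))
    ev = comp.f_tissue * e_t * r_ev * f_resp
    total = iv + ev
    if total <= 0:
        raise ValueError("composition has no oxygenation response")
    return float(iv / total)
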