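"""Model-independent bolus delay mapping.

Both the AIF and each voxel time course are linearly interpolated to a
0.5 s grid; the AIF is shifted forward in 0.5 s steps up to 8 s and the
shift maximizing the linear correlation over the overlap is the voxel's
delay (ties resolve to the smallest shift).  The resulting maps conflate
arrival delay, transit and dispersion -- there is no separate dispersion
parameter -- which is exactly what makes them model-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .input_functions import InputFunction
from .preprocess import RelaxationSeries

STEP_S = 0.5
MAX_SHIFT_S = 8.0


@dataclass
class DelayMap:
    delay: np.ndarray  # s, NaN where invalid
    r_max: np.ndarray
    valid: np.ndarray


def _interp_05(t: np.ndarray, x: np.ndarray, step: float):
    tf = np.arange(t[0], t[-1] + step / 2, step)
    return tf, np.interp(tf, t, x)


def estimate_delay(
    voxel: np.ndarray,
    aif: np.ndarray,
    t: np.ndarray,
    max_shift_s: float = MAX_SHIFT_S,
    step_s: float = STEP_S,
):
    """Delay of one voxel time course relative to the AIF.

    Returns ``(delay_s, r_max)``; ``(nan, nan)`` for a zero-variance voxel.
    """
    n_steps = int(round(max_shift_s / step_s))
    if abs(n_steps * step_s - max_shift_s) > 1e-9:
        raise ValueError("step must divide the maximum shift")
    _, a = _interp_05(t, aif, step_s)
    _, v = _interp_05(t, voxel, step_s)
    if np.std(v) == 0 or np.std(a) == 0:
        return np.nan, np.nan
    best_r, best_shift = -np.inf, np.nan
    for s in range(n_steps + 1):
        # AIF shifted forward by s samples; overlap region of both series
        aa = a[: len(a) - s] if s else a
        vv = v[s:]
        if len(aa) < 3 or np.std(aa) == 0 or np.std(vv) == 0:
            continue
        r = np.corrcoef(aa, vv)[0, 1]
        if r > best_r + 1e-12:  # ties keep the smallest shift
            best_r, best_shift = r, s * step_s
    return best_shift, best_r


def delay_map(
    rs: RelaxationSeries,
    aif: InputFunction | np.ndarray,
    mask: np.ndarray | None = None,
    max_shift_s: float = MAX_SHIFT_S,
    step_s: float = STEP_S,
) -> DelayMap:
    """Per-voxel delay map against the (sign-flipped, scaled) AIF.

    Correlation is invariant to affine rescaling of either series, so an
    unscaled AIF works too -- but using the scaled AIF makes tissue and
    AIF covary positively, keeping r_max interpretable.
    """
    if isinstance(aif, InputFunction):
        a = aif.timecourse
    else:
        a = np.asarray(aif, float)
    if mask is None:
        mask = rs.brain_mask if rs.brain_mask is not None else np.ones(rs.dR2s.shape[:-1], bool)
    shp = mask.shape
    delay = np.full(shp, np.nan)
    rmax = np.full(shp, np.nan)
    for idx in np.argwhere(mask):
        d, r = estimate_delay(rs.dR2s[tuple(idx)], a, rs.t, max_shift_s, step_s)
        delay[tuple(idx)] = d
        rmax[tuple(idx)] = r
    return DelayMap(delay=delay, r_max=rmax, valid=np.isfinite(delay))
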