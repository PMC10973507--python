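"""Time-course preprocessing: detrending/smoothing, breath-hold bolus
averaging, and conversion to percent signal change, contrast-to-noise and
apparent transverse relaxation rate.

Conventions
-----------
The bolus-averaged window is 72 s centered at the bolus maximum; baseline
signal S0 is the mean of ten temporal volumes immediately before bolus
onset and ten after the signal returns to baseline, and the baseline
temporal standard deviation eps_t is computed over the same volumes.
Percent signal change is ``100*|S_ext - S0|/S0`` with the sign of the
excursion stored separately, so that negative-going (vasodilation) voxels
keep their identity.  The apparent relaxation change is
``dR2*(t) = -(1/TE) * ln(S(t)/S0)``: a signal *increase* maps to a
*negative* dR2*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .params import BreathHoldProtocol

#: Normalized 1x5 Gaussian smoothing kernel (sigma = 1 sample).
GAUSS_KERNEL = np.exp(-0.5 * np.arange(-2, 3) ** 2)
GAUSS_KERNEL = GAUSS_KERNEL / GAUSS_KERNEL.sum()

#: Bolus-maximum search span relative to [hold onset, block end] in seconds.
SEARCH_PAD_AFTER_HOLD_S = 5.0
SEARCH_PAD_AFTER_BLOCK_S = 20.0


@dataclass
class TimeSeries4D:
    """A 4D (x, y, z, t) signal array with acquisition metadata."""

    data: np.ndarray
    TR: float
    TE: float
    field_strength: float = 7.0
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("expected a 4D (x, y, z, t) array")
        if self.TR <= 0 or self.TE <= 0:
            raise ValueError("TR and TE must be positive")
        if self.brain_mask is None:
            self.brain_mask = self.data.mean(axis=-1) > 0
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]


@dataclass
class BolusAverageMap:
    """Per-voxel bolus-averaged window with baseline bookkeeping.

    ``data`` holds the averaged 72 s windows (x, y, z, w); ``S0``,
    ``S_ext`` (extremum signal), ``sign`` (+1 positive-going, -1
    negative-going), and ``eps_t`` are 3D maps. ``t`` gives window sample
    times in seconds relative to the window start.
    """

    data: np.ndarray
    S0: np.ndarray
    S_ext: np.ndarray
    sign: np.ndarray
    eps_t: np.ndarray
    t: np.ndarray
    TR: float
    TE: float
    n_boluses_used: int
    brain_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_window(self) -> int:
        return self.data.shape[-1]


@dataclass
class RelaxationSeries:
    """Apparent dR2*(t) series (1/s) on the bolus-averaged window."""

    dR2s: np.ndarray
    t: np.ndarray
    TR: float
    TE: float
    brain_mask: np.ndarray | None = None

    def auc(self, start: int | None = None, stop: int | None = None) -> np.ndarray:
        """Signed trapezoidal integral over [start, stop) window samples."""
        sl = slice(start, stop)
        return np.trapezoid(self.dR2s[..., sl], self.t[sl], axis=-1)


def detrend_and_smooth(ts: TimeSeries4D) -> TimeSeries4D:
    """Remove the per-voxel linear trend (mean preserved) and smooth with
    the normalized 1x5 Gaussian kernel (edges handled by reflection)."""
    n = ts.n_volumes
    if n < 5:
        raise ValueError("need at least 5 time points to detrend and smooth")
    t = np.arange(n, dtype=float)
    tc = t - t.mean()
    slope = ts.data @ tc / (tc @ tc)
    detrended = ts.data - slope[..., None] * tc
    padded = np.concatenate(
        [detrended[..., 2:0:-1], detrended, detrended[..., -2:-4:-1]], axis=-1
    )
    sm = np.apply_along_axis(
        lambda v: np.convolve(v, GAUSS_KERNEL, mode="valid"), -1, padded
    )
    return TimeSeries4D(sm, ts.TR, ts.TE, ts.field_strength, ts.brain_mask)


def _block_peak_indices(
    ts: TimeSeries4D, protocol: BreathHoldProtocol, n_use: int
) -> list[int]:
    """Locate each block's bolus maximum on the brain-mean reference.

    One common peak index per block is used for every voxel so that
    inter-voxel delays survive the averaging.
    """
    ref = ts.data[ts.brain_mask].mean(axis=0)
    peaks = []
    for i in range(n_use):
        lo_s = protocol.hold_onset_s(i) + SEARCH_PAD_AFTER_HOLD_S
        hi_s = protocol.block_start_s(i) + protocol.block_s + SEARCH_PAD_AFTER_BLOCK_S
        lo = int(np.floor(lo_s / ts.TR))
        hi = min(int(np.ceil(hi_s / ts.TR)), ts.n_volumes)
        seg = ref[lo:hi]
        dev = np.abs(seg - np.median(seg))
        peaks.append(lo + int(np.argmax(dev)))
    return peaks


def _window_indices(center: int, n_win: int, n_total: int) -> np.ndarray:
    start = center - n_win // 2
    idx = np.arange(start, start + n_win)
    if idx[0] < 0 or idx[-1] >= n_total:
        warnings.warn("bolus window exceeds series bounds; padding by edge")
        idx = np.clip(idx, 0, n_total - 1)
    return idx


def _baseline_windows(win: np.ndarray, n_side: int):
    """Per-voxel baseline sample indices (pre-onset and post-return).

    The provisional pre-bolus baseline is the first ``n_side`` window
    volumes; bolus onset is the last pre-peak sample within one baseline
    standard deviation of the pre-bolus mean, and the return to baseline is
    the first post-peak sample meeting the same criterion.
    """
    nw = win.shape[-1]
    flat = win.reshape(-1, nw)
    pre_mean = flat[:, :n_side].mean(axis=1)
    pre_sd = flat[:, :n_side].std(axis=1, ddof=1)
    dev = np.abs(flat - pre_mean[:, None])
    peak = np.argmax(dev, axis=1)
    thresh = np.maximum(pre_sd, 1e-12 * np.maximum(np.abs(pre_mean), 1.0))
    within = dev <= thresh[:, None]
    n_vox = flat.shape[0]
    cols = np.arange(nw)
    # onset: last within-baseline sample strictly before the peak
    before = within & (cols[None, :] < peak[:, None])
    onset = np.where(before.any(axis=1), nw - 1 - np.argmax(before[:, ::-1], axis=1), n_side)
    onset = np.maximum(onset, n_side - 1)
    # return: first within-baseline sample strictly after the peak
    after = within & (cols[None, :] > peak[:, None])
    ret = np.where(after.any(axis=1), np.argmax(after, axis=1), nw - n_side)
    ret = np.minimum(ret, nw - n_side)
    sel = np.zeros((n_vox, nw), dtype=bool)
    for v in range(n_vox):
        pre_lo = max(onset[v] - n_side + 1, 0)
        sel[v, pre_lo : onset[v] + 1] = True
        sel[v, ret[v] : ret[v] + n_side] = True
    return sel, peak


def average_boluses(
    ts: TimeSeries4D,
    protocol: BreathHoldProtocol,
    n_use: int = 8,
    window_s: float = 72.0,
    baseline_n: str = "10+10",
) -> BolusAverageMap:
    """Average the first ``n_use`` breath-hold boluses.

    Each bolus is allotted a ``window_s`` (default 72 s) window centered at
    the bolus maximum; the windows are averaged sample-wise.  ``baseline_n``
    selects the baseline convention for S0/eps_t: ``"10+10"`` (ten volumes
    before onset plus ten after return, the default) or ``"10total"``
    (five plus five).
    """
    if n_use > protocol.n_blocks:
        raise ValueError(
            f"n_use={n_use} exceeds the {protocol.n_blocks} protocol blocks"
        )
    if ts.n_volumes < protocol.n_volumes:
        warnings.warn(
            f"series has {ts.n_volumes} volumes, protocol expects {protocol.n_volumes}"
        )
    n_win = int(round(window_s / ts.TR))
    peaks = _block_peak_indices(ts, protocol, n_use)
    windows = [ts.data[..., _window_indices(p, n_win, ts.n_volumes)] for p in peaks]
    avg = np.mean(windows, axis=0)

    n_side = {"10+10": 10, "10total": 5}[baseline_n]
    sel, peak = _baseline_windows(avg, n_side)
    flat = avg.reshape(-1, n_win)
    counts = sel.sum(axis=1)
    S0 = np.where(counts > 0, (flat * sel).sum(axis=1) / np.maximum(counts, 1), np.nan)
    ssq = (((flat - S0[:, None]) * sel) ** 2).sum(axis=1)
    eps_t = np.sqrt(ssq / np.maximum(counts - 1, 1))
    s_ext = flat[np.arange(flat.shape[0]), peak]
    sign = np.where(s_ext >= S0, 1, -1)

    shp = avg.shape[:-1]
    return BolusAverageMap(
        data=avg,
        S0=S0.reshape(shp),
        S_ext=s_ext.reshape(shp),
        sign=sign.reshape(shp),
        eps_t=eps_t.reshape(shp),
        t=np.arange(n_win) * ts.TR,
        TR=ts.TR,
        TE=ts.TE,
        n_boluses_used=n_use,
        brain_mask=ts.brain_mask,
    )


def delta_s(b: BolusAverageMap):
    """Percent maximal signal change with its sign flag.

    Returns ``(dS_pct, sign)``: ``dS_pct = 100*|S_ext - S0|/S0``.  Raises
    if any in-mask baseline is non-positive.
    """
    mask = b.brain_mask if b.brain_mask is not None else np.ones(b.S0.shape, bool)
    if np.any(b.S0[mask] <= 0):
        bad = np.argwhere(mask & (b.S0 <= 0))[0]
        raise ValueError(
            f"non-positive baseline S0 at voxel {tuple(int(i) for i in bad)}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        ds = 100.0 * np.abs(b.S_ext - b.S0) / b.S0
    return ds, b.sign.copy()


def cnr(b: BolusAverageMap):
    """Contrast-to-noise ratio |S_ext - S0| / eps_t.

    Returns ``(cnr_map, valid)``; voxels with zero baseline noise are
    flagged invalid (NaN in the map) rather than infinite.
    """
    valid = b.eps_t > 0
    out = np.full(b.eps_t.shape, np.nan)
    np.divide(np.abs(b.S_ext - b.S0), b.eps_t, out=out, where=valid)
    return out, valid


def gw_contrast(cnr_gm: float, cnr_wm: float) -> float:
    """Gray-to-white contrast: mean GM CNR minus mean WM CNR."""
    if not (np.isfinite(cnr_gm) and np.isfinite(cnr_wm)):
        raise ValueError("mean CNRs must be finite")
    return float(cnr_gm) - float(cnr_wm)


def delta_r2star(
    S: np.ndarray,
    S0: np.ndarray | float,
    TE: float,
    t: np.ndarray | None = None,
    TR: float | None = None,
    brain_mask: np.ndarray | None = None,
) -> RelaxationSeries:
    """Apparent relaxation change ``dR2*(t) = -(1/TE) ln(S(t)/S0)``."""
    if TE <= 0:
        raise ValueError("TE must be positive")
    S = np.asarray(S, dtype=float)
    S0 = np.asarray(S0, dtype=float)
    check = S if brain_mask is None else S[brain_mask]
    if np.any(check <= 0):
        if brain_mask is None:
            bad = np.argwhere(S <= 0)[0]
        else:
            bad = np.argwhere((S <= 0) & brain_mask[..., None])[0]
        raise ValueError(
            "non-positive signal sample at index "
            f"{tuple(int(i) for i in bad)}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = -np.log(S / S0[..., None] if S0.ndim == S.ndim - 1 else S / S0) / TE
    if TR is None:
        TR = 1.0 if t is None else float(t[1] - t[0])
    if t is None:
        t = np.arange(S.shape[-1]) * TR
    return RelaxationSeries(dR2s=d, t=np.asarray(t, float), TR=TR, TE=TE, brain_mask=brain_mask)


def bolus_average_to_relaxation(b: BolusAverageMap) -> RelaxationSeries:
    """Convert a bolus-averaged window to an apparent dR2*(t) series."""
    return delta_r2star(b.data, b.S0, b.TE, t=b.t, TR=b.TR, brain_mask=b.brain_mask)


def auc_map(rs: RelaxationSeries, start: int | None = None, stop: int | None = None) -> np.ndarray:
    """Per-voxel signed trapezoidal integral of dR2*(t) (units 1/s * s)."""
    return rs.auc(start, stop)
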