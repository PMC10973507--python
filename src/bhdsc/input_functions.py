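"""Arterial input function (AIF), venous output function (VOF) and
tissue-mask refinement.

The breath-hold AIF is *not* a contrast-agent bolus: arterial blood is
near-saturation, so the arterial signature of hypercapnia is a
vasodilation-driven signal *decrease*.  AIF voxels are therefore selected
among negative-going voxels (|dS| above the 99th percentile, short delay);
VOF voxels in or near the superior sagittal sinus are positive-going with
|dS| above the 99.9th percentile, long delay (~2-3 s) and low baseline
signal.  The AIF is scaled by the VOF integral, which sign-flips it into
the tissue sign convention while normalizing its magnitude to the amount
of contrast (deoxyhemoglobin) rather than the degree of vasodilation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import RelaxationSeries

TARGET_VOXELS = 20
MIN_VOXELS = 15
AIF_PERCENTILE = 99.0
VOF_PERCENTILE = 99.9
SHORT_DELAY_MAX_S = 0.5
VOF_DELAY_WINDOW_S = (1.5, 4.0)
EDGE_FRACTION = 0.10  # bolus start/end threshold as a fraction of the peak


@dataclass
class InputFunction:
    """An AIF or VOF: member voxels, averaged dR2*(t), and bolus edges."""

    kind: str  # "AIF" | "VOF"
    voxel_indices: list
    timecourse: np.ndarray
    t: np.ndarray
    bolus_start: float
    bolus_end: float
    scaled: bool = False
    scale_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("AIF", "VOF"):
            raise ValueError("kind must be 'AIF' or 'VOF'")
        if not self.bolus_start < self.bolus_end:
            raise ValueError("bolus_start must precede bolus_end")

    @property
    def integral(self) -> float:
        """Trapezoidal integral of the time course over the bolus window."""
        sel = (self.t >= self.bolus_start) & (self.t <= self.bolus_end)
        return float(np.trapezoid(self.timecourse[sel], self.t[sel]))

    def window_integral(self, t_start: float, t_end: float) -> float:
        sel = (self.t >= t_start) & (self.t <= t_end)
        return float(np.trapezoid(self.timecourse[sel], self.t[sel]))


@dataclass
class TissueMasks:
    """Refined gray/white matter masks with the maps used to build them."""

    gm: np.ndarray
    wm: np.ndarray
    eps_t_threshold: float
    counts: dict = field(default_factory=dict)


def bolus_edges(timecourse: np.ndarray, t: np.ndarray, min_run: int = 2):
    """First/last sustained crossing of 10% of the peak |dR2*|.

    A crossing counts only if at least ``min_run`` consecutive samples
    exceed the threshold, which guards against locking onto noise.
    """
    x = np.abs(np.asarray(timecourse, float))
    thr = EDGE_FRACTION * x.max()
    above = x > thr
    run = np.convolve(above.astype(int), np.ones(min_run, int), mode="valid") == min_run
    if not run.any():
        idx = int(np.argmax(x))
        return float(t[max(idx - 1, 0)]), float(t[min(idx + 1, len(t) - 1)])
    starts = np.flatnonzero(run)
    first = starts[0]
    last = starts[-1] + min_run - 1
    return float(t[first]), float(t[last])


def _make_input_function(kind, idx_list, rs: RelaxationSeries) -> InputFunction:
    curves = np.stack([rs.dR2s[tuple(i)] for i in idx_list])
    tc = curves.mean(axis=0)
    start, end = bolus_edges(tc, rs.t)
    return InputFunction(
        kind=kind, voxel_indices=[tuple(i) for i in idx_list],
        timecourse=tc, t=rs.t.copy(), bolus_start=start, bolus_end=end,
    )


def _take_top(order_idx, magnitudes, n_candidates):
    n_keep = min(TARGET_VOXELS, n_candidates)
    return order_idx[:n_keep]


def select_aif(
    dS: np.ndarray,
    sign: np.ndarray,
    rs: RelaxationSeries,
    candidate_mask: np.ndarray,
    delay: np.ndarray | None = None,
    percentile: float = AIF_PERCENTILE,
    short_delay_max_s: float = SHORT_DELAY_MAX_S,
) -> InputFunction:
    """Select the vasodilation AIF from negative-going candidate voxels.

    Among candidate voxels with negative dS, voxels with |dS| above the
    given percentile (computed over the negative candidates) and short
    delay are ranked by |dS|; the top 15-20 are averaged.  If the
    percentile/delay filters leave fewer than 15 voxels, the ranking
    backfills from the remaining negative candidates (warning below 3).
    """
    neg = candidate_mask & (sign < 0)
    if not neg.any():
        raise ValueError("no candidate AIF: no negative-dS voxels in the mask")
    mags = dS[neg]
    thr = np.percentile(mags, percentile)
    passes = dS >= thr
    if delay is not None:
        passes = passes & (delay <= short_delay_max_s)
    primary = neg & passes
    idx_primary = np.argwhere(primary)
    idx_rest = np.argwhere(neg & ~primary)
    # rank by |dS| within each tier, primary tier first
    idx_primary = idx_primary[np.argsort(-dS[tuple(idx_primary.T)])] if len(idx_primary) else idx_primary
    idx_rest = idx_rest[np.argsort(-dS[tuple(idx_rest.T)])] if len(idx_rest) else idx_rest
    ranked = list(idx_primary) + (
        list(idx_rest) if len(idx_primary) < MIN_VOXELS else []
    )
    selected = ranked[: min(TARGET_VOXELS, len(ranked))]
    if len(selected) < 3:
        warnings.warn(f"only {len(selected)} AIF voxels survive selection")
    aif = _make_input_function("AIF", selected, rs)
    if aif.integral <= 0:
        warnings.warn("AIF raw integral is not positive; check candidate voxels")
    return aif


def select_vof(
    dS: np.ndarray,
    sign: np.ndarray,
    rs: RelaxationSeries,
    candidate_mask: np.ndarray,
    delay: np.ndarray | None = None,
    S0: np.ndarray | None = None,
    percentile: float = VOF_PERCENTILE,
    delay_window_s: tuple = VOF_DELAY_WINDOW_S,
) -> InputFunction:
    """Select the venous output function from positive-going candidates.

    Criteria: dS above the 99.9th percentile of positive candidates, delay
    within ~2-3 s (window [1.5, 4.0] s), and baseline signal below the
    candidate median.  If the delay window empties the selection it is
    progressively relaxed (with a warning) before giving up.
    """
    pos = candidate_mask & (sign > 0)
    if not pos.any():
        raise ValueError("no candidate VOF: no positive-dS voxels in the mask")
    thr = np.percentile(dS[pos], percentile)
    # candidate pool: positive-going, low baseline signal (venous blood is
    # dark); fall back to all positives if the S0 cut is too strict
    pool = pos
    if S0 is not None:
        low_s0 = pos & (S0 < np.median(S0[candidate_mask]))
        if low_s0.sum() >= MIN_VOXELS:
            pool = low_s0
    base = pool & (dS >= thr)
    lo, hi = delay_window_s
    survivors = base
    if delay is not None:
        for widen in (0.0, 0.5, 1.0, 2.0, np.inf):
            survivors = base & (delay >= max(lo - widen, 0.0)) & (delay <= hi + widen)
            if survivors.any():
                if widen > 0:
                    warnings.warn(
                        f"VOF delay window relaxed by {widen} s to find candidates"
                    )
                break
        if not survivors.any():
            survivors = base
    # rank: percentile/delay survivors first, then the rest of the pool
    idx = np.argwhere(survivors)
    idx = idx[np.argsort(-dS[tuple(idx.T)])] if len(idx) else idx
    if len(idx) < MIN_VOXELS:
        extra = np.argwhere(pool & ~survivors)
        extra = extra[np.argsort(-dS[tuple(extra.T)])] if len(extra) else extra
        idx = np.concatenate([idx, extra]) if len(extra) else idx
    selected = list(idx[: min(TARGET_VOXELS, len(idx))])
    vof = _make_input_function("VOF", selected, rs)
    if vof.integral >= 0:
        warnings.warn("VOF integral is not negative; check candidate voxels")
    return vof


def scale_aif(aif: InputFunction, vof: InputFunction) -> InputFunction:
    """Scale the AIF by the VOF integral over the truncated bolus window.

    ``AIF_scaled(t) = (int VOF / int AIF) * AIF(t)``.  With a positive AIF
    integral (vasodilation) and a negative VOF integral (oxygenation), the
    ratio is negative and the scaling flips the AIF into the tissue sign
    convention; the scaled integral equals the VOF integral exactly.
    """
    t0, t1 = aif.bolus_start, vof.bolus_end
    if not t0 < t1:
        raise ValueError("AIF bolus start must precede VOF bolus end")
    a = aif.window_integral(t0, t1)
    v = vof.window_integral(t0, t1)
    if a == 0:
        raise ValueError("zero AIF integral over the truncated window")
    if v == 0:
        raise ValueError("zero VOF integral over the truncated window")
    ratio = v / a
    return InputFunction(
        kind="AIF",
        voxel_indices=list(aif.voxel_indices),
        timecourse=ratio * aif.timecourse,
        t=aif.t.copy(),
        bolus_start=aif.bolus_start,
        bolus_end=aif.bolus_end,
        scaled=True,
        scale_ratio=ratio,
    )


def refine_tissue_masks(
    pve_gm: np.ndarray,
    pve_wm: np.ndarray,
    eps_t_map: np.ndarray,
    brain_mask: np.ndarray | None = None,
    pve_threshold: float = 0.9,
    eps_fraction: float = 0.10,
) -> TissueMasks:
    """Threshold partial-volume maps and strip high-noise (vessel) voxels.

    Keeps voxels with PVE > 0.9 whose baseline temporal standard deviation
    lies in the lowest 10% of the eps_t range within the brain mask (high
    eps_t marks pulsatile, high-blood-volume voxels).
    """
    if brain_mask is None:
        brain_mask = np.isfinite(eps_t_map)
    eps = eps_t_map[brain_mask]
    thr = eps.min() + eps_fraction * (eps.max() - eps.min())
    quiet = brain_mask & (eps_t_map <= thr)
    gm = (pve_gm > pve_threshold) & quiet
    wm = (pve_wm > pve_threshold) & quiet & ~gm
    counts = {
        "gm_pve": int(((pve_gm > pve_threshold) & brain_mask).sum()),
        "wm_pve": int(((pve_wm > pve_threshold) & brain_mask).sum()),
        "quiet": int(quiet.sum()),
        "gm": int(gm.sum()),
        "wm": int(wm.sum()),
    }
    if not gm.any() or not wm.any():
        raise ValueError(f"empty refined mask; filter-stage counts: {counts}")
    return TissueMasks(gm=gm, wm=wm, eps_t_threshold=float(thr), counts=counts)
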