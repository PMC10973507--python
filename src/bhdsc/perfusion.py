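"""Truncated-SVD deconvolution and relative perfusion maps.

Standard tracer-kinetic discretization: the tissue curve is modeled as
``c_tis = A k`` with ``A[i, j] = dt * AIF_scaled(t_{i-j})`` lower
triangular (rectangle rule, non-circulant).  The residue function ``k``
is recovered by zeroing singular values below 20% of the largest, and

    CBV = (k_H / rho) * int c_tis / int AIF_scaled,
    CBF = (k_H / rho) * max k,         MTT = CBV / CBF,

with hematocrit correction k_H = 1.45 and brain density rho = 1.05.
All values are relative (a.u.); voxels with negative CBV or CBF are
excluded from the validity mask but preserved in the maps (negative
values carry meaning in steal physiology).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .input_functions import InputFunction
from .preprocess import RelaxationSeries


@dataclass(frozen=True)
class KineticConstants:
    k_H: float = 1.45
    rho: float = 1.05
    svd_threshold: float = 0.20

    def __post_init__(self) -> None:
        if not 0.0 <= self.svd_threshold < 1.0:
            raise ValueError("svd_threshold must lie in [0, 1)")
        if self.k_H <= 0 or self.rho <= 0:
            raise ValueError("k_H and rho must be positive")

    @property
    def scale(self) -> float:
        return self.k_H / self.rho


@dataclass
class PerfusionResult:
    """Relative CBV/CBF (a.u.) and MTT (s) maps with a validity mask."""

    CBV: np.ndarray
    CBF: np.ndarray
    MTT: np.ndarray
    valid_mask: np.ndarray
    t: np.ndarray | None = None


def truncate_window(
    rs: RelaxationSeries, aif: InputFunction, vof: InputFunction
) -> tuple[np.ndarray, np.ndarray, slice]:
    """Cut all series to [AIF bolus start, VOF bolus end].

    Returns ``(t_window, dR2s_window, window_slice)``.
    """
    t0, t1 = aif.bolus_start, vof.bolus_end
    if not t0 < t1:
        raise ValueError("inverted truncation window")
    sel = np.flatnonzero((rs.t >= t0) & (rs.t <= t1))
    sl = slice(int(sel[0]), int(sel[-1]) + 1)
    return rs.t[sl], rs.dR2s[..., sl], sl


def build_convolution_matrix(aif_scaled: np.ndarray, dt: float) -> np.ndarray:
    """Lower-triangular Toeplitz matrix A[i, j] = dt * AIF(t_{i-j})."""
    if dt <= 0:
        raise ValueError("non-uniform or non-positive sampling step")
    a = np.asarray(aif_scaled, float)
    n = a.size
    i, j = np.indices((n, n))
    A = np.where(j <= i, a[np.clip(i - j, 0, n - 1)], 0.0) * dt
    return A


def svd_deconvolve(
    tissue: np.ndarray, A: np.ndarray, constants: KineticConstants = KineticConstants()
) -> np.ndarray:
    """Residue curve(s) from truncated-SVD inversion of ``A``.

    Singular values below ``svd_threshold`` times the largest are zeroed.
    ``tissue`` may be one curve (n,) or a stack (..., n).
    """
    U, s, Vt = np.linalg.svd(A)
    keep = (s > 0) & (s >= constants.svd_threshold * s[0])
    if not keep.any():
        raise ValueError("all singular values fall below the SVD threshold")
    s_inv = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
    Ainv = (Vt.T * s_inv) @ U.T
    return np.einsum("ij,...j->...i", Ainv, np.asarray(tissue, float))


def compute_cbv(
    tissue: np.ndarray,
    aif_scaled: np.ndarray,
    t: np.ndarray,
    constants: KineticConstants = KineticConstants(),
) -> np.ndarray:
    """Relative CBV from the ratio of tissue to scaled-AIF integrals."""
    denom = np.trapezoid(aif_scaled, t)
    if denom == 0:
        raise ValueError("zero AIF integral")
    num = np.trapezoid(tissue, t, axis=-1)
    return constants.scale * num / denom


def compute_cbf_mtt(
    k: np.ndarray, cbv: np.ndarray, constants: KineticConstants = KineticConstants()
):
    """CBF from the residue maximum; MTT by the central volume principle."""
    kmax = np.max(k, axis=-1)
    cbf = constants.scale * kmax
    valid = (kmax > 0) & (np.asarray(cbv) > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mtt = np.where(valid, np.asarray(cbv) / np.where(cbf != 0, cbf, np.nan), np.nan)
    return cbf, mtt, valid


def perfusion_maps(
    rs: RelaxationSeries,
    aif: InputFunction,
    vof: InputFunction,
    constants: KineticConstants = KineticConstants(),
    mask: np.ndarray | None = None,
) -> PerfusionResult:
    """Full per-voxel perfusion estimation on a relaxation-series map.

    Applies truncation to [AIF start, VOF end]; VOF scaling is assumed
    already applied to ``aif`` (``aif.scaled``), then SVD
    deconvolution and CBV/CBF/MTT.  Per-voxel failures (negative CBV or
    CBF) are excluded from ``valid_mask``, never raised.
    """
    if not aif.scaled:
        warnings.warn("AIF does not appear to be VOF-scaled; proceeding anyway")
    t_w, c_w, _ = truncate_window(rs, aif, vof)
    sel = (aif.t >= t_w[0]) & (aif.t <= t_w[-1])
    a_w = aif.timecourse[sel]
    dt = float(np.median(np.diff(t_w)))
    if mask is None:
        mask = rs.brain_mask if rs.brain_mask is not None else np.ones(rs.dR2s.shape[:-1], bool)
    curves = c_w[mask]
    if not np.any(np.abs(curves) > 0):
        warnings.warn("all tissue curves are zero; empty validity mask")
    A = build_convolution_matrix(a_w, dt)
    k = svd_deconvolve(curves, A, constants)
    cbv_v = compute_cbv(curves, a_w, t_w, constants)
    cbf_v, mtt_v, valid_v = compute_cbf_mtt(k, cbv_v, constants)

    shp = mask.shape
    CBV = np.full(shp, np.nan)
    CBF = np.full(shp, np.nan)
    MTT = np.full(shp, np.nan)
    valid = np.zeros(shp, bool)
    CBV[mask] = cbv_v
    CBF[mask] = cbf_v
    MTT[mask] = mtt_v
    valid[mask] = valid_v & (cbv_v > 0)
    return PerfusionResult(CBV=CBV, CBF=CBF, MTT=MTT, valid_mask=valid, t=t_w)


def region_summary(result: PerfusionResult, masks: dict) -> "pd.DataFrame":
    """Mean/SD/CV per region for CBV, CBF, MTT within the validity mask."""
    import pandas as pd

    rows = []
    for name, m in masks.items():
        mm = m & result.valid_mask
        for param, arr in (("CBV", result.CBV), ("CBF", result.CBF), ("MTT", result.MTT)):
            vals = arr[mm]
            vals = vals[np.isfinite(vals)]
            mean = float(np.mean(vals)) if vals.size else np.nan
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
            rows.append(
                {"region": name, "parameter": param, "n_voxels": int(vals.size),
                 "mean": mean, "sd": sd,
                 "cv": sd / mean if vals.size > 1 and mean else np.nan}
            )
    return pd.DataFrame(rows)
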