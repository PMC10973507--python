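"""End-to-end driver: raw 4D series -> perfusion, delay and CNR outputs.

Stages: detrend/smooth -> bolus averaging -> dS/CNR/dR2* -> AIF selection
-> delay map -> VOF selection -> AIF scaling -> truncated-SVD perfusion.
Every stage's products are returned in a bundle and optionally written to
disk (NIfTI maps, TSV input functions and summaries, provenance JSON).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import delay as delay_mod
from . import input_functions as ifn
from . import io as bio
from . import perfusion as perf
from . import preprocess as pre
from .config import PipelineConfig


@dataclass
class PipelineOutputs:
    bolus_average: pre.BolusAverageMap
    dS: np.ndarray
    sign: np.ndarray
    cnr: np.ndarray
    relaxation: pre.RelaxationSeries
    aif: ifn.InputFunction
    vof: ifn.InputFunction
    aif_scaled: ifn.InputFunction
    delay: delay_mod.DelayMap
    perfusion: perf.PerfusionResult
    timings: dict = field(default_factory=dict)


def run_pipeline(
    ts: pre.TimeSeries4D,
    artery_mask: np.ndarray,
    vein_mask: np.ndarray,
    config: PipelineConfig | None = None,
    gm_mask: np.ndarray | None = None,
    wm_mask: np.ndarray | None = None,
    out_dir=None,
) -> PipelineOutputs:
    """Run the full breath-hold DSC analysis on one 4D series.

    ``artery_mask`` / ``vein_mask`` are the candidate regions for AIF/VOF
    selection (region labels for phantoms, user-supplied seed masks for
    real data).  Stage failures raise with the stage name attached.
    """
    config = (config or PipelineConfig()).validate()
    timings: dict = {}
    stage = "preprocess"
    try:
        t0 = time.perf_counter()
        work = pre.detrend_and_smooth(ts) if config.detrend else ts
        bav = pre.average_boluses(
            work, config.protocol, n_use=config.n_use,
            window_s=config.window_s, baseline_n=config.baseline_n)
        dS, sign = pre.delta_s(bav)
        cnr_map, _ = pre.cnr(bav)
        rs = pre.bolus_average_to_relaxation(bav)
        timings[stage] = time.perf_counter() - t0

        stage = "aif"
        t0 = time.perf_counter()
        aif = ifn.select_aif(dS, sign, rs, artery_mask,
                             percentile=config.aif_percentile,
                             short_delay_max_s=config.short_delay_max_s)
        timings[stage] = time.perf_counter() - t0

        stage = "delay"
        t0 = time.perf_counter()
        # correlate against the sign-flipped AIF so tissue covaries positively
        dmap = delay_mod.delay_map(rs, -aif.timecourse,
                                   max_shift_s=config.delay_max_s,
                                   step_s=config.delay_step_s)
        for v in aif.voxel_indices:  # AIF voxels anchor delay zero
            dmap.delay[v] = 0.0
        timings[stage] = time.perf_counter() - t0

        stage = "vof"
        t0 = time.perf_counter()
        vof = ifn.select_vof(dS, sign, rs, vein_mask, delay=dmap.delay,
                             S0=bav.S0, percentile=config.vof_percentile,
                             delay_window_s=config.vof_delay_window_s)
        aif_scaled = ifn.scale_aif(aif, vof)
        timings[stage] = time.perf_counter() - t0

        stage = "perfusion"
        t0 = time.perf_counter()
        constants = perf.KineticConstants(
            k_H=config.k_H, rho=config.rho, svd_threshold=config.svd_threshold)
        result = perf.perfusion_maps(rs, aif_scaled, vof, constants)
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    out = PipelineOutputs(
        bolus_average=bav, dS=dS, sign=sign, cnr=cnr_map, relaxation=rs,
        aif=aif, vof=vof, aif_scaled=aif_scaled, delay=dmap,
        perfusion=result, timings=timings,
    )
    if out_dir is not None:
        _write_outputs(out, config, ts, gm_mask, wm_mask, Path(out_dir))
    return out


def _write_outputs(out, config, ts, gm_mask, wm_mask, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bio.save_nifti(out.dS, out_dir / "dS.nii.gz")
    bio.save_nifti(out.sign.astype(np.int8), out_dir / "dS_sign.nii.gz")
    bio.save_nifti(out.cnr, out_dir / "cnr.nii.gz")
    bio.save_nifti(out.relaxation.auc(), out_dir / "auc.nii.gz")
    bio.save_nifti(out.delay.delay, out_dir / "delay.nii.gz")
    bio.save_nifti(out.delay.r_max, out_dir / "rmax.nii.gz")
    bio.save_nifti(out.perfusion.CBV, out_dir / "cbv.nii.gz")
    bio.save_nifti(out.perfusion.CBF, out_dir / "cbf.nii.gz")
    bio.save_nifti(out.perfusion.MTT, out_dir / "mtt.nii.gz")
    bio.save_nifti(out.perfusion.valid_mask.astype(np.uint8),
                   out_dir / "valid_mask.nii.gz")
    bio.save_input_function(out.aif, out_dir / "aif.tsv")
    bio.save_input_function(out.vof, out_dir / "vof.tsv")
    bio.save_input_function(out.aif_scaled, out_dir / "aif_scaled.tsv")
    masks = {}
    if gm_mask is not None:
        masks["GM"] = gm_mask
    if wm_mask is not None:
        masks["WM"] = wm_mask
    if masks:
        perf.region_summary(out.perfusion, masks).to_csv(
            out_dir / "summary.tsv", sep="\t", index=False)
    cfg = config.to_dict()
    prov = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "n_volumes": ts.n_volumes,
        "stage_timings_s": out.timings,
    }
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2)
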