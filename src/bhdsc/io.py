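"""NIfTI / TSV / JSON input-output helpers.

Images travel as NIfTI-1 with a JSON sidecar carrying TR, TE, field
strength and (for phantoms) the generator seed; input functions as TSV
(time_s, dR2s) with JSON metadata.  Affines are passed through untouched;
all voxel coordinates are 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .input_functions import InputFunction
from .preprocess import TimeSeries4D


def save_nifti(data: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_timeseries(ts: TimeSeries4D, path, sidecar: dict | None = None) -> None:
    path = Path(path)
    save_nifti(ts.data, path)
    meta = {"TR": ts.TR, "TE": ts.TE, "field_strength": ts.field_strength}
    meta.update(sidecar or {})
    json_path = str(path).replace(".nii.gz", "").replace(".nii", "") + ".json"
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=2)


def load_timeseries(path, brain_mask: np.ndarray | None = None) -> TimeSeries4D:
    data, _ = load_nifti(path)
    json_path = str(path).replace(".nii.gz", "").replace(".nii", "") + ".json"
    with open(json_path) as fh:
        meta = json.load(fh)
    return TimeSeries4D(
        data=np.asarray(data, float), TR=meta["TR"], TE=meta["TE"],
        field_strength=meta.get("field_strength", 7.0), brain_mask=brain_mask,
    )


def save_input_function(fn: InputFunction, path) -> None:
    path = Path(path)
    pd.DataFrame({"time_s": fn.t, "dR2s": fn.timecourse}).to_csv(
        path, sep="\t", index=False)
    meta = {
        "kind": fn.kind,
        "n_voxels": len(fn.voxel_indices),
        "voxel_indices": [list(map(int, v)) for v in fn.voxel_indices],
        "bolus_start_s": fn.bolus_start,
        "bolus_end_s": fn.bolus_end,
        "integral": fn.integral,
        "scaled": fn.scaled,
        "scale_ratio": fn.scale_ratio,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_input_function(path) -> InputFunction:
    df = pd.read_csv(path, sep="\t")
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    return InputFunction(
        kind=meta["kind"],
        voxel_indices=[tuple(v) for v in meta.get("voxel_indices", [])],
        timecourse=df["dR2s"].to_numpy(),
        t=df["time_s"].to_numpy(),
        bolus_start=meta["bolus_start_s"],
        bolus_end=meta["bolus_end_s"],
        scaled=meta.get("scaled", False),
        scale_ratio=meta.get("scale_ratio", 1.0),
    )
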