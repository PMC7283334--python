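"""File formats: NIfTI-1 volumes, TSV tables and sidecars, JSON models.

Volumes are written RAS+ with an isotropic scaled-identity affine.  Dynamic
frame timing travels in a TSV sidecar (frame_start_s, frame_duration_s)
because 4D NIfTI timing fields are unreliable across dialects.  All tables
are UTF-8, tab-delimited, with a header row.
"""

from __future__ import annotations

import json

import nibabel as nib
import numpy as np
import pandas as pd

from .acquisition import BloodSamples, DynamicImage, FrameSchedule, TAC
from .input_function import InputFunctionModel
from .phantom import LabelAtlas, TissueMaps

__all__ = [
    "save_volume", "load_volume",
    "save_dynamic_image", "load_dynamic_image",
    "save_schedule_tsv", "load_schedule_tsv",
    "save_atlas", "load_atlas",
    "save_tissue_maps", "load_tissue_maps",
    "save_tac_tsv", "load_tac_tsv",
    "save_blood_tsv", "load_blood_tsv",
    "save_input_model", "load_input_model",
    "write_tsv", "read_tsv",
]


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def save_volume(path, data, voxel_size_mm, description=""):
    img = nib.Nifti1Image(np.asarray(data), _affine(voxel_size_mm))
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))


def load_volume(path):
    img = nib.load(str(path))
    vx = float(img.header.get_zooms()[0])
    return np.asarray(img.dataobj), vx


def save_schedule_tsv(path, schedule: FrameSchedule):
    pd.DataFrame({
        "frame_start_s": schedule.start_s,
        "frame_duration_s": schedule.duration_s,
    }).to_csv(path, sep="\t", index=False)


def load_schedule_tsv(path) -> FrameSchedule:
    df = pd.read_csv(path, sep="\t")
    for col in ("frame_start_s", "frame_duration_s"):
        if col not in df.columns:
            raise ValueError(f"schedule sidecar {path} lacks column '{col}'")
    return FrameSchedule(start_s=df["frame_start_s"].to_numpy(),
                         duration_s=df["frame_duration_s"].to_numpy())


def save_dynamic_image(path, sidecar_path, image: DynamicImage):
    save_volume(path, image.data.astype(np.float32), image.voxel_size_mm,
                description="dynamic PET, kBq/mL")
    save_schedule_tsv(sidecar_path, image.schedule)


def load_dynamic_image(path, sidecar_path) -> DynamicImage:
    data, vx = load_volume(path)
    schedule = load_schedule_tsv(sidecar_path)
    if data.ndim != 4 or data.shape[3] != schedule.n_frames:
        raise ValueError(
            f"{path}: {data.shape[3] if data.ndim == 4 else 'non-4D'} frames do not "
            f"match sidecar {sidecar_path} ({schedule.n_frames} frames)"
        )
    return DynamicImage(data=np.asarray(data, dtype=np.float64),
                        schedule=schedule, voxel_size_mm=vx)


def save_atlas(nifti_path, table_path, atlas: LabelAtlas):
    save_volume(nifti_path, atlas.labels.astype(np.int16), atlas.voxel_size_mm,
                description="label atlas")
    atlas.region_table.to_csv(table_path, sep="\t", index=False)


def load_atlas(nifti_path, table_path) -> LabelAtlas:
    labels, vx = load_volume(nifti_path)
    table = pd.read_csv(table_path, sep="\t")
    return LabelAtlas(labels=np.asarray(labels, dtype=np.int16),
                      voxel_size_mm=vx, region_table=table)


def save_tissue_maps(prefix, maps: TissueMaps, voxel_size_mm):
    for name in ("gm", "wm", "csf"):
        save_volume(f"{prefix}_{name}.nii", getattr(maps, name).astype(np.float32),
                    voxel_size_mm, description=f"{name} fraction")


def load_tissue_maps(prefix) -> TissueMaps:
    vols = {}
    for name in ("gm", "wm", "csf"):
        vols[name], _ = load_volume(f"{prefix}_{name}.nii")
        vols[name] = np.asarray(vols[name], dtype=np.float64)
    return TissueMaps(**vols)


def save_tac_tsv(path, tac: TAC):
    pd.DataFrame({"time_min": tac.times_min,
                  "activity_kBq_per_mL": tac.activity}).to_csv(path, sep="\t", index=False)


def load_tac_tsv(path, label="") -> TAC:
    df = pd.read_csv(path, sep="\t")
    return TAC(times_min=df["time_min"].to_numpy(),
               activity=df["activity_kBq_per_mL"].to_numpy(), label=label)


def save_blood_tsv(path, blood: BloodSamples):
    df = pd.DataFrame({"time_min": blood.times_min,
                       "activity_kBq_per_mL": blood.activity})
    df["plasma_glucose_mmol_L"] = blood.plasma_glucose
    df.to_csv(path, sep="\t", index=False)


def load_blood_tsv(path) -> BloodSamples:
    df = pd.read_csv(path, sep="\t")
    return BloodSamples(times_min=df["time_min"].to_numpy(),
                        activity=df["activity_kBq_per_mL"].to_numpy(),
                        plasma_glucose=float(df["plasma_glucose_mmol_L"].iloc[0]))


def save_input_model(path, model: InputFunctionModel):
    with open(path, "w") as fh:
        json.dump({
            "t_peak_min": model.t_peak,
            "amplitudes_kBq_per_mL": list(map(float, model.amplitudes)),
            "rates_per_min": list(map(float, model.rates)),
            "injection_start_min": model.injection_start,
            "calibration_scale": model.scale,
            "fit_residual": model.fit_residual,
        }, fh, indent=2)


def load_input_model(path) -> InputFunctionModel:
    with open(path) as fh:
        d = json.load(fh)
    return InputFunctionModel(
        t_peak=d["t_peak_min"], amplitudes=np.array(d["amplitudes_kBq_per_mL"]),
        rates=np.array(d["rates_per_min"]), injection_start=d["injection_start_min"],
        scale=d["calibration_scale"], fit_residual=d["fit_residual"],
    )


def save_effect_spec(path, spec: pd.DataFrame):
    """EffectSpec (region-indexed effect table) as YAML."""
    import yaml
    with open(path, "w") as fh:
        yaml.safe_dump({name: {k: float(v) for k, v in row.items()}
                        for name, row in spec.iterrows()}, fh, sort_keys=True)


def load_effect_spec(path) -> pd.DataFrame:
    import yaml
    with open(path) as fh:
        data = yaml.safe_load(fh)
    df = pd.DataFrame.from_dict(data, orient="index")
    df.index.name = "name"
    return df


def write_tsv(path, df: pd.DataFrame):
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
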