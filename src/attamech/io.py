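"""File interchange: cohort CSV, trace CSV, voxel TIFF, YAML parameters.

Units are encoded in CSV column names (``_mN``, ``_um``, ``_GPa``, ``_mm3``,
...); a validation pass rejects unlabeled numeric columns so that unit
mistakes fail loudly at the file boundary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .indentation import IndentationTrace
from .thickness import ThicknessMap, VoxelVolume

__all__ = [
    "validate_unit_columns",
    "write_cohort",
    "read_cohort",
    "write_trace",
    "read_trace",
    "write_volume",
    "read_volume",
    "write_thickness_map",
    "load_params",
    "dump_params",
]

_UNIT_SUFFIXES = (
    "_mN", "_um", "_GPa", "_mm3", "_mg", "_deg", "_d", "_s", "_nm", "_uN",
    "_per_mm", "_per_mm2", "_mN_mm", "_px", "_hz",
)
#: dimensionless or identifier columns that need no unit suffix
_UNITLESS = {
    "ant_id", "colony", "stage", "brightness", "kappa_hat",
    "rho", "p_value", "df", "r2", "slope", "intercept", "cv", "n",
}


def validate_unit_columns(df: pd.DataFrame):
    """Reject numeric columns that carry neither a unit suffix nor a
    dimensionless whitelist entry (flag columns are exempt)."""
    for col in df.columns:
        if col.endswith("_flag") or col in _UNITLESS:
            continue
        if pd.api.types.is_numeric_dtype(df[col]):
            if not any(col.endswith(suf) for suf in _UNIT_SUFFIXES):
                raise ValueError(
                    f"numeric column {col!r} has no unit suffix; "
                    f"allowed suffixes: {', '.join(_UNIT_SUFFIXES)}"
                )


def write_cohort(df: pd.DataFrame, path):
    validate_unit_columns(df)
    df.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_unit_columns(df)
    return df


def write_trace(trace: IndentationTrace, path):
    pd.DataFrame(
        {
            "time_s": trace.time_s,
            "displacement_nm": trace.displacement_nm,
            "load_uN": trace.load_uN,
        }
    ).to_csv(path, index=False)


def read_trace(path) -> IndentationTrace:
    df = pd.read_csv(path)
    missing = {"time_s", "displacement_nm", "load_uN"} - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    return IndentationTrace(
        time_s=df["time_s"].to_numpy(),
        displacement_nm=df["displacement_nm"].to_numpy(),
        load_uN=df["load_uN"].to_numpy(),
    )


def write_volume(vol: VoxelVolume, path):
    """8-bit single-channel TIFF stack (foreground 255) with voxel size in
    the ImageJ-style resolution metadata."""
    res = 1.0 / vol.voxel_size_um
    tifffile.imwrite(
        path,
        (vol.data.astype(np.uint8) * 255),
        imagej=True,
        resolution=(res, res),
        metadata={"spacing": vol.voxel_size_um, "unit": "um"},
    )


def read_volume(path, voxel_size_um: float | None = None) -> VoxelVolume:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if voxel_size_um is None:
            voxel_size_um = 1.0
            if tf.imagej_metadata and "spacing" in tf.imagej_metadata:
                voxel_size_um = float(tf.imagej_metadata["spacing"])
    if data.ndim == 2:
        data = data[None]
    return VoxelVolume(data=data > 0, voxel_size_um=voxel_size_um,
                       provenance=str(path))


def write_thickness_map(tmap: ThicknessMap, path):
    """32-bit float TIFF of per-voxel thickness (μm), zero on background."""
    tifffile.imwrite(path, tmap.values_um.astype(np.float32), imagej=True,
                     metadata={"spacing": tmap.voxel_size_um, "unit": "um"})


def load_params(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_params(params: dict, path):
    with open(path, "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)
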