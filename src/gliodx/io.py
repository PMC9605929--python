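"""NIfTI / CSV I/O helpers shared by the CLI and pipeline."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .kinetics import ArterialInputFunction

#: canonical lesion-table schema
LESION_COLUMNS = [
    "patient_id", "lesion_id", "enhancing",
    "vol_ce_ml", "vol_fet_ml", "vol_bv_ml",
    "tbr_max", "tbr_med", "bv_max", "nbv_max",
    "f_med", "bv_med", "ki_med",
    "outcome", "reference_basis",
]


def affine_from_voxel_size(voxel_size_mm: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(voxel_size_mm)
    return aff


def save_nifti(data: np.ndarray, path, voxel_size_mm=(2.0, 2.0, 2.0), affine=None) -> None:
    if affine is None:
        affine = affine_from_voxel_size(voxel_size_mm)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header.set_zooms(tuple(np.abs(np.diag(affine))[:3]) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def save_aif_csv(aif: ArterialInputFunction, path) -> None:
    pd.DataFrame({"time_s": aif.times, "conc_mM": aif.concentration}).to_csv(
        path, index=False
    )


def load_aif_csv(path, bolus_arrival: float | None = None) -> ArterialInputFunction:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    c = df["conc_mM"].to_numpy(dtype=float)
    if bolus_arrival is None:
        # first sample that is not negligibly small; clipping only negligible
        # values avoids biasing the deconvolution model with a mutilated
        # bolus upslope
        above = np.nonzero(c > 1e-6 * c.max())[0]
        bolus_arrival = float(t[above[0]]) if above.size else float(t[0])
        c = np.where(t < bolus_arrival, 0.0, c)
    return ArterialInputFunction(t, c, bolus_arrival)


def lesion_records_to_frame(records) -> pd.DataFrame:
    rows = [{c: getattr(r, c) for c in LESION_COLUMNS} for r in records]
    return pd.DataFrame(rows, columns=LESION_COLUMNS)


def write_lesion_table(df: pd.DataFrame, path: Path | str) -> None:
    missing = [c for c in LESION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"lesion table is missing columns: {missing}")
    df.to_csv(path, index=False, columns=LESION_COLUMNS, float_format="%.6g")


def read_lesion_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
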