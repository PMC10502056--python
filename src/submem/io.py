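"""Readers and writers for the on-disk formats.

NIfTI volumes (float32, TR recorded in the fourth pixdim), BIDS-style
events TSVs (onset/duration in seconds from run start), phenotype and
result tables as TSV, ground truth as a JSON sidecar plus NIfTI maps.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .glm import BoldRun, ContrastImage

__all__ = [
    "ShapeError",
    "write_nifti",
    "read_nifti",
    "write_bold",
    "read_bold",
    "write_contrast",
    "read_contrast",
    "write_events",
    "read_events",
    "write_table",
    "read_table",
]


class ShapeError(ValueError):
    """A volume on disk does not have the expected dimensionality."""


def write_nifti(
    path: str | Path,
    data: np.ndarray,
    voxel_size_mm: float = 3.0,
    tr: float | None = None,
) -> None:
    """Write a 3-D or 4-D float32 NIfTI; TR goes into the time-axis zoom."""
    data = np.asarray(data, dtype=np.float32)
    img = nib.Nifti1Image(data, affine=np.diag([voxel_size_mm] * 3 + [1.0]))
    if data.ndim == 4 and tr is not None:
        img.header.set_zooms((voxel_size_mm,) * 3 + (float(tr),))
        img.header.set_xyzt_units("mm", "sec")
    else:
        img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_nifti(path: str | Path, expect_ndim: int | None = None):
    """Load a NIfTI; returns (data, voxel_size_mm, tr_or_None)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if expect_ndim is not None and data.ndim != expect_ndim:
        raise ShapeError(
            f"{path}: expected a {expect_ndim}-D volume, found {data.ndim}-D"
        )
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if data.ndim == 4 and len(zooms) > 3 else None
    return data, float(zooms[0]), tr


def write_bold(path: str | Path, run: BoldRun, voxel_size_mm: float = 3.0) -> None:
    write_nifti(path, run.data, voxel_size_mm=voxel_size_mm, tr=run.tr)


def read_bold(
    path: str | Path,
    mask: np.ndarray | None = None,
    motion: np.ndarray | None = None,
    subject_id=None,
) -> BoldRun:
    data, _, tr = read_nifti(path, expect_ndim=4)
    if tr is None:
        raise ShapeError(f"{path}: 4-D volume lacks a TR in the header")
    return BoldRun(data=data, tr=tr, mask=mask, motion=motion, subject_id=subject_id)


def write_contrast(
    path: str | Path, con: ContrastImage, voxel_size_mm: float = 3.0
) -> None:
    write_nifti(path, con.values, voxel_size_mm=voxel_size_mm)


def read_contrast(path: str | Path, name: str = "", subject_id=None) -> ContrastImage:
    data, _, _ = read_nifti(path, expect_ndim=3)
    return ContrastImage(name=name or Path(path).stem, values=data, subject_id=subject_id)


def write_events(path: str | Path, events: pd.DataFrame) -> None:
    events.to_csv(path, sep="\t", index=False, na_rep="n/a")
    meta = {"run_length": float(events.attrs.get("run_length", 0.0))}
    Path(path).with_suffix(".json").write_text(json.dumps(meta))


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    sidecar = Path(path).with_suffix(".json")
    if sidecar.exists():
        df.attrs["run_length"] = json.loads(sidecar.read_text()).get("run_length", 0.0)
    return df


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
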