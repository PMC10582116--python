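"""File I/O: NIfTI-1 volumes, BIDS-style TSV event tables, plain TSV tables.

All tables are UTF-8 TSV with a header row and '.' decimal separator; all
volumes are NIfTI-1 via nibabel.  Write-then-read round-trips reproduce
data, affine and mask exactly.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import BoldRun, StatMap, default_affine

__all__ = [
    "read_stat_map",
    "write_stat_map",
    "read_bold_run",
    "write_bold_run",
    "read_events",
    "write_events",
    "read_table",
    "write_table",
]

EVENT_COLUMNS = ["onset", "duration", "trial_type"]


def write_stat_map(stat: StatMap, path: str | Path, mask_path: str | Path | None = None) -> None:
    """Write a StatMap as NIfTI-1; optionally write its mask alongside."""
    nib.save(nib.Nifti1Image(stat.data.astype(np.float64), stat.affine), str(path))
    if mask_path is not None:
        nib.save(
            nib.Nifti1Image(stat.mask.astype(np.uint8), stat.affine), str(mask_path)
        )


def read_stat_map(path: str | Path, mask_path: str | Path | None = None) -> StatMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    return StatMap(data, mask, np.asarray(img.affine))


def write_bold_run(run: BoldRun, path: str | Path, voxel_size_mm: float = 2.0) -> None:
    aff = default_affine(voxel_size_mm)
    img = nib.Nifti1Image(run.data.astype(np.float64), aff)
    img.header["pixdim"][4] = run.tr_s
    nib.save(img, str(path))


def read_bold_run(
    path: str | Path,
    tr_s: float | None = None,
    mask: np.ndarray | None = None,
    **meta,
) -> BoldRun:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got shape {data.shape}")
    if tr_s is None:
        tr_s = float(img.header["pixdim"][4])
        if tr_s <= 0:
            raise ValueError(f"{path}: no TR in header; pass tr_s explicitly")
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return BoldRun(data=data, tr_s=tr_s, mask=mask, **meta)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events[EVENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: event table missing column(s) {missing}")
    return df


def write_table(table: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    table.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
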