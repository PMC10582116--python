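"""Shared volumetric containers.

A :class:`StatMap` is the currency of every group-level computation: a 3D
scalar field (beta / cope / varcope / t / TFCE / p) on a common voxel grid,
together with the boolean brain mask it is defined on and a voxel-to-world
affine.  A :class:`BoldRun` is one 4D acquisition, the unit of first-level
model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StatMap", "BoldRun", "default_affine"]


def default_affine(voxel_size_mm: float = 2.0) -> np.ndarray:
    """Diagonal NIfTI affine for an isotropic voxel grid at the origin."""
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = float(voxel_size_mm)
    return aff


@dataclass
class StatMap:
    """A 3D scalar field on a voxel grid with a brain mask.

    Parameters
    ----------
    data :
        3D float array, shape (x, y, z).
    mask :
        3D boolean array of the same shape; statistics are only meaningful
        inside the mask.  Defaults to the full grid.
    affine :
        4x4 voxel-to-world affine (NIfTI convention).
    """

    data: np.ndarray
    mask: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=default_affine)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"StatMap data must be 3D, got shape {self.data.shape}")
        if self.mask is None:
            self.mask = np.ones(self.data.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} != data shape {self.data.shape}"
                )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def in_mask(self) -> np.ndarray:
        """Flat vector of the in-mask values."""
        return self.data[self.mask]

    def like(self, data: np.ndarray) -> "StatMap":
        """New StatMap on the same grid/mask/affine."""
        return StatMap(np.asarray(data, dtype=float), self.mask, self.affine)


@dataclass
class BoldRun:
    """One 4D BOLD acquisition: (x, y, z, t) plus its repetition time."""

    data: np.ndarray
    tr_s: float
    mask: np.ndarray
    run_index: int = 0
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BoldRun data must be 4D, got shape {self.data.shape}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match the spatial grid")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not np.isfinite(self.data[self.mask]).all():
            raise ValueError("non-finite values inside the mask")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]
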