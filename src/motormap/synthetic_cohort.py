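"""Synthetic two-group motor-mapping cohorts.

Emulates the design of the whole-brain motor-mapping study this pipeline
targets: 12 movement conditions, 16-s blocks performed twice per run, six
runs per subject at TR = 2 s, two groups with group-specific activation
extent (footprint radius), amplitude, and between-subject spatial
variability (footprint-center jitter).  Every downstream stage — first-level
GLM, fixed effects, TFCE permutation inference, activation and variability
metrics — can therefore be exercised against known ground truth.

Each condition activates a spherical "footprint" of voxels around a
per-subject center; a subject's center is the group center plus isotropic
Gaussian jitter (truncated so the footprint stays in-grid).  The BOLD signal
inside a footprint is the block boxcar convolved with the canonical
double-gamma HRF (unit-integral scaling, so the block plateau equals the
specified percent signal change), riding on a constant baseline with
i.i.d. Gaussian noise.  Conditions without a footprint entry (e.g. a "rest"
fixation condition) are scheduled and modelled but evoke no signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import BoldRun
from .design_glm import HrfParams, condition_regressor
from .reference import CONDITIONS

__all__ = [
    "CohortSpec",
    "Footprint",
    "SubjectTruth",
    "SchedulingError",
    "make_cohort",
    "make_block_design",
    "simulate_run",
    "make_structural_table",
    "footprint_mask",
    "default_structural_params",
]

GROUPS = ("A", "B")

#: structural metrics generated per subject (left/right split where applicable)
STRUCTURAL_METRICS = [
    "brain_volume_mm3",
    "thickness_mm_left",
    "thickness_mm_right",
    "gm_volume_mm3_left",
    "gm_volume_mm3_right",
    "surface_area_mm2_left",
    "surface_area_mm2_right",
]


class SchedulingError(ValueError):
    """Raised when the requested blocks cannot fit into a run."""


def _per_group(value, name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = set(GROUPS) - set(value)
        if missing:
            raise ValueError(f"{name} missing group(s) {sorted(missing)}")
        return {g: float(value[g]) for g in GROUPS}
    return {g: float(value) for g in GROUPS}


@dataclass
class CohortSpec:
    """Full generative description of a synthetic two-group cohort.

    ``footprint_radius_vox``, ``amplitude`` (percent signal change) and
    ``center_jitter_sd_vox`` may each be a scalar (shared by both groups) or
    a ``{"A": ..., "B": ...}`` mapping.  Conditions absent from
    ``footprint_centers`` evoke no signal (baseline-only, e.g. "rest").
    """

    n_group_a: int = 8
    n_group_b: int = 8
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 2.0
    tr_s: float = 2.0
    n_runs: int = 2
    conditions: Sequence[str] = ("eyes", "jaw", "fingers", "toes")
    block_duration_s: float = 16.0
    blocks_per_run_per_condition: int = 2
    footprint_centers: dict[str, tuple[float, float, float]] | None = None
    footprint_radius_vox: float | Mapping[str, float] = 3.0
    amplitude: float | Mapping[str, float] = 1.5
    center_jitter_sd_vox: float | Mapping[str, float] = 0.5
    noise_sd: float = 1.0
    baseline: float = 100.0
    rest_gap_s: float = 2.0
    initial_rest_s: float = 10.0
    run_duration_s: float | None = None
    seed: int = 0
    hrf: HrfParams = field(default_factory=HrfParams)

    def __post_init__(self) -> None:
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ValueError("group sizes n_group_a/n_group_b must be >= 1")
        if len(self.grid_shape) != 3 or any(int(s) < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive ints")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        for name in ("voxel_size_mm", "tr_s", "block_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_runs < 1 or self.blocks_per_run_per_condition < 1:
            raise ValueError("n_runs and blocks_per_run_per_condition must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        self.conditions = list(self.conditions)
        if self.footprint_centers is None:
            self.footprint_centers = self._default_centers()
        radius = _per_group(self.footprint_radius_vox, "footprint_radius_vox")
        jitter = _per_group(self.center_jitter_sd_vox, "center_jitter_sd_vox")
        _per_group(self.amplitude, "amplitude")
        if any(r <= 0 for r in radius.values()):
            raise ValueError("footprint_radius_vox must be positive")
        if any(j < 0 for j in jitter.values()):
            raise ValueError("center_jitter_sd_vox must be non-negative")
        if max(radius.values()) >= min(self.grid_shape) / 2:
            raise ValueError(
                "footprint_radius_vox must be < min(grid_shape)/2 so footprints fit"
            )
        for cond, c in self.footprint_centers.items():
            if len(c) != 3 or not all(0 <= ci < s for ci, s in zip(c, self.grid_shape)):
                raise ValueError(
                    f"footprint_centers[{cond!r}] = {tuple(c)} outside grid {self.grid_shape}"
                )
        n_blocks = len(self.conditions) * self.blocks_per_run_per_condition
        needed = self.initial_rest_s + n_blocks * (self.block_duration_s + self.rest_gap_s)
        if self.run_duration_s is None:
            self.run_duration_s = needed
        elif self.run_duration_s < needed:
            raise SchedulingError(
                f"run_duration_s = {self.run_duration_s}s cannot host {n_blocks} "
                f"blocks (needs {needed}s)"
            )

    def _default_centers(self) -> dict[str, tuple[float, float, float]]:
        """Spread condition centers on a coarse lattice inside the grid."""
        nx, ny, nz = self.grid_shape
        conds = [c for c in self.conditions if c != "rest"]
        side = int(np.ceil(len(conds) ** (1 / 3))) or 1
        lows = [s / 4 for s in (nx, ny, nz)]
        highs = [3 * s / 4 for s in (nx, ny, nz)]
        axes = [
            np.linspace(lo, hi, side) if side > 1 else np.array([(lo + hi) / 2])
            for lo, hi in zip(lows, highs)
        ]
        centers = {}
        for i, cond in enumerate(conds):
            ix, iy, iz = np.unravel_index(i, (side, side, side))
            centers[cond] = (float(axes[0][ix]), float(axes[1][iy]), float(axes[2][iz]))
        return centers

    @property
    def n_timepoints(self) -> int:
        return int(np.ceil(self.run_duration_s / self.tr_s))

    @property
    def task_seconds_per_condition(self) -> float:
        """Total task-evoked seconds per condition across all runs."""
        return self.n_runs * self.blocks_per_run_per_condition * self.block_duration_s

    def radius(self, group: str) -> float:
        return _per_group(self.footprint_radius_vox, "footprint_radius_vox")[group]

    def amp(self, group: str) -> float:
        return _per_group(self.amplitude, "amplitude")[group]

    def jitter(self, group: str) -> float:
        return _per_group(self.center_jitter_sd_vox, "center_jitter_sd_vox")[group]

    @classmethod
    def paper_scale(cls, **overrides) -> "CohortSpec":
        """The full study design (33 + 28 subjects, 12 conditions, 6 runs);
        the voxel grid stays modest — spatial resolution, not design shape,
        is the scaled-down quantity."""
        defaults = dict(
            n_group_a=33,
            n_group_b=28,
            grid_shape=(32, 32, 32),
            n_runs=6,
            conditions=list(CONDITIONS),
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class Footprint:
    """One condition's activation sphere for one subject."""

    center: tuple[float, float, float]
    radius_vox: float
    amplitude: float


@dataclass(frozen=True)
class SubjectTruth:
    subject_id: str
    group: str
    footprints: dict[str, Footprint]


def footprint_mask(
    center: Sequence[float], radius: float, grid_shape: Sequence[int]
) -> np.ndarray:
    """Boolean mask of grid voxels within Euclidean distance ``radius`` of
    ``center`` (voxel coordinates)."""
    grids = np.ogrid[tuple(slice(0, s) for s in grid_shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def _jittered_center(
    center: Sequence[float],
    sd: float,
    radius: float,
    grid_shape: Sequence[int],
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    """Gaussian per-axis displacement, resampled (then clipped) so the whole
    footprint stays inside the grid."""
    lo = [radius for _ in grid_shape]
    hi = [s - 1 - radius for s in grid_shape]
    for _ in range(100):
        cand = np.asarray(center, dtype=float) + rng.normal(0.0, sd, size=3)
        if all(l <= c <= h for c, l, h in zip(cand, lo, hi)):
            return tuple(cand)
    return tuple(np.clip(cand, lo, hi))


def make_cohort(spec: CohortSpec) -> list[SubjectTruth]:
    """Draw per-subject ground truth (jittered footprint center, radius,
    amplitude per condition).  Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    subjects = []
    for group, n in (("A", spec.n_group_a), ("B", spec.n_group_b)):
        for i in range(n):
            footprints = {}
            for cond in spec.conditions:
                if cond not in spec.footprint_centers:
                    continue  # baseline-only condition (e.g. rest)
                center = _jittered_center(
                    spec.footprint_centers[cond],
                    spec.jitter(group),
                    spec.radius(group),
                    spec.grid_shape,
                    rng,
                )
                footprints[cond] = Footprint(center, spec.radius(group), spec.amp(group))
            subjects.append(SubjectTruth(f"sub-{group}{i:02d}", group, footprints))
    return subjects


def make_block_design(spec: CohortSpec, run_index: int, seed: int) -> pd.DataFrame:
    """Randomized block schedule for one run.

    Each condition appears ``blocks_per_run_per_condition`` times; block
    order is shuffled by ``(seed, run_index)``; blocks are separated by
    ``rest_gap_s`` of rest after an initial ``initial_rest_s`` lead-in.
    Returns a BIDS-style event table with columns onset, duration,
    trial_type.
    """
    rng = np.random.default_rng([seed, run_index])
    blocks = [c for c in spec.conditions for _ in range(spec.blocks_per_run_per_condition)]
    order = rng.permutation(len(blocks))
    t = spec.initial_rest_s
    rows = []
    for k in order:
        rows.append({"onset": t, "duration": spec.block_duration_s, "trial_type": blocks[k]})
        t += spec.block_duration_s + spec.rest_gap_s
    if t - spec.rest_gap_s > spec.run_duration_s + 1e-9:
        raise SchedulingError("blocks overflow the run duration")
    return pd.DataFrame(rows)


def simulate_run(
    truth: SubjectTruth,
    events: pd.DataFrame,
    spec: CohortSpec,
    seed: int,
    run_index: int = 0,
) -> BoldRun:
    """Simulate one BOLD run for one subject.

    Signal model: ``baseline * (1 + sum_c amplitude_c/100 * regressor_c(t))``
    inside each condition's footprint, where the regressor is the block
    boxcar convolved with the unit-integral double-gamma kernel (so the
    plateau percent signal change equals the amplitude), plus i.i.d.
    Gaussian noise of SD ``noise_sd`` at every voxel-timepoint.
    """
    nt = spec.n_timepoints
    shape = (*spec.grid_shape, nt)
    rel = np.ones(shape)
    for cond, fp in truth.footprints.items():
        if not (events["trial_type"] == cond).any():
            continue
        reg = condition_regressor(
            events, cond, nt, spec.tr_s, spec.hrf, normalize="integral"
        )
        mask3d = footprint_mask(fp.center, fp.radius_vox, spec.grid_shape)
        rel[mask3d] += (fp.amplitude / 100.0) * reg
    data = spec.baseline * rel
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=shape)
    return BoldRun(
        data=data,
        tr_s=spec.tr_s,
        mask=np.ones(spec.grid_shape, dtype=bool),
        run_index=run_index,
        subject_id=truth.subject_id,
        group=truth.group,
    )


def default_structural_params() -> tuple[dict, dict]:
    """Group means and SDs for the structural generator.

    Derived from the published group statistics of the motor-mapping cohort:
    brain volume is printed directly; the per-hemisphere metrics are printed
    as ratios to brain volume, so raw means/SDs are reconstructed as
    ratio x group-mean brain volume.
    """
    from .reference import structural_summary

    s = structural_summary()
    bv_f = s.loc["brain_volume_mm3", "mean_female"]
    bv_m = s.loc["brain_volume_mm3", "mean_male"]
    means: dict[str, dict[str, float]] = {"A": {}, "B": {}}
    sds: dict[str, dict[str, float]] = {"A": {}, "B": {}}
    ratio_of = {
        "thickness_mm": "thickness_ratio",
        "gm_volume_mm3": "gm_volume_ratio",
        "surface_area_mm2": "surface_area_ratio",
    }
    for grp, bv, col_m, col_s in (
        ("A", bv_f, "mean_female", "sd_female"),
        ("B", bv_m, "mean_male", "sd_male"),
    ):
        means[grp]["brain_volume_mm3"] = s.loc["brain_volume_mm3", col_m]
        sds[grp]["brain_volume_mm3"] = s.loc["brain_volume_mm3", col_s]
        for metric, ratio in ratio_of.items():
            for hemi in ("left", "right"):
                means[grp][f"{metric}_{hemi}"] = s.loc[f"{ratio}_{hemi}", col_m] * bv
                sds[grp][f"{metric}_{hemi}"] = s.loc[f"{ratio}_{hemi}", col_s] * bv
    return means, sds


def make_structural_table(
    spec: CohortSpec,
    group_means: Mapping[str, Mapping[str, float]] | None = None,
    group_sds: Mapping[str, Mapping[str, float]] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-subject structural metrics drawn independently lognormal.

    Lognormal parameters are moment-matched so each metric has exactly the
    requested mean and SD (an SD of 0 gives the mean deterministically);
    positivity is automatic.  Columns: subject_id, group, and the seven
    metrics of :data:`STRUCTURAL_METRICS`.
    """
    if group_means is None or group_sds is None:
        d_means, d_sds = default_structural_params()
        group_means = group_means or d_means
        group_sds = group_sds or d_sds
    for grp in GROUPS:
        for metric in STRUCTURAL_METRICS:
            m = group_means[grp][metric]
            s = group_sds[grp][metric]
            if m <= 0:
                raise ValueError(f"mean for {metric} group {grp} must be positive")
            if s < 0:
                raise ValueError(f"SD for {metric} group {grp} must be non-negative")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows = []
    for group, n in (("A", spec.n_group_a), ("B", spec.n_group_b)):
        for i in range(n):
            row = {"subject_id": f"sub-{group}{i:02d}", "group": group}
            for metric in STRUCTURAL_METRICS:
                m = group_means[group][metric]
                s = group_sds[group][metric]
                if s == 0:
                    row[metric] = m
                else:
                    sigma2 = np.log1p((s / m) ** 2)
                    mu = np.log(m) - sigma2 / 2.0
                    row[metric] = float(rng.lognormal(mu, np.sqrt(sigma2)))
            rows.append(row)
    return pd.DataFrame(rows)
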