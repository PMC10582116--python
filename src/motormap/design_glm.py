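"""First-level block-design GLM.

The model is the standard task-fMRI general linear model: each movement
condition is a boxcar of 16-s blocks, convolved with a canonical double-gamma
hemodynamic response function (HRF) and accompanied by its temporal
derivative; per-voxel ordinary least squares yields a contrast of parameter
estimates (cope), its variance (varcope) and a t statistic per condition, and
a subject's runs are combined by fixed effects — the arithmetic mean of the
run copes with propagated within-run variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import BoldRun, StatMap

__all__ = [
    "HrfParams",
    "DesignMatrix",
    "FirstLevelResult",
    "SubjectLevelResult",
    "double_gamma_hrf",
    "condition_regressor",
    "build_design_matrix",
    "fit_glm",
    "fixed_effects_combine",
]

#: kernel support in seconds; the double-gamma response has decayed to ~0 by then
HRF_DURATION_S = 32.0


@dataclass(frozen=True)
class HrfParams:
    """Canonical double-gamma HRF parameters.

    The kernel is the difference of two gamma densities — a response peaking
    at ``peak_delay_s`` minus ``undershoot_ratio`` times an undershoot peaking
    at ``undershoot_delay_s`` — rescaled to unit peak.  Defaults are the
    conventional 6 s / 16 s / ratio 1/6 parameterization.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    oversample_dt_s: float = 0.1

    def __post_init__(self) -> None:
        if self.peak_delay_s <= 0 or self.undershoot_delay_s <= 0:
            raise ValueError("HRF delays must be positive")
        if self.undershoot_delay_s <= self.peak_delay_s:
            raise ValueError("undershoot_delay_s must exceed peak_delay_s")
        if not 0 < self.undershoot_ratio < 1:
            raise ValueError("undershoot_ratio must lie in (0, 1)")
        if self.peak_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ValueError("dispersions must be positive")
        if self.oversample_dt_s <= 0:
            raise ValueError("oversample_dt_s must be positive")


def double_gamma_hrf(params: HrfParams = HrfParams()) -> tuple[np.ndarray, np.ndarray]:
    """Sample the double-gamma HRF kernel on its oversampled time grid.

    Returns ``(t, kernel)`` with ``t`` spanning [0, 32 s) at
    ``params.oversample_dt_s`` resolution and the kernel scaled to max 1.
    With shape parameters > 1 the kernel vanishes at t = 0.
    """
    t = np.arange(0.0, HRF_DURATION_S, params.oversample_dt_s)
    peak = sps.gamma.pdf(
        t, params.peak_delay_s / params.peak_dispersion, scale=params.peak_dispersion
    )
    undershoot = sps.gamma.pdf(
        t,
        params.undershoot_delay_s / params.undershoot_dispersion,
        scale=params.undershoot_dispersion,
    )
    kernel = peak - params.undershoot_ratio * undershoot
    return t, kernel / kernel.max()


def _validate_events(events: pd.DataFrame) -> pd.DataFrame:
    required = {"onset", "duration", "trial_type"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"event table missing column(s): {sorted(missing)}")
    if len(events) == 0:
        raise ValueError("event table is empty")
    return events


def _boxcar(
    events: pd.DataFrame, condition: str, t_hi: np.ndarray
) -> np.ndarray:
    u = np.zeros_like(t_hi)
    rows = events[events["trial_type"] == condition]
    for onset, duration in zip(rows["onset"], rows["duration"]):
        u[(t_hi >= onset) & (t_hi < onset + duration)] = 1.0
    return u


def condition_regressor(
    events: pd.DataFrame,
    condition: str,
    n_timepoints: int,
    tr_s: float,
    hrf: HrfParams = HrfParams(),
    normalize: str = "peak",
) -> np.ndarray:
    """Predicted BOLD time course for one condition, sampled at the TR.

    The condition boxcar is built on the oversampled grid, convolved with the
    double-gamma kernel, and sampled at multiples of the TR.  With
    ``normalize="peak"`` the convolution approximates the continuous integral
    against the unit-peak kernel (the design-matrix convention); with
    ``normalize="integral"`` the kernel is rescaled to unit area so a
    sustained block plateaus at exactly 1 (the simulation convention, which
    makes amplitudes read directly as percent signal change).
    """
    dt = hrf.oversample_dt_s
    t_hi = np.arange(0.0, n_timepoints * tr_s, dt)
    u = _boxcar(events, condition, t_hi)
    _, kernel = double_gamma_hrf(hrf)
    conv = np.convolve(u, kernel)[: len(t_hi)] * dt
    if normalize == "integral":
        conv /= kernel.sum() * dt
    elif normalize != "peak":
        raise ValueError(f"unknown normalize mode {normalize!r}")
    idx = np.round(np.arange(n_timepoints) * tr_s / dt).astype(int)
    return conv[idx]


@dataclass
class DesignMatrix:
    """Time x regressor design with named columns and the sampling TR."""

    matrix: pd.DataFrame
    tr_s: float

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy()

    @property
    def columns(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_timepoints(self) -> int:
        return len(self.matrix)


def build_design_matrix(
    events: pd.DataFrame,
    n_timepoints: int,
    tr_s: float,
    hrf: HrfParams = HrfParams(),
    conditions: list[str] | None = None,
) -> DesignMatrix:
    """Build the first-level design: task + temporal-derivative column per
    condition, plus an intercept.

    The derivative column is the first difference of the convolved task
    column divided by the TR (first sample 0), absorbing small HRF latency
    shifts.  Raises if the design is rank deficient, naming the offending
    columns.
    """
    _validate_events(events)
    if conditions is None:
        conditions = list(dict.fromkeys(events["trial_type"]))
    end = events["onset"] + events["duration"]
    if end.max() > n_timepoints * tr_s + 1e-9:
        raise ValueError(
            f"events extend to {end.max():.1f}s beyond the run "
            f"({n_timepoints * tr_s:.1f}s)"
        )
    cols: dict[str, np.ndarray] = {}
    for cond in conditions:
        task = condition_regressor(events, cond, n_timepoints, tr_s, hrf)
        cols[cond] = task
        cols[f"{cond}_derivative"] = np.diff(task, prepend=task[0]) / tr_s
    cols["intercept"] = np.ones(n_timepoints)
    X = pd.DataFrame(cols)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        norms = np.linalg.norm(X.to_numpy(), axis=0)
        suspects = [c for c, nn in zip(X.columns, norms) if nn < 1e-12]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear/empty columns: {suspects or 'correlated regressors'}"
        )
    return DesignMatrix(X, tr_s)


@dataclass
class FirstLevelResult:
    """Per-condition cope/varcope/t maps from one run's GLM fit."""

    cope: dict[str, StatMap]
    varcope: dict[str, StatMap]
    tmap: dict[str, StatMap]
    dof: int
    conditions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.conditions:
            self.conditions = list(self.cope)


def _t_from_cope_varcope(cope: np.ndarray, varcope: np.ndarray) -> np.ndarray:
    """t = cope / sqrt(varcope); zero-variance voxels get 0 when the cope is
    0 and an infinite sentinel otherwise (excluded from correlations
    downstream)."""
    t = np.zeros_like(cope)
    pos = varcope > 0
    t[pos] = cope[pos] / np.sqrt(varcope[pos])
    degen = ~pos & (cope != 0)
    t[degen] = np.sign(cope[degen]) * np.inf
    return t


def fit_glm(run: BoldRun, design: DesignMatrix) -> FirstLevelResult:
    """Voxel-wise OLS over the in-mask voxels of one run.

    For each condition the contrast selects the task column only (the
    derivative is a nuisance regressor): cope = beta_task,
    varcope = sigma^2 * (X'X)^-1[task, task], t = cope / sqrt(varcope).
    """
    X = design.values
    if run.n_timepoints != X.shape[0]:
        raise ValueError(
            f"run has {run.n_timepoints} timepoints but design has {X.shape[0]} rows"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("degenerate design matrix (rank deficient)")
    dof = X.shape[0] - rank

    Y = run.data[run.mask].T  # time x voxels
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)

    conditions = [c for c in design.columns if c != "intercept" and not c.endswith("_derivative")]
    cope_maps, var_maps, t_maps = {}, {}, {}
    for cond in conditions:
        i = design.columns.index(cond)
        cope_v = beta[i]
        var_v = sigma2 * xtx_inv[i, i]
        t_v = _t_from_cope_varcope(cope_v, var_v)
        for store, vec in ((cope_maps, cope_v), (var_maps, var_v), (t_maps, t_v)):
            vol = np.zeros(run.mask.shape)
            vol[run.mask] = vec
            store[cond] = StatMap(vol, run.mask)
    return FirstLevelResult(cope_maps, var_maps, t_maps, dof, conditions)


@dataclass
class SubjectLevelResult:
    """Fixed-effects combination of a subject's runs."""

    cope: dict[str, StatMap]
    varcope: dict[str, StatMap]
    tmap: dict[str, StatMap]
    dof: int
    n_runs_combined: int
    conditions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.conditions:
            self.conditions = list(self.cope)


def fixed_effects_combine(run_results: list[FirstLevelResult]) -> SubjectLevelResult:
    """Average run-level copes into a single per-subject activation map.

    cope = mean of run copes; varcope = (sum of run varcopes) / K^2 (the
    variance of a mean of independent estimates); t = cope / sqrt(varcope);
    dof = sum of run dofs.
    """
    if len(run_results) < 2:
        raise ValueError("fixed effects needs at least 2 runs")
    first = run_results[0]
    for r in run_results[1:]:
        if r.conditions != first.conditions:
            raise ValueError("runs have mismatched condition lists")
        for cond in first.conditions:
            if r.cope[cond].shape != first.cope[cond].shape:
                raise ValueError("runs have mismatched grids")
    K = len(run_results)
    cope_maps, var_maps, t_maps = {}, {}, {}
    for cond in first.conditions:
        ref = first.cope[cond]
        cope = np.mean([r.cope[cond].data for r in run_results], axis=0)
        var = np.sum([r.varcope[cond].data for r in run_results], axis=0) / K**2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t = _t_from_cope_varcope(cope, var)
        cope_maps[cond] = ref.like(cope)
        var_maps[cond] = ref.like(var)
        t_maps[cond] = ref.like(t)
    return SubjectLevelResult(
        cope_maps,
        var_maps,
        t_maps,
        dof=sum(r.dof for r in run_results),
        n_runs_combined=K,
        conditions=list(first.conditions),
    )
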