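"""Group-level nonparametric inference.

Threshold-free cluster enhancement (TFCE) integrates, over all supra-
threshold heights h, each voxel's supporting cluster extent^E times h^H —
yielding cluster-supported voxel scores without a cluster-forming threshold.
Family-wise error (FWE) control uses the max-statistic permutation scheme:
each voxel's observed TFCE score is compared with the permutation
distribution of the image-wide maximum (sign-flips of subject maps for
one-sample tests, group-label exchanges for two-sample tests).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import StatMap

__all__ = [
    "TfceParams",
    "GroupPermResult",
    "tfce_transform",
    "permutation_one_sample",
    "permutation_two_sample",
    "threshold_map",
]

#: finite stand-in for an infinite t (zero residual variance) so TFCE and
#: max-statistic comparisons stay well defined
T_SENTINEL = 1.0e6

#: relative slack for ">=" comparisons so float noise cannot drop exact ties
_TIE_EPS = 1e-12


@dataclass(frozen=True)
class TfceParams:
    """TFCE parameters: the established volumetric defaults E = 0.5, H = 2,
    26-connectivity, with the threshold step dh = max/n_steps."""

    height_exponent: float = 2.0
    extent_exponent: float = 0.5
    n_steps: int = 100
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.height_exponent < 0 or self.extent_exponent < 0:
            raise ValueError("TFCE exponents must be >= 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    @property
    def structure(self) -> np.ndarray:
        rank = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, rank)


def _tfce_positive(data: np.ndarray, mask: np.ndarray, params: TfceParams) -> np.ndarray:
    """Enhance the positive part of ``data`` inside ``mask``."""
    vals = np.where(mask, data, 0.0)
    h_max = vals.max(initial=0.0)
    out = np.zeros_like(vals)
    if h_max <= 0:
        return out
    dh = h_max / params.n_steps
    structure = params.structure
    E, H = params.extent_exponent, params.height_exponent
    # endpoint-exact thresholds: the top one equals h_max so the peak voxel
    # is never lost to float rounding
    for h in np.linspace(dh, h_max, params.n_steps):
        supra = vals >= h
        if not supra.any():
            break
        labels, n_lab = ndimage.label(supra, structure=structure)
        sizes = np.bincount(labels.ravel())
        contrib = sizes.astype(float) ** E * h**H * dh
        contrib[0] = 0.0
        out += contrib[labels]
    return out


def tfce_transform(stat: StatMap, params: TfceParams = TfceParams()) -> StatMap:
    """TFCE of a signed statistic map.

    Positive and negative parts are enhanced separately and recombined with
    sign, matching standard volumetric tooling.  An all-zero map maps to an
    all-zero map.
    """
    data = stat.data
    if not np.isfinite(data[stat.mask]).all():
        raise ValueError("tfce_transform requires a finite map")
    pos = _tfce_positive(data, stat.mask, params)
    neg = _tfce_positive(-data, stat.mask, params)
    return stat.like(pos - neg)


@dataclass
class GroupPermResult:
    """Observed t and TFCE maps, the max-statistic null, and FWE p-values."""

    observed_stat: StatMap
    observed_tfce: StatMap
    null_max: np.ndarray
    fwe_p: StatMap
    n_perm: int
    seed: int | None
    exhaustive: bool = False


def _one_sample_t(stack: np.ndarray) -> np.ndarray:
    """Voxel-wise one-sample t over axis 0, with sentinel handling of
    zero-variance voxels (t = 0 when the mean is 0, +/- T_SENTINEL else)."""
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / math.sqrt(n))
    degen = ~ok & (mean != 0)
    t[degen] = np.sign(mean[degen]) * T_SENTINEL
    return np.clip(t, -T_SENTINEL, T_SENTINEL)


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Voxel-wise pooled-variance two-sample t (a minus b) over axis 0."""
    na, nb = a.shape[0], b.shape[0]
    diff = a.mean(axis=0) - b.mean(axis=0)
    sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / (
        na + nb - 2
    )
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t = np.zeros_like(diff)
    ok = se > 0
    t[ok] = diff[ok] / se[ok]
    degen = ~ok & (diff != 0)
    t[degen] = np.sign(diff[degen]) * T_SENTINEL
    return np.clip(t, -T_SENTINEL, T_SENTINEL)


def _max_tfce(data3d: np.ndarray, mask: np.ndarray, params: TfceParams) -> float:
    return float(_tfce_positive(data3d, mask, params).max(initial=0.0))


def _fwe_from_null(
    obs_tfce: np.ndarray,
    mask: np.ndarray,
    null_max: np.ndarray,
    exhaustive: bool,
) -> np.ndarray:
    """Voxel-wise FWE p from the null of image-wide maxima.

    Sampled permutations use the add-one convention (the observed statistic
    counts as one permutation); exhaustive enumeration already contains the
    identity relabeling, so the plain fraction is used.
    """
    n = len(null_max)
    p = np.ones(obs_tfce.shape)
    obs = obs_tfce[mask]
    tol = _TIE_EPS * np.maximum(1.0, np.abs(obs))
    # count of null maxima >= each voxel's observed score (ties count)
    counts = (null_max[None, :] >= (obs - tol)[:, None]).sum(axis=1)
    if exhaustive:
        p[mask] = counts / n
    else:
        p[mask] = (1.0 + counts) / (n + 1.0)
    return p


def _check_stack(copes: list[StatMap]) -> tuple[np.ndarray, np.ndarray]:
    if len(copes) < 2:
        raise ValueError("need at least 2 subjects")
    mask = copes[0].mask
    for c in copes[1:]:
        if c.shape != copes[0].shape or not np.array_equal(c.mask, mask):
            raise ValueError("subject maps must share one grid and mask")
    stack = np.stack([c.data for c in copes])
    return stack, mask


def permutation_one_sample(
    copes: list[StatMap],
    params: TfceParams = TfceParams(),
    n_perm: int = 5000,
    seed: int | None = None,
) -> GroupPermResult:
    """One-sample (mean > 0) TFCE inference by sign-flip permutation.

    The null flips the sign of whole subject maps; each permutation records
    the in-mask maximum of the (positively enhanced) TFCE map.  When the
    sign-flip space has at most ``n_perm`` elements (2^n), it is enumerated
    exhaustively; otherwise ``n_perm`` flips are sampled.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    stack, mask = _check_stack(copes)
    n = stack.shape[0]
    ref = copes[0]

    obs_t3d = _one_sample_t(stack)
    obs_tfce = _tfce_positive(obs_t3d, mask, params)

    exhaustive = 2**n <= n_perm
    if exhaustive:
        flips = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        flips = rng.choice([1.0, -1.0], size=(n_perm, n))
    null_max = np.empty(len(flips))
    for i, s in enumerate(flips):
        t3d = _one_sample_t(stack * s[:, None, None, None])
        null_max[i] = _max_tfce(t3d, mask, params)

    fwe = _fwe_from_null(obs_tfce, mask, null_max, exhaustive)
    return GroupPermResult(
        observed_stat=ref.like(obs_t3d),
        observed_tfce=ref.like(obs_tfce),
        null_max=null_max,
        fwe_p=ref.like(fwe),
        n_perm=len(flips),
        seed=seed,
        exhaustive=exhaustive,
    )


def permutation_two_sample(
    copes_a: list[StatMap],
    copes_b: list[StatMap],
    params: TfceParams = TfceParams(),
    n_perm: int = 5000,
    seed: int | None = None,
    direction: str = "a_gt_b",
) -> GroupPermResult:
    """One-tailed two-sample TFCE inference by group-label permutation.

    The observed statistic is the pooled-variance t in the requested
    direction ("a_gt_b" or "b_gt_a"); the null re-assigns subjects to groups
    (exhaustively when C(n, n_a) <= n_perm).
    """
    if direction not in ("a_gt_b", "b_gt_a"):
        raise ValueError("direction must be 'a_gt_b' or 'b_gt_a'")
    if len(copes_a) < 2 or len(copes_b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    stack, mask = _check_stack(list(copes_a) + list(copes_b))
    na, nb = len(copes_a), len(copes_b)
    n = na + nb
    sign = 1.0 if direction == "a_gt_b" else -1.0
    ref = copes_a[0]

    obs_t3d = sign * _two_sample_t(stack[:na], stack[na:])
    obs_tfce = _tfce_positive(obs_t3d, mask, params)

    n_splits = math.comb(n, na)
    exhaustive = n_splits <= n_perm
    if exhaustive:
        assignments = [np.array(c) for c in itertools.combinations(range(n), na)]
    else:
        rng = np.random.default_rng(seed)
        assignments = [rng.permutation(n)[:na] for _ in range(n_perm)]
    all_idx = np.arange(n)
    null_max = np.empty(len(assignments))
    for i, a_idx in enumerate(assignments):
        b_idx = np.setdiff1d(all_idx, a_idx, assume_unique=True)
        t3d = sign * _two_sample_t(stack[a_idx], stack[b_idx])
        null_max[i] = _max_tfce(t3d, mask, params)

    fwe = _fwe_from_null(obs_tfce, mask, null_max, exhaustive)
    return GroupPermResult(
        observed_stat=ref.like(obs_t3d),
        observed_tfce=ref.like(obs_tfce),
        null_max=null_max,
        fwe_p=ref.like(fwe),
        n_perm=len(assignments),
        seed=seed,
        exhaustive=exhaustive,
    )


def threshold_map(result: GroupPermResult, alpha: float = 0.05) -> StatMap:
    """Binary significance map: voxel significant iff FWE p <= alpha."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    sig = (result.fwe_p.data <= alpha) & result.fwe_p.mask
    return result.fwe_p.like(sig.astype(float))
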