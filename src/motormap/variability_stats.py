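"""Inter-subject and inter-run activation-variability statistics.

The variability index is the Pearson correlation between whole-brain t-maps
over in-mask voxels: computed for every unordered pair of subjects within a
group (between-subject consistency; a higher mean means lower variability)
and for every unordered pair of a subject's runs (within-subject
consistency, e.g. C(6,2)=15 comparisons at six runs).  Groups are compared
with a two-tailed pooled-variance t-test whose p-value comes from random
relabeling permutations, with manual Bonferroni correction across the
condition family.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import StatMap

__all__ = [
    "PairwiseCorrSet",
    "PermTestResult",
    "pairwise_correlation",
    "pairwise_between_subject",
    "within_subject_between_run",
    "permutation_ttest",
    "bonferroni_flags",
]

logger = logging.getLogger(__name__)

_CHUNK = 2000  # permutations vectorized per block


@dataclass
class PairwiseCorrSet:
    """All unordered-pair t-map correlations within one group/condition."""

    group: str
    condition: str
    values: np.ndarray
    n_subjects: int
    n_excluded_pairs: int = 0

    @property
    def n_pairs_expected(self) -> int:
        return self.n_subjects * (self.n_subjects - 1) // 2


@dataclass
class PermTestResult:
    """Pooled-variance two-sample t with a permutation p-value."""

    t_statistic: float
    dof: int
    p_value: float
    cohens_d: float
    n_perm: int
    seed: int | None = None
    exhaustive: bool = False
    significant_bonferroni: bool | None = None


def pairwise_correlation(
    map_a: StatMap, map_b: StatMap, mask: np.ndarray | None = None
) -> float | None:
    """Pearson r between two t-maps over in-mask voxels.

    Non-finite voxels (the zero-variance sentinels of the GLM) are excluded
    pairwise.  Returns None — with a logged warning — if either map has zero
    variance over the usable voxels.
    """
    if mask is None:
        mask = map_a.mask & map_b.mask
    a = map_a.data[mask]
    b = map_b.data[mask]
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        logger.warning("zero-variance or empty map pair excluded from correlation set")
        return None
    return float(np.corrcoef(a, b)[0, 1])


def _pairwise_set(
    maps: Sequence[StatMap], mask: np.ndarray | None, group: str, condition: str
) -> PairwiseCorrSet:
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    values, excluded = [], 0
    for m1, m2 in itertools.combinations(maps, 2):
        r = pairwise_correlation(m1, m2, mask)
        if r is None:
            excluded += 1
        else:
            values.append(r)
    return PairwiseCorrSet(group, condition, np.asarray(values), len(maps), excluded)


def pairwise_between_subject(
    tmaps: Sequence[StatMap],
    mask: np.ndarray | None = None,
    group: str = "",
    condition: str = "",
) -> PairwiseCorrSet:
    """Between-subject consistency: Pearson r for every unordered pair of
    subjects' t-maps (n(n-1)/2 values)."""
    return _pairwise_set(tmaps, mask, group, condition)


def within_subject_between_run(
    run_tmaps: Sequence[StatMap], mask: np.ndarray | None = None
) -> float:
    """Mean Pearson r over all unordered pairs of one subject's run t-maps
    (15 comparisons at six runs)."""
    s = _pairwise_set(run_tmaps, mask, group="", condition="")
    if s.values.size == 0:
        raise ValueError("all run pairs were degenerate")
    return float(s.values.mean())


def _pooled_t_and_d(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    na, nb = a.size, b.size
    diff = a.mean() - b.mean()
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        if diff == 0:
            return 0.0, 0.0
        return math.copysign(math.inf, diff), math.copysign(math.inf, diff)
    sp = math.sqrt(sp2)
    t = diff / (sp * math.sqrt(1.0 / na + 1.0 / nb))
    return t, diff / sp


def _perm_t_batch(pool: np.ndarray, a_idx: np.ndarray) -> np.ndarray:
    """Pooled-variance t for a batch of relabelings; rows of ``a_idx`` are
    the indices assigned to group A."""
    n = pool.size
    na = a_idx.shape[1]
    nb = n - na
    total_sum = pool.sum()
    total_sq = (pool**2).sum()
    a_vals = pool[a_idx]
    sa = a_vals.sum(axis=1)
    qa = (a_vals**2).sum(axis=1)
    sb = total_sum - sa
    qb = total_sq - qa
    ma, mb = sa / na, sb / nb
    va = (qa - na * ma**2) / (na - 1)
    vb = (qb - nb * mb**2) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t[~np.isfinite(t)] = np.where(
        (ma - mb)[~np.isfinite(t)] == 0, 0.0, np.sign((ma - mb)[~np.isfinite(t)]) * np.inf
    )
    return t


def permutation_ttest(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_perm: int = 20000,
    seed: int | None = None,
    two_tailed: bool = True,
) -> PermTestResult:
    """Two-sample pooled-variance t-test with a relabeling-permutation
    p-value.

    The observed statistic is Student's t (positive when group A's mean is
    larger); the null distribution re-assigns the pooled values to groups at
    random, enumerated exhaustively when the label space C(n, n_a) has at
    most ``n_perm`` elements.  Sampled p-values use the add-one convention
    so p >= 1/(n_perm+1).  Cohen's d is the mean difference over the pooled
    ((n-1)-weighted) SD.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    t_obs, d = _pooled_t_and_d(a, b)
    dof = a.size + b.size - 2
    pool = np.concatenate([a, b])
    n, na = pool.size, a.size

    n_splits = math.comb(n, na)
    exhaustive = n_splits <= n_perm
    ref = abs(t_obs) if two_tailed else t_obs
    tol = 1e-12 * max(1.0, abs(ref)) if math.isfinite(ref) else 0.0
    count = 0
    total = 0
    if exhaustive:
        combos = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n), na)),
            dtype=np.intp,
        ).reshape(-1, na)
        batches = np.array_split(combos, max(1, len(combos) // _CHUNK))
    else:
        rng = np.random.default_rng(seed)
        batches = []
        remaining = n_perm
        while remaining > 0:
            k = min(_CHUNK, remaining)
            idx = np.argsort(rng.random((k, n)), axis=1)[:, :na]
            batches.append(idx)
            remaining -= k
    for batch in batches:
        t_perm = _perm_t_batch(pool, np.asarray(batch))
        stat = np.abs(t_perm) if two_tailed else t_perm
        count += int((stat >= ref - tol).sum())
        total += len(batch)

    if exhaustive:
        p = count / total
    else:
        p = (1 + count) / (total + 1)
    return PermTestResult(
        t_statistic=t_obs,
        dof=dof,
        p_value=float(p),
        cohens_d=d,
        n_perm=total,
        seed=seed,
        exhaustive=exhaustive,
    )


def bonferroni_flags(
    p_values: Sequence[float], m: int, alpha: float = 0.05
) -> np.ndarray:
    """Manual Bonferroni correction: flag i iff p_i <= alpha/m (exact ratio,
    no rounding of the threshold)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.asarray(p_values, dtype=float) <= alpha / m
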