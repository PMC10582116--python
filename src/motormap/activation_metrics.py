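"""Activation-extent and spatial-similarity metrics.

Per condition: the number of significant voxels in each group's FWE-
thresholded activation map, the between-group percent difference of those
counts, and the Pearson spatial similarity of the two groups' significance
maps (encoded as 1 - p with sub-threshold voxels zeroed), plus across-
condition mean +/- sample-SD summaries.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import StatMap
from .group_inference import GroupPermResult

__all__ = [
    "count_significant_voxels",
    "percent_difference",
    "spatial_similarity",
    "similarity_by_condition",
    "summarize_across_conditions",
    "significance_map",
    "activation_summary",
]


def count_significant_voxels(mask_map: StatMap) -> int:
    """Number of nonzero in-mask voxels of a binary map."""
    return int(np.count_nonzero(mask_map.data[mask_map.mask]))


def percent_difference(count_a: int, count_b: int) -> float:
    """(count_b - count_a) / count_a * 100 — group B's extent relative to A."""
    if count_a <= 0:
        raise ValueError("percent_difference undefined for count_a <= 0")
    return (count_b - count_a) / count_a * 100.0


def significance_map(result: GroupPermResult, alpha: float = 0.05) -> StatMap:
    """Encode an FWE-corrected result as 1 - p with sub-threshold voxels set
    to 0 — the spatial map that enters the similarity analysis."""
    p = result.fwe_p.data
    sig = np.where((p <= alpha) & result.fwe_p.mask, 1.0 - p, 0.0)
    return result.fwe_p.like(sig)


def spatial_similarity(map_a: StatMap, map_b: StatMap, mask: np.ndarray | None = None) -> float:
    """Demeaned Pearson correlation of two maps over the in-mask voxels."""
    if mask is None:
        mask = map_a.mask & map_b.mask
    a = map_a.data[mask]
    b = map_b.data[mask]
    if a.size < 2:
        raise ValueError("need at least 2 in-mask voxels")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("spatial_similarity undefined for a zero-variance map")
    return float(np.corrcoef(a, b)[0, 1])


def similarity_by_condition(
    maps_a: Mapping[str, StatMap],
    maps_b: Mapping[str, StatMap],
    mask: np.ndarray | None = None,
) -> pd.Series:
    """Matched-condition spatial similarities between two map sets.

    The full cross-correlation matrix (every A condition against every B
    condition) is computed; the diagonal — same condition in both groups —
    is returned and the inter-condition entries are discarded.
    """
    conds = list(maps_a)
    if conds != list(maps_b):
        raise ValueError(
            f"condition lists differ: {conds} vs {list(maps_b)}"
        )
    matrix = pd.DataFrame(
        {
            cb: [spatial_similarity(maps_a[ca], maps_b[cb], mask) for ca in conds]
            for cb in conds
        },
        index=conds,
    )
    return pd.Series(np.diag(matrix), index=conds, name="similarity_r")


def summarize_across_conditions(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and (n-1)-denominator sample SD of per-condition values."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values for a sample SD")
    return float(arr.mean()), float(arr.std(ddof=1))


def activation_summary(
    counts_a: Mapping[str, int],
    counts_b: Mapping[str, int],
    similarities: Mapping[str, float] | pd.Series,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the per-condition activation table and its across-condition
    summary (means and sample SDs of counts, percent differences and r)."""
    conds = list(counts_a)
    table = pd.DataFrame(
        {
            "voxels_a": [counts_a[c] for c in conds],
            "voxels_b": [counts_b[c] for c in conds],
            "percent_difference": [
                percent_difference(counts_a[c], counts_b[c]) for c in conds
            ],
            "similarity_r": [similarities[c] for c in conds],
        },
        index=pd.Index(conds, name="condition"),
    )
    summary = {}
    for col in table.columns:
        mean, sd = summarize_across_conditions(table[col].to_numpy())
        summary[f"{col}_mean"] = mean
        summary[f"{col}_sd"] = sd
    return table, summary
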