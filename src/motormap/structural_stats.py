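"""Structural-metric group comparisons.

Per-hemisphere cortical thickness, grey-matter volume and surface area are
normalized as ratios to each subject's overall brain volume (removing the
common brain-size scale), then the seven-comparison family — total brain
volume plus the six normalized hemisphere metrics — is tested between
groups with two-tailed permutation t-tests and a manual Bonferroni
correction at alpha/7.
"""

from __future__ import annotations

import pandas as pd

from .variability_stats import bonferroni_flags, permutation_ttest

__all__ = [
    "STRUCTURAL_FAMILY",
    "normalize_metric",
    "normalize_table",
    "compare_structural",
]

#: the seven comparisons: raw total volume + 3 normalized metrics x 2 hemispheres
STRUCTURAL_FAMILY = [
    "brain_volume_mm3",
    "thickness_ratio_left",
    "thickness_ratio_right",
    "gm_volume_ratio_left",
    "gm_volume_ratio_right",
    "surface_area_ratio_left",
    "surface_area_ratio_right",
]

_RAW_OF = {
    "thickness_ratio": "thickness_mm",
    "gm_volume_ratio": "gm_volume_mm3",
    "surface_area_ratio": "surface_area_mm2",
}


def normalize_metric(raw_value: float, brain_volume_mm3: float) -> float:
    """Ratio of a raw structural metric to overall brain volume."""
    if raw_value <= 0:
        raise ValueError("raw_value must be positive")
    if brain_volume_mm3 <= 0:
        raise ValueError("brain_volume_mm3 must be positive")
    return raw_value / brain_volume_mm3


def normalize_table(records: pd.DataFrame) -> pd.DataFrame:
    """Normalize a per-subject structural table.

    Input columns: subject_id, group, brain_volume_mm3 and the six raw
    per-hemisphere metrics (thickness_mm_*, gm_volume_mm3_*,
    surface_area_mm2_*).  Output keeps subject_id/group/brain_volume_mm3 and
    adds the six *_ratio_* columns.
    """
    out = records[["subject_id", "group", "brain_volume_mm3"]].copy()
    bv = records["brain_volume_mm3"]
    if (bv <= 0).any():
        raise ValueError("brain_volume_mm3 must be positive for every subject")
    for ratio, raw in _RAW_OF.items():
        for hemi in ("left", "right"):
            col = f"{raw}_{hemi}"
            if (records[col] <= 0).any():
                raise ValueError(f"{col} must be positive for every subject")
            out[f"{ratio}_{hemi}"] = records[col] / bv
    return out


def compare_structural(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    n_perm: int = 20000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare the seven structural metrics between groups.

    Both inputs are raw per-subject tables (see :func:`normalize_table`);
    each metric is tested with a two-tailed permutation t-test and flagged
    at the Bonferroni-corrected threshold alpha/7.  Returns one row per
    metric with group means/SDs, t, dof, p, Cohen's d and the flag.
    """
    if len(records_a) < 2 or len(records_b) < 2:
        raise ValueError("each group needs at least 2 records")
    norm_a = normalize_table(records_a)
    norm_b = normalize_table(records_b)
    rows = []
    for i, metric in enumerate(STRUCTURAL_FAMILY):
        va = norm_a[metric].to_numpy()
        vb = norm_b[metric].to_numpy()
        res = permutation_ttest(
            va, vb, n_perm=n_perm, seed=None if seed is None else seed + i
        )
        rows.append(
            {
                "metric": metric,
                "mean_a": va.mean(),
                "sd_a": va.std(ddof=1),
                "mean_b": vb.mean(),
                "sd_b": vb.std(ddof=1),
                "t": res.t_statistic,
                "dof": res.dof,
                "p": res.p_value,
                "cohens_d": res.cohens_d,
            }
        )
    table = pd.DataFrame(rows).set_index("metric")
    table["significant"] = bonferroni_flags(
        table["p"].to_numpy(), m=len(STRUCTURAL_FAMILY), alpha=alpha
    )
    return table
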