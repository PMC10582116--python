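"""Published group-level summary tables from the 61-subject whole-brain motor
mapping dataset (OpenNeuro ds004044: 33 female, 28 male adults, 12 movement
conditions, 6 runs each).

These printed summaries are *inputs*: the raw images are not shipped, but the
per-condition activation counts, spatial-map similarities, pairwise-correlation
summaries and structural group statistics are enough to exercise the table
arithmetic (percent differences, across-condition summaries, pooled-SD effect
sizes, degrees of freedom) end to end.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "CONDITIONS",
    "N_FEMALE",
    "N_MALE",
    "activation_table",
    "between_subject_summary",
    "within_subject_summary",
    "structural_summary",
]

#: The 12 movement conditions, in table order.
CONDITIONS = [
    "eyes",
    "jaw",
    "lips",
    "tongue",
    "upper_arms",
    "forearms",
    "wrists",
    "fingers",
    "left_leg",
    "right_leg",
    "ankles",
    "toes",
]

N_FEMALE = 33
N_MALE = 28

# condition -> (significant voxels F, significant voxels M,
#               printed percent difference, printed similarity r)
_ACTIVATION = {
    "eyes": (38843, 53649, 38.12, 0.66),
    "jaw": (14336, 34774, 142.56, 0.56),
    "lips": (27593, 36828, 33.47, 0.64),
    "tongue": (37443, 52374, 39.88, 0.64),
    "upper_arms": (9434, 30045, 218.48, 0.48),
    "forearms": (22018, 38586, 75.25, 0.60),
    "wrists": (26317, 47832, 81.75, 0.64),
    "fingers": (27359, 47557, 73.83, 0.65),
    "left_leg": (6267, 8892, 41.89, 0.70),
    "right_leg": (5325, 10933, 105.31, 0.64),
    "ankles": (11112, 35301, 217.68, 0.51),
    "toes": (29737, 42820, 44.00, 0.64),
}

# Between-subject pairwise-correlation summaries, per condition:
# (mean F, SD F, mean M, SD M, printed t, printed d).  Pair counts are
# C(33,2)=528 and C(28,2)=378; the printed dof is 904.
_BETWEEN_SUBJECT = {
    "eyes": (0.259, 0.085, 0.226, 0.064, 6.247, 0.430),
    "jaw": (0.228, 0.056, 0.187, 0.055, 11.021, 0.744),
    "lips": (0.231, 0.066, 0.201, 0.063, 6.883, 0.465),
    "tongue": (0.278, 0.069, 0.264, 0.056, 3.274, 0.224),
    "upper_arms": (0.216, 0.079, 0.200, 0.061, 3.483, 0.240),
    "forearms": (0.239, 0.072, 0.209, 0.047, 7.253, 0.505),
    "wrists": (0.302, 0.063, 0.266, 0.062, 8.530, 0.576),
    "fingers": (0.303, 0.068, 0.280, 0.066, 5.179, 0.350),
    "left_leg": (0.217, 0.085, 0.183, 0.083, 5.886, 0.398),
    "right_leg": (0.199, 0.096, 0.209, 0.083, -1.598, -0.109),
    "ankles": (0.216, 0.072, 0.188, 0.066, 5.906, 0.401),
    "toes": (0.244, 0.070, 0.184, 0.055, 9.023, 0.620),
}

# Within-subject between-run correlation summaries (subjects as observations,
# dof 59), including the rest fixation condition.
_WITHIN_SUBJECT = {
    "eyes": (0.190, 0.101, 0.181, 0.100, 0.369, 0.095),
    "jaw": (0.174, 0.063, 0.172, 0.092, 0.096, 0.024),
    "lips": (0.189, 0.086, 0.180, 0.082, 0.452, 0.116),
    "tongue": (0.269, 0.085, 0.226, 0.103, 1.774, 0.452),
    "upper_arms": (0.241, 0.079, 0.225, 0.089, 0.700, 0.179),
    "forearms": (0.195, 0.080, 0.186, 0.073, 0.452, 0.116),
    "wrists": (0.223, 0.092, 0.219, 0.087, 0.161, 0.041),
    "fingers": (0.206, 0.092, 0.199, 0.071, 0.335, 0.087),
    "left_leg": (0.195, 0.067, 0.219, 0.099, -1.129, -0.285),
    "right_leg": (0.181, 0.054, 0.242, 0.120, -2.588, -0.646),
    "ankles": (0.148, 0.073, 0.161, 0.071, -0.705, -0.181),
    "toes": (0.154, 0.073, 0.141, 0.079, 0.685, 0.175),
    "rest": (0.059, 0.033, 0.048, 0.022, 1.511, 0.394),
}

# Structural group statistics: total brain volume in mm^3; the other metrics
# are printed as ratios to brain volume (thickness mm / mm^3, others
# dimensionless-ish per-volume ratios).
_STRUCTURAL = {
    "brain_volume_mm3": (1_099_719.242, 55_040.247, 1_230_966.679, 110_273.860),
    "thickness_ratio_left": (2.18e-6, 1.17e-7, 1.99e-6, 1.75e-7),
    "thickness_ratio_right": (2.19e-6, 1.17e-7, 1.99e-6, 1.70e-7),
    "gm_volume_ratio_left": (0.211, 0.008, 0.214, 0.007),
    "gm_volume_ratio_right": (0.212, 0.008, 0.215, 0.007),
    "surface_area_ratio_left": (0.075, 0.002, 0.075, 0.002),
    "surface_area_ratio_right": (0.075, 0.002, 0.075, 0.002),
}


def activation_table() -> pd.DataFrame:
    """Group-level activation extent and spatial similarity, per condition.

    Columns: ``voxels_female``, ``voxels_male`` (significant-voxel counts on
    the 2 mm grid), ``percent_difference_printed``, ``similarity_r``.
    """
    return pd.DataFrame.from_dict(
        _ACTIVATION,
        orient="index",
        columns=[
            "voxels_female",
            "voxels_male",
            "percent_difference_printed",
            "similarity_r",
        ],
    ).rename_axis("condition")


def between_subject_summary() -> pd.DataFrame:
    """Between-subject pairwise-correlation summaries per condition."""
    return pd.DataFrame.from_dict(
        _BETWEEN_SUBJECT,
        orient="index",
        columns=["mean_female", "sd_female", "mean_male", "sd_male", "t_printed", "d_printed"],
    ).rename_axis("condition")


def within_subject_summary() -> pd.DataFrame:
    """Within-subject between-run correlation summaries per condition."""
    return pd.DataFrame.from_dict(
        _WITHIN_SUBJECT,
        orient="index",
        columns=["mean_female", "sd_female", "mean_male", "sd_male", "t_printed", "d_printed"],
    ).rename_axis("condition")


def structural_summary() -> pd.DataFrame:
    """Structural group statistics (brain volume raw, other metrics as ratios)."""
    return pd.DataFrame.from_dict(
        _STRUCTURAL,
        orient="index",
        columns=["mean_female", "sd_female", "mean_male", "sd_male"],
    ).rename_axis("metric")
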