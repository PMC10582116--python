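"""Monte-Carlo calibration and planted-effect recovery experiments.

These experiments validate the inference machinery against the synthetic
generator's ground truth: type-I error of the max-statistic FWE procedure
and of the pair-level permutation test under null cohorts, and recovery of
planted group differences in activation extent (footprint radius) and
between-subject spatial variability (footprint-center jitter).
"""

from __future__ import annotations

import numpy as np

from .design_glm import build_design_matrix, fit_glm, fixed_effects_combine
from .group_inference import (
    TfceParams,
    permutation_one_sample,
    permutation_two_sample,
    threshold_map,
)
from .activation_metrics import count_significant_voxels
from .synthetic_cohort import (
    CohortSpec,
    footprint_mask,
    make_block_design,
    make_cohort,
    simulate_run,
)
from .variability_stats import pairwise_between_subject, permutation_ttest, within_subject_between_run

__all__ = [
    "fit_cohort",
    "null_cohort_fwe_rate",
    "pair_test_type_i_rate",
    "structural_volume_power",
    "extent_recovery",
    "jitter_recovery",
]


def _seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(np.random.SeedSequence(seed)).integers(2**31, size=n)


def fit_cohort(spec: CohortSpec, seed: int):
    """Simulate and fit every subject of a cohort.

    Returns ``(truth, results)`` where ``results[subject_id]`` is the
    fixed-effects :class:`~motormap.design_glm.SubjectLevelResult` (or the
    single run's first-level result when the cohort has one run) plus the
    per-run t-maps.
    """
    truth = make_cohort(spec)
    events = [make_block_design(spec, r, spec.seed) for r in range(spec.n_runs)]
    designs = [
        build_design_matrix(ev, spec.n_timepoints, spec.tr_s, spec.hrf, list(spec.conditions))
        for ev in events
    ]
    sim_seeds = _seeds(seed, len(truth) * spec.n_runs).reshape(len(truth), spec.n_runs)
    results = {}
    for si, subj in enumerate(truth):
        run_results = [
            fit_glm(
                simulate_run(subj, events[r], spec, int(sim_seeds[si, r]), r), designs[r]
            )
            for r in range(spec.n_runs)
        ]
        combined = (
            fixed_effects_combine(run_results) if spec.n_runs > 1 else run_results[0]
        )
        results[subj.subject_id] = (subj.group, combined, run_results)
    return truth, results


def null_cohort_fwe_rate(
    n_replicates: int = 200,
    n_subjects: int = 8,
    grid_shape: tuple[int, int, int] = (10, 10, 10),
    n_perm: int = 99,
    alpha: float = 0.05,
    seed: int = 0,
    tfce: TfceParams = TfceParams(n_steps=25),
) -> dict:
    """Type-I error of the one-sample max-TFCE FWE procedure.

    Each replicate simulates a cohort with zero activation amplitude through
    the full generator + GLM path and asks whether any voxel reaches
    FWE p <= alpha.  Returns the rejection rate, its Monte-Carlo SE and the
    replicate count.
    """
    spec = CohortSpec(
        n_group_a=n_subjects,
        n_group_b=1,
        grid_shape=grid_shape,
        conditions=["eyes"],
        footprint_centers={"eyes": tuple(s / 2 for s in grid_shape)},
        footprint_radius_vox=2.0,
        amplitude=0.0,
        center_jitter_sd_vox=0.0,
        noise_sd=1.0,
        n_runs=1,
        seed=seed,
    )
    events = make_block_design(spec, 0, spec.seed)
    design = build_design_matrix(events, spec.n_timepoints, spec.tr_s, spec.hrf, ["eyes"])
    truth = make_cohort(spec)[:n_subjects]
    rep_seeds = _seeds(seed, n_replicates * (n_subjects + 1)).reshape(n_replicates, -1)
    rejections = 0
    for rep in range(n_replicates):
        copes = [
            fit_glm(
                simulate_run(truth[i], events, spec, int(rep_seeds[rep, i])), design
            ).cope["eyes"]
            for i in range(n_subjects)
        ]
        res = permutation_one_sample(copes, tfce, n_perm, int(rep_seeds[rep, -1]))
        rejections += bool((res.fwe_p.data <= alpha).any())
    rate = rejections / n_replicates
    return {
        "rate": rate,
        "mc_se": float(np.sqrt(alpha * (1 - alpha) / n_replicates)),
        "n": n_replicates,
    }


def pair_test_type_i_rate(
    n_replicates: int = 500,
    n_a: int = 20,
    n_b: int = 20,
    n_perm: int = 299,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the pair-level permutation t-test on i.i.d. null
    draws."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for rep in range(n_replicates):
        a = rng.standard_normal(n_a)
        b = rng.standard_normal(n_b)
        res = permutation_ttest(a, b, n_perm=n_perm, seed=int(rng.integers(2**31)))
        rejections += res.p_value <= alpha
    return {
        "rate": rejections / n_replicates,
        "mc_se": float(np.sqrt(alpha * (1 - alpha) / n_replicates)),
        "n": n_replicates,
    }


def structural_volume_power(
    n_replicates: int = 100,
    n_a: int = 33,
    n_b: int = 28,
    n_perm: int = 2000,
    seed: int = 0,
) -> dict:
    """Power to detect the published brain-volume group difference.

    Each replicate draws a structural table at the published group means and
    SDs (group B ~12% larger brains) at full cohort sizes and asks whether
    total brain volume is flagged at the Bonferroni-corrected alpha/7."""
    from .structural_stats import compare_structural
    from .synthetic_cohort import make_structural_table

    spec = CohortSpec(
        n_group_a=n_a, n_group_b=n_b, grid_shape=(8, 8, 8),
        conditions=["eyes"], footprint_centers={"eyes": (4.0, 4.0, 4.0)},
        footprint_radius_vox=1.5, seed=seed,
    )
    rep_seeds = _seeds(seed, 2 * n_replicates).reshape(n_replicates, 2)
    hits = 0
    for rep in range(n_replicates):
        table = make_structural_table(spec, seed=int(rep_seeds[rep, 0]))
        out = compare_structural(
            table[table["group"] == "A"], table[table["group"] == "B"],
            n_perm=n_perm, seed=int(rep_seeds[rep, 1]),
        )
        hits += bool(out.loc["brain_volume_mm3", "significant"])
    return {"power": hits / n_replicates, "n": n_replicates}


def _recovery_spec(seed: int, **overrides) -> CohortSpec:
    defaults = dict(
        n_group_a=8,
        n_group_b=8,
        grid_shape=(16, 16, 16),
        conditions=["eyes", "fingers"],
        footprint_centers={"eyes": (5.0, 5.0, 8.0), "fingers": (11.0, 11.0, 8.0)},
        footprint_radius_vox=2.5,
        amplitude=2.5,
        center_jitter_sd_vox=0.3,
        noise_sd=1.0,
        n_runs=2,
        seed=seed,
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)


def extent_recovery(
    seed: int = 0,
    n_perm: int = 1000,
    alpha: float = 0.05,
    tfce: TfceParams = TfceParams(n_steps=50),
) -> dict:
    """Recovery of a planted activation-extent difference.

    Group A footprints have radius 2 voxels, group B radius 4: group B must
    show more significant voxels in every condition, the b>a contrast must
    reject inside the B-only ring, and the a>b contrast must reject nowhere.
    """
    spec = _recovery_spec(seed, footprint_radius_vox={"A": 2.0, "B": 4.0})
    _, results = fit_cohort(spec, seed)
    copes = {
        g: {
            c: [res.cope[c] for grp, res, _ in results.values() if grp == g]
            for c in spec.conditions
        }
        for g in ("A", "B")
    }
    pseeds = _seeds(seed + 1, 4 * len(spec.conditions))
    out: dict = {"conditions": list(spec.conditions)}
    counts_a, counts_b, ring_hits, agtb_hits = {}, {}, {}, {}
    for ci, cond in enumerate(spec.conditions):
        res_a = permutation_one_sample(copes["A"][cond], tfce, n_perm, int(pseeds[4 * ci]))
        res_b = permutation_one_sample(copes["B"][cond], tfce, n_perm, int(pseeds[4 * ci + 1]))
        counts_a[cond] = count_significant_voxels(threshold_map(res_a, alpha))
        counts_b[cond] = count_significant_voxels(threshold_map(res_b, alpha))
        res_bga = permutation_two_sample(
            copes["A"][cond], copes["B"][cond], tfce, n_perm,
            int(pseeds[4 * ci + 2]), direction="b_gt_a",
        )
        res_agb = permutation_two_sample(
            copes["A"][cond], copes["B"][cond], tfce, n_perm,
            int(pseeds[4 * ci + 3]), direction="a_gt_b",
        )
        center = spec.footprint_centers[cond]
        ring = footprint_mask(center, 4.0, spec.grid_shape) & ~footprint_mask(
            center, 2.0, spec.grid_shape
        )
        sig_bga = threshold_map(res_bga, alpha).data.astype(bool)
        ring_hits[cond] = int((sig_bga & ring).sum())
        agtb_hits[cond] = count_significant_voxels(threshold_map(res_agb, alpha))
    out["voxels_a"] = counts_a
    out["voxels_b"] = counts_b
    out["b_gt_a_ring_voxels"] = ring_hits
    out["a_gt_b_voxels"] = agtb_hits
    return out


def jitter_recovery(
    seed: int = 0,
    n_perm: int = 2000,
    jitter_levels: tuple[float, ...] = (0.3, 1.2, 2.4),
) -> dict:
    """Recovery of a planted between-subject variability difference.

    Group B's footprint centers jitter more than group A's (2.4 vs 0.3
    voxels SD): group B's mean between-subject t-map correlation must be
    lower, while within-subject between-run consistency — which jitter does
    not touch — must not differ.  Also returns the mean between-subject
    correlation at increasing jitter levels (same group size and seeds) to
    expose the monotone decrease.
    """
    spec = _recovery_spec(seed, center_jitter_sd_vox={"A": 0.3, "B": 2.4})
    _, results = fit_cohort(spec, seed)
    cond = "eyes"
    tmaps = {g: [res.tmap[cond] for grp, res, _ in results.values() if grp == g] for g in ("A", "B")}
    set_a = pairwise_between_subject(tmaps["A"], group="A", condition=cond)
    set_b = pairwise_between_subject(tmaps["B"], group="B", condition=cond)
    between = permutation_ttest(set_a.values, set_b.values, n_perm=n_perm, seed=seed + 7)

    within = {
        g: np.array(
            [
                within_subject_between_run([rr.tmap[cond] for rr in runs])
                for grp, _, runs in results.values()
                if grp == g
            ]
        )
        for g in ("A", "B")
    }
    within_test = permutation_ttest(within["A"], within["B"], n_perm=n_perm, seed=seed + 11)

    sweep = []
    for li, level in enumerate(jitter_levels):
        sp = _recovery_spec(seed + 100 + li, center_jitter_sd_vox=level)
        _, res_l = fit_cohort(sp, seed + 200 + li)
        maps = [r.tmap[cond] for grp, r, _ in res_l.values() if grp == "A"]
        sweep.append(float(pairwise_between_subject(maps).values.mean()))

    return {
        "between_mean_a": float(set_a.values.mean()),
        "between_mean_b": float(set_b.values.mean()),
        "between_t": between.t_statistic,
        "between_p": between.p_value,
        "within_mean_a": float(within["A"].mean()),
        "within_mean_b": float(within["B"].mean()),
        "within_p": within_test.p_value,
        "jitter_levels": list(jitter_levels),
        "between_mean_by_jitter": sweep,
        "n_pairs_per_group": int(len(set_a.values)),
    }
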