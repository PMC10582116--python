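"""End-to-end orchestration of the motor-mapping analysis on a synthetic
cohort.

Stages: simulate cohort -> first-level GLM per run -> fixed-effects
combination per subject -> per-group one-sample and between-group two-sample
TFCE permutation inference -> activation-extent/similarity table ->
between-subject and within-subject variability tables -> structural
comparisons -> JSON manifest.  Every stage seed derives from the single
config seed and is recorded in the manifest; outputs are written only to
the run's output directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activation_metrics import (
    activation_summary,
    count_significant_voxels,
    significance_map,
    similarity_by_condition,
)
from .core import StatMap
from .design_glm import (
    HrfParams,
    build_design_matrix,
    fit_glm,
    fixed_effects_combine,
)
from .group_inference import (
    GroupPermResult,
    TfceParams,
    permutation_one_sample,
    permutation_two_sample,
    threshold_map,
)
from .io import write_events, write_stat_map, write_table
from .structural_stats import compare_structural
from .synthetic_cohort import (
    CohortSpec,
    make_block_design,
    make_cohort,
    make_structural_table,
    simulate_run,
)
from .variability_stats import (
    bonferroni_flags,
    pairwise_between_subject,
    permutation_ttest,
    within_subject_between_run,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs.

    ``n_perm_group`` / ``n_perm_behavioral`` default to the full-scale
    analysis settings (5,000 map permutations, 20,000 scalar permutations);
    :meth:`test_scale` provides a minutes-scale profile.
    ``bonferroni_m_variability`` of None means "the number of conditions
    actually compared" (12 at full scale, i.e. alpha = 0.05/12).
    """

    cohort: CohortSpec = field(default_factory=CohortSpec)
    hrf: HrfParams = field(default_factory=HrfParams)
    tfce: TfceParams = field(default_factory=TfceParams)
    n_perm_group: int = 5000
    n_perm_behavioral: int = 20000
    alpha: float = 0.05
    bonferroni_m_variability: int | None = None
    bonferroni_m_structural: int = 7
    seed: int = 0
    write_runs: bool = False

    @classmethod
    def test_scale(cls, **overrides) -> "PipelineConfig":
        """Small profile: 12^3 grid, 2 conditions + rest, 4+4 subjects."""
        defaults = dict(
            cohort=CohortSpec(
                n_group_a=6,
                n_group_b=6,
                grid_shape=(12, 12, 12),
                n_runs=2,
                conditions=["eyes", "fingers", "rest"],
                footprint_centers={"eyes": (4.0, 4.0, 6.0), "fingers": (8.0, 8.0, 6.0)},
                footprint_radius_vox=2.5,
                amplitude=3.0,
                noise_sd=1.0,
            ),
            tfce=TfceParams(n_steps=25),
            n_perm_group=100,
            n_perm_behavioral=500,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def paper_scale(cls, **overrides) -> "PipelineConfig":
        """The full study profile: 33 + 28 subjects, 12 conditions, 6 runs,
        5,000 / 20,000 permutations (the voxel grid stays scaled down)."""
        defaults = dict(cohort=CohortSpec.paper_scale())
        defaults.update(overrides)
        return cls(**defaults)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "cohort" in d:
            cohort = d["cohort"]
            if "hrf" in cohort:
                cohort["hrf"] = HrfParams(**cohort["hrf"])
            if "grid_shape" in cohort:
                cohort["grid_shape"] = tuple(cohort["grid_shape"])
            if "footprint_centers" in cohort and cohort["footprint_centers"]:
                cohort["footprint_centers"] = {
                    k: tuple(v) for k, v in cohort["footprint_centers"].items()
                }
            d["cohort"] = CohortSpec(**cohort)
        if "hrf" in d:
            d["hrf"] = HrfParams(**d["hrf"])
        if "tfce" in d:
            d["tfce"] = TfceParams(**d["tfce"])
        return cls(**d)


@dataclass
class PipelineResult:
    """In-memory bundle of everything the pipeline computed."""

    activation_table: pd.DataFrame
    activation_summary: dict
    between_subject_table: pd.DataFrame
    within_subject_table: pd.DataFrame
    structural_table: pd.DataFrame
    group_results: dict
    manifest: dict


def _derive_seeds(seed: int, n_subjects: int, n_runs: int) -> dict:
    """Per-stage integer seeds, all derived from the single master seed."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return {
        "simulate": rng.integers(2**31, size=(n_subjects, n_runs)).tolist(),
        "group": int(rng.integers(2**31)),
        "behavioral": int(rng.integers(2**31)),
        "structural": int(rng.integers(2**31)),
    }


def _write_group_maps(out: Path, tag: str, res: GroupPermResult, alpha: float) -> None:
    write_stat_map(res.observed_stat, out / f"{tag}_stat-t.nii.gz")
    write_stat_map(res.observed_tfce, out / f"{tag}_stat-tfce.nii.gz")
    write_stat_map(res.fwe_p, out / f"{tag}_stat-fwep.nii.gz")
    sidecar = {
        "n_perm": res.n_perm,
        "seed": res.seed,
        "exhaustive": res.exhaustive,
        "alpha": alpha,
    }
    (out / f"{tag}.json").write_text(json.dumps(sidecar, indent=2))


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Run every stage on one synthetic cohort and write the report bundle.

    Idempotent for fixed seeds: rerunning with the same config produces
    byte-identical tables.
    """
    t_start = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.cohort
    conditions = list(spec.conditions)
    n_subj = spec.n_group_a + spec.n_group_b
    seeds = _derive_seeds(config.seed, n_subj, spec.n_runs)
    runtimes: dict[str, float] = {}

    # --- simulate + first level + fixed effects -------------------------
    t0 = time.time()
    truth = make_cohort(spec)
    events_by_run = [make_block_design(spec, r, spec.seed) for r in range(spec.n_runs)]
    designs = [
        build_design_matrix(ev, spec.n_timepoints, spec.tr_s, config.hrf, conditions)
        for ev in events_by_run
    ]
    for r, ev in enumerate(events_by_run):
        write_events(ev, out / f"run-{r}_events.tsv")

    subject_t: dict[str, dict[str, StatMap]] = {}
    subject_cope: dict[str, dict[str, StatMap]] = {}
    run_t: dict[str, dict[str, list[StatMap]]] = {}
    groups: dict[str, str] = {}
    for si, subj in enumerate(truth):
        run_results = []
        for r in range(spec.n_runs):
            run = simulate_run(
                subj, events_by_run[r], spec, seed=seeds["simulate"][si][r], run_index=r
            )
            if config.write_runs:
                from .io import write_bold_run

                write_bold_run(run, out / f"{subj.subject_id}_run-{r}_bold.nii.gz")
            run_results.append(fit_glm(run, designs[r]))
        combined = fixed_effects_combine(run_results)
        subject_t[subj.subject_id] = combined.tmap
        subject_cope[subj.subject_id] = combined.cope
        run_t[subj.subject_id] = {
            c: [rr.tmap[c] for rr in run_results] for c in conditions
        }
        groups[subj.subject_id] = subj.group
        logger.info("first-level %s done (%d runs)", subj.subject_id, spec.n_runs)
    runtimes["first_level"] = time.time() - t0

    ids_a = [s.subject_id for s in truth if s.group == "A"]
    ids_b = [s.subject_id for s in truth if s.group == "B"]

    # --- group inference -------------------------------------------------
    t0 = time.time()
    group_results: dict[str, dict[str, GroupPermResult]] = {}
    for ci, cond in enumerate(conditions):
        copes_a = [subject_cope[i][cond] for i in ids_a]
        copes_b = [subject_cope[i][cond] for i in ids_b]
        gseed = seeds["group"] + ci
        res = {
            "one_sample_a": permutation_one_sample(
                copes_a, config.tfce, config.n_perm_group, gseed
            ),
            "one_sample_b": permutation_one_sample(
                copes_b, config.tfce, config.n_perm_group, gseed + 10_000
            ),
            "a_gt_b": permutation_two_sample(
                copes_a, copes_b, config.tfce, config.n_perm_group,
                gseed + 20_000, direction="a_gt_b",
            ),
            "b_gt_a": permutation_two_sample(
                copes_a, copes_b, config.tfce, config.n_perm_group,
                gseed + 30_000, direction="b_gt_a",
            ),
        }
        group_results[cond] = res
        for tag, r in res.items():
            _write_group_maps(out, f"cond-{cond}_{tag}", r, config.alpha)
        logger.info("group inference %s done", cond)
    runtimes["group_inference"] = time.time() - t0

    # --- activation metrics ----------------------------------------------
    t0 = time.time()
    sig_a = {c: significance_map(group_results[c]["one_sample_a"], config.alpha) for c in conditions}
    sig_b = {c: significance_map(group_results[c]["one_sample_b"], config.alpha) for c in conditions}
    counts_a = {
        c: count_significant_voxels(threshold_map(group_results[c]["one_sample_a"], config.alpha))
        for c in conditions
    }
    counts_b = {
        c: count_significant_voxels(threshold_map(group_results[c]["one_sample_b"], config.alpha))
        for c in conditions
    }
    # similarity needs variance in both maps; percent difference needs a
    # nonzero group-A count — baseline-only conditions (rest) drop out here
    sim_conds = [c for c in conditions if counts_a[c] > 0 and counts_b[c] > 0]
    if sim_conds:
        sims = similarity_by_condition(
            {c: sig_a[c] for c in sim_conds}, {c: sig_b[c] for c in sim_conds}
        ).reindex(conditions)
    else:
        logger.warning("no condition significant in both groups; similarities NaN")
        sims = pd.Series({c: np.nan for c in conditions})
    usable = [c for c in conditions if counts_a[c] > 0]
    if len(usable) >= 2:
        act_table, act_summary = activation_summary(
            {c: counts_a[c] for c in usable},
            {c: counts_b[c] for c in usable},
            sims[usable],
        )
        act_table = act_table.reindex(conditions)
        act_table["voxels_a"] = [counts_a[c] for c in conditions]
        act_table["voxels_b"] = [counts_b[c] for c in conditions]
    else:
        logger.warning("fewer than 2 conditions with group-A activation; no summary")
        act_table = pd.DataFrame(
            {
                "voxels_a": [counts_a[c] for c in conditions],
                "voxels_b": [counts_b[c] for c in conditions],
                "percent_difference": np.nan,
                "similarity_r": sims,
            },
            index=pd.Index(conditions, name="condition"),
        )
        act_summary = {}
    write_table(act_table, out / "activation_table.tsv")
    runtimes["activation_metrics"] = time.time() - t0

    # --- variability -----------------------------------------------------
    t0 = time.time()
    m_var = config.bonferroni_m_variability or len(conditions)
    rows = []
    for ci, cond in enumerate(conditions):
        set_a = pairwise_between_subject(
            [subject_t[i][cond] for i in ids_a], group="A", condition=cond
        )
        set_b = pairwise_between_subject(
            [subject_t[i][cond] for i in ids_b], group="B", condition=cond
        )
        res = permutation_ttest(
            set_a.values, set_b.values,
            n_perm=config.n_perm_behavioral, seed=seeds["behavioral"] + ci,
        )
        rows.append(
            {
                "condition": cond,
                "mean_a": set_a.values.mean(),
                "sd_a": set_a.values.std(ddof=1),
                "mean_b": set_b.values.mean(),
                "sd_b": set_b.values.std(ddof=1),
                "t": res.t_statistic,
                "dof": res.dof,
                "p": res.p_value,
                "cohens_d": res.cohens_d,
            }
        )
    between_table = pd.DataFrame(rows).set_index("condition")
    between_table["significant"] = bonferroni_flags(
        between_table["p"].to_numpy(), m=m_var, alpha=config.alpha
    )
    write_table(between_table, out / "between_subject_variability.tsv")

    rows = []
    for ci, cond in enumerate(conditions):
        within_a = np.array(
            [within_subject_between_run(run_t[i][cond]) for i in ids_a]
        )
        within_b = np.array(
            [within_subject_between_run(run_t[i][cond]) for i in ids_b]
        )
        res = permutation_ttest(
            within_a, within_b,
            n_perm=config.n_perm_behavioral, seed=seeds["behavioral"] + 10_000 + ci,
        )
        rows.append(
            {
                "condition": cond,
                "mean_a": within_a.mean(),
                "sd_a": within_a.std(ddof=1),
                "mean_b": within_b.mean(),
                "sd_b": within_b.std(ddof=1),
                "t": res.t_statistic,
                "dof": res.dof,
                "p": res.p_value,
                "cohens_d": res.cohens_d,
            }
        )
    within_table = pd.DataFrame(rows).set_index("condition")
    within_table["significant"] = bonferroni_flags(
        within_table["p"].to_numpy(), m=m_var, alpha=config.alpha
    )
    write_table(within_table, out / "within_subject_variability.tsv")
    runtimes["variability"] = time.time() - t0

    # --- structural -------------------------------------------------------
    t0 = time.time()
    struct = make_structural_table(spec, seed=seeds["structural"])
    write_table(struct, out / "structural_metrics.tsv", index=False)
    struct_table = compare_structural(
        struct[struct["group"] == "A"],
        struct[struct["group"] == "B"],
        n_perm=config.n_perm_behavioral,
        seed=seeds["structural"],
        alpha=config.alpha,
    )
    write_table(struct_table, out / "structural_comparisons.tsv")
    runtimes["structural"] = time.time() - t0

    manifest = {
        "motormap_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "derived_seeds": seeds,
        "n_perm_group": config.n_perm_group,
        "n_perm_behavioral": config.n_perm_behavioral,
        "alpha": config.alpha,
        "bonferroni_m_variability": m_var,
        "bonferroni_m_structural": config.bonferroni_m_structural,
        "tfce": asdict(config.tfce),
        "cohort": {
            k: v for k, v in asdict(spec).items() if k != "hrf"
        },
        "runtimes_s": {k: round(v, 3) for k, v in runtimes.items()},
        "total_runtime_s": round(time.time() - t_start, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return PipelineResult(
        activation_table=act_table,
        activation_summary=act_summary,
        between_subject_table=between_table,
        within_subject_table=within_table,
        structural_table=struct_table,
        group_results=group_results,
        manifest=manifest,
    )
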