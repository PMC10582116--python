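"""Ground-truth generator: footprints, block schedules, BOLD simulation,
structural tables."""

import numpy as np
import pandas as pd
import pytest

from motormap.design_glm import double_gamma_hrf
from motormap.synthetic_cohort import (
    CohortSpec,
    SchedulingError,
    footprint_mask,
    make_block_design,
    make_cohort,
    make_structural_table,
    simulate_run,
)


def paper_design_spec(**overrides):
    """12 conditions x 2 blocks x 6 runs — the full block-design shape."""
    from motormap.reference import CONDITIONS

    defaults = dict(
        n_group_a=2, n_group_b=2, grid_shape=(16, 16, 16), n_runs=6,
        conditions=list(CONDITIONS), footprint_radius_vox=2.0,
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)


class TestMakeCohort:
    def test_zero_jitter_centers_equal_group_centers(self, tiny_spec):
        truth = make_cohort(tiny_spec)
        for subj in truth:
            for cond, fp in subj.footprints.items():
                assert fp.center == tuple(tiny_spec.footprint_centers[cond])

    def test_footprint_count_matches_exhaustive_voxel_scan(self):
        center, radius, shape = (5.2, 4.8, 5.0), 3.0, (11, 11, 11)
        mask = footprint_mask(center, radius, shape)
        # brute force: scan every voxel and test its Euclidean distance
        count = 0
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    d = np.sqrt(
                        (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
                    )
                    if d <= radius:
                        count += 1
        assert mask.sum() == count

    def test_same_seed_is_bit_identical(self, tiny_spec):
        spec = CohortSpec(**{**tiny_spec.__dict__, "center_jitter_sd_vox": 1.0})
        t1, t2 = make_cohort(spec), make_cohort(spec)
        for s1, s2 in zip(t1, t2):
            assert s1 == s2

    def test_footprint_volume_monotone_in_radius(self):
        shape = (15, 15, 15)
        counts = [
            footprint_mask((7, 7, 7), r, shape).sum()
            for r in np.linspace(0.5, 6.0, 12)
        ]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_center_outside_grid_names_field(self):
        with pytest.raises(ValueError, match="footprint_centers"):
            CohortSpec(
                grid_shape=(10, 10, 10),
                conditions=["eyes"],
                footprint_centers={"eyes": (20.0, 5.0, 5.0)},
            )

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValueError, match="footprint_radius_vox"):
            CohortSpec(grid_shape=(10, 10, 10), footprint_radius_vox=6.0)


class TestBlockDesign:
    def test_full_design_counts_and_task_time(self):
        spec = paper_design_spec()
        events = make_block_design(spec, run_index=0, seed=0)
        assert len(events) == 24  # 12 conditions x 2 blocks
        assert events["duration"].sum() == pytest.approx(384.0)  # 24 x 16 s
        assert (events.groupby("trial_type").size() == 2).all()

    def test_single_condition_single_block(self):
        spec = CohortSpec(
            conditions=["eyes"],
            blocks_per_run_per_condition=1,
            footprint_centers={"eyes": (12.0, 12.0, 12.0)},
        )
        events = make_block_design(spec, 0, 0)
        assert len(events) == 1
        assert events.loc[0, "duration"] == 16.0

    def test_task_seconds_per_condition_is_192_at_full_scale(self):
        spec = paper_design_spec()
        total = sum(
            make_block_design(spec, r, 0)
            .groupby("trial_type")["duration"]
            .sum()["tongue"]
            for r in range(spec.n_runs)
        )
        assert total == pytest.approx(192.0)
        assert spec.task_seconds_per_condition == pytest.approx(192.0)

    def test_blocks_of_same_condition_never_overlap(self):
        spec = paper_design_spec()
        events = make_block_design(spec, 3, 11).sort_values("onset")
        ends = (events["onset"] + events["duration"]).to_numpy()
        assert (events["onset"].to_numpy()[1:] >= ends[:-1]).all()

    def test_too_short_run_raises_scheduling_error(self):
        with pytest.raises(SchedulingError):
            CohortSpec(conditions=["eyes", "jaw"], run_duration_s=30.0)


class TestSimulateRun:
    def test_zero_amplitude_zero_noise_is_constant_baseline(self, tiny_spec):
        spec = CohortSpec(**{**tiny_spec.__dict__, "amplitude": 0.0, "noise_sd": 0.0})
        truth = make_cohort(spec)
        events = make_block_design(spec, 0, 0)
        run = simulate_run(truth[0], events, spec, seed=0)
        assert np.all(run.data == spec.baseline)

    def test_plateau_matches_direct_convolution_oracle(self, tiny_spec):
        spec = CohortSpec(**{**tiny_spec.__dict__, "amplitude": 1.5, "noise_sd": 0.0})
        truth = make_cohort(spec)
        events = make_block_design(spec, 0, 0)
        run = simulate_run(truth[0], events, spec, seed=0)
        # independent oracle: discrete convolution of the boxcar with the
        # unit-integral double-gamma kernel on the oversampled grid
        dt = spec.hrf.oversample_dt_s
        t_hi = np.arange(0.0, spec.n_timepoints * spec.tr_s, dt)
        u = np.zeros_like(t_hi)
        for _, row in events[events["trial_type"] == "eyes"].iterrows():
            u[(t_hi >= row["onset"]) & (t_hi < row["onset"] + row["duration"])] = 1.0
        _, kernel = double_gamma_hrf(spec.hrf)
        conv = np.convolve(u, kernel / kernel.sum())[: len(t_hi)]
        idx = np.round(np.arange(spec.n_timepoints) * spec.tr_s / dt).astype(int)
        expected = spec.baseline * (1.0 + 0.015 * conv[idx])
        cx, cy, cz = (int(round(c)) for c in truth[0].footprints["eyes"].center)
        np.testing.assert_allclose(run.data[cx, cy, cz], expected, rtol=1e-10)
        # a voxel outside every footprint stays at baseline
        assert np.all(run.data[0, 0, 0] == spec.baseline)

    def test_noise_sd_recovered_from_time_series(self, tiny_spec):
        spec = CohortSpec(**{**tiny_spec.__dict__, "amplitude": 0.0, "noise_sd": 10.0})
        truth = make_cohort(spec)
        events = make_block_design(spec, 0, 0)
        run = simulate_run(truth[0], events, spec, seed=42)
        sds = run.data.std(axis=3, ddof=1)
        # SE of a sample SD of n normal draws is roughly sd/sqrt(2(n-1))
        se = 10.0 / np.sqrt(2 * (run.n_timepoints - 1)) / np.sqrt(sds.size)
        assert abs(sds.mean() - 10.0) < 3 * se

    def test_noise_free_run_is_bit_reproducible(self, tiny_spec):
        spec = CohortSpec(**{**tiny_spec.__dict__, "noise_sd": 0.0})
        truth = make_cohort(spec)
        events = make_block_design(spec, 0, 0)
        r1 = simulate_run(truth[0], events, spec, seed=0)
        r2 = simulate_run(truth[0], events, spec, seed=99)  # seed irrelevant w/o noise
        assert np.array_equal(r1.data, r2.data)


class TestStructuralTable:
    MEANS = {
        g: {m: v for m, v in zip(
            ["brain_volume_mm3", "thickness_mm_left", "thickness_mm_right",
             "gm_volume_mm3_left", "gm_volume_mm3_right",
             "surface_area_mm2_left", "surface_area_mm2_right"],
            vals,
        )}
        for g, vals in {
            "A": [1.10e6, 2.40, 2.41, 2.3e5, 2.3e5, 8.2e4, 8.2e4],
            "B": [1.23e6, 2.45, 2.45, 2.6e5, 2.6e5, 9.2e4, 9.2e4],
        }.items()
    }

    def test_zero_sd_reproduces_means_exactly(self, tiny_spec):
        sds = {g: {m: 0.0 for m in ms} for g, ms in self.MEANS.items()}
        table = make_structural_table(tiny_spec, self.MEANS, sds, seed=0)
        for _, row in table.iterrows():
            for metric, mean in self.MEANS[row["group"]].items():
                assert row[metric] == mean

    def test_lognormal_moments_match_at_large_n(self):
        spec = CohortSpec(n_group_a=500, n_group_b=500, grid_shape=(8, 8, 8),
                          conditions=["eyes"], footprint_centers={"eyes": (4, 4, 4)},
                          footprint_radius_vox=1.5)
        sds = {g: {m: 0.05 * v for m, v in ms.items()} for g, ms in self.MEANS.items()}
        table = make_structural_table(spec, self.MEANS, sds, seed=3)
        a = table[table["group"] == "A"]
        assert a["brain_volume_mm3"].mean() == pytest.approx(1.10e6, rel=0.01)
        b = table[table["group"] == "B"]
        assert b["brain_volume_mm3"].mean() == pytest.approx(1.23e6, rel=0.01)

    def test_same_seed_identical_table(self, tiny_spec):
        t1 = make_structural_table(tiny_spec, seed=5)
        t2 = make_structural_table(tiny_spec, seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_nonpositive_mean_rejected(self, tiny_spec):
        means = {g: dict(ms) for g, ms in self.MEANS.items()}
        means["A"]["thickness_mm_left"] = -1.0
        sds = {g: {m: 0.0 for m in ms} for g, ms in self.MEANS.items()}
        with pytest.raises(ValueError, match="thickness_mm_left"):
            make_structural_table(tiny_spec, means, sds, seed=0)
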