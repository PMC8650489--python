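"""Synthetic cohort generator: design arithmetic, determinism, planted structure."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from nmigraph import (build_connectivity_matrix, censor_motion, make_atlas_fixture,
                      make_block_design, select_task_volumes, simulate_cohort,
                      simulate_subject, small_spec)


class TestMakeBlockDesign:
    def test_study_design_360_volumes_180_task(self):
        d = make_block_design(15, 30, 30, 2.5)
        assert d.n_volumes == 360
        assert d.n_task_volumes == 180
        assert d.task_mask[0] and not d.task_mask[-1]

    def test_single_block_one_volume_each(self):
        d = make_block_design(1, 30, 30, 30)
        assert d.task_mask.tolist() == [True, False]

    def test_derived_arithmetic(self):
        d = make_block_design(2, 10, 20, 2.5)
        assert d.n_volumes == 24
        assert d.n_task_volumes == 8

    def test_non_divisible_timing_rejected_with_remainder(self):
        with pytest.raises(ValueError, match="remainder"):
            make_block_design(3, 31, 30, 2.5)


class TestSimulateSubject:
    def test_deterministic_given_seeds(self):
        spec = small_spec(seed=4, n_rois=12)
        ts1, m1 = simulate_subject(spec, "A", 3)
        ts2, m2 = simulate_subject(spec, "A", 3)
        assert np.array_equal(ts1.values, ts2.values)
        assert np.array_equal(m1.mm, m2.mm)

    def test_zero_coupling_leaves_no_dependence(self):
        # mean off-diagonal NMI below the 95th percentile of a permutation null
        spec = small_spec(seed=0, n_rois=12, within=0.0, between=0.0)
        ts, motion = simulate_subject(spec, "A", 0)
        ts = select_task_volumes(ts, spec.design, censor_motion(motion.mm))
        cm = build_connectivity_matrix(ts)
        off = cm.weights[~np.eye(12, dtype=bool)]
        rng = np.random.default_rng(99)
        null = []
        from nmigraph import nmi_coefficient
        for _ in range(200):
            i, j = rng.choice(12, 2, replace=False)
            null.append(nmi_coefficient(
                ts.values[i], rng.permutation(ts.values[j]), cm.n_bins).nmi)
        assert off.mean() < np.quantile(null, 0.95)

    def test_inactive_rois_are_pure_noise(self):
        spec = small_spec(seed=1, n_rois=10, within=0.9, between=0.0)
        from nmigraph import GroupEffect
        spec.structure.group_effects["B"] = GroupEffect(inactive_rois=(0, 1))
        ts, motion = simulate_subject(spec, "B", 0)
        tsa = select_task_volumes(ts, spec.design, censor_motion(motion.mm))
        cm = build_connectivity_matrix(tsa)
        aff = spec.structure.affiliation
        mates = np.flatnonzero((aff == aff[0]))[2:]  # same module, active
        active_pair = cm.weights[mates[0], mates[1]]
        inactive_pair = cm.weights[0, mates[0]]
        assert active_pair > inactive_pair

    def test_motion_spikes_exceed_threshold(self):
        spec = small_spec(seed=2, n_rois=5)
        _, motion = simulate_subject(spec, "A", 0)
        assert np.all(motion.mm >= 0)
        spikes = motion.mm > 0.5
        assert spikes.any()  # spike rate 0.05 over 360 volumes
        assert np.all(motion.mm[spikes] >= spec.motion_spike_mm)


class TestSimulateCohort:
    def test_group_sizes(self):
        spec = small_spec(seed=0, n_rois=6, n_per_group={"A": 26, "B": 20})
        cohort = simulate_cohort(spec)
        assert len(cohort) == 46
        assert sum(r.group == "A" for r in cohort) == 26

    def test_single_subject(self):
        cohort = simulate_cohort(small_spec(seed=0, n_rois=6, n_per_group={"A": 1}))
        assert len(cohort) == 1

    def test_cohort_deterministic(self):
        spec = small_spec(seed=7, n_rois=8, n_per_group={"A": 2, "B": 2})
        c1 = simulate_cohort(spec)
        c2 = simulate_cohort(spec)
        for r1, r2 in zip(c1, c2):
            assert r1.subject_id == r2.subject_id
            assert np.array_equal(r1.timeseries.values, r2.timeseries.values)
            assert np.array_equal(r1.motion.mm, r2.motion.mm)

    def test_subjects_differ_within_cohort(self):
        cohort = simulate_cohort(small_spec(seed=0, n_rois=6, n_per_group={"A": 2}))
        assert not np.array_equal(cohort[0].timeseries.values,
                                  cohort[1].timeseries.values)


class TestMakeAtlasFixture:
    def test_full_parcellation_212_rois(self):
        labels, names = make_atlas_fixture(142, 36, 34, (12, 12, 6), seed=0)
        assert len(names) == 212
        counts = np.bincount(labels.ravel(), minlength=213)
        assert np.all(counts[1:213] >= 2)
        assert names[0].startswith("ctx") and names[-1].startswith("cbl")

    def test_single_roi_two_voxels(self):
        labels, names = make_atlas_fixture(1, 0, 0, (2, 2, 2), seed=0)
        assert (labels == 1).sum() >= 2

    def test_label_histogram(self):
        labels, _ = make_atlas_fixture(3, 2, 1, (6, 6, 6), seed=0)
        counts = np.bincount(labels.ravel())
        nonzero = counts[1:]
        assert (nonzero > 0).sum() == 6
        assert np.all(nonzero[nonzero > 0] >= 2)

    def test_too_many_rois_rejected(self):
        with pytest.raises(ValueError):
            make_atlas_fixture(5, 0, 0, (2, 2, 2), seed=0)


class TestStatisticalStructure:
    def test_within_coupling_monotone_in_within_module_nmi(self):
        # median within-module NMI non-decreasing in coupling, 5 seeds;
        # steps chosen large enough to clear the plug-in estimator's bias
        medians = []
        for within in (0.0, 0.5, 0.9):
            vals = []
            for seed in range(5):
                spec = small_spec(seed=seed, n_rois=18, within=within, between=0.0)
                ts, motion = simulate_subject(spec, "A", 0)
                ts = select_task_volumes(ts, spec.design, censor_motion(motion.mm))
                cm = build_connectivity_matrix(ts)
                aff = spec.structure.affiliation
                same = (aff[:, None] == aff[None, :]) & ~np.eye(18, dtype=bool)
                vals.append(cm.weights[same].mean())
            medians.append(np.median(vals))
        assert medians[0] <= medians[1] <= medians[2]

    def test_null_nmi_exchangeable_across_pair_types(self):
        # with no planted structure, within- and between-module NMI agree
        rejections = 0
        for seed in range(5):
            spec = small_spec(seed=seed, n_rois=12, within=0.0, between=0.0)
            ts, motion = simulate_subject(spec, "A", 0)
            ts = select_task_volumes(ts, spec.design, censor_motion(motion.mm))
            cm = build_connectivity_matrix(ts)
            aff = spec.structure.affiliation
            iu = np.triu_indices(12, 1)
            same = aff[iu[0]] == aff[iu[1]]
            w = cm.weights[iu]
            p = mannwhitneyu(w[same], w[~same]).pvalue
            rejections += p < 0.01
        assert rejections <= 1
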