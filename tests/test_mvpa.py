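import math

import numpy as np
import pytest

from glassdev.contrasts import (
    STIMULUS_VS_BLANK,
    STRUCTURED_VS_RANDOM,
    ContrastDef,
)
from glassdev.glmmap import GlmResult
from glassdev.mvpa import (
    ContrastNotApplicableError,
    PatternMatrix,
    VoxelRanking,
    _paired_folds,
    assemble_patterns,
    chance_level,
    crossvalidate,
    rank_voxels,
)
from glassdev.stimgen import ScheduleEvent, StimulusSchedule
from glassdev.synthbold import BoldRun


def fake_glm(t_values):
    t = np.asarray(t_values, dtype=float)
    return GlmResult(
        betas=np.zeros((t.size, 2)),
        t=t,
        p=np.full(t.size, 0.5),
        df=10,
        contrast=np.array([1.0, 0.0]),
    )


class TestRankVoxels:
    def test_positive_sorted_descending(self):
        ranking = rank_voxels(fake_glm([5.0, 3.0, -1.0, 4.0]), np.arange(4))
        np.testing.assert_array_equal(ranking.voxel_ids, [0, 3, 1])

    def test_truncation_at_70(self, rng):
        t = rng.uniform(0.1, 10.0, size=200)
        ranking = rank_voxels(fake_glm(t), np.arange(200))
        assert len(ranking) == 70
        assert np.all(np.diff(ranking.t_values) <= 0)

    def test_all_nonpositive_yields_empty_with_warning(self):
        with pytest.warns(UserWarning, match="no positively"):
            ranking = rank_voxels(fake_glm([-1.0, 0.0, -3.0]), np.arange(3))
        assert ranking.empty

    def test_fewer_than_truncation_warns_and_keeps_all(self):
        with pytest.warns(UserWarning, match="only"):
            ranking = rank_voxels(fake_glm([1.0, 2.0, 3.0]), np.arange(3))
        assert len(ranking) == 3

    def test_tie_break_ascending_index(self):
        t = np.full(8, -1.0)
        t[[7, 3, 5]] = 2.0
        ranking = rank_voxels(fake_glm(t), np.array([7, 3, 5]))
        np.testing.assert_array_equal(ranking.voxel_ids, [3, 5, 7])

    def test_empty_voi_errors(self):
        with pytest.raises(ValueError, match="empty"):
            rank_voxels(fake_glm([1.0]), np.array([], dtype=int))


def toy_run(values_by_volume, schedule, n_voxels=3):
    data = np.tile(np.asarray(values_by_volume, dtype=float), (n_voxels, 1))
    return BoldRun(
        data=data, tr=6.0, schedule=schedule,
        voi_of_voxel=np.array(["V1"] * n_voxels),
    )


class TestAssemblePatterns:
    def test_one_volume_delay(self):
        # block occupies volumes 5-10; the delayed boxcar reads volumes 6-11
        events = [
            ScheduleEvent(0.0, 30.0, "blank"),
            ScheduleEvent(30.0, 36.0, "concentric_static"),
            ScheduleEvent(66.0, 30.0, "blank"),
        ]
        sched = StimulusSchedule(events=events)
        n_vol = sched.n_volumes(6.0)
        run = toy_run(np.arange(n_vol), sched)
        ranking = VoxelRanking(voi="V1", voxel_ids=np.arange(3), t_values=np.ones(3))
        contrast = ContrastDef("stim", frozenset({"concentric_static"}), frozenset({"blank"}))
        pm = assemble_patterns(run, contrast, ranking)
        stim_rows = pm.data[pm.labels == 1]
        assert stim_rows[0][0] == pytest.approx(np.mean(np.arange(6, 12)))

    def test_noiseless_classes_separate(self):
        events = []
        t = 0.0
        vals = []
        for i in range(8):
            label = "concentric_static" if i % 2 == 0 else "random_static"
            events.append(ScheduleEvent(t, 36.0, label))
            vals += [10.0 if i % 2 == 0 else 20.0] * 6
            t += 36.0
        sched = StimulusSchedule(events=events)
        run = toy_run(vals[: sched.n_volumes(6.0)], sched)
        ranking = VoxelRanking(voi="V1", voxel_ids=np.arange(3), t_values=np.ones(3))
        contrast = ContrastDef("c", frozenset({"concentric_static"}), frozenset({"random_static"}))
        pm = assemble_patterns(run, contrast, ranking, delay_volumes=0)
        a = pm.data[pm.labels == 1]
        b = pm.data[pm.labels == -1]
        assert np.linalg.norm(a.mean(0) - b.mean(0)) > 0
        assert np.allclose(a.std(0), 0) and np.allclose(b.std(0), 0)

    def test_session_without_random_dipoles_dropped(self, small_schedule):
        # remove the random-dipole conditions from the schedule
        events, t = [], 0.0
        for ev in small_schedule.events:
            if ev.trial_type.startswith("random"):
                continue
            events.append(ScheduleEvent(t, ev.duration, ev.trial_type))
            t += ev.duration
        sched = StimulusSchedule(events=events)
        run = toy_run(np.zeros(sched.n_volumes(6.0)), sched)
        ranking = VoxelRanking(voi="V1", voxel_ids=np.arange(3), t_values=np.ones(3))
        with pytest.raises(ContrastNotApplicableError):
            assemble_patterns(run, STRUCTURED_VS_RANDOM, ranking)

    def test_runs_with_same_schedule_averaged(self, small_schedule):
        n_vol = small_schedule.n_volumes(6.0)
        run_a = toy_run(np.zeros(n_vol), small_schedule)
        run_b = toy_run(np.full(n_vol, 10.0), small_schedule)
        ranking = VoxelRanking(voi="V1", voxel_ids=np.arange(3), t_values=np.ones(3))
        pm = assemble_patterns([run_a, run_b], STIMULUS_VS_BLANK, ranking)
        assert np.allclose(pm.data, 5.0)


class TestChanceLevel:
    def test_n100_is_0p58(self):
        assert chance_level(100).upper == pytest.approx(0.58)

    def test_n4_is_one(self):
        # CDF(3) = 0.9375 < 0.95, so k = 4
        assert chance_level(4).upper == pytest.approx(1.0)

    def test_matches_exact_enumeration(self):
        # independent oracle: exact binomial CDF via math.comb
        for n in (2, 5, 17, 64, 100, 189):
            cdf = 0.0
            k = None
            for i in range(n + 1):
                cdf += math.comb(n, i) / 2**n
                if cdf >= 0.95 - 1e-12:
                    k = i
                    break
            assert chance_level(n).upper == pytest.approx(k / n)
            assert chance_level(n).lower == pytest.approx((n - k) / n)

    def test_approaches_half_from_above(self):
        values = [chance_level(n).upper for n in (8, 32, 128, 512, 2048)]
        assert all(v > 0.5 for v in values)
        assert values == sorted(values, reverse=True)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            chance_level(0)


def separable_patterns(n_pairs=16, n_voxels=30, margin=5.0, seed=0, noise=1.0):
    rng = np.random.default_rng(seed)
    X = noise * rng.standard_normal((2 * n_pairs, n_voxels))
    y = np.array([1, -1] * n_pairs)
    X[y == 1, 0] += margin
    X[y == -1, 0] -= margin
    return PatternMatrix(
        data=X, labels=y, voxel_ids=np.arange(n_voxels), contrast="test"
    )


class TestCrossvalidate:
    def test_separable_all_folds_perfect(self):
        res = crossvalidate(separable_patterns(margin=20.0, noise=0.0), pool_size=30)
        assert res.fold_accuracies.shape == (8,)
        np.testing.assert_allclose(res.fold_accuracies, 1.0)
        assert res.significant and not res.below_chance

    def test_fold_disjointness_and_coverage(self):
        labels = np.array([1, -1] * 20)
        folds = _paired_folds(labels, 8, np.random.default_rng(0))
        all_idx = np.concatenate(folds)
        assert len(all_idx) == len(set(all_idx))  # disjoint
        # every used pattern is tested exactly once and folds are balanced
        for fold in folds:
            assert labels[fold].sum() == 0

    def test_too_few_pairs_errors(self):
        labels = np.array([1, -1] * 5)
        with pytest.raises(ValueError, match="pairs"):
            _paired_folds(labels, 8, np.random.default_rng(0))

    def test_pool_size_truncated_with_warning(self):
        pm = separable_patterns(n_voxels=10)
        with pytest.warns(UserWarning, match="exceeds"):
            res = crossvalidate(pm, pool_size=70)
        assert res.pool_size == 10

    def test_deterministic_per_seed(self):
        pm = separable_patterns(margin=1.0, seed=3)
        a = crossvalidate(pm, pool_size=30, seed=11)
        b = crossvalidate(pm, pool_size=30, seed=11)
        np.testing.assert_array_equal(a.fold_accuracies, b.fold_accuracies)

    def test_no_leakage_canary(self):
        # voxel informative only on fold-0's held-out patterns: training
        # never sees the signal, so fold 0 must stay near chance.
        rng = np.random.default_rng(5)
        n_pairs = 24
        X = rng.standard_normal((2 * n_pairs, 20))
        y = np.array([1, -1] * n_pairs)
        folds = _paired_folds(y, 8, np.random.default_rng(77))
        X[folds[0], 0] = y[folds[0]] * 50.0
        pm = PatternMatrix(data=X, labels=y, voxel_ids=np.arange(20), contrast="canary")
        res = crossvalidate(pm, pool_size=20, seed=77)
        assert res.fold_accuracies[0] <= 0.75

    def test_trace_monotone_setup(self, adult_session, infant_session):
        from glassdev.glmmap import build_design, fit_glm

        def trace_for(session):
            pin = session.pinwheel_run
            glm = fit_glm(pin, build_design(pin.schedule, pin.tr))
            ranking = rank_voxels(glm, pin.voi_indices("V1"), voi="V1")
            pm = assemble_patterns(session.glass_runs, STIMULUS_VS_BLANK, ranking)
            return crossvalidate(pm, pool_size=len(ranking), seed=1, compute_trace=True)

        adult = trace_for(adult_session)
        assert adult.trace is not None
        # rises above chance and saturates before the full pool
        assert adult.trace[-1] > adult.chance.upper
        assert np.max(adult.trace[:20]) > adult.chance.upper

        infant = trace_for(infant_session)
        inside = (infant.trace <= infant.chance.upper) & (
            infant.trace >= infant.chance.lower
        )
        assert inside[10:].mean() > 0.8

    def test_below_chance_flag(self):
        from glassdev.mvpa import ChanceLevel, ClassificationResult

        low = ClassificationResult(
            fold_accuracies=np.full(8, 0.2),
            n_patterns=64,
            pool_size=10,
            chance=ChanceLevel(n=64, upper=0.609375, lower=0.390625),
        )
        assert low.below_chance and not low.significant
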