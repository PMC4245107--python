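import numpy as np
import pytest

import storyenc as se
from storyenc.evaluation import FoldPlan, segment_series


class TestMakeFolds:
    def test_even_partition(self):
        plan = se.make_folds(100, n_folds=10, trim=0)
        assert plan.blocks == [(i * 10, (i + 1) * 10) for i in range(10)]

    def test_remainder_rows_go_to_first_blocks(self):
        plan = se.make_folds(103, n_folds=10, trim=0)
        sizes = [e - s for s, e in plan.blocks]
        assert sizes == [11, 11, 11, 10, 10, 10, 10, 10, 10, 10]
        assert plan.blocks[0][0] == 0 and plan.blocks[-1][1] == 103

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError, match="n_folds"):
            se.make_folds(100, n_folds=1)

    def test_too_small_T_reports_minimum(self):
        with pytest.raises(ValueError, match="at least"):
            se.make_folds(50, n_folds=10, trim=4)

    def test_trim_rows_belong_to_neither_side(self):
        plan = se.make_folds(100, n_folds=10, trim=3)
        train = set(plan.training_rows(4))
        held = set(plan.held_rows(4))
        assert not train & held
        trimmed = set(range(37, 40)) | set(range(50, 53))
        assert not train & trimmed
        assert train | held | trimmed == set(range(100))

    def test_held_blocks_partition_time_axis(self):
        plan = se.make_folds(97, n_folds=7, trim=2)
        rows = np.concatenate([plan.held_rows(f) for f in range(7)])
        np.testing.assert_array_equal(np.sort(rows), np.arange(97))


class TestSegmentSeries:
    def test_block_of_45_yields_two_segments(self):
        plan = FoldPlan(T=45, n_folds=1, trim=0, blocks=[(0, 45)])
        segs = segment_series(plan, seg_len=20)
        assert segs.segments == [(0, 20), (20, 40)]

    def test_exact_block_yields_one_segment(self):
        plan = FoldPlan(T=20, n_folds=1, trim=0, blocks=[(0, 20)])
        assert segment_series(plan, 20).segments == [(0, 20)]

    def test_blocks_25_and_19_yield_one_segment_total(self):
        plan = FoldPlan(T=44, n_folds=2, trim=0, blocks=[(0, 25), (25, 44)])
        segs = segment_series(plan, 20)
        assert segs.segments == [(0, 20)]
        assert segs.fold_of == [0]

    def test_oversized_segment_rejected(self):
        plan = FoldPlan(T=30, n_folds=2, trim=0, blocks=[(0, 15), (15, 30)])
        with pytest.raises(ValueError, match="exceeds"):
            segment_series(plan, 20)


class TestClassifyPair:
    def test_exact_match_wins(self):
        obs = np.array([[1.0, 2.0]])
        assert se.classify_pair(obs, obs, obs + 1) == 1.0

    def test_distances_by_hand(self):
        obs = np.array([[2.0, 0.0]])
        assert se.classify_pair(obs, [[1.0, 0.0]], [[0.0, 0.0]]) == 1.0
        assert se.classify_pair(obs, [[0.0, 0.0]], [[1.0, 0.0]]) == 0.0

    def test_tie_scores_half(self):
        obs = np.array([[1.0, 0.0]])
        assert se.classify_pair(obs, [[1.0, 1.0]], [[0.0, 0.0]]) == 0.5

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            se.classify_pair(np.zeros((2, 2)), np.zeros((2, 3)),
                             np.zeros((2, 2)))


class TestGroupConcatenate:
    def test_two_subjects_pool_voxel_axes(self):
        out = se.group_concatenate([np.zeros((20, 100)), np.ones((20, 100))])
        assert out.shape == (20, 200)

    def test_single_subject_is_identity(self):
        m = np.arange(6.0).reshape(3, 2)
        np.testing.assert_array_equal(se.group_concatenate([m]), m)

    def test_within_subject_order_preserved(self):
        a = np.arange(3.0).reshape(1, 3)
        b = np.arange(5.0).reshape(1, 5)
        out = se.group_concatenate([a, b])
        np.testing.assert_array_equal(out, np.concatenate([a, b], axis=1))

    def test_tr_mismatch_rejected(self):
        with pytest.raises(ValueError, match="TR"):
            se.group_concatenate([np.zeros((20, 3)), np.zeros((19, 3))])


class TestRunClassification:
    def test_noise_free_data_classified_perfectly(self):
        story, subjects, _ = se.default_scenario(
            seed=5, snr=np.inf, T=200, n_voxels=40, n_subjects=2,
            n_features=6)
        res = se.run_classification(subjects, story, n_folds=5,
                                    n_pairings=4, seed=0)
        assert res.accuracy == 1.0

    def test_accuracy_invariant_to_subject_order(self, small_dataset):
        story, subjects, _ = small_dataset
        kw = dict(n_folds=5, n_pairings=4, seed=2)
        a = se.run_classification(subjects, story, **kw)
        b = se.run_classification(subjects[::-1], story, **kw)
        assert a.accuracy == b.accuracy

    def test_all_alternatives_make_result_seed_free(self, small_dataset):
        story, subjects, _ = small_dataset
        kw = dict(n_folds=5, n_pairings=1000)
        a = se.run_classification(subjects, story, seed=1, **kw)
        b = se.run_classification(subjects, story, seed=99, **kw)
        assert a.accuracy == b.accuracy
        assert a.n_trials == b.n_trials

    def test_deterministic_given_seed(self, small_dataset):
        story, subjects, _ = small_dataset
        kw = dict(n_folds=5, n_pairings=3, seed=7)
        a = se.run_classification(subjects, story, **kw)
        b = se.run_classification(subjects, story, **kw)
        assert a.accuracy == b.accuracy
        assert a.per_segment.equals(b.per_segment)

    def test_trial_bookkeeping_consistent(self, small_dataset):
        story, subjects, _ = small_dataset
        res = se.run_classification(subjects, story, n_folds=5,
                                    n_pairings=4, seed=0)
        assert res.n_trials == res.per_segment["n_pairings"].sum()
        assert 0.0 <= res.accuracy <= 1.0
        assert "chance" in res.summary()

    def test_single_feature_set_restriction_runs(self, small_dataset):
        story, subjects, _ = small_dataset
        res = se.run_classification(subjects, story, feature_set="semantics",
                                    n_folds=5, n_pairings=2, seed=0)
        assert res.n_trials > 0

    def test_null_calibration_mean_near_half(self):
        # noise-only replicates: mean accuracy within 0.5 +/- 0.02
        accs = []
        for i in range(50):
            story, subjects, _ = se.default_scenario(
                seed=100 + i, snr=0.0, T=240, n_voxels=30, n_subjects=2,
                n_features=6)
            res = se.run_classification(subjects, story, n_folds=6,
                                        n_pairings=1000, seed=i)
            accs.append(res.accuracy)
        assert abs(np.mean(accs) - 0.5) <= 0.02

    def test_fewer_than_two_segments_rejected(self):
        story, subjects, _ = se.default_scenario(
            seed=5, snr=0.0, T=101, n_voxels=20, n_subjects=1,
            n_features=6)
        # only the first (21-row) block fits one 21-TR segment: no alternative
        with pytest.raises(ValueError, match="2 segments"):
            se.run_classification(subjects, story, n_folds=5, seg_len=21,
                                  n_pairings=1, seed=0)
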