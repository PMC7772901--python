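"""Segmentation, window-label assignment, task mapping, splits and folds."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from stresswear import (SyntheticSpec, Window, WindowSet,
                        assign_window_condition, generate_subject, make_folds,
                        map_task_labels, scramble_split, segment_record)


def _single_condition_record(seconds, cond=2, seed=0):
    return generate_subject(
        SyntheticSpec(n_subjects=1, schedule=((cond, float(seconds)),),
                      seed=seed), 0)


def _toy_windowset(conditions):
    windows = [Window("S0", 5.0 * i, {"EDA": np.zeros(20)}, c)
               for i, c in enumerate(conditions)]
    return WindowSet(windows, "wrist", 5.0)


class TestSegmentRecord:
    def test_chest_50s_single_condition_gives_10_windows_of_3500(self):
        rec = _single_condition_record(50)  # 35,000 samples per chest channel
        ws = segment_record(rec, site="chest")
        assert len(ws) == 10
        assert all(len(w.signals["ECG"]) == 3500 for w in ws.windows)
        assert len(ws.windows[0].signals) == 8

    def test_wrist_window_lengths_at_native_rates(self):
        rec = _single_condition_record(20)
        ws = segment_record(rec, site="wrist")
        w = ws.windows[0]
        assert len(w.signals["BVP"]) == 320
        for axis in ("ACC_X", "ACC_Y", "ACC_Z"):
            assert len(w.signals[axis]) == 160
        assert len(w.signals["EDA"]) == 20
        assert len(w.signals["TEMP"]) == 20

    def test_record_shorter_than_window_is_empty(self):
        rec = _single_condition_record(3)
        assert len(segment_record(rec, window_s=5.0)) == 0

    def test_include_acc_false_omits_acc_channels(self):
        rec = _single_condition_record(10)
        ws = segment_record(rec, site="chest", include_acc=False)
        assert set(ws.windows[0].signals) == {"ECG", "EDA", "EMG", "RESP",
                                              "TEMP"}

    def test_default_purity_rejects_condition_transitions(self):
        rec = generate_subject(
            SyntheticSpec(n_subjects=1, schedule=((1, 7.0), (2, 8.0)), seed=0),
            0)
        ws = segment_record(rec, site="chest")  # purity 1.0
        # the 5-10 s window straddles the transition and must be dropped
        assert [w.condition for w in ws.windows] == [1, 2]
        ws_maj = segment_record(rec, site="chest", purity=0.5)
        # at majority purity the 40/60 transition window is kept as stress
        assert [w.condition for w in ws_maj.windows] == [1, 2, 2]

    def test_degenerate_window_raises(self):
        rec = _single_condition_record(10)
        with pytest.raises(ValueError):
            segment_record(rec, window_s=0.1, stride_s=0.1, site="wrist")

    @given(total_s=st.integers(5, 40), window_s=st.integers(1, 8),
           stride_s=st.integers(1, 8))
    def test_window_count_matches_brute_force(self, total_s, window_s,
                                              stride_s):
        rec = _single_condition_record(total_s, seed=3)
        ws = segment_record(rec, window_s=float(window_s),
                            stride_s=float(stride_s), site="chest")
        brute = len([t for t in range(0, total_s + 1, stride_s)
                     if t + window_s <= total_s])
        assert len(ws) == brute == (total_s - window_s) // stride_s + 1


class TestAssignWindowCondition:
    def test_pure_slice_returns_its_condition(self):
        assert assign_window_condition(np.full(700, 2), purity=1.0) == 2

    def test_mixed_slice_rejected_at_full_purity(self):
        slice_ = np.array([2] * 60 + [1] * 40)
        assert assign_window_condition(slice_, purity=1.0) is None

    def test_mixed_slice_accepted_at_majority_purity(self):
        slice_ = np.array([2] * 60 + [1] * 40)
        assert assign_window_condition(slice_, purity=0.5) == 2

    def test_non_study_mode_rejected(self):
        assert assign_window_condition(np.full(100, 4)) is None

    def test_empty_slice_raises(self):
        with pytest.raises(ValueError):
            assign_window_condition(np.array([]))


class TestMapTaskLabels:
    def test_binary_groups_amusement_with_baseline(self):
        ws = map_task_labels(_toy_windowset([1, 2, 3]), "binary")
        assert ws.labels.tolist() == [0, 1, 0]
        assert ws.task == "binary"

    def test_three_class_codes(self):
        ws = map_task_labels(_toy_windowset([1, 2, 3]), "three_class")
        assert ws.labels.tolist() == [0, 1, 2]

    def test_meditation_windows_dropped_and_counted(self):
        ws = map_task_labels(_toy_windowset([1, 4, 2, 4]), "three_class")
        assert len(ws) == 2
        assert ws.meta["dropped"] == 2

    def test_unknown_condition_code_raises(self):
        with pytest.raises(ValueError, match="42"):
            map_task_labels(_toy_windowset([1, 42]), "three_class")

    def test_double_mapping_raises(self):
        ws = map_task_labels(_toy_windowset([1, 2]), "binary")
        with pytest.raises(ValueError):
            map_task_labels(ws, "binary")


class TestScrambleSplit:
    def test_70_30_counts(self):
        ws = map_task_labels(_toy_windowset([1, 2] * 50), "binary")
        train, test = scramble_split(ws, 0.7, seed=5)
        assert (len(train), len(test)) == (70, 30)

    def test_same_seed_same_membership(self):
        ws = map_task_labels(_toy_windowset([1, 2] * 20), "binary")
        a = scramble_split(ws, seed=9)
        b = scramble_split(ws, seed=9)
        assert [w.t_start for w in a[0].windows] == \
               [w.t_start for w in b[0].windows]

    @given(n_pairs=st.integers(1, 40), seed=st.integers(0, 1000))
    def test_partition_is_disjoint_and_exhaustive(self, n_pairs, seed):
        ws = map_task_labels(_toy_windowset([1, 2] * n_pairs), "binary")
        train, test = scramble_split(ws, seed=seed)
        starts = lambda s: {w.t_start for w in s.windows}
        assert starts(train) | starts(test) == starts(ws)
        assert starts(train) & starts(test) == set()

    def test_subject_level_split_keeps_subjects_whole(self, chest_windows):
        ws = map_task_labels(chest_windows, "three_class")
        train, test = scramble_split(ws, seed=0, level="subject")
        assert set(train.subjects) & set(test.subjects) == set()
        assert len(train) + len(test) == len(ws)

    def test_too_few_windows_raises(self):
        ws = map_task_labels(_toy_windowset([1]), "binary")
        with pytest.raises(ValueError):
            scramble_split(ws, seed=0)


class TestMakeFolds:
    def test_100_windows_10_balanced_folds(self):
        ws = map_task_labels(_toy_windowset([1, 2] * 50), "binary")
        folds = make_folds(ws, k=10, seed=1)
        assert len(folds) == 10
        assert all(len(te) == 10 for _, te in folds)
        assert all(len(tr) == 90 for tr, _ in folds)

    def test_105_windows_balanced_remainder(self):
        ws = map_task_labels(_toy_windowset([1, 2, 3] * 35), "three_class")
        sizes = sorted(len(te) for _, te in make_folds(ws, k=10, seed=1))
        assert sizes == [10] * 5 + [11] * 5

    def test_every_window_in_exactly_one_test_fold(self):
        ws = map_task_labels(_toy_windowset([1, 2] * 13), "binary")
        folds = make_folds(ws, k=4, seed=2)
        seen = [w.t_start for _, te in folds for w in te.windows]
        assert sorted(seen) == sorted(w.t_start for w in ws.windows)

    def test_fewer_windows_than_folds_raises(self):
        ws = map_task_labels(_toy_windowset([1, 2] * 3), "binary")
        with pytest.raises(ValueError):
            make_folds(ws, k=10, seed=0)


class TestSerialization:
    def test_windowset_npz_round_trip(self, chest_windows, tmp_path):
        ws = map_task_labels(chest_windows, "three_class")
        path = tmp_path / "ws.npz"
        ws.save(path)
        back = WindowSet.load(path)
        assert len(back) == len(ws)
        assert back.task == ws.task
        assert back.labels.tolist() == ws.labels.tolist()
        np.testing.assert_array_equal(back.channel_matrix("ECG"),
                                      ws.channel_matrix("ECG"))
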