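import dataclasses

import numpy as np
import pytest

import semgrip as sg
from semgrip import labeling as lab
from semgrip.preprocess import AccSummary, MavStream
from semgrip.protocol import NR

from conftest import truth_labels


def _summary(times, stat):
    times = np.asarray(times, dtype=float)
    stat = np.asarray(stat, dtype=float)
    return AccSummary(times=times, stat=stat, median=float(np.median(stat)))


class TestOnsetDetection:
    def test_constant_statistic_gives_no_onsets(self):
        s = _summary(np.arange(10) * 0.05, np.ones(10))
        assert lab.detect_movement_onsets(s).size == 0

    def test_isolated_spike_above_double_median(self):
        stat = np.ones(100)
        stat[40] = 3.0  # 3x the median
        s = _summary(np.arange(100) * 0.05, stat)
        onsets = lab.detect_movement_onsets(s)
        assert onsets.tolist() == [pytest.approx(40 * 0.05)]

    def test_all_zero_statistic_is_empty_not_error(self):
        s = _summary(np.arange(10) * 0.05, np.zeros(10))
        assert lab.detect_movement_onsets(s).size == 0

    def test_nearby_spikes_cluster_into_one_event(self):
        stat = np.zeros(100)
        stat[40:44] = 5.0
        s = AccSummary(times=np.arange(100) * 0.05, stat=stat, median=1.0)
        events = lab.detect_acc_events(s)
        assert len(events) == 1
        assert events[0][0] == pytest.approx(2.0)

    def test_zero_noise_run_recovers_every_movement_onset(
        self, quiet_hammer_run, quiet_hammer_features
    ):
        _, _, summary = quiet_hammer_features
        onsets = lab.detect_movement_onsets(summary)
        sched = sg.make_schedule("hammer")
        for code, t0, _ in quiet_hammer_run.truth:
            if code in (NR, sched.grip_code):
                continue
            assert np.min(np.abs(onsets - t0)) <= 0.05


class TestAlignment:
    def test_identical_grids_identity(self):
        t = 0.05 * np.arange(1, 50)
        mav = MavStream(times=t, values=np.zeros((49, 8)))
        s = _summary(t, np.zeros_like(t))
        idx = lab.align_acc_to_emg(s, mav)
        np.testing.assert_array_equal(idx, np.arange(49))

    def test_stated_rate_grids_within_30_ms(self):
        mav_t = 0.05 * np.arange(1, 2401)
        acc_t = (7 / 148.1) * np.arange(1, 2538)
        mav = MavStream(times=mav_t, values=np.zeros((mav_t.size, 8)))
        s = _summary(acc_t, np.zeros_like(acc_t))
        idx = lab.align_acc_to_emg(s, mav)
        assert np.max(np.abs(mav_t[idx] - acc_t)) <= 0.030

    def test_tie_prefers_earlier_instant(self):
        mav = MavStream(times=np.asarray([0.0, 1.0]), values=np.zeros((2, 8)))
        s = _summary(np.asarray([0.5]), np.asarray([0.0]))
        assert lab.align_acc_to_emg(s, mav).tolist() == [0]


class TestLabelRun:
    def test_zero_noise_labels_match_truth_at_boundary_resolution(
        self, quiet_hammer_run, quiet_hammer_features
    ):
        _, mav, summary = quiet_hammer_features
        labeled = lab.label_run(mav, summary, sg.make_schedule("hammer"))
        truth = truth_labels(mav, quiet_hammer_run.truth)
        mismatch = np.flatnonzero(labeled.labels != truth)
        # mismatches only within one 50 ms step of a truth boundary
        boundaries = np.asarray([t0 for _, t0, _ in quiet_hammer_run.truth])
        for i in mismatch:
            assert np.min(np.abs(boundaries - mav.times[i])) <= 0.05 + 1e-9

    def test_run_start_is_rest(self, quiet_hammer_features):
        _, mav, summary = quiet_hammer_features
        labeled = lab.label_run(mav, summary, sg.make_schedule("hammer"))
        head = labeled.labels[labeled.times < 4.5]
        assert set(head) == {NR}

    def test_grip_adjustment_never_exceeds_500_ms(self, quiet_profile):
        profile = dataclasses.replace(quiet_profile, jitter_s=0.45)
        run = sg.generate_run(sg.make_schedule("ball"), profile, seed=8)
        bundle = run.as_bundle()
        mav, summary = sg.compute_mav(bundle), sg.summarize_acc(bundle)
        labeled = lab.label_run(mav, summary, sg.make_schedule("ball"))
        segs = lab.segment_activities(labeled, include_nr=False)
        sched = sg.make_schedule("ball")
        for seg in segs:
            if seg.label == "BG":
                scheduled = sched.rep_starts[seg.rep_index - 1]
                assert abs(seg.times[0] - scheduled) <= 0.5 + 0.05


class TestSubsampleNr:
    def test_eight_runs_retain_480(self, default_subject_data):
        total = sum(len(s) for s in default_subject_data.nr_segments)
        assert total == 480
        assert all(len(s) == 60 for s in default_subject_data.nr_segments)

    def test_non_nr_instances_untouched(self, quiet_hammer_features):
        _, mav, summary = quiet_hammer_features
        labeled = lab.label_run(mav, summary, sg.make_schedule("hammer"))
        sub = lab.subsample_nr(labeled)
        assert np.sum(sub.labels != NR) == np.sum(labeled.labels != NR)
        kept_nr = sub.times[sub.labels == NR]
        assert kept_nr.size == 60
        assert np.all((kept_nr >= 1.0) & (kept_nr < 4.0))

    def test_stream_without_nr_unchanged(self):
        stream = lab.LabeledStream(
            times=0.05 * np.arange(1, 11),
            values=np.ones((10, 8)),
            labels=np.asarray(["HG"] * 10),
        )
        sub = lab.subsample_nr(stream)
        assert len(sub) == 10


class TestSegmentation:
    @staticmethod
    def _stream(labels):
        m = len(labels)
        return lab.LabeledStream(
            times=0.05 * np.arange(1, m + 1),
            values=np.tile(np.arange(m)[:, None], (1, 8)).astype(float),
            labels=np.asarray(labels),
        )

    def test_run_length_encoding_oracle(self):
        labels = ["HG"] * 3 + ["HR"] * 2 + ["HG"] * 4
        segs = lab.segment_activities(self._stream(labels))
        assert [(s.label, len(s)) for s in segs] == [("HG", 3), ("HR", 2), ("HG", 4)]

    def test_truncation_to_40(self):
        segs = lab.segment_activities(self._stream(["HG"] * 60))
        assert len(segs) == 1 and len(segs[0]) == 40

    def test_short_segment_untruncated(self):
        segs = lab.segment_activities(self._stream(["HR"] * 20))
        assert len(segs[0]) == 20

    def test_concatenation_reproduces_label_track(self):
        rng = np.random.default_rng(5)
        labels = [str(c) for c in rng.choice(["HG", "HR", NR], size=200)]
        segs = lab.segment_activities(self._stream(labels), max_len=10**9)
        rebuilt = [s.label for s in segs for _ in range(len(s))]
        assert rebuilt == labels

    def test_timestamp_gap_breaks_segment(self):
        stream = self._stream(["HG"] * 10)
        stream.times[5:] += 1.0  # hole in the stream
        segs = lab.segment_activities(stream)
        assert [len(s) for s in segs] == [5, 5]
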