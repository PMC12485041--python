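"""Synthetic event-recording generator tests: label structure, amplitude
calibration, segment labeling against brute-force window enumeration, and
channel ranking."""

import numpy as np
import pytest

from fgl.synthetic_events import (
    ICTAL,
    INTERICTAL,
    PREICTAL,
    EventRecording,
    generate_recording,
    label_segments,
    select_top_k_channels,
)


def brute_force_window_count(state, window_len, stride, keep_states):
    """Oracle: scan every run, count stride positions fully inside it."""
    total = 0
    s = 0
    for e in range(1, len(state) + 1):
        if e == len(state) or state[e] != state[s]:
            if state[s] in keep_states and e - s >= window_len:
                total += (e - s - window_len) // stride + 1
            s = e
    return total


class TestGenerator:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("n_events,duration", [(1, 900.0), (3, 2400.0)])
    def test_label_structure_invariants(self, seed, n_events, duration):
        rec = generate_recording(
            n_channels=2, duration=duration, fs=16.0, n_events=n_events,
            preictal_horizon=120.0, ictal_duration=15.0, seed=seed,
        )
        pre_n = int(120.0 * rec.fs)
        ict_n = int(15.0 * rec.fs)
        assert len(rec.event_times) == n_events
        for onset in rec.event_times:
            assert np.all(rec.state[onset : onset + ict_n] == ICTAL)
            start = max(0, onset - pre_n)
            assert np.all(rec.state[start:onset] == PREICTAL)
        # states partition the timeline
        assert rec.state.shape == (rec.n_samples,)
        assert set(np.unique(rec.state)) <= {INTERICTAL, PREICTAL, ICTAL}
        # every ictal sample is accounted for by an event
        assert int(np.sum(rec.state == ICTAL)) == n_events * ict_n

    def test_no_events_means_all_interictal(self):
        rec = generate_recording(duration=300.0, fs=16.0, n_events=0, seed=0)
        assert rec.event_times == []
        assert np.all(rec.state == INTERICTAL)

    def test_rms_ratio_matches_configuration(self):
        ratio = 4.0
        rec = generate_recording(
            n_channels=2, duration=3600.0, fs=16.0, n_events=4,
            preictal_horizon=60.0, ictal_duration=40.0, amplitude_ratio=ratio,
            kappa=0.0, artifact_rate=0.0, seed=5,
        )
        ict = rec.signal[:, rec.state == ICTAL]
        inter = rec.signal[:, rec.state == INTERICTAL]
        assert ict.shape[1] > 1e4 / 4
        got = np.sqrt(np.mean(ict**2)) / np.sqrt(np.mean(inter**2))
        assert got == pytest.approx(ratio, rel=0.10)

    def test_null_effect_size_leaves_preictal_unshifted(self):
        rec = generate_recording(
            n_channels=2, duration=2400.0, fs=16.0, n_events=3,
            preictal_horizon=120.0, kappa=0.0, artifact_rate=0.0, seed=6,
        )
        pre = rec.signal[:, rec.state == PREICTAL]
        inter = rec.signal[:, rec.state == INTERICTAL]
        # same generative distribution: variances agree closely
        assert pre.var() == pytest.approx(inter.var(), rel=0.1)

    def test_infeasible_packing_reports_required_duration(self):
        with pytest.raises(ValueError, match="need at least"):
            generate_recording(duration=200.0, fs=16.0, n_events=3, preictal_horizon=120.0)

    def test_deterministic_per_seed(self):
        a = generate_recording(duration=400.0, fs=16.0, n_events=1, preictal_horizon=60.0, seed=7)
        b = generate_recording(duration=400.0, fs=16.0, n_events=1, preictal_horizon=60.0, seed=7)
        np.testing.assert_array_equal(a.signal, b.signal)
        assert a.event_times == b.event_times

    def test_save_load_round_trip(self, tmp_path):
        rec = generate_recording(duration=300.0, fs=16.0, n_events=1, preictal_horizon=30.0, seed=8)
        prefix = str(tmp_path / "rec")
        rec.save(prefix)
        back = EventRecording.load(prefix)
        np.testing.assert_array_equal(back.signal, rec.signal)
        np.testing.assert_array_equal(back.state, rec.state)
        assert back.event_times == rec.event_times


@pytest.fixture(scope="module")
def rec():
    return generate_recording(
        n_channels=3, duration=1800.0, fs=10.0, n_events=2,
        preictal_horizon=120.0, ictal_duration=60.0, seed=11,
    )


class TestLabelSegments:

    def test_sixty_second_run_gives_twelve_windows(self, rec):
        # 60 s ictal at 10 Hz, 5 s windows, 5 s stride -> 12 per event
        ds = label_segments(rec, window_len=50, stride=50, task="detection")
        assert int(np.sum(ds.labels == 1)) == 12 * 2

    def test_detection_excludes_preictal(self, rec):
        ds = label_segments(rec, 50, 50, task="detection")
        # every window lies wholly inside an ictal or interictal run
        for st, lab in zip(ds.origin, ds.labels):
            run = rec.state[st : st + 50]
            assert np.all(run == (ICTAL if lab else INTERICTAL))
        assert ds.n_excluded_preictal == brute_force_window_count(
            rec.state, 50, 50, {PREICTAL}
        )

    def test_counts_match_bruteforce(self, rec):
        for task, keep in (("detection", {ICTAL, INTERICTAL}), ("prediction", {PREICTAL, INTERICTAL})):
            for wl, stride in ((50, 50), (30, 10), (25, 7)):
                ds = label_segments(rec, wl, stride, task=task)
                assert len(ds) == brute_force_window_count(rec.state, wl, stride, keep)

    def test_missing_class_reported(self):
        rec = generate_recording(duration=300.0, fs=10.0, n_events=0, seed=1)
        with pytest.raises(ValueError, match="ictal"):
            label_segments(rec, 20, 20, task="detection")

    def test_split_at_partitions_chronologically(self, rec):
        ds = label_segments(rec, 50, 50, task="prediction")
        early, late = ds.split_at(rec.n_samples // 2)
        assert len(early) + len(late) == len(ds)
        assert early.origin.max() < rec.n_samples // 2 <= late.origin.min()


class TestChannelRanking:
    def test_single_signal_channel_ranked_first(self):
        gains = np.array([0.0, 0.0, 0.0, 1.0, 0.0])
        rec = generate_recording(
            n_channels=5, duration=1200.0, fs=16.0, n_events=2,
            preictal_horizon=60.0, event_channel_gains=gains, seed=13,
        )
        ranked = select_top_k_channels(rec, k=5, window_len=32, stride=32)
        assert ranked[0] == 3

    def test_k_equals_channels_is_permutation(self):
        rec = generate_recording(
            n_channels=4, duration=1200.0, fs=16.0, n_events=2, preictal_horizon=60.0, seed=14
        )
        ranked = select_top_k_channels(rec, k=4, window_len=32, stride=32)
        assert sorted(ranked) == [0, 1, 2, 3]

    def test_invalid_k(self):
        rec = generate_recording(duration=900.0, fs=16.0, n_events=1, preictal_horizon=60.0, seed=15)
        with pytest.raises(ValueError):
            select_top_k_channels(rec, k=0)
        with pytest.raises(ValueError):
            select_top_k_channels(rec, k=99)
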