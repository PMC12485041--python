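"""Synthetic multichannel event recordings with seizure-like state structure.

Emulates the statistical skeleton of long-term EEG seizure data — a long,
low-amplitude interictal background (1/f-shaped colored noise), a short
high-energy oscillatory ictal event, and a preictal period immediately
before each event carrying only a subtle distributional shift (a variance
drift plus a tilt of band power toward the ictal rhythm, both scaled by an
effect size ``kappa``).  The point is to make the detector-teacher ->
predictor-student pathway testable without any EEG download: the teacher
learns ictal vs interictal, the student preictal vs interictal, and the
teacher's softened event probability on preictal windows is the signal the
student distills.

What this generator does *not* emulate: real EEG nonstationarity, artifacts,
electrode montage geometry, or patient-to-patient variability beyond
per-channel gains.  Passing tests show the training machinery behaves as
designed, not that it reaches any particular performance on clinical data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EventRecording",
    "SegmentDataset",
    "generate_recording",
    "label_segments",
    "select_top_k_channels",
    "load_edf_recording",
]

INTERICTAL, PREICTAL, ICTAL = 0, 1, 2
STATE_NAMES = {INTERICTAL: "interictal", PREICTAL: "preictal", ICTAL: "ictal"}


@dataclass
class EventRecording:
    """Multichannel signal with per-sample state labels and event onsets."""

    signal: np.ndarray  # (channels, samples)
    fs: float
    state: np.ndarray  # per-sample label in {0: interictal, 1: preictal, 2: ictal}
    event_times: list[int]  # ictal onset sample indices
    seed: int
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.signal.ndim != 2:
            raise ValueError("signal must be (channels, samples)")
        if self.state.shape != (self.signal.shape[1],):
            raise ValueError("state must label every sample")

    @property
    def n_channels(self) -> int:
        return int(self.signal.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.signal.shape[1])

    def save(self, path_prefix: str) -> None:
        """Save as ``<prefix>.npz`` plus a JSON sidecar with the metadata."""
        np.savez(path_prefix + ".npz", signal=self.signal, state=self.state)
        with open(path_prefix + ".json", "w") as fh:
            json.dump(
                {
                    "fs": self.fs,
                    "event_times": [int(t) for t in self.event_times],
                    "seed": self.seed,
                    "config": self.config,
                },
                fh,
            )

    @classmethod
    def load(cls, path_prefix: str) -> "EventRecording":
        arrs = np.load(path_prefix + ".npz")
        with open(path_prefix + ".json") as fh:
            meta = json.load(fh)
        return cls(
            signal=arrs["signal"],
            fs=meta["fs"],
            state=arrs["state"],
            event_times=meta["event_times"],
            seed=meta["seed"],
            config=meta.get("config", {}),
        )


@dataclass
class SegmentDataset:
    """Fixed-length windows cut from a recording for one task.

    ``task="detection"`` keeps ictal (label 1) vs interictal (label 0)
    windows and provably contains zero preictal windows; ``task="prediction"``
    keeps preictal (label 1) vs interictal (label 0).  ``origin`` holds the
    start sample of each window in the source recording.
    """

    windows: np.ndarray  # (n, channels, window_len)
    labels: np.ndarray  # (n,) binary
    task: str
    origin: np.ndarray
    n_dropped_short_runs: int = 0
    n_excluded_preictal: int = 0

    def __len__(self) -> int:
        return int(self.labels.size)

    def split_at(self, sample_index: int) -> tuple["SegmentDataset", "SegmentDataset"]:
        """Chronological split: windows starting before ``sample_index`` vs after."""
        early = self.origin < sample_index
        parts = []
        for mask in (early, ~early):
            parts.append(
                SegmentDataset(
                    windows=self.windows[mask],
                    labels=self.labels[mask],
                    task=self.task,
                    origin=self.origin[mask],
                    n_dropped_short_runs=self.n_dropped_short_runs,
                    n_excluded_preictal=self.n_excluded_preictal,
                )
            )
        return parts[0], parts[1]


def load_edf_recording(
    path,
    state_from_annotations=None,
    fs: float | None = None,
) -> EventRecording:
    """Optional loader for real EEG in EDF format (requires ``mne``).

    Never needed for the synthetic benchmarks or tests.  ``state_from_
    annotations`` is an optional callable mapping an ``(onset_sample,
    duration_samples, description)`` annotation triple to a state label (or
    None to skip); samples not covered by any mapped annotation are
    interictal.
    """
    import mne  # deferred: optional dependency for real-data use only

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if fs is not None and abs(raw.info["sfreq"] - fs) > 1e-6:
        raw = raw.resample(fs, verbose="error")
    signal = raw.get_data()
    n = signal.shape[1]
    state = np.full(n, INTERICTAL, dtype=np.int8)
    event_times: list[int] = []
    if state_from_annotations is not None:
        sfreq = raw.info["sfreq"]
        for ann in raw.annotations:
            onset = int(round(ann["onset"] * sfreq))
            dur = int(round(ann["duration"] * sfreq))
            lab = state_from_annotations(onset, dur, ann["description"])
            if lab is None:
                continue
            state[onset : onset + max(dur, 1)] = lab
            if lab == ICTAL:
                event_times.append(onset)
    return EventRecording(
        signal=signal,
        fs=float(raw.info["sfreq"]),
        state=state,
        event_times=event_times,
        seed=-1,
        config={"source": str(path)},
    )


def _colored_noise(rng: np.random.Generator, n_channels: int, n: int, exponent: float = 1.0):
    """Unit-RMS 1/f^exponent noise per channel via spectral shaping."""
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC drift
    sig = np.fft.irfft(spec * shape[None, :], n=n, axis=1)
    sig /= sig.std(axis=1, keepdims=True)
    return sig


def generate_recording(
    n_channels: int = 4,
    duration: float = 4000.0,
    fs: float = 32.0,
    n_events: int = 4,
    preictal_horizon: float = 600.0,
    ictal_duration: float = 20.0,
    amplitude_ratio: float = 4.0,
    kappa: float = 1.0,
    ictal_freq: float = 6.0,
    min_interictal: float = 60.0,
    artifact_rate: float = 1.0,
    artifact_duration: float = 1.0,
    artifact_amp: float = 3.0,
    event_channel_gains: np.ndarray | None = None,
    seed: int = 0,
) -> EventRecording:
    """Generate a labeled multichannel recording.

    Parameters
    ----------
    preictal_horizon : seconds of preictal state preceding each ictal onset
        (default 600 s = 10 synthetic minutes; truncated only at the
        recording start).
    amplitude_ratio : target ictal/interictal RMS ratio (>= 1).
    kappa : preictal effect size; 0 makes preictal generatively identical
        to interictal (a null task on which any classifier's expected AUC
        is 0.5).
    artifact_rate : mean broadband artifact bursts per minute, scattered
        uniformly over the recording regardless of state (rate 0 disables
        them).  Artifacts are high-power but spectrally flat, unlike the
        narrowband ictal rhythm — the realism that makes raw signal power an
        unreliable event marker, as it is in scalp EEG.
    event_channel_gains : optional per-channel multiplier on the ictal and
        preictal oscillatory signature (default all ones); a one-hot vector
        confines the event signature to a single channel.
    """
    if amplitude_ratio < 1.0:
        raise ValueError("amplitude_ratio must be >= 1")
    n = int(round(duration * fs))
    ictal_n = int(round(ictal_duration * fs))
    pre_n = int(round(preictal_horizon * fs))
    gap_n = int(round(min_interictal * fs))
    rng = np.random.default_rng([seed, 7])

    required = n_events * (ictal_n + pre_n + gap_n) + gap_n
    if n_events > 0 and required > n:
        raise ValueError(
            f"cannot pack {n_events} events into {duration:.0f}s; need at least "
            f"{required / fs:.0f}s for the requested horizons and spacing"
        )

    gains = rng.uniform(0.8, 1.2, size=n_channels)
    sig = _colored_noise(rng, n_channels, n) * gains[:, None]
    state = np.full(n, INTERICTAL, dtype=np.int8)

    # place events: partition the timeline into n_events blocks, put each
    # onset at a seeded position inside its block with room for preictal
    # before and the ictal run plus a gap after
    event_times: list[int] = []
    if n_events > 0:
        block = n // n_events
        for i in range(n_events):
            lo = i * block + (pre_n if i == 0 else gap_n // 2 + pre_n)
            hi = (i + 1) * block - ictal_n - gap_n
            if hi <= lo:
                raise ValueError(
                    f"cannot pack {n_events} events into {duration:.0f}s; "
                    f"need at least {required / fs:.0f}s"
                )
            onset = int(rng.integers(lo, hi))
            event_times.append(onset)

    t = np.arange(n) / fs
    ch_gains = (
        np.ones(n_channels) if event_channel_gains is None
        else np.asarray(event_channel_gains, dtype=float)
    )
    if ch_gains.shape != (n_channels,):
        raise ValueError("event_channel_gains must have one entry per channel")

    # ictal oscillation amplitude: background is unit RMS per channel (times
    # gain); adding a sinusoid of RMS a gives total RMS sqrt(1 + a^2), so
    # a = sqrt(ratio^2 - 1) hits the requested ictal/interictal RMS ratio
    a_ict = np.sqrt(amplitude_ratio**2 - 1.0)
    for onset in event_times:
        pre_start = max(0, onset - pre_n)
        state[pre_start:onset] = PREICTAL
        state[onset : onset + ictal_n] = ICTAL
        phase = rng.uniform(0, 2 * np.pi)
        seg = slice(onset, onset + ictal_n)
        osc = np.sqrt(2.0) * np.sin(2 * np.pi * ictal_freq * t[seg] + phase)  # unit RMS
        sig[:, seg] += a_ict * (gains * ch_gains)[:, None] * osc[None, :]
        # preictal: subtle shift — variance drift ramping toward onset plus a
        # low-amplitude tilt of band power toward the ictal rhythm
        pre = slice(pre_start, onset)
        ramp = np.linspace(0.0, 1.0, onset - pre_start, endpoint=False)
        sig[:, pre] *= 1.0 + 0.3 * kappa * ramp[None, :]
        osc_p = np.sqrt(2.0) * np.sin(2 * np.pi * ictal_freq * t[pre] + phase)
        sig[:, pre] += 0.4 * kappa * (gains * ch_gains)[:, None] * (ramp * osc_p)[None, :]

    # broadband artifact bursts: state-independent, spectrally flat, high
    # power — they decouple "high amplitude" from "event", so narrowband
    # structure (not raw power) is what separates ictal activity
    if artifact_rate > 0:
        art_n = max(1, int(round(artifact_duration * fs)))
        n_art = rng.poisson(artifact_rate * duration / 60.0)
        for _ in range(n_art):
            st = int(rng.integers(0, n - art_n))
            burst = rng.standard_normal((n_channels, art_n))
            taper = np.hanning(art_n)[None, :]
            sig[:, st : st + art_n] += artifact_amp * gains[:, None] * burst * taper

    return EventRecording(
        signal=sig,
        fs=fs,
        state=state,
        event_times=event_times,
        seed=seed,
        config={
            "n_channels": n_channels,
            "duration": duration,
            "fs": fs,
            "n_events": n_events,
            "preictal_horizon": preictal_horizon,
            "ictal_duration": ictal_duration,
            "amplitude_ratio": amplitude_ratio,
            "kappa": kappa,
            "ictal_freq": ictal_freq,
            "artifact_rate": artifact_rate,
            "artifact_amp": artifact_amp,
        },
    )


def _state_runs(state: np.ndarray):
    """Yield (label, start, end_exclusive) for maximal constant-state runs."""
    change = np.flatnonzero(np.diff(state)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [state.size]))
    for s, e in zip(starts, ends):
        yield int(state[s]), int(s), int(e)


def label_segments(
    recording: EventRecording,
    window_len: int,
    stride: int,
    task: str,
) -> SegmentDataset:
    """Cut non-straddling fixed-length windows and label them for one task.

    Windows are tiled within each maximal constant-state run (so none ever
    straddles a state boundary); a run yields
    ``floor((run_len - window_len)/stride) + 1`` windows, and runs shorter
    than ``window_len`` are dropped and counted.  ``task="detection"``
    returns ictal (1) vs interictal (0) windows with preictal excluded and
    counted; ``task="prediction"`` returns preictal (1) vs interictal (0).
    """
    if task not in ("detection", "prediction"):
        raise ValueError(f"unknown task {task!r}")
    if window_len < 1 or stride < 1:
        raise ValueError("window_len and stride must be positive")
    pos_state = ICTAL if task == "detection" else PREICTAL
    skip_state = PREICTAL if task == "detection" else ICTAL

    wins, labels, origin = [], [], []
    n_short = 0
    n_excluded_preictal = 0
    for lab, s, e in _state_runs(recording.state):
        run_len = e - s
        if run_len < window_len:
            n_short += 1
            continue
        n_w = (run_len - window_len) // stride + 1
        if lab == skip_state:
            if lab == PREICTAL:
                n_excluded_preictal += n_w
            continue
        for i in range(n_w):
            st = s + i * stride
            wins.append(recording.signal[:, st : st + window_len])
            labels.append(1 if lab == pos_state else 0)
            origin.append(st)

    labels_arr = np.asarray(labels, dtype=int)
    for cls, name in ((1, STATE_NAMES[pos_state]), (0, "interictal")):
        if not np.any(labels_arr == cls):
            raise ValueError(f"no {name} windows available for task {task!r}")
    return SegmentDataset(
        windows=np.asarray(wins),
        labels=labels_arr,
        task=task,
        origin=np.asarray(origin, dtype=int),
        n_dropped_short_runs=n_short,
        n_excluded_preictal=n_excluded_preictal,
    )


def _log_band_power(windows: np.ndarray) -> np.ndarray:
    """Log total power per channel of each window: (n, channels)."""
    return np.log(np.mean(windows**2, axis=2) + 1e-12)


def select_top_k_channels(
    recordings: EventRecording | list[EventRecording],
    k: int,
    window_len: int = 64,
    stride: int = 64,
) -> list[int]:
    """Rank channels by event/background separability and return the top k.

    The score is the absolute standardized mean difference (pooled-SD
    Cohen's d) of log window power between ictal and interictal windows,
    computed per channel; ties break toward the lower channel index.  Used
    to reconcile channel dimensionality when a universal (out-of-
    distribution) detector teacher supervises a student recorded with a
    different montage.
    """
    if isinstance(recordings, EventRecording):
        recordings = [recordings]
    if not recordings:
        raise ValueError("need at least one recording")
    n_ch = recordings[0].n_channels
    if not 1 <= k <= n_ch:
        raise ValueError(f"k must be in [1, {n_ch}]")

    ev_feats, bg_feats = [], []
    for rec in recordings:
        ds = label_segments(rec, window_len, stride, task="detection")
        f = _log_band_power(ds.windows)
        ev_feats.append(f[ds.labels == 1])
        bg_feats.append(f[ds.labels == 0])
    ev = np.concatenate(ev_feats)
    bg = np.concatenate(bg_feats)
    pooled_sd = np.sqrt(0.5 * (ev.var(axis=0, ddof=1) + bg.var(axis=0, ddof=1)))
    smd = np.abs(ev.mean(axis=0) - bg.mean(axis=0)) / np.where(pooled_sd > 0, pooled_sd, 1.0)
    # stable sort on -score ranks ties by ascending channel index
    order = np.argsort(-smd, kind="stable")
    return [int(c) for c in order[:k]]
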