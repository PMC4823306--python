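"""Synthetic multichannel EEG with the signal structure the analysis assumes.

The generator emulates, channel by channel:

* narrowband steady-state somatosensory responses (SSSEPs) at the two
  stimulation frequencies, with strictly contralateral scalp topography,
  a unimodal frequency tuning curve, and a multiplicative attention gain on
  the cued hand;
* transient twitch-locked SSSEP attenuation ("blocking"), modeled as a
  rectangular multiplicative dip on the SSSEP amplitude in a fixed window
  after each twitch of the corresponding hand;
* a P300-like positive deflection after attended twitches, peaking 300-400 ms
  post onset with a centro-parietal topography;
* 1/f^beta background noise plus alpha-band activity, independent per channel;
* optional high-amplitude artifact trials and EOG contamination.

Everything is additive, so a session equals the sample-wise sum of its
fragments; downstream stages are tested by recovering the injected
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimulation import (
    ScreeningSchedule,
    StimulationConfig,
    TrialSchedule,
    TwitchPattern,
    bci_events_table,
    generate_bci_schedule,
    generate_screening_schedule,
    generate_twitch_patterns,
    rectangular_envelope,
    insert_twitches,
    screening_events_table,
)

__all__ = [
    "EEG_CHANNELS",
    "EOG_CHANNELS",
    "SubjectProfile",
    "Recording",
    "SimulatedSession",
    "simulate_background",
    "simulate_sssep",
    "simulate_p300",
    "simulate_session",
    "simulate_ideal_stim_signal",
]

#: 29 EEG channel labels (10-20 extended grid over the sensorimotor strip).
EEG_CHANNELS = (
    "F3", "Fz", "F4",
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "P3", "Pz", "P4", "O1", "O2",
)
EOG_CHANNELS = ("EOG1", "EOG2", "EOG3")

# Strictly contralateral SSSEP source maps (left hand -> right hemisphere).
_LEFT_SSSEP_MAP = {"FC4": 1.0, "FC2": 0.4, "FC6": 0.4, "C4": 0.3, "C2": 0.2}
_RIGHT_SSSEP_MAP = {"FC3": 1.0, "FC1": 0.4, "FC5": 0.4, "C3": 0.3, "C1": 0.2}
_P300_MAP = {
    "Cz": 1.0, "CPz": 0.9, "FCz": 0.8, "Pz": 0.7,
    "C1": 0.6, "C2": 0.6, "CP1": 0.5, "CP2": 0.5, "Fz": 0.4,
    "C3": 0.35, "C4": 0.35,
}


def _gaussian_tuning(freq: float, peak: float, width: float) -> float:
    return float(np.exp(-0.5 * ((freq - peak) / width) ** 2))


@dataclass(frozen=True)
class SubjectProfile:
    """Free parameters of the synthetic subject.

    Amplitudes are in microvolts.  The tuning curve is a unimodal Gaussian
    over stimulation frequency (peak location ``tuning_peak`` Hz, width
    ``tuning_width`` Hz), the same for both fingers unless per-finger peaks
    are given.  ``attention_gain`` multiplies the attended finger's SSSEP;
    ``blocking_depth_db`` attenuates the SSSEP inside ``blocking_window``
    (seconds after each twitch of the same hand).
    """

    tuning_peak: float = 27.0
    tuning_width: float = 5.0
    tuning_peak_left: float | None = None
    tuning_peak_right: float | None = None
    sssep_base_amp: float = 2.5
    attention_gain: float = 1.3
    blocking_depth_db: float = 2.5
    blocking_window: tuple[float, float] = (0.05, 0.20)
    p300_amp: float = 3.0
    p300_latency: float = 0.35
    p300_width: float = 0.3
    p300_nontarget_amp: float = 0.0
    alpha_amp: float = 1.0
    noise_amp: float = 5.0
    noise_exponent: float = 1.0
    eog_amp: float = 0.0
    eog_coupling: float = 0.0
    artifact_rate: float = 0.0
    artifact_amp: float = 150.0

    def tuning_gain(self, freq: float, finger: str) -> float:
        peak = {
            "left": self.tuning_peak_left,
            "right": self.tuning_peak_right,
        }.get(finger) or self.tuning_peak
        if not 10.0 <= freq <= 45.0:
            raise ValueError(f"stimulation frequency {freq} Hz outside tuning support")
        return _gaussian_tuning(freq, peak, self.tuning_width)

    def spatial_weights(self, source: str) -> dict[str, float]:
        return {
            "left_sssep": _LEFT_SSSEP_MAP,
            "right_sssep": _RIGHT_SSSEP_MAP,
            "p300": _P300_MAP,
        }[source]


@dataclass
class Recording:
    """Multichannel time series with an event table.

    ``data`` is channels x samples in microvolts; ``events`` is the flat
    delimited event table of the stimulation module.
    """

    data: np.ndarray
    sample_rate: float
    channel_labels: tuple[str, ...]
    events: pd.DataFrame

    def __post_init__(self) -> None:
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data rows must match channel labels")
        if len(self.events) and self.events["time_s"].max() > self.duration + 1e-9:
            raise ValueError("event times outside the recording span")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def get(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(data, self.sample_rate, tuple(self.channel_labels),
                         self.events.copy())


@dataclass
class SimulatedSession:
    """A simulated recording bundled with its generating schedule."""

    recording: Recording
    patterns: list[TwitchPattern]
    schedule: list[TrialSchedule] | ScreeningSchedule
    config: StimulationConfig
    profile: SubjectProfile


def _channel_array(n_samples: int, labels) -> np.ndarray:
    return np.zeros((len(labels), n_samples))


def simulate_background(
    duration: float,
    profile: SubjectProfile,
    rng_seed: int | np.random.SeedSequence | None = None,
    sample_rate: float = 600.0,
    channel_labels: tuple[str, ...] = EEG_CHANNELS + EOG_CHANNELS,
) -> np.ndarray:
    """1/f^beta noise plus an alpha-band sinusoid, independent per channel.

    The noise is spectrally shaped white noise (flat below 0.5 Hz to keep the
    variance finite), scaled to ``noise_amp`` standard deviation per channel;
    the alpha component has a random frequency in 8-12 Hz and random phase.
    Output is zero-mean, channels x samples.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    from scipy import fft as _fft

    rng = np.random.default_rng(rng_seed)
    n = int(round(duration * sample_rate))
    out = _channel_array(n, channel_labels)
    n_fft = _fft.next_fast_len(n)
    freqs = np.fft.rfftfreq(n_fft, 1.0 / sample_rate)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = np.maximum(freqs[nz], 0.5) ** (-profile.noise_exponent / 2.0)
    shape[0] = 0.0
    t = np.arange(n) / sample_rate
    for c in range(len(channel_labels)):
        white = rng.standard_normal(n_fft)
        colored = _fft.irfft(_fft.rfft(white) * shape, n_fft)[:n]
        std = colored.std()
        if std > 0:
            colored *= profile.noise_amp / std
        colored -= colored.mean()
        if profile.alpha_amp > 0:
            f_alpha = rng.uniform(8.0, 12.0)
            phase = rng.uniform(0, 2 * np.pi)
            colored = colored + profile.alpha_amp * np.sin(2 * np.pi * f_alpha * t + phase)
        out[c] = colored
    return out


def _hand_class(hand: str) -> str:
    return {"left": "focus_left", "right": "focus_right"}[hand]


def simulate_sssep(
    schedule,
    patterns: list[TwitchPattern],
    profile: SubjectProfile,
    rng_seed=None,
    config: StimulationConfig | None = None,
    sample_rate: float = 600.0,
    n_samples: int | None = None,
    channel_labels: tuple[str, ...] = EEG_CHANNELS + EOG_CHANNELS,
) -> np.ndarray:
    """SSSEP fragment: envelope-frequency sinusoids during stimulation.

    BCI schedules add, per hand and trial, a phase-continuous sinusoid at that
    hand's stimulation frequency from stimulation start to trial end, scaled
    by the tuning curve, spatial map and attention gain, and attenuated by
    ``blocking_depth_db`` inside the blocking window after each of that hand's
    twitches.  Screening schedules add one burst per stimulation interval at
    the interval's frequency on the stimulated finger's contralateral map.
    """
    rng = np.random.default_rng(rng_seed)
    labels = list(channel_labels)
    if isinstance(schedule, ScreeningSchedule):
        end = max(iv.t_start + iv.duration for iv in schedule.intervals) + 1.0
        n = n_samples or int(round(end * sample_rate))
        out = _channel_array(n, labels)
        for iv in schedule.intervals:
            i0 = int(round(iv.t_start * sample_rate))
            i1 = min(int(round((iv.t_start + iv.duration) * sample_rate)), n)
            t = np.arange(i1 - i0) / sample_rate
            amp = profile.sssep_base_amp * profile.tuning_gain(iv.freq, iv.finger)
            phase = rng.uniform(0, 2 * np.pi)
            wave = amp * np.sin(2 * np.pi * iv.freq * t + phase)
            wmap = profile.spatial_weights(f"{iv.finger}_sssep")
            for ch, w in wmap.items():
                if ch in labels:
                    out[labels.index(ch), i0:i1] += w * wave
        return out

    if config is None:
        raise ValueError("a StimulationConfig is required for BCI schedules")
    by_id = {p.pattern_id: p for p in patterns}
    end = max(tr.t_trial_end for tr in schedule) + 1.0
    n = n_samples or int(round(end * sample_rate))
    out = _channel_array(n, labels)
    block_gain = 10.0 ** (-profile.blocking_depth_db / 20.0)
    d_on, d_off = profile.blocking_window
    for tr in schedule:
        pat = by_id[tr.pattern_id]
        i0 = int(round(tr.t_stim_start * sample_rate))
        i1 = min(int(round(tr.t_trial_end * sample_rate)), n)
        t = np.arange(i1 - i0) / sample_rate
        for hand in ("left", "right"):
            freq = config.stim_freq(hand)
            amp = profile.sssep_base_amp * profile.tuning_gain(freq, hand)
            if tr.class_label == _hand_class(hand):
                amp *= profile.attention_gain
            envelope = np.full(i1 - i0, amp)
            for tw in tr.twitch_times(pat, hand):
                j0 = int(round((tw + d_on - tr.t_stim_start) * sample_rate))
                j1 = int(round((tw + d_off - tr.t_stim_start) * sample_rate))
                envelope[max(j0, 0):max(j1, 0)] *= block_gain
            phase = rng.uniform(0, 2 * np.pi)
            wave = envelope * np.sin(2 * np.pi * freq * t + phase)
            wmap = profile.spatial_weights(f"{hand}_sssep")
            for ch, w in wmap.items():
                if ch in labels:
                    out[labels.index(ch), i0:i1] += w * wave
    return out


def simulate_p300(
    schedule: list[TrialSchedule],
    patterns: list[TwitchPattern],
    profile: SubjectProfile,
    rng_seed=None,
    sample_rate: float = 600.0,
    n_samples: int | None = None,
    channel_labels: tuple[str, ...] = EEG_CHANNELS + EOG_CHANNELS,
) -> np.ndarray:
    """P300 fragment: a positive raised-cosine bump after attended twitches.

    The bump peaks ``p300_latency`` seconds after the twitch with support
    ``p300_width`` and amplitude ``p300_amp`` at the strongest channel of the
    centro-parietal map.  Idle trials (and non-target twitches, unless
    ``p300_nontarget_amp`` > 0) contribute nothing.
    """
    by_id = {p.pattern_id: p for p in patterns}
    end = max(tr.t_trial_end for tr in schedule) + 1.0
    n = n_samples or int(round(end * sample_rate))
    labels = list(channel_labels)
    out = _channel_array(n, labels)
    wmap = profile.spatial_weights("p300")
    half = profile.p300_width / 2.0
    for tr in schedule:
        pat = by_id[tr.pattern_id]
        for hand in ("left", "right"):
            target = tr.class_label == _hand_class(hand)
            amp = profile.p300_amp if target else profile.p300_nontarget_amp
            if amp == 0:
                continue
            for tw in tr.twitch_times(pat, hand):
                peak = tw + profile.p300_latency
                j0 = max(int(np.ceil((peak - half) * sample_rate)), 0)
                j1 = min(int(np.floor((peak + half) * sample_rate)) + 1, n)
                tt = np.arange(j0, j1) / sample_rate
                bump = amp * 0.5 * (1 + np.cos(np.pi * (tt - peak) / half))
                for ch, w in wmap.items():
                    if ch in labels:
                        out[labels.index(ch), j0:j1] += w * bump
    return out


def _simulate_artifacts(
    schedule: list[TrialSchedule],
    profile: SubjectProfile,
    rng: np.random.Generator,
    n: int,
    sample_rate: float,
    labels: list[str],
) -> np.ndarray:
    out = _channel_array(n, labels)
    eeg_idx = [labels.index(ch) for ch in labels if not ch.startswith("EOG")]
    for tr in schedule:
        if rng.uniform() >= profile.artifact_rate:
            continue
        ch = int(rng.choice(eeg_idx))
        t = rng.uniform(tr.t_cue_onset, tr.t_trial_end - 0.1)
        j0 = int(round(t * sample_rate))
        width = int(0.05 * sample_rate)
        out[ch, j0:j0 + width] += profile.artifact_amp
    return out


def simulate_session(
    paradigm: str = "bci",
    profile: SubjectProfile | None = None,
    rng_seed: int | None = None,
    config: StimulationConfig | None = None,
    sample_rate: float = 600.0,
    n_runs: int = 8,
    trials_per_class_per_run: int = 10,
    screening_kwargs: dict | None = None,
) -> SimulatedSession:
    """Compose a full synthetic session: background + SSSEP (+ P300, BCI only).

    The session seed is split deterministically into child seeds for the
    schedule, the twitch patterns, and each signal fragment, so a fixed seed
    reproduces the event table and data bit-exactly.
    """
    if paradigm not in ("bci", "screening"):
        raise ValueError("paradigm must be 'bci' or 'screening'")
    profile = profile or SubjectProfile()
    config = config or StimulationConfig()
    root = np.random.SeedSequence(rng_seed)
    (s_sched, s_pat, s_bg, s_sssep, s_p300, s_art, s_eog) = root.spawn(7)
    labels = EEG_CHANNELS + EOG_CHANNELS

    if paradigm == "screening":
        schedule = generate_screening_schedule(
            np.random.default_rng(s_sched).integers(2**31), **(screening_kwargs or {})
        )
        end = max(iv.t_start + iv.duration for iv in schedule.intervals) + 1.0
        n = int(round(end * sample_rate))
        data = simulate_background(end, profile, s_bg, sample_rate, labels)[:, :n]
        data += simulate_sssep(schedule, [], profile, s_sssep,
                               sample_rate=sample_rate, n_samples=n,
                               channel_labels=labels)
        events = screening_events_table(schedule)
        rec = Recording(data, sample_rate, labels, events)
        return SimulatedSession(rec, [], schedule, config, profile)

    patterns = generate_twitch_patterns(
        rng_seed=np.random.default_rng(s_pat).integers(2**31),
        stim_freq_left=config.stim_freq_left,
        stim_freq_right=config.stim_freq_right,
    )
    schedule = generate_bci_schedule(
        n_runs=n_runs,
        trials_per_class_per_run=trials_per_class_per_run,
        patterns=patterns,
        rng_seed=int(np.random.default_rng(s_sched).integers(2**31)),
    )
    end = max(tr.t_trial_end for tr in schedule) + 1.0
    n = int(round(end * sample_rate))
    data = simulate_background(end, profile, s_bg, sample_rate, labels)[:, :n]
    data += simulate_sssep(schedule, patterns, profile, s_sssep, config,
                           sample_rate, n, labels)
    data += simulate_p300(schedule, patterns, profile, s_p300,
                          sample_rate, n, labels)
    rng_art = np.random.default_rng(s_art)
    if profile.artifact_rate > 0:
        data += _simulate_artifacts(schedule, profile, rng_art, n, sample_rate,
                                    list(labels))
    if profile.eog_amp > 0:
        data += _simulate_eog(profile, np.random.default_rng(s_eog), n,
                              sample_rate, list(labels))
    events = bci_events_table(schedule, patterns)
    rec = Recording(data, sample_rate, labels, events)
    return SimulatedSession(rec, patterns, schedule, config, profile)


def _simulate_eog(
    profile: SubjectProfile,
    rng: np.random.Generator,
    n: int,
    sample_rate: float,
    labels: list[str],
) -> np.ndarray:
    """Blink-like low-frequency bursts on the EOG channels with frontal leakage."""
    out = _channel_array(n, labels)
    t = np.arange(n) / sample_rate
    n_blinks = max(1, int(n / sample_rate / 5.0))
    blink = np.zeros(n)
    for _ in range(n_blinks):
        c = rng.uniform(1.0, n / sample_rate - 1.0)
        blink += np.exp(-0.5 * ((t - c) / 0.15) ** 2)
    blink *= profile.eog_amp
    for i, ch in enumerate(labels):
        if ch.startswith("EOG"):
            out[i] = blink * rng.uniform(0.8, 1.2)
        elif ch in ("F3", "Fz", "F4"):
            out[i] = profile.eog_coupling * blink
    return out


def simulate_ideal_stim_signal(
    freq: float,
    twitch_onsets,
    duration: float,
    sample_rate: float = 600.0,
    duty_cycle: float = 0.5,
) -> np.ndarray:
    """Noiseless rectangular stimulation envelope with one-period twitch gaps.

    This is the envelope signal itself (no carrier): the steady-state response
    follows the envelope frequency, so the envelope is the relevant ideal
    input for validating the fast lock-in amplitude extraction.
    """
    env = rectangular_envelope(freq, duration, sample_rate, duty_cycle)
    onsets = np.asarray(twitch_onsets, dtype=float)
    onsets = np.round(onsets * freq) / freq  # snap to the envelope period grid
    if onsets.size == 0:
        return env
    return insert_twitches(env, onsets, freq, sample_rate)
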