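"""Lock-in amplifier system (LAS) demodulation and SSSEP feature extraction.

The LAS is realized as textbook quadrature demodulation: the signal is
multiplied by unit sine and cosine references at the stimulation frequency,
each product is low-pass filtered (4th-order Butterworth, zero phase, cutoff
half the configured bandwidth — "bandwidth" is the total two-sided width of
the equivalent band-pass around the reference frequency), and the amplitude
is ``2 * sqrt(I^2 + Q^2)`` so that a unit sinusoid at the reference frequency
reads 1.  The standard setting (2 Hz bandwidth, 1 s moving average) tracks
the mean SSSEP strength; the fast setting (4 Hz bandwidth, no moving
average) settles quickly enough to resolve twitch-locked transients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.signal import windows

from .preprocess import TrialDataset

__all__ = [
    "LasSetting",
    "SpectrogramSpec",
    "FeatureSet",
    "lock_in_amplitude",
    "extract_sssep_features",
    "extract_blocking_features",
    "compute_spectrogram",
]

#: Amplitude floor (microvolts) applied before the log transform, so that an
#: all-zero input yields a finite, trial-independent "noise floor" feature.
AMPLITUDE_FLOOR = 1e-9


@dataclass(frozen=True)
class LasSetting:
    """LAS configuration: total bandwidth (Hz), moving-average length (s or
    None), and whether the log10 transform is applied to the amplitude."""

    bandwidth: float = 2.0
    mav_length: float | None = 1.0
    log_transform: bool = True
    filter_order: int = 4

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")

    @classmethod
    def standard(cls) -> "LasSetting":
        return cls(bandwidth=2.0, mav_length=1.0, log_transform=True)

    @classmethod
    def fast(cls) -> "LasSetting":
        return cls(bandwidth=4.0, mav_length=None, log_transform=True)

    def linear(self) -> "LasSetting":
        """The same setting without the log transform (pre-log amplitude)."""
        return replace(self, log_transform=False)


def lock_in_amplitude(
    x: np.ndarray,
    freq: float,
    setting: LasSetting,
    sample_rate: float,
) -> np.ndarray:
    """Amplitude envelope of `x` at the reference frequency.

    Works on the last axis of an arbitrary-dimensional array.  A pure
    sinusoid of amplitude A at ``freq`` yields a steady-state (pre-log)
    amplitude of A.
    """
    if freq >= sample_rate / 2:
        raise ValueError("reference frequency must be below Nyquist")
    cutoff = setting.bandwidth / 2.0
    if cutoff >= freq:
        raise ValueError(
            f"half-bandwidth {cutoff} Hz reaches the reference frequency "
            f"{freq} Hz: demodulation images would overlap"
        )
    x = np.asarray(x, dtype=float)
    t = np.arange(x.shape[-1]) / sample_rate
    ref_c = np.cos(2 * np.pi * freq * t)
    ref_s = np.sin(2 * np.pi * freq * t)
    sos = signal.butter(setting.filter_order, cutoff, fs=sample_rate, output="sos")
    i = signal.sosfiltfilt(sos, x * ref_c, axis=-1)
    q = signal.sosfiltfilt(sos, x * ref_s, axis=-1)
    amp = 2.0 * np.hypot(i, q)
    if setting.mav_length:
        n = max(1, int(round(setting.mav_length * sample_rate)))
        kernel = np.ones(n) / n
        amp = np.apply_along_axis(
            lambda v: np.convolve(v, kernel, mode="same"), -1, amp
        )
    if setting.log_transform:
        amp = np.log10(np.maximum(amp, AMPLITUDE_FLOOR))
    return amp


@dataclass
class FeatureSet:
    """Per-trial feature vectors with a feature-group tag.

    ``X`` is trials x features; ``trial_ids`` maps rows back to schedule
    trials (rejected trials are absent for the SSSEP/blocking groups).
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    group: str
    trial_ids: np.ndarray

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "trial_id", self.trial_ids)
        df.insert(1, "class_label", self.y)
        return df


def _amp_series(trial: np.ndarray, freqs, setting, fs) -> np.ndarray:
    """(n_freqs, n_channels, n_samples) LAS amplitudes of one trial slice."""
    return np.stack([lock_in_amplitude(trial, f, setting, fs) for f in freqs])


def extract_sssep_features(
    dataset: TrialDataset,
    stim_freqs: tuple[float, float],
    setting: LasSetting | None = None,
    window: tuple[float, float] = (1.0, 8.5),
) -> FeatureSet:
    """Mean log-LAS amplitude per (bipolar channel x stimulation frequency).

    The amplitude is averaged over ``window`` seconds after cue onset
    (default 1-8.5 s, the steady-state portion of the focus period), giving
    13 channels x 2 frequencies = 26 features per kept trial.
    """
    setting = setting or LasSetting.standard()
    fs = dataset.sample_rate
    rows, ids, ys = [], [], []
    for i in dataset.kept_indices():
        trial = dataset.bipolar[i]
        cue = dataset.meta["cue_offset"].iloc[i]
        i0 = int(round((cue + window[0]) * fs))
        i1 = int(round((cue + window[1]) * fs))
        if i1 > trial.shape[-1]:
            raise ValueError(
                f"trial {dataset.meta['trial_id'].iloc[i]} shorter than "
                f"{window[1]} s after cue onset"
            )
        amp = _amp_series(trial, stim_freqs, setting, fs)
        rows.append(amp[..., i0:i1].mean(axis=-1).T.ravel())  # ch-major
        ids.append(dataset.meta["trial_id"].iloc[i])
        ys.append(dataset.meta["class_label"].iloc[i])
    names = [
        f"sssep:{ch}@{f:g}Hz"
        for ch in dataset.bipolar_labels
        for f in stim_freqs
    ]
    return FeatureSet(np.asarray(rows), np.asarray(ys), names, "sssep",
                      np.asarray(ids))


def extract_blocking_features(
    dataset: TrialDataset,
    stim_freqs: tuple[float, float],
    setting: LasSetting | None = None,
    window: tuple[float, float] = (0.0, 0.4),
    time_points: int | None = None,
) -> FeatureSet:
    """Twitch-locked fast-LAS features per (channel x finger).

    For each trial and finger, the fast-setting log-LAS amplitude at that
    finger's stimulation frequency is epoched over ``window`` seconds after
    each of the finger's twitch onsets and averaged across twitches.  By
    default the epoch is then averaged over time (13 channels x 2 fingers =
    26 features); ``time_points`` instead block-averages the epoch into that
    many time samples per channel and finger, retaining temporal detail.
    """
    setting = setting or LasSetting.fast()
    fs = dataset.sample_rate
    hands = ("left", "right")
    win_len = int(round((window[1] - window[0]) * fs))
    rows, ids, ys = [], [], []
    for i in dataset.kept_indices():
        trial = dataset.bipolar[i]
        feats = []
        for hand, freq in zip(hands, stim_freqs):
            onsets = dataset.twitch_onsets[hand][i]
            if onsets.size == 0:
                raise ValueError(
                    f"trial {dataset.meta['trial_id'].iloc[i]} has no "
                    f"{hand}-hand twitch events"
                )
            amp = lock_in_amplitude(trial, freq, setting, fs)
            epochs = []
            for onset in onsets:
                j0 = int(round((onset + window[0]) * fs))
                if j0 < 0 or j0 + win_len > amp.shape[-1]:
                    continue
                epochs.append(amp[:, j0:j0 + win_len])
            if not epochs:
                raise ValueError("all twitch epochs fall outside the trial span")
            mean_epoch = np.mean(epochs, axis=0)  # channels x time
            if time_points is None:
                feats.append(mean_epoch.mean(axis=-1))
            else:
                feats.append(_block_mean(mean_epoch, time_points))
        rows.append(np.concatenate([f.ravel() for f in feats]))
        ids.append(dataset.meta["trial_id"].iloc[i])
        ys.append(dataset.meta["class_label"].iloc[i])
    names = []
    for hand, freq in zip(hands, stim_freqs):
        for ch in dataset.bipolar_labels:
            if time_points is None:
                names.append(f"blocking:{ch}@{freq:g}Hz[{hand}]")
            else:
                names.extend(
                    f"blocking:{ch}@{freq:g}Hz[{hand}]t{k}"
                    for k in range(time_points)
                )
    return FeatureSet(np.asarray(rows), np.asarray(ys), names, "blocking",
                      np.asarray(ids))


def _block_mean(x: np.ndarray, n_blocks: int) -> np.ndarray:
    """Average the last axis into ``n_blocks`` (nearly) equal blocks."""
    edges = np.linspace(0, x.shape[-1], n_blocks + 1).astype(int)
    return np.stack(
        [x[..., a:b].mean(axis=-1) for a, b in zip(edges[:-1], edges[1:])],
        axis=-1,
    )


# ---------------------------------------------------------------------------
# Spectrograms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrogramSpec:
    """STFT spectrogram parameters: Gaussian window, 4096-point FFT.

    ``window_length``/``overlap`` in seconds (3/2.95 for steady-state views,
    1/0.95 for transient views); ``alignment`` selects whether trials are
    averaged aligned to trial start or to the first twitch.
    """

    fft_length: int = 4096
    window_length: float = 3.0
    overlap: float = 2.95
    alignment: str = "trial_start"
    db_reference: float = 1.0  # uV^2/Hz

    def __post_init__(self) -> None:
        if self.overlap >= self.window_length:
            raise ValueError("overlap must be shorter than the window")
        if self.alignment not in ("trial_start", "first_twitch"):
            raise ValueError("alignment must be 'trial_start' or 'first_twitch'")


def compute_spectrogram(
    trials: list[np.ndarray],
    pattern_ids: np.ndarray,
    spec: SpectrogramSpec,
    sample_rate: float,
    first_twitch_offsets: np.ndarray | None = None,
):
    """Average per-pattern PSD maps (dB) of single-channel trial slices.

    Trials with the same twitch pattern are aligned (to trial start, or by
    shifting each slice so its first twitch coincides) and their PSDs
    averaged.  Returns ``(freqs, times, {pattern_id: time x freq dB map})``.
    Groups with no trials are omitted with a warning.
    """
    fs = sample_rate
    nper = int(round(spec.window_length * fs))
    nover = int(round(spec.overlap * fs))
    win = windows.gaussian(nper, std=nper / 6.0)
    pattern_ids = np.asarray(pattern_ids)
    out: dict[int, np.ndarray] = {}
    freqs = times = None
    groups: dict[int, list[np.ndarray]] = {}
    for pid in np.unique(pattern_ids):
        idx = np.flatnonzero(pattern_ids == pid)
        slices = []
        for i in idx:
            x = np.asarray(trials[i], dtype=float).ravel()
            if spec.alignment == "first_twitch":
                if first_twitch_offsets is None:
                    raise ValueError(
                        "first_twitch alignment requires first_twitch_offsets"
                    )
                shift = int(round(first_twitch_offsets[i] * fs))
                x = x[shift:]
            slices.append(x)
        groups[int(pid)] = slices
    # common length across all groups so every PSD map shares one time axis
    n_min = min(len(x) for slices in groups.values() for x in slices)
    for pid, slices in groups.items():
        if n_min < nper:
            warnings.warn(f"pattern {pid}: trials shorter than one window; omitted")
            continue
        psds = []
        for x in slices:
            f, t, sxx = signal.spectrogram(
                x[:n_min], fs=fs, window=win, noverlap=nover,
                nfft=spec.fft_length, mode="psd",
            )
            psds.append(sxx)
        freqs, times = f, t
        mean_psd = np.mean(psds, axis=0)
        out[pid] = 10.0 * np.log10(
            np.maximum(mean_psd, 1e-30) / spec.db_reference
        ).T
    return freqs, times, out
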