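"""Montage derivation, filtering, EOG regression removal, trial epoching and
threshold-based artifact rejection.

The SSSEP channel set is a bipolar fronto-central to centro-parietal grid
above the somatosensory cortex (13 pairs, including FC3-CP3 and FC4-CP4);
the P300 channel set is 10 monopolar channels including Fz, Cz and Pz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .simulate import Recording
from .stimulation import TrialSchedule, TwitchPattern

__all__ = [
    "Montage",
    "default_montage",
    "apply_acquisition_filters",
    "derive_bipolar",
    "remove_eog",
    "TrialDataset",
    "build_trial_dataset",
    "reject_artifact_trials",
]

_DEFAULT_BIPOLAR = (
    ("FC5", "CP5"), ("FC3", "CP3"), ("FC1", "CP1"), ("FCz", "CPz"),
    ("FC2", "CP2"), ("FC4", "CP4"), ("FC6", "CP6"),
    ("FC3", "C3"), ("FC4", "C4"),
    ("C3", "CP3"), ("C4", "CP4"),
    ("C1", "CP1"), ("C2", "CP2"),
)
# Screening tuning maps use the 7-pair fronto-central row only.
_SCREENING_BIPOLAR = _DEFAULT_BIPOLAR[:7]
_DEFAULT_P300 = ("Fz", "FCz", "Cz", "CPz", "Pz", "C3", "C4", "CP1", "CP2", "P3")


@dataclass(frozen=True)
class Montage:
    """Channel sets for the two feature streams.

    ``sssep_bipolar_pairs`` are (anode, cathode) label pairs; the derived
    channel ``anode - cathode`` is labeled ``"ANODE-CATHODE"``.
    ``screening_pairs`` is the 7-pair subset used for tuning-curve maps.
    """

    sssep_bipolar_pairs: tuple[tuple[str, str], ...] = _DEFAULT_BIPOLAR
    p300_channels: tuple[str, ...] = _DEFAULT_P300
    screening_pairs: tuple[tuple[str, str], ...] = _SCREENING_BIPOLAR
    excluded_channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for a, c in self.sssep_bipolar_pairs:
            if a == c:
                raise ValueError(f"bipolar pair members must differ: {a}")

    @property
    def bipolar_labels(self) -> tuple[str, ...]:
        return tuple(f"{a}-{c}" for a, c in self.sssep_bipolar_pairs)

    def validate(self, channel_labels) -> None:
        present = set(channel_labels)
        for a, c in self.sssep_bipolar_pairs:
            for lab in (a, c):
                if lab not in present:
                    raise KeyError(f"montage channel {lab!r} missing from recording")
        missing = [ch for ch in self.p300_channels if ch not in present]
        if missing:
            raise KeyError(f"P300 channels missing from recording: {missing}")

    @classmethod
    def from_file(cls, path) -> "Montage":
        """Read a montage file: one 'A-C' pair or monopolar label per line."""
        pairs, monos = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "-" in line:
                    a, c = line.split("-", 1)
                    pairs.append((a.strip(), c.strip()))
                else:
                    monos.append(line)
        return cls(tuple(pairs), tuple(monos), tuple(pairs[:7]))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for a, c in self.sssep_bipolar_pairs:
                fh.write(f"{a}-{c}\n")
            for ch in self.p300_channels:
                fh.write(f"{ch}\n")


def default_montage() -> Montage:
    montage = Montage()
    return montage


def apply_acquisition_filters(
    recording: Recording,
    band: tuple[float, float] = (0.5, 200.0),
    notch: float = 50.0,
    notch_q: float = 35.0,
    order: int = 4,
) -> Recording:
    """Zero-phase acquisition filters: band-pass plus power-line notch."""
    if recording.sample_rate <= 2 * band[1]:
        raise ValueError(
            f"sample rate {recording.sample_rate} Hz too low for a {band[1]} Hz "
            "band edge"
        )
    sos = signal.butter(order, band, btype="bandpass",
                        fs=recording.sample_rate, output="sos")
    data = signal.sosfiltfilt(sos, recording.data, axis=-1)
    b, a = signal.iirnotch(notch, notch_q, fs=recording.sample_rate)
    data = signal.filtfilt(b, a, data, axis=-1)
    return recording.copy_with(data)


def derive_bipolar(recording: Recording, montage: Montage) -> Recording:
    """Bipolar derivation: each output channel is anode minus cathode."""
    montage.validate(recording.channel_labels)
    rows = [
        recording.get(a) - recording.get(c)
        for a, c in montage.sssep_bipolar_pairs
    ]
    return Recording(
        np.asarray(rows), recording.sample_rate, montage.bipolar_labels,
        recording.events.copy(),
    )


def remove_eog(
    recording: Recording,
    calibration: Recording | np.ndarray,
    eog_labels: tuple[str, ...] = ("EOG1", "EOG2", "EOG3"),
) -> Recording:
    """Subtract EOG leakage from the EEG channels by least-squares regression.

    Regression coefficients are estimated on a calibration segment (induced
    eye movements and blinks) and applied to the whole recording: this is the
    stationary special case of adaptive autoregressive EOG removal.  The EOG
    channels themselves are passed through unchanged.
    """
    eog_idx = [recording.channel_index(ch) for ch in eog_labels]
    eeg_idx = [i for i in range(len(recording.channel_labels)) if i not in eog_idx]
    cal = calibration.data if isinstance(calibration, Recording) else np.asarray(calibration)
    cal_eog = cal[eog_idx].T  # samples x n_eog
    cal_eeg = cal[eeg_idx].T
    cal_eog = cal_eog - cal_eog.mean(axis=0)
    cal_eeg = cal_eeg - cal_eeg.mean(axis=0)
    cov = cal_eog.T @ cal_eog
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > 1e10:
        raise np.linalg.LinAlgError(
            "EOG covariance of the calibration segment is rank deficient"
        )
    coeffs = np.linalg.solve(cov, cal_eog.T @ cal_eeg)  # n_eog x n_eeg
    data = recording.data.copy()
    eog = data[eog_idx] - data[eog_idx].mean(axis=1, keepdims=True)
    data[eeg_idx] = data[eeg_idx] - coeffs.T @ eog
    return recording.copy_with(data)


# ---------------------------------------------------------------------------
# Trial dataset
# ---------------------------------------------------------------------------

@dataclass
class TrialDataset:
    """Per-trial channel x time arrays for both feature streams.

    Each trial slice runs from trial start to trial end; ``cue_offsets`` give
    the cue time relative to the slice start, ``twitch_onsets[hand][i]`` the
    twitch times of trial ``i`` relative to the slice start.  The rejection
    masks apply to the SSSEP and blocking feature streams only: the P300
    stream deliberately uses all trials.
    """

    bipolar: list[np.ndarray]
    monopolar: list[np.ndarray]
    sample_rate: float
    bipolar_labels: tuple[str, ...]
    monopolar_labels: tuple[str, ...]
    meta: pd.DataFrame
    twitch_onsets: dict[str, list[np.ndarray]]
    rejected: np.ndarray = field(default=None)
    rejection_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rejected is None:
            self.rejected = np.zeros(len(self.bipolar), dtype=bool)
            self.rejection_reasons = [""] * len(self.bipolar)

    @property
    def n_trials(self) -> int:
        return len(self.bipolar)

    @property
    def labels(self) -> np.ndarray:
        return self.meta["class_label"].to_numpy()

    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.rejected)


def build_trial_dataset(
    recording: Recording,
    schedule: list[TrialSchedule],
    patterns: list[TwitchPattern],
    montage: Montage,
    bipolar_subset: tuple[str, ...] | None = None,
    pad: float = 1.0,
) -> TrialDataset:
    """Slice a continuous recording into per-trial arrays for both channel sets.

    ``bipolar_subset`` restricts the derived bipolar channels (by "A-C"
    label), which keeps targeted analyses such as the blocking scan cheap.
    ``pad`` extends each slice past the trial end (into the feedback period,
    never into the next trial) so that epochs locked to late twitches remain
    usable.
    """
    pairs = montage.sssep_bipolar_pairs
    if bipolar_subset is not None:
        wanted = set(bipolar_subset)
        pairs = tuple(p for p in pairs if f"{p[0]}-{p[1]}" in wanted)
        if len(pairs) != len(wanted):
            raise KeyError(f"bipolar subset {sorted(wanted)} not all in montage")
    sub_montage = Montage(pairs, montage.p300_channels, montage.screening_pairs)
    bip = derive_bipolar(recording, sub_montage)
    mono_idx = [recording.channel_index(ch) for ch in montage.p300_channels]
    fs = recording.sample_rate
    by_id = {p.pattern_id: p for p in patterns}

    bipolar, monopolar, rows = [], [], []
    twitches: dict[str, list[np.ndarray]] = {"left": [], "right": []}
    for tr in schedule:
        i0 = int(round(tr.t_trial_start * fs))
        i1 = min(int(round((tr.t_trial_end + pad) * fs)), recording.n_samples)
        bipolar.append(bip.data[:, i0:i1])
        monopolar.append(recording.data[mono_idx, i0:i1])
        rows.append(
            {
                "trial_id": tr.trial_id,
                "run": tr.run,
                "class_label": tr.class_label,
                "pattern_id": tr.pattern_id,
                "cue_offset": tr.t_cue_onset - tr.t_trial_start,
                "duration": (i1 - i0) / fs,
            }
        )
        pat = by_id[tr.pattern_id]
        for hand in ("left", "right"):
            twitches[hand].append(tr.twitch_times(pat, hand) - tr.t_trial_start)
    return TrialDataset(
        bipolar=bipolar,
        monopolar=monopolar,
        sample_rate=fs,
        bipolar_labels=sub_montage.bipolar_labels,
        monopolar_labels=tuple(montage.p300_channels),
        meta=pd.DataFrame(rows),
        twitch_onsets=twitches,
    )


def reject_artifact_trials(
    dataset: TrialDataset,
    thresholds: tuple[float, float] = (90.0, 60.0),
) -> TrialDataset:
    """Mark trials whose peak magnitude strictly exceeds the thresholds.

    ``thresholds`` is (monopolar, bipolar) in microvolts.  A trial is rejected
    for the SSSEP/blocking streams if any sample in either channel set exceeds
    its threshold; the reason records which set triggered.  The input dataset
    is returned with its mask filled in (a new object, input left untouched).
    """
    mono_thr, bip_thr = thresholds
    rejected = np.zeros(dataset.n_trials, dtype=bool)
    reasons = [""] * dataset.n_trials
    for i in range(dataset.n_trials):
        why = []
        if np.abs(dataset.monopolar[i]).max(initial=0.0) > mono_thr:
            why.append("monopolar_threshold")
        if np.abs(dataset.bipolar[i]).max(initial=0.0) > bip_thr:
            why.append("bipolar_threshold")
        if why:
            rejected[i] = True
            reasons[i] = "+".join(why)
    return TrialDataset(
        bipolar=dataset.bipolar,
        monopolar=dataset.monopolar,
        sample_rate=dataset.sample_rate,
        bipolar_labels=dataset.bipolar_labels,
        monopolar_labels=dataset.monopolar_labels,
        meta=dataset.meta,
        twitch_onsets=dataset.twitch_onsets,
        rejected=rejected,
        rejection_reasons=reasons,
    )
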