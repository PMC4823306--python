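"""Screening analysis: tuning-curve maps, bootstrap CIs, frequency selection.

Each subject shows "resonance-like" stimulation frequencies with maximal
steady-state response.  The screening paradigm stimulates each index finger
at 10 frequencies (17-35 Hz); the tuning-curve map is the percentage
band-power increase of the stimulation intervals relative to the reference
intervals, per (frequency x bipolar channel x finger), and the two BCI
stimulation frequencies are selected from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import Montage
from .simulate import Recording
from .stimulation import ScreeningSchedule

__all__ = ["TuningCurveMap", "ScreeningModel", "bootstrap_ci", "select_frequencies"]


def bootstrap_ci(
    samples: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    rng_seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of the sample mean."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least two samples for a bootstrap CI")
    rng = np.random.default_rng(rng_seed)
    idx = rng.integers(samples.size, size=(n_boot, samples.size))
    means = samples[idx].mean(axis=1)
    lo = (1.0 - level) / 2.0
    return (
        float(np.quantile(means, lo)),
        float(np.quantile(means, 1.0 - lo)),
    )


@dataclass
class TuningCurveMap:
    """Results object: relative band-power increase with bootstrap CIs.

    ``rel_bp`` (and the CI bounds) are percent, indexed
    (frequency x channel x finger).
    """

    rel_bp: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    freqs: tuple[float, ...]
    channels: tuple[str, ...]
    fingers: tuple[str, str]
    n_repetitions: int

    def __post_init__(self) -> None:
        if (self.rel_bp < -100.0 - 1e-9).any():
            raise ValueError("relative band power cannot fall below -100%")
        if (self.ci_low > self.ci_high + 1e-12).any():
            raise ValueError("CI bounds out of order")

    def value(self, freq: float, channel: str, finger: str) -> float:
        i = self.freqs.index(freq)
        j = self.channels.index(channel)
        k = self.fingers.index(finger)
        return float(self.rel_bp[i, j, k])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.freqs):
            for j, ch in enumerate(self.channels):
                for k, fi in enumerate(self.fingers):
                    rows.append(
                        {
                            "freq": f,
                            "channel": ch,
                            "finger": fi,
                            "rel_bp": self.rel_bp[i, j, k],
                            "ci_low": self.ci_low[i, j, k],
                            "ci_high": self.ci_high[i, j, k],
                        }
                    )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Tuning-curve map "
            f"({len(self.freqs)} frequencies x {len(self.channels)} channels x "
            f"{len(self.fingers)} fingers, {self.n_repetitions} repetitions each)",
        ]
        for k, fi in enumerate(self.fingers):
            best = np.unravel_index(np.argmax(self.rel_bp[:, :, k]),
                                    self.rel_bp[:, :, k].shape)
            lines.append(
                f"  {fi} finger: peak {self.rel_bp[best[0], best[1], k]:.0f}% "
                f"at {self.freqs[best[0]]:g} Hz on {self.channels[best[1]]}"
            )
        f_left, f_right = self.select_frequencies()
        lines.append(f"  selected stimulation frequencies: left {f_left:g} Hz, "
                     f"right {f_right:g} Hz")
        return "\n".join(lines)

    def select_frequencies(
        self,
        left_channel: str = "FC4-CP4",
        right_channel: str = "FC3-CP3",
        min_separation: float = 4.0,
    ) -> tuple[float, float]:
        return select_frequencies(self, left_channel, right_channel,
                                  min_separation)

    def export(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")


class ScreeningModel:
    """Tuning-curve model of one screening session.

    Band power per repetition is the variance of the band-pass filtered
    bipolar signal (2 Hz band centered on the stimulation frequency) over the
    last ``analysis_window`` seconds of the stimulation interval; the
    reference power is the same statistic over the trial's reference period.
    ``fit`` averages the per-repetition relative increases and bootstraps
    their mean.
    """

    def __init__(
        self,
        recording: Recording,
        schedule: ScreeningSchedule,
        montage: Montage | None = None,
        bandwidth: float = 2.0,
        filter_order: int = 4,
    ) -> None:
        from .preprocess import default_montage, derive_bipolar, Montage as _M

        self.montage = montage or default_montage()
        pairs = self.montage.screening_pairs
        self.recording = derive_bipolar(
            recording, _M(pairs, self.montage.p300_channels, pairs)
        )
        self.schedule = schedule
        self.bandwidth = bandwidth
        self.filter_order = filter_order

    def _band_power(self, band_data: np.ndarray, t0: float, dur: float) -> np.ndarray:
        fs = self.recording.sample_rate
        i0 = int(round(t0 * fs))
        i1 = int(round((t0 + dur) * fs))
        return band_data[:, i0:i1].var(axis=1)

    def fit(self, n_boot: int = 1000, rng_seed: int | None = None) -> TuningCurveMap:
        fs = self.recording.sample_rate
        freqs = tuple(sorted({iv.freq for iv in self.schedule.intervals}))
        fingers = ("left", "right")
        channels = self.recording.channel_labels
        rng = np.random.default_rng(rng_seed)
        win = self.schedule.analysis_window
        ref_by_trial = {(r, t): (t0, d) for r, t, t0, d in self.schedule.ref_periods}

        rel = {}
        for fi, freq in enumerate(freqs):
            half = self.bandwidth / 2.0
            sos = signal.butter(self.filter_order, (freq - half, freq + half),
                                btype="bandpass", fs=fs, output="sos")
            band = signal.sosfiltfilt(sos, self.recording.data, axis=-1)
            ref_power = {
                key: self._band_power(band, t0, d)
                for key, (t0, d) in ref_by_trial.items()
            }
            for iv in self.schedule.intervals:
                if iv.freq != freq:
                    continue
                p_ref = ref_power[(iv.run, iv.trial)]
                if (p_ref <= 0).any():
                    raise ZeroDivisionError("reference band power is zero")
                t0 = iv.t_start + iv.duration - win
                p_stim = self._band_power(band, t0, win)
                rel.setdefault((freq, iv.finger), []).append(
                    100.0 * (p_stim - p_ref) / p_ref
                )

        n_rep = min(len(v) for v in rel.values())
        shape = (len(freqs), len(channels), len(fingers))
        rel_bp = np.zeros(shape)
        ci_lo = np.zeros(shape)
        ci_hi = np.zeros(shape)
        for i, freq in enumerate(freqs):
            for k, finger in enumerate(fingers):
                reps = np.asarray(rel[(freq, finger)])  # n_rep x n_channels
                rel_bp[i, :, k] = reps.mean(axis=0)
                for j in range(len(channels)):
                    ci_lo[i, j, k], ci_hi[i, j, k] = bootstrap_ci(
                        reps[:, j], n_boot=n_boot, rng_seed=rng
                    )
        return TuningCurveMap(rel_bp, ci_lo, ci_hi, freqs, channels, fingers,
                              n_rep)


def select_frequencies(
    tuning_map: TuningCurveMap,
    left_channel: str = "FC4-CP4",
    right_channel: str = "FC3-CP3",
    min_separation: float = 4.0,
) -> tuple[float, float]:
    """Pick the left/right stimulation frequencies from a tuning map.

    Responses are read on the channel contralateral to each finger.  Over all
    ordered pairs separated by at least ``min_separation`` Hz (one
    intervening frequency on the 2 Hz grid), the pair maximizing the smaller
    of the two responses wins; ties prefer more similar responses, then the
    lower frequency sum, then lexicographic order.
    """
    freqs = tuning_map.freqs
    resp_l = {f: tuning_map.value(f, left_channel, "left") for f in freqs}
    resp_r = {f: tuning_map.value(f, right_channel, "right") for f in freqs}
    best = None
    best_key = None
    for fl in freqs:
        for fr in freqs:
            if abs(fl - fr) < min_separation:
                continue
            key = (
                -min(resp_l[fl], resp_r[fr]),
                abs(resp_l[fl] - resp_r[fr]),
                fl + fr,
                fl,
                fr,
            )
            if best_key is None or key < best_key:
                best_key = key
                best = (fl, fr)
    if best is None:
        raise ValueError("no feasible frequency pair under the separation rule")
    return best
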