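"""P300 epoch extraction, averaging, and the averages-vs-accuracy analysis.

Twitches are rare, countable events in the repetitive tactile streams; an
attended twitch evokes a positive event-related deflection around 300-400 ms.
Features are built per trial and hand from the 10 monopolar channels: 10 Hz
low-pass, 0-800 ms epochs after each of the hand's twitch onsets, per-epoch
linear detrend, average across twitches, block-mean downsampling by 10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .lockin import FeatureSet
from .preprocess import TrialDataset

__all__ = ["P300Config", "extract_p300_features", "subsample_averages_analysis"]


@dataclass(frozen=True)
class P300Config:
    """P300 feature parameters: low-pass cutoff/order, epoch window (s post
    twitch onset), and the downsampling factor."""

    lowpass_cutoff: float = 10.0
    filter_order: int = 3
    epoch_window: tuple[float, float] = (0.0, 0.8)
    downsample_factor: int = 10

    def epoch_samples(self, sample_rate: float) -> int:
        n = int(round((self.epoch_window[1] - self.epoch_window[0]) * sample_rate))
        if n % self.downsample_factor:
            raise ValueError(
                f"downsample factor {self.downsample_factor} does not divide the "
                f"epoch length of {n} samples"
            )
        return n


def _detrend_average_decimate(
    epochs: list[np.ndarray], factor: int
) -> np.ndarray:
    """Linear detrend per epoch/channel, average, block-mean decimate."""
    stacked = np.stack([signal.detrend(e, axis=-1, type="linear") for e in epochs])
    mean = stacked.mean(axis=0)  # channels x time
    n_ch, n_t = mean.shape
    return mean.reshape(n_ch, n_t // factor, factor).mean(axis=-1)


def extract_p300_features(
    dataset: TrialDataset,
    config: P300Config | None = None,
    n_averages: int | None = None,
    rng_seed: int | np.random.Generator | None = None,
) -> FeatureSet:
    """Averaged twitch-locked epochs from the monopolar channel set.

    Every trial is used (no artifact rejection for this stream).  With the
    defaults at 600 Hz each hand contributes 10 channels x 48 samples, and
    both hands concatenated give 960 features per trial.  ``n_averages``
    randomly subsamples that many twitch epochs per hand and trial before
    averaging (used by the averages-vs-accuracy analysis); epochs that would
    extend past the trial end are dropped with a warning.
    """
    config = config or P300Config()
    fs = dataset.sample_rate
    n_epoch = config.epoch_samples(fs)
    sos = signal.butter(config.filter_order, config.lowpass_cutoff,
                        fs=fs, output="sos")
    rng = np.random.default_rng(rng_seed)
    hands = ("left", "right")
    rows, ids, ys = [], [], []
    n_dropped = 0
    for i in range(dataset.n_trials):
        filtered = signal.sosfiltfilt(sos, dataset.monopolar[i], axis=-1)
        feats = []
        for hand in hands:
            onsets = dataset.twitch_onsets[hand][i]
            if onsets.size == 0:
                raise ValueError(
                    f"trial {dataset.meta['trial_id'].iloc[i]} has no "
                    f"{hand}-hand twitch events"
                )
            epochs = []
            for onset in onsets:
                j0 = int(round((onset + config.epoch_window[0]) * fs))
                if j0 < 0 or j0 + n_epoch > filtered.shape[-1]:
                    n_dropped += 1
                    continue
                epochs.append(filtered[:, j0:j0 + n_epoch])
            if not epochs:
                raise ValueError(
                    f"trial {dataset.meta['trial_id'].iloc[i]}: no usable "
                    f"{hand}-hand twitch epochs"
                )
            if n_averages is not None:
                if n_averages > len(epochs):
                    raise ValueError(
                        f"n_averages={n_averages} exceeds the {len(epochs)} "
                        "available twitch epochs"
                    )
                pick = rng.choice(len(epochs), size=n_averages, replace=False)
                epochs = [epochs[k] for k in sorted(pick)]
            feats.append(
                _detrend_average_decimate(epochs, config.downsample_factor)
            )
        rows.append(np.concatenate([f.ravel() for f in feats]))
        ids.append(dataset.meta["trial_id"].iloc[i])
        ys.append(dataset.meta["class_label"].iloc[i])
    if n_dropped:
        warnings.warn(f"{n_dropped} twitch epochs extended past trial end; dropped")
    n_keep = n_epoch // config.downsample_factor
    names = [
        f"p300:{ch}[{hand}]t{k}"
        for hand in hands
        for ch in dataset.monopolar_labels
        for k in range(n_keep)
    ]
    return FeatureSet(np.asarray(rows), np.asarray(ys), names, "p300",
                      np.asarray(ids))


def subsample_averages_analysis(
    dataset: TrialDataset,
    config: P300Config | None = None,
    n_range=range(1, 8),
    n_repeats: int = 10,
    rng_seed: int | None = None,
    cv_repeats: int = 10,
    cv_folds: int = 10,
) -> pd.DataFrame:
    """Classification accuracy as a function of the number of averaged epochs.

    For each number of averages ``n``, twitch epochs are randomly subsampled
    per hand and trial, features rebuilt, and repeated stratified
    cross-validation run; the subsampling is repeated ``n_repeats`` times.
    Returns a tidy frame with one row per (n, repeat) plus the accuracy; when
    ``n`` equals the available epoch count the subsampling is degenerate and
    a single repeat is recorded.
    """
    from .lda import ShrinkageLDA, cross_validate

    config = config or P300Config()
    root = np.random.SeedSequence(rng_seed)
    rows = []
    n_available = min(
        min(len(v) for v in dataset.twitch_onsets["left"]),
        min(len(v) for v in dataset.twitch_onsets["right"]),
    )
    for n in n_range:
        repeats = 1 if n >= n_available else n_repeats
        for rep in range(repeats):
            s_sub, s_cv = root.spawn(2)
            fs = extract_p300_features(dataset, config, n_averages=n,
                                       rng_seed=np.random.default_rng(s_sub))
            res = cross_validate(
                fs.X, fs.y, n_repeats=cv_repeats, n_folds=cv_folds,
                rng_seed=int(np.random.default_rng(s_cv).integers(2**31)),
                estimator=ShrinkageLDA(),
            )
            rows.append({"n_averages": n, "repeat": rep, "accuracy": res.accuracy})
    return pd.DataFrame(rows)
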