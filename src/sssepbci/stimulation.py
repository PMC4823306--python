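"""Tactile stimulation waveforms, twitch patterns, and session schedules.

The stimulation signal is a 237 Hz sinusoidal carrier, amplitude-modulated by a
rectangular envelope at the stimulation frequency (17-35 Hz in 2 Hz steps).
The duty cycle is realized as an integer number of full carrier cycles per
envelope period so that the carrier always starts and stops at phase zero.
"Twitches" are transient target stimuli: complete interruptions of the
stimulation signal for exactly one envelope period, pseudo-randomly embedded
into the focus period of a trial with a pooled (within- and across-hand)
inter-stimulus interval of at least 250 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "STIM_FREQ_GRID",
    "StimulationConfig",
    "TwitchPattern",
    "TrialSchedule",
    "ScreeningInterval",
    "ScreeningSchedule",
    "carrier_cycles_per_burst",
    "rectangular_envelope",
    "generate_stimulus_waveform",
    "insert_twitches",
    "generate_twitch_patterns",
    "generate_bci_schedule",
    "generate_screening_schedule",
    "bci_events_table",
    "screening_events_table",
    "write_events",
    "read_events",
]

#: Stimulation frequency grid used for screening (Hz).
STIM_FREQ_GRID = tuple(range(17, 36, 2))

CLASS_LABELS = ("focus_left", "focus_right", "idle")


@dataclass(frozen=True)
class StimulationConfig:
    """Stimulation waveform parameters for one session.

    Parameters
    ----------
    carrier_freq : float
        Carrier frequency in Hz (vibrotactile carrier, default 237).
    stim_freq_left, stim_freq_right : float
        Rectangular-envelope (stimulation) frequencies for the left and right
        index fingers, in Hz; must lie on the 17-35 Hz screening grid.
    sample_rate : float
        Output sampling rate in Hz.  600 Hz aligns waveform envelopes with the
        EEG; use a higher rate for audio-rate waveform export.
    duty_cycle_target : float
        Requested envelope duty cycle; the realized duty cycle is the nearest
        value achievable with an integer number of carrier cycles per burst.
    """

    carrier_freq: float = 237.0
    stim_freq_left: float = 25.0
    stim_freq_right: float = 29.0
    sample_rate: float = 600.0
    duty_cycle_target: float = 0.5

    def __post_init__(self) -> None:
        for f in (self.stim_freq_left, self.stim_freq_right):
            if f not in STIM_FREQ_GRID:
                raise ValueError(
                    f"stimulation frequency {f} Hz not on the "
                    f"{STIM_FREQ_GRID[0]}-{STIM_FREQ_GRID[-1]} Hz grid"
                )
        if not 0.0 < self.duty_cycle_target < 1.0:
            raise ValueError("duty_cycle_target must lie in (0, 1)")
        if self.carrier_freq <= 2 * max(self.stim_freq_left, self.stim_freq_right):
            raise ValueError("carrier_freq must exceed twice the stimulation frequency")

    def stim_freq(self, hand: str) -> float:
        if hand == "left":
            return self.stim_freq_left
        if hand == "right":
            return self.stim_freq_right
        raise ValueError(f"unknown hand {hand!r}")


def carrier_cycles_per_burst(freq: float, config: StimulationConfig) -> int:
    """Number of full carrier cycles in each envelope on-burst.

    The realized duty cycle ``n_cycles * freq / carrier_freq`` is the integer
    realization nearest ``duty_cycle_target`` (minimum one cycle), which keeps
    every on/off transition at carrier phase zero.
    """
    if freq <= 0:
        raise ValueError("stimulation frequency must be positive")
    if config.carrier_freq <= 2 * freq:
        raise ValueError("carrier_freq must exceed twice the stimulation frequency")
    return max(1, round(config.duty_cycle_target * config.carrier_freq / freq))


def realized_duty_cycle(freq: float, config: StimulationConfig) -> float:
    return carrier_cycles_per_burst(freq, config) * freq / config.carrier_freq


def rectangular_envelope(
    freq: float,
    duration: float,
    sample_rate: float,
    duty_cycle: float = 0.5,
) -> np.ndarray:
    """0/1 rectangular envelope at `freq` with the given duty cycle."""
    if freq <= 0:
        raise ValueError("stimulation frequency must be positive")
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    return ((t * freq) % 1.0 < duty_cycle).astype(float)


def generate_stimulus_waveform(
    freq: float,
    duration: float,
    config: StimulationConfig,
) -> np.ndarray:
    """Carrier sinusoid gated by the rectangular stimulation envelope.

    Within every envelope period the carrier restarts at phase zero and the
    burst spans an integer number of carrier cycles.  ``duration`` may be zero,
    in which case an empty array is returned.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    n_cycles = carrier_cycles_per_burst(freq, config)
    n = int(round(duration * config.sample_rate))
    if n == 0:
        return np.zeros(0)
    t = np.arange(n) / config.sample_rate
    tau = t % (1.0 / freq)  # time since the start of the current envelope period
    gate = tau < n_cycles / config.carrier_freq
    return np.where(gate, np.sin(2 * np.pi * config.carrier_freq * tau), 0.0)


def insert_twitches(
    envelope: np.ndarray,
    twitch_onsets: np.ndarray,
    freq: float,
    sample_rate: float,
) -> np.ndarray:
    """Force the envelope/waveform to zero for one stimulation period per twitch.

    Each twitch suppresses the half-open window ``[onset, onset + 1/freq)``.
    Overlapping twitch windows raise, since a sample cannot belong to two
    deleted periods.
    """
    onsets = np.sort(np.asarray(twitch_onsets, dtype=float))
    if onsets.size and (np.diff(onsets) < 1.0 / freq - 1e-12).any():
        raise ValueError("twitch windows overlap (onsets closer than one period)")
    out = np.array(envelope, dtype=float, copy=True)
    n = out.shape[-1]
    span = n / sample_rate
    for onset in onsets:
        if onset < 0 or onset >= span:
            raise ValueError(f"twitch onset {onset} s outside the envelope span")
        i0 = int(np.ceil(onset * sample_rate - 1e-9))
        i1 = int(np.ceil((onset + 1.0 / freq) * sample_rate - 1e-9))
        out[..., i0:min(i1, n)] = 0.0
    return out


# ---------------------------------------------------------------------------
# Twitch patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwitchPattern:
    """Pseudo-randomized twitch onsets for both hands within one focus period.

    Onsets are seconds relative to the start of the focus period.  Onsets are
    strictly increasing per hand, and pooling both hands the consecutive
    spacing never falls below the minimum inter-stimulus interval.
    """

    pattern_id: int
    onsets_left: np.ndarray
    onsets_right: np.ndarray

    def onsets(self, hand: str) -> np.ndarray:
        if hand == "left":
            return self.onsets_left
        if hand == "right":
            return self.onsets_right
        raise ValueError(f"unknown hand {hand!r}")

    def pooled_onsets(self) -> np.ndarray:
        return np.sort(np.concatenate([self.onsets_left, self.onsets_right]))

    def min_pooled_isi(self) -> float:
        pooled = self.pooled_onsets()
        if pooled.size < 2:
            return np.inf
        return float(np.diff(pooled).min())

    def validate(self, min_isi: float, focus_duration: float) -> None:
        for hand in ("left", "right"):
            o = self.onsets(hand)
            if o.size > 1 and not (np.diff(o) > 0).all():
                raise ValueError(f"{hand} onsets not strictly increasing")
            if o.size and (o.min() < 0 or o.max() > focus_duration):
                raise ValueError(f"{hand} onsets outside the focus period")
        if self.min_pooled_isi() < min_isi - 1e-12:
            raise ValueError("pooled inter-stimulus interval below the minimum")


def generate_twitch_patterns(
    n_patterns: int = 3,
    n_twitches: int = 7,
    focus_duration: float = 9.5,
    min_isi: float = 0.25,
    rng_seed: int | np.random.Generator | None = None,
    stim_freq_left: float | None = None,
    stim_freq_right: float | None = None,
    max_attempts: int = 10_000,
) -> list[TwitchPattern]:
    """Rejection-sample twitch patterns under the pooled-ISI constraint.

    Onsets per hand are drawn uniformly over the focus window (leaving room
    for the deleted period at the end) and a candidate is accepted when the
    pooled, sorted onsets of both hands are spaced at least ``min_isi`` apart.
    When the stimulation frequencies are given, onsets are quantized to the
    corresponding hand's envelope-period grid so that a twitch deletes exactly
    one stimulation period.
    """
    if 2 * n_twitches * min_isi >= focus_duration:
        raise ValueError(
            f"infeasible: 2*{n_twitches}*{min_isi} s of minimum spacing does not "
            f"fit into a {focus_duration} s focus period"
        )
    rng = np.random.default_rng(rng_seed)
    # leave room for the deleted envelope period after the last onset;
    # the longest period on the frequency grid (17 Hz) bounds it when the
    # actual frequencies are not yet known.
    freqs = {"left": stim_freq_left, "right": stim_freq_right}
    margin = max(1.0 / f if f else 1.0 / STIM_FREQ_GRID[0] for f in freqs.values())
    upper = focus_duration - margin

    patterns: list[TwitchPattern] = []
    for pid in range(1, n_patterns + 1):
        for _ in range(max_attempts):
            onsets = {}
            for hand, f in freqs.items():
                u = np.sort(rng.uniform(0.0, upper, size=n_twitches))
                if f is not None:
                    u = np.unique(np.round(u * f) / f)
                    if u.size < n_twitches:
                        break
                onsets[hand] = u
            else:
                cand = TwitchPattern(pid, onsets["left"], onsets["right"])
                if cand.min_pooled_isi() >= min_isi:
                    if n_twitches == 0 or all(
                        not (
                            np.array_equal(cand.onsets_left, p.onsets_left)
                            and np.array_equal(cand.onsets_right, p.onsets_right)
                        )
                        for p in patterns
                    ):
                        patterns.append(cand)
                        break
        else:
            raise RuntimeError(
                f"could not draw a valid twitch pattern in {max_attempts} attempts"
            )
    return patterns


# ---------------------------------------------------------------------------
# BCI schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialSchedule:
    """Timing and class assignment of one cue-based BCI trial.

    All times are seconds relative to session start.  Stimulation of both
    fingers runs from ``t_stim_start`` to ``t_trial_end``; twitches occur only
    inside the focus/idle period ``[t_cue_onset, t_trial_end)``.
    """

    trial_id: int
    run: int
    class_label: str
    t_trial_start: float
    ref_duration: float
    focus_duration: float
    pattern_id: int

    @property
    def t_stim_start(self) -> float:
        return self.t_trial_start + 0.2

    @property
    def t_ref_start(self) -> float:
        return self.t_trial_start + 0.5

    @property
    def t_cue_onset(self) -> float:
        return self.t_ref_start + self.ref_duration

    @property
    def t_trial_end(self) -> float:
        return self.t_cue_onset + self.focus_duration

    def twitch_times(self, pattern: TwitchPattern, hand: str) -> np.ndarray:
        """Absolute twitch onset times for one hand."""
        return self.t_cue_onset + pattern.onsets(hand)


def generate_bci_schedule(
    n_runs: int = 8,
    trials_per_class_per_run: int = 10,
    patterns: list[TwitchPattern] | None = None,
    rng_seed: int | None = None,
    ref_range: tuple[float, float] = (1.0, 1.5),
    focus_range: tuple[float, float] = (9.5, 10.0),
    feedback_duration: float = 2.0,
    break_range: tuple[float, float] = (3.0, 4.0),
) -> list[TrialSchedule]:
    """Cue-based three-class schedule: class-balanced runs in random order.

    Each run holds ``trials_per_class_per_run`` trials of each of the three
    classes (focus left / focus right / idle), shuffled within the run.  One
    of the pre-generated twitch patterns is drawn uniformly per trial.
    Reference and focus periods are drawn uniformly within their ranges from
    per-trial child seeds, so the schedule is reproducible bit-exactly.
    """
    if n_runs < 1 or trials_per_class_per_run < 1:
        raise ValueError("n_runs and trials_per_class_per_run must be positive")
    if not patterns:
        raise ValueError("patterns must be a non-empty list of TwitchPattern")
    root = np.random.SeedSequence(rng_seed)
    order_rng = np.random.default_rng(root.spawn(1)[0])
    trial_seeds = root.spawn(n_runs * 3 * trials_per_class_per_run)

    trials: list[TrialSchedule] = []
    t = 0.0
    trial_id = 0
    for run in range(1, n_runs + 1):
        labels = list(CLASS_LABELS) * trials_per_class_per_run
        order_rng.shuffle(labels)
        for label in labels:
            rng = np.random.default_rng(trial_seeds[trial_id])
            ref = rng.uniform(*ref_range)
            focus = rng.uniform(*focus_range)
            pid = int(rng.integers(len(patterns)))
            trial = TrialSchedule(
                trial_id=trial_id,
                run=run,
                class_label=label,
                t_trial_start=t,
                ref_duration=ref,
                focus_duration=focus,
                pattern_id=patterns[pid].pattern_id,
            )
            trials.append(trial)
            t = trial.t_trial_end + feedback_duration + rng.uniform(*break_range)
            trial_id += 1
    return trials


# ---------------------------------------------------------------------------
# Screening schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreeningInterval:
    """One 2.3 s stimulation interval of the screening paradigm."""

    run: int
    trial: int
    t_start: float
    duration: float
    freq: float
    finger: str


@dataclass(frozen=True)
class ScreeningSchedule:
    """Screening session: runs x trials, each trial a reference period plus
    10 stimulation intervals with (frequency, finger) assignments."""

    intervals: list[ScreeningInterval]
    ref_periods: list[tuple[int, int, float, float]]  # (run, trial, t_start, duration)
    interval_length: float = 2.3
    analysis_window: float = 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "run": iv.run,
                    "trial": iv.trial,
                    "t_start": iv.t_start,
                    "duration": iv.duration,
                    "freq": iv.freq,
                    "finger": iv.finger,
                }
                for iv in self.intervals
            ]
        )


def _no_repeat_order(pool: list[tuple[float, str]], rng: np.random.Generator,
                     max_iter: int = 100_000) -> list[tuple[float, str]]:
    """Shuffle, then repair adjacent (freq, finger) repeats by local re-draws."""
    items = list(pool)
    rng.shuffle(items)
    for _ in range(max_iter):
        bad = [i for i in range(1, len(items)) if items[i] == items[i - 1]]
        if not bad:
            return items
        i = bad[0]
        j = int(rng.integers(len(items)))
        items[i], items[j] = items[j], items[i]
    raise RuntimeError("could not resolve adjacent repeats in the screening order")


def generate_screening_schedule(
    rng_seed: int | None = None,
    n_runs: int = 8,
    trials_per_run: int = 10,
    intervals_per_trial: int = 10,
    freqs: tuple[float, ...] = STIM_FREQ_GRID,
    fingers: tuple[str, str] = ("left", "right"),
    interval_length: float = 2.3,
    pause: float = 0.25,
    ref_range: tuple[float, float] = (3.0, 3.5),
    inter_trial_gap: float = 2.0,
) -> ScreeningSchedule:
    """Balanced screening schedule: every (frequency, finger) combination
    appears equally often, with no immediate repetition within a run.

    The per-run interval count must be a multiple of the number of
    combinations; with the defaults each of the 20 combinations appears 5
    times per run and 40 times over the 8-run session (800 intervals total).
    """
    n_per_run = trials_per_run * intervals_per_trial
    combos = [(f, fi) for f in freqs for fi in fingers]
    reps, rem = divmod(n_per_run, len(combos))
    if rem:
        raise ValueError("intervals per run must be a multiple of the number of "
                         "(frequency, finger) combinations")
    root = np.random.SeedSequence(rng_seed)
    rng = np.random.default_rng(root)

    intervals: list[ScreeningInterval] = []
    refs: list[tuple[int, int, float, float]] = []
    t = 0.0
    for run in range(1, n_runs + 1):
        order = _no_repeat_order(combos * reps, rng)
        k = 0
        for trial in range(1, trials_per_run + 1):
            ref = rng.uniform(*ref_range)
            refs.append((run, trial, t, ref))
            t += ref
            for _ in range(intervals_per_trial):
                freq, finger = order[k]
                intervals.append(
                    ScreeningInterval(run, trial, t, interval_length, freq, finger)
                )
                t += interval_length + pause
                k += 1
            t += inter_trial_gap
    return ScreeningSchedule(intervals, refs, interval_length)


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

_CUE_EVENT = {"focus_left": "cue_left", "focus_right": "cue_right", "idle": "cue_idle"}


def bci_events_table(
    schedule: list[TrialSchedule],
    patterns: list[TwitchPattern],
) -> pd.DataFrame:
    """Flat event table: trial start/cue/twitch/end markers with times in s."""
    by_id = {p.pattern_id: p for p in patterns}
    rows = []
    for tr in schedule:
        pat = by_id[tr.pattern_id]
        rows.append((tr.t_trial_start, "trial_start", tr.trial_id, tr.pattern_id))
        rows.append((tr.t_cue_onset, _CUE_EVENT[tr.class_label], tr.trial_id, tr.pattern_id))
        for hand in ("left", "right"):
            for t in tr.twitch_times(pat, hand):
                rows.append((t, f"twitch_{hand}", tr.trial_id, tr.pattern_id))
        rows.append((tr.t_trial_end, "trial_end", tr.trial_id, tr.pattern_id))
    df = pd.DataFrame(rows, columns=["time_s", "event_type", "trial_id", "pattern_id"])
    return df.sort_values(["time_s", "event_type"], kind="stable").reset_index(drop=True)


def screening_events_table(schedule: ScreeningSchedule) -> pd.DataFrame:
    rows = [
        (t0, "ref_start", (run - 1) * 1000 + trial, -1)
        for run, trial, t0, _dur in schedule.ref_periods
    ]
    for iv in schedule.intervals:
        rows.append(
            (iv.t_start, f"stim_{iv.finger}_{iv.freq:g}", (iv.run - 1) * 1000 + iv.trial, -1)
        )
    df = pd.DataFrame(rows, columns=["time_s", "event_type", "trial_id", "pattern_id"])
    return df.sort_values(["time_s", "event_type"], kind="stable").reset_index(drop=True)


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
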