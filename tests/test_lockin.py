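"""Lock-in amplitude extraction, SSSEP/blocking features, spectrograms."""

import numpy as np
import pytest
from scipy import signal

import sssepbci as s
from sssepbci.lockin import (
    AMPLITUDE_FLOOR,
    LasSetting,
    SpectrogramSpec,
    compute_spectrogram,
    extract_blocking_features,
    extract_sssep_features,
    lock_in_amplitude,
)

FS = 600.0


def _sine(freq, amp=1.0, duration=10.0, phase=0.0):
    t = np.arange(int(duration * FS)) / FS
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestLockInAmplitude:
    def test_unit_calibration(self):
        """A=2 sinusoid at the reference frequency reads 2.0 pre-log."""
        amp = lock_in_amplitude(_sine(35.0, 2.0), 35.0,
                                LasSetting.fast().linear(), FS)
        assert amp[3000:4000].mean() == pytest.approx(2.0, rel=0.01)

    def test_out_of_band_rejection(self):
        """5 Hz off-tune input is rejected to <10% by the 4 Hz-bandwidth
        setting (filter frequency-response oracle)."""
        amp = lock_in_amplitude(_sine(40.0, 1.0), 35.0,
                                LasSetting.fast().linear(), FS)
        assert amp[3000:4000].mean() < 0.1

    @pytest.mark.parametrize("phase", np.linspace(0, 2 * np.pi, 8, endpoint=False))
    def test_phase_invariance(self, phase):
        amp = lock_in_amplitude(_sine(25.0, 1.0, phase=phase), 25.0,
                                LasSetting.standard().linear(), FS)
        assert amp[3000:4000].mean() == pytest.approx(1.0, rel=0.01)

    def test_fast_settles_faster_than_standard(self):
        """Settling to 90% of the final value on a step-modulated sinusoid."""
        x = _sine(27.0)
        x[:int(2 * FS)] = 0.0  # step at t=2 s

        def settle(setting):
            amp = lock_in_amplitude(x, 27.0, setting, FS)
            final = amp[4000:5000].mean()
            i = np.argmax(amp[int(2 * FS):] >= 0.9 * final)
            return i / FS

        assert settle(LasSetting.fast().linear()) < settle(
            LasSetting.standard().linear())

    def test_log_preserves_ordering(self):
        rng = np.random.default_rng(0)
        amps = rng.uniform(0.1, 5.0, size=12)
        lin, log = [], []
        for a in amps:
            x = _sine(21.0, a)
            lin.append(lock_in_amplitude(x, 21.0, LasSetting.fast().linear(),
                                         FS)[3000:4000].mean())
            log.append(lock_in_amplitude(x, 21.0, LasSetting.fast(),
                                         FS)[3000:4000].mean())
        assert np.array_equal(np.argsort(lin), np.argsort(log))

    def test_bandwidth_overlap_error(self):
        with pytest.raises(ValueError, match="images"):
            lock_in_amplitude(_sine(2.0), 1.5, LasSetting(bandwidth=4.0), FS)


class TestSssepFeatures:
    def test_feature_count_and_names(self, bci_dataset, stim_freqs):
        fs = extract_sssep_features(bci_dataset, stim_freqs)
        assert fs.n_features == 26
        assert fs.X.shape[0] == len(bci_dataset.kept_indices())
        assert fs.group == "sssep"
        assert fs.feature_names[0].startswith("sssep:FC5-CP5@")

    def test_attention_separates_classes(self, clean_profile):
        """Left-cue trials boost left-frequency features on right-hemisphere
        channels relative to idle trials (construction oracle)."""
        sess = s.simulate_session("bci", clean_profile, rng_seed=8, n_runs=1)
        ds = s.build_trial_dataset(sess.recording, sess.schedule, sess.patterns,
                                   s.default_montage())
        fs = extract_sssep_features(
            ds, (sess.config.stim_freq_left, sess.config.stim_freq_right))
        col = fs.feature_names.index(
            f"sssep:FC4-CP4@{sess.config.stim_freq_left:g}Hz")
        left = fs.X[fs.y == "focus_left", col].mean()
        idle = fs.X[fs.y == "idle", col].mean()
        assert left > idle

    def test_zero_signal_noise_floor(self, bci_dataset, stim_freqs):
        import copy

        ds = copy.copy(bci_dataset)
        ds.bipolar = [np.zeros_like(b) for b in bci_dataset.bipolar]
        fs = extract_sssep_features(ds, stim_freqs)
        assert np.allclose(fs.X, np.log10(AMPLITUDE_FLOOR))

    def test_short_trial_error(self, bci_dataset, stim_freqs):
        import copy

        ds = copy.copy(bci_dataset)
        ds.bipolar = [b[:, :1200] for b in bci_dataset.bipolar]
        with pytest.raises(ValueError, match="shorter"):
            extract_sssep_features(ds, stim_freqs)


class TestBlockingFeatures:
    def test_default_feature_count(self, bci_dataset, stim_freqs):
        fs = extract_blocking_features(bci_dataset, stim_freqs)
        assert fs.n_features == 26
        assert fs.group == "blocking"

    def test_time_resolved_variant(self, bci_dataset, stim_freqs):
        fs = extract_blocking_features(bci_dataset, stim_freqs, time_points=14)
        assert fs.n_features == 26 * 14

    def test_blocked_lower_than_unblocked(self):
        """Construction oracle: with 2.5 dB blocking the twitch-locked features
        drop below the no-blocking version of the same session."""
        means = {}
        for depth in (0.0, 2.5):
            prof = s.SubjectProfile(noise_amp=0.5, alpha_amp=0.0,
                                    blocking_depth_db=depth)
            sess = s.simulate_session("bci", prof, rng_seed=9, n_runs=1)
            ds = s.build_trial_dataset(sess.recording, sess.schedule,
                                       sess.patterns, s.default_montage())
            fs = extract_blocking_features(
                ds, (sess.config.stim_freq_left, sess.config.stim_freq_right))
            col = fs.feature_names.index(
                f"blocking:FC4-CP4@{sess.config.stim_freq_left:g}Hz[left]")
            means[depth] = fs.X[:, col].mean()
        assert means[2.5] < means[0.0]

    def test_missing_twitches_error(self, bci_dataset, stim_freqs):
        import copy

        ds = copy.copy(bci_dataset)
        ds.twitch_onsets = {
            "left": [np.array([])] * ds.n_trials,
            "right": list(bci_dataset.twitch_onsets["right"]),
        }
        with pytest.raises(ValueError, match="twitch"):
            extract_blocking_features(ds, stim_freqs)


class TestSpectrogram:
    def test_pure_tone_ridge(self):
        x = _sine(25.0, duration=20.0)
        spec = SpectrogramSpec(window_length=3.0, overlap=2.95)
        freqs, times, maps = compute_spectrogram([x], np.array([1]), spec, FS)
        psd = maps[1]
        ridge = freqs[np.argmax(psd.mean(axis=0))]
        bin_width = FS / spec.fft_length
        assert abs(ridge - 25.0) <= bin_width

    def test_time_frequency_tradeoff(self):
        """Direct STFT oracle: a frequency step is sharper in frequency with
        the 3 s window and sharper in time with the 1 s window."""
        t = np.arange(int(40 * FS)) / FS
        x = np.where(t < 20, np.sin(2 * np.pi * 20 * t), np.sin(2 * np.pi * 30 * t))

        def analyze(wl, ov):
            spec = SpectrogramSpec(window_length=wl, overlap=ov)
            freqs, times, maps = compute_spectrogram([x], np.array([1]), spec, FS)
            psd = 10 ** (maps[1] / 10.0)
            mid = psd[len(times) // 4]  # stationary 20 Hz segment
            keep = (freqs > 10) & (freqs < 40)
            p = mid[keep] / mid[keep].sum()
            f_spread = np.sqrt(np.sum(p * (freqs[keep] - 20.0) ** 2))
            # temporal sharpness: width of the transition in the 30 Hz band
            band30 = psd[:, np.argmin(np.abs(freqs - 30.0))]
            rising = (band30 - band30.min()) / (band30.max() - band30.min())
            t_spread = times[rising > 0.9][0] - times[rising > 0.1][0]
            return f_spread, t_spread

        f3, t3 = analyze(3.0, 2.95)
        f1, t1 = analyze(1.0, 0.95)
        assert f3 < f1
        assert t1 < t3

    def test_blocking_dip_time_locked(self):
        """1 s-window spectrogram of a blocked SSSEP dips at the stimulation
        frequency after each twitch (first-twitch alignment)."""
        prof = s.SubjectProfile(noise_amp=0.2, alpha_amp=0.0, p300_amp=0.0,
                                blocking_depth_db=6.0)
        sess = s.simulate_session("bci", prof, rng_seed=10, n_runs=1,
                                  trials_per_class_per_run=2)
        rec = sess.recording
        freq = sess.config.stim_freq_left
        pats = {p.pattern_id: p for p in sess.patterns}
        trials, pids, offsets = [], [], []
        for tr in sess.schedule:
            i0 = int(tr.t_trial_start * FS)
            i1 = int(tr.t_trial_end * FS)
            trials.append(rec.get("FC4")[i0:i1])
            pids.append(tr.pattern_id)
            offsets.append(tr.twitch_times(pats[tr.pattern_id], "left")[0]
                           - tr.t_trial_start)
        spec = SpectrogramSpec(window_length=1.0, overlap=0.95,
                               alignment="first_twitch")
        freqs, times, maps = compute_spectrogram(
            trials, np.array(pids), spec, FS, np.array(offsets))
        fbin = np.argmin(np.abs(freqs - freq))
        for pid, psd in maps.items():
            series = psd[:, fbin]
            pat = pats[pid]
            rel = pat.onsets_left - pat.onsets_left[0]
            tested = 0
            for onset in rel:
                if onset < times[0] + 0.2 or onset + 0.5 > times[-1]:
                    continue
                near = series[(times >= onset - 0.1) & (times <= onset + 0.45)]
                base = np.median(series)
                assert near.min() < base
                tested += 1
            assert tested > 0
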