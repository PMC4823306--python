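"""Synthetic EEG generator: spectra, topography, injected effects, composition."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal, stats

import sssepbci as s
from sssepbci.lockin import LasSetting, lock_in_amplitude
from sssepbci.simulate import EEG_CHANNELS, EOG_CHANNELS


class TestBackground:
    def test_white_noise_flat_spectrum(self):
        """beta=0, no alpha: Welch log-log PSD slope is ~0."""
        prof = s.SubjectProfile(noise_exponent=0.0, alpha_amp=0.0)
        x = s.simulate_background(60.0, prof, rng_seed=0)[0]
        f, p = signal.welch(x, fs=600.0, nperseg=4096)
        keep = (f > 1) & (f < 250)
        slope = stats.linregress(np.log10(f[keep]), np.log10(p[keep])).slope
        assert abs(slope) < 0.1

    def test_pink_noise_slope(self):
        prof = s.SubjectProfile(noise_exponent=1.0, alpha_amp=0.0)
        x = s.simulate_background(60.0, prof, rng_seed=0)[0]
        f, p = signal.welch(x, fs=600.0, nperseg=4096)
        keep = (f > 1) & (f < 100)
        slope = stats.linregress(np.log10(f[keep]), np.log10(p[keep])).slope
        assert slope == pytest.approx(-1.0, abs=0.25)

    def test_sample_count_and_zero_mean(self):
        x = s.simulate_background(1.0, s.SubjectProfile(), rng_seed=1)
        assert x.shape == (32, 600)
        assert np.abs(x.mean(axis=1)).max() < 1.0

    def test_alpha_band_peak_everywhere(self):
        """Strong alpha: 8-12 Hz band power dominates neighbours on all channels."""
        prof = s.SubjectProfile(alpha_amp=10.0, noise_amp=1.0)
        x = s.simulate_background(30.0, prof, rng_seed=2)
        f, p = signal.welch(x, fs=600.0, nperseg=4096, axis=-1)
        alpha = p[:, (f >= 8) & (f <= 12)].mean(axis=1)
        neigh = p[:, (f >= 15) & (f <= 25)].mean(axis=1)
        assert np.all(alpha > 5 * neigh)


class TestSssep:
    @pytest.fixture(scope="class")
    def clean_session(self, clean_profile):
        return s.simulate_session("bci", clean_profile, rng_seed=3, n_runs=1)

    def _trial_amp(self, sess, trial, hand, channel):
        cfg = sess.config
        rec = sess.recording
        freq = cfg.stim_freq(hand)
        i0 = int((trial.t_cue_onset + 1.0) * rec.sample_rate)
        i1 = int((trial.t_cue_onset + 8.0) * rec.sample_rate)
        x = rec.get(channel)[i0:i1]
        amp = lock_in_amplitude(x, freq, LasSetting.standard().linear(),
                                rec.sample_rate)
        return amp[600:-600].mean()

    def test_attention_gain_recovered(self, clean_session):
        """Cue-left trials carry 1.3x the idle left-frequency amplitude on the
        contralateral channel (construction oracle)."""
        by_class = {}
        for tr in clean_session.schedule:
            by_class.setdefault(tr.class_label, []).append(tr)
        amp_att = np.mean([
            self._trial_amp(clean_session, tr, "left", "FC4")
            for tr in by_class["focus_left"]
        ])
        amp_idle = np.mean([
            self._trial_amp(clean_session, tr, "left", "FC4")
            for tr in by_class["idle"]
        ])
        assert amp_att / amp_idle == pytest.approx(1.3, rel=0.05)

    def test_contralateral_topography(self, clean_session):
        """Left-hand SSSEP absent on left-hemisphere channels."""
        tr = clean_session.schedule[0]
        a_contra = self._trial_amp(clean_session, tr, "left", "FC4")
        a_ipsi = self._trial_amp(clean_session, tr, "left", "FC3")
        assert a_contra > 5 * a_ipsi

    def test_blocking_depth_zero_flat(self, null_profile):
        prof = s.SubjectProfile(
            attention_gain=1.0, blocking_depth_db=0.0, p300_amp=0.0,
            noise_amp=0.0, alpha_amp=0.0,
        )
        sess = s.simulate_session("bci", prof, rng_seed=4, n_runs=1,
                                  trials_per_class_per_run=1)
        tr = sess.schedule[0]
        rec = sess.recording
        freq = sess.config.stim_freq_left
        i0 = int(tr.t_cue_onset * rec.sample_rate)
        i1 = int(tr.t_trial_end * rec.sample_rate)
        amp = lock_in_amplitude(rec.get("FC4")[i0:i1], freq,
                                LasSetting.fast().linear(), rec.sample_rate)
        core = amp[900:-900]
        assert core.std() / core.mean() < 0.02

    def test_blocking_depth_visible(self):
        """2.5 dB blocking: fast-LAS amplitude in the blocking window sits
        below the surrounding level."""
        prof = s.SubjectProfile(noise_amp=0.0, alpha_amp=0.0, p300_amp=0.0)
        sess = s.simulate_session("bci", prof, rng_seed=5, n_runs=1,
                                  trials_per_class_per_run=1)
        rec = sess.recording
        freq = sess.config.stim_freq_left
        amp = lock_in_amplitude(rec.get("FC4"), freq,
                                LasSetting.fast().linear(), rec.sample_rate)
        raw = rec.get("FC4")
        pat = {p.pattern_id: p for p in sess.patterns}
        raw_db, las_db = [], []
        for tr in sess.schedule:
            if tr.class_label != "idle":
                continue
            for tw in tr.twitch_times(pat[tr.pattern_id], "left"):
                j = int(tw * rec.sample_rate)
                # construction: raw RMS inside the blocking window vs before
                rms_in = np.sqrt(np.mean(raw[j + 36:j + 114] ** 2))
                rms_out = np.sqrt(np.mean(raw[j - 240:j - 60] ** 2))
                raw_db.append(20 * np.log10(rms_out / rms_in))
                # readout: the fast LAS sees the dip, attenuated by its
                # low-pass smoothing of the 150 ms rectangular window
                inside = amp[j + int(0.07 * 600):j + int(0.18 * 600)].mean()
                before = amp[j - int(0.4 * 600):j - int(0.1 * 600)].mean()
                las_db.append(20 * np.log10(before / inside))
        assert np.median(raw_db) == pytest.approx(2.5, abs=0.2)
        assert np.median(las_db) > 1.0


class TestP300:
    def test_idle_trials_zero(self, patterns):
        sched = s.generate_bci_schedule(1, 2, patterns, rng_seed=6)
        idle = [t for t in sched if t.class_label == "idle"]
        frag = s.simulate_p300(idle, patterns, s.SubjectProfile(), rng_seed=0)
        assert np.all(frag == 0.0)

    def test_target_bump_in_window(self, patterns):
        sched = [t for t in s.generate_bci_schedule(1, 2, patterns, rng_seed=6)
                 if t.class_label == "focus_left"]
        prof = s.SubjectProfile()
        frag = s.simulate_p300(sched, patterns, prof, rng_seed=0)
        cz = frag[list(EEG_CHANNELS).index("Cz")]
        pat = {p.pattern_id: p for p in patterns}
        peaks = []
        for tr in sched:
            for tw in tr.twitch_times(pat[tr.pattern_id], "left"):
                j = int(tw * 600)
                seg = cz[j:j + 480]
                assert seg[int(0.30 * 600):int(0.40 * 600)].mean() > 0
                peaks.append(np.argmax(seg) / 600.0)
        # grand-average peak latency inside 300-400 ms
        assert 0.30 <= np.mean(peaks) <= 0.40


class TestSession:
    def test_linearity_of_composition(self, null_profile):
        """The session equals the sample-wise sum of its fragments."""
        sess = s.simulate_session("bci", rng_seed=12, n_runs=1,
                                  trials_per_class_per_run=2)
        root = np.random.SeedSequence(12)
        s_sched, s_pat, s_bg, s_sssep, s_p300, _, _ = root.spawn(7)
        n = sess.recording.n_samples
        end = n / 600.0
        labels = EEG_CHANNELS + EOG_CHANNELS
        total = s.simulate_background(end, sess.profile, s_bg, 600.0, labels)[:, :n]
        total += s.simulate_sssep(sess.schedule, sess.patterns, sess.profile,
                                  s_sssep, sess.config, 600.0, n, labels)
        total += s.simulate_p300(sess.schedule, sess.patterns, sess.profile,
                                 s_p300, 600.0, n, labels)
        assert np.allclose(total, sess.recording.data)

    def test_default_bci_counts(self, bci_session):
        ev = bci_session.recording.events
        assert ev[ev.event_type == "trial_start"].trial_id.nunique() == 60
        for hand in ("left", "right"):
            per_trial = ev[ev.event_type == f"twitch_{hand}"].groupby("trial_id").size()
            assert (per_trial == 7).all()

    def test_event_table_deterministic(self):
        a = s.simulate_session("bci", rng_seed=13, n_runs=1)
        b = s.simulate_session("bci", rng_seed=13, n_runs=1)
        pd.testing.assert_frame_equal(a.recording.events, b.recording.events)
        assert np.array_equal(a.recording.data, b.recording.data)


class TestIdealStimSignal:
    def test_no_twitch_constant_amplitude(self):
        sig = s.simulate_ideal_stim_signal(35.0, [], 10.0)
        amp = lock_in_amplitude(sig, 35.0, LasSetting.fast().linear(), 600.0)
        core = amp[1200:-1200]
        assert core.std() / core.mean() < 1e-3

    def test_twitch_zero_window(self):
        sig = s.simulate_ideal_stim_signal(35.0, [2.0], 10.0, sample_rate=4200.0)
        t = np.arange(len(sig)) / 4200.0
        onset = np.round(2.0 * 35) / 35
        assert np.all(sig[(t >= onset) & (t < onset + 1 / 35)] == 0.0)

    def test_fast_dips_standard_flat(self):
        """Twitch transients appear in the fast LAS setting but not in the
        standard setting (2 Hz bandwidth + 1 s moving average)."""
        onsets = [1.0, 2.2, 3.5, 4.6, 6.0, 7.2, 8.4]
        sig = s.simulate_ideal_stim_signal(35.0, onsets, 10.0)
        t = np.arange(len(sig)) / 600.0
        fast = lock_in_amplitude(sig, 35.0, LasSetting.fast().linear(), 600.0)
        steady = np.median(fast[(t > 0.5) & (t < 9.5)])
        for o in onsets:
            dip = (steady - fast[(t >= o) & (t < o + 0.1)].min()) / steady
            assert dip > 0.05, f"no dip after twitch at {o} s"
        std = lock_in_amplitude(sig, 35.0, LasSetting.standard().linear(), 600.0)
        level = np.median(std[(t > 2) & (t < 8)])
        dev = np.abs(std[(t > 1.5) & (t < 9)] - level).max() / level
        assert dev < 0.10
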