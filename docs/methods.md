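# Methods

This note documents the models and procedures implemented in `sssepbci`, the
assumptions behind the synthetic-EEG generator, and the numerical and design
choices a maintainer would want to know about.

## The paradigm being modeled

Both index fingers are stimulated simultaneously with amplitude-modulated
vibration: a 237 Hz sinusoidal carrier gated by a rectangular envelope at a
subject-specific stimulation frequency per hand (17–35 Hz in 2 Hz steps,
selected in a screening session). The repetitive stimulus entrains a
narrowband steady-state somatosensory evoked potential (SSSEP) at the
envelope frequency over the contralateral somatosensory cortex. Rare,
countable "twitches" — complete interruptions of the stimulation for exactly
one envelope period — are embedded in both streams so that users can focus
attention on one hand; attended twitches additionally evoke a P300-like
event-related deflection. A hybrid three-class BCI (focus left / focus right
/ idle) classifies SSSEP features and P300 features with separate shrinkage-
LDA classifiers, and a Monte-Carlo permutation test asks whether twitches
transiently attenuate ("block") the SSSEP itself.

## Stimulus and schedule generation

* **Duty cycle / phase-zero constraint.** The envelope on-burst holds
  `round(0.5 · f_carrier / f_stim)` full carrier cycles (minimum 1), and the
  carrier restarts at phase zero at each burst onset. This makes the realized
  duty cycle the closest value to 50% compatible with whole carrier cycles
  (e.g. 0.443 at 35 Hz). A consequence worth knowing: the waveform is
  periodic at the envelope frequency, so its spectrum lives on the envelope
  harmonic grid and the "carrier line" is the harmonic nearest 237 Hz.
* **Twitch patterns.** Per trial one of three pre-generated patterns is used.
  Onsets (7 per hand) are drawn uniformly over the focus window by rejection
  sampling until the pooled across-hand spacing is ≥ 250 ms (up to 10 000
  attempts, then an error). When stimulation frequencies are supplied, onsets
  are quantized to each hand's envelope-period grid so a twitch deletes
  exactly one period. The last admissible onset leaves room for the deleted
  period (one 17 Hz period when the frequency is unknown).
* **Schedules.** The BCI session is 8 runs × 10 trials/class, class order
  shuffled within run; reference periods are U(1, 1.5) s, focus periods
  U(9.5, 10) s, with stimulation from 0.2 s after trial start to trial end.
  The screening session is 8 runs × 10 trials × 10 intervals of 2.3 s; each
  of the 20 (frequency, finger) combinations appears exactly 5 times per run
  (40 per session), ordered by shuffling with local swap-repair so no
  combination repeats back-to-back within a run (runs are separated by
  breaks, so the constraint is not enforced across runs). All randomness
  flows from a session seed through per-trial child seeds
  (`numpy.random.SeedSequence`), so schedules and event tables are bit-exact
  reproducible.

## Synthetic EEG

The generator produces 29 EEG + 3 EOG channels at 600 Hz and is the test bed
for every downstream stage. It is a sum of independent parts (linearity is a
tested invariant):

* **Background**: per-channel 1/f^β noise (β = 1, std 5 μV, spectrum
  flattened below 0.5 Hz) plus an alpha-band sinusoid (8–12 Hz, 1 μV,
  random phase/frequency per channel).
* **SSSEP**: a sinusoid at each hand's stimulation frequency during
  stimulation, amplitude `base · tuning(f) · attention`, projected onto a
  strictly contralateral fronto-central channel map (peak weight on FC4 for
  the left hand, FC3 for the right). The tuning curve is a Gaussian over
  frequency peaking at 27 Hz (width 5 Hz); the attention gain (default 1.3)
  applies to the cued hand only. The base amplitude (2.5 μV) is a free
  parameter — no absolute SSSEP amplitude is available to match — chosen so
  that screening maps and the blocking test operate at realistic
  signal-to-noise (relative band-power increases of a few hundred percent at
  the tuning peak).
* **Blocking**: after each twitch, that hand's SSSEP amplitude is multiplied
  by `10^(−depth/20)` (default 2.5 dB) inside a rectangular 50–200 ms
  post-onset window. The rectangular shape is the simplest testable choice;
  time–frequency resolution limits prevent characterizing the real shape.
* **P300**: a raised-cosine positive bump (3 μV, peak 350 ms, width 300 ms)
  after each attended twitch, on a centro-parietal map peaking at Cz.
  Non-target twitches evoke nothing by default (`p300_nontarget_amp`
  reproduces the attention-capture confound when wanted).
* Optional extras: threshold-exceeding artifact spikes on random trials, and
  blink-like EOG activity with frontal leakage.

What the generator does **not** emulate: volume conduction and inter-channel
noise correlation, realistic multi-component ERP morphology, overlapping-ERP
effects of closely spaced twitches, non-stationary rhythms, trigger loss.
Passing recovery tests therefore demonstrates correctness of the analysis
chain under the assumed signal structure, not performance on real EEG.

## Preprocessing

Zero-phase acquisition filters (0.5–200 Hz 4th-order Butterworth band-pass,
50 Hz notch, Q = 35); bipolar derivation (anode − cathode) of a 13-pair
fronto-central→centro-parietal grid whose 7-pair FC→CP row is the screening
subset (only FC3-CP3/FC4-CP4 and the monopolar Fz/Cz/Pz are pinned by the
montage description; the remaining pairs are a declared approximation);
EOG removal by multichannel least-squares regression estimated on a
calibration segment — the stationary special case of the adaptive
autoregressive method the paradigm calls for; and threshold rejection
(strictly greater than 90 μV monopolar / 60 μV bipolar) applied to the SSSEP
and blocking streams only — the P300 stream uses all trials. Trial slices
are padded 1 s past trial end (into the feedback pause) so 800 ms epochs of
late twitches remain usable.

## Lock-in amplitude (LAS)

Quadrature demodulation: multiply by unit sine/cosine at the stimulation
frequency, low-pass each product with a 4th-order zero-phase Butterworth at
half the configured bandwidth ("bandwidth" is the total two-sided width of
the equivalent band-pass), amplitude `2·√(I²+Q²)` so a unit sinusoid reads 1,
then an optional 1 s moving average and log10. The standard setting
(2 Hz bandwidth + MAV) estimates mean SSSEP strength over 1–8.5 s after cue
onset (13 channels × 2 frequencies = 26 features); the fast setting
(4 Hz, no MAV) trades selectivity for settling time and drives the blocking
analysis. Amplitudes are floored at 1e-9 μV before the log so silent inputs
give finite, constant features.

A physical bound worth stating: a single deleted envelope period removes a
fixed signal area, so the readout dip depth is ≈ (1/f_stim)·max|h| for the
demodulation low-pass impulse response h. With the 2 Hz cutoff needed for
the documented out-of-band rejection (a 5 Hz-offset tone attenuated below
10%), the dip from one 35 Hz period is ~11% of the steady level — clearly
visible, but no linear low-pass can make it ≥30% while keeping that
rejection; the sharper the filter, the shallower the dip.

Blocking features are the fast-setting log amplitudes epoched 0–400 ms after
each twitch of a finger, averaged over the 7 twitches, and by default also
averaged over time (26 features); a `time_points` option block-averages the
epoch into a retained time axis instead, for combined-feature classification
where the temporal profile of the attenuation carries information.

Spectrograms use a 4096-point FFT with Gaussian windows (σ = window/6):
3 s / 2.95 s overlap for steady-state views, 1 s / 0.95 s for transients;
PSDs are averaged per twitch pattern after aligning trials to trial start or
to the first twitch, in dB re 1 μV²/Hz.

## P300 features

10 monopolar channels, 3rd-order 10 Hz zero-phase Butterworth low-pass,
epochs [0, 800) ms after each twitch onset, per-epoch linear detrend,
average across the hand's twitches, block-mean decimation ×10 → 48 samples ×
10 channels × 2 hands = 960 features. The averages-vs-accuracy analysis
subsamples n ∈ 1..7 epochs per hand/trial (degenerate at n = 7, recorded
once) and repeats cross-validation per subsample.

## Classification

One-vs-all linear discriminants sharing a pooled within-class covariance
shrunk toward its diagonal with the analytic (Schäfer–Strimmer) intensity
λ* = Σ_{i≠j} Var(s_ij) / Σ_{i≠j} s_ij², clipped to [0, 1]; class residuals
are treated as zero-mean when pooling. Scores map to probabilities by
softmax (a design choice: it is monotone in the scores and yields the
0–100% certainty scale that fusion needs). Fusion takes each
classifier's (class, max probability); the higher probability wins if it
reaches 50%, otherwise no decision; exact ties go to the first (SSSEP)
classifier. Performance is 10×10 stratified cross-validation (stratification
is a declared choice), and significance is judged against the real chance
level: the smallest k with P(Binomial(n, 1/3) ≥ k) < α, as a percentage —
40.8% for n = 240, α = 1%.

## Blocking permutation test

Null hypothesis: twitch-pattern labels are exchangeable across trials. The
statistic is the mean pre-log fast-LAS amplitude over all trials × twitches
in a 50 ms half-open window at lag τ from the onsets implied by the (real or
permuted) assignment; the linear amplitude is used because the hypothesis
concerns the amplitude itself, not the log feature. The null distribution is
the observed value plus N shuffles of the per-trial label vector (preserving
pattern counts); FPP = #(null ≤ observed)/(N+1) ≥ 1/(N+1). The scan covers
lags −500..+450 ms in 20 non-overlapping windows on FC3-CP3 and FC4-CP4 with
the finger-matched frequency convention (left twitches → left stimulation
frequency), Bonferroni-corrected over windows × fingers × channels
(α/80 = 1.25e-4 at α = 1%); adjacent significant windows merge into reported
intervals. Permutations are shared across cells within a scan (valid for
Bonferroni, and an order of magnitude cheaper); per-(trial, pattern, lag)
window means are precomputed so each permutation is a gather.
Note N must exceed 8000 for the corrected threshold to be attainable at all;
at the full N = 100 000 the floor is ~1e-5.

## Problem sizes in the test suite

The recovery and calibration tests run on sessions scaled to desk size:
60-trial sessions (20 seeds, N = 10 000) for blocking recovery; 30-trial
sessions (50 seeds, N = 2000) for the null-scan calibration; one 240-trial
session with 100 label permutations of 10×10 CV for the classifier null; a
120-trial session with 5 subsampling repeats and 3×10 CV per n for the
averages analysis. These sizes are the package's own choices for routine
runs; all analysis code takes the full-size parameters as plain arguments.

## Known limitations

* The EOG stage is stationary regression, not the adaptive AR original.
* The exact 13-pair/10-channel montage is only partially pinned by its
  source description; the shipped default is symmetric and configurable.
* The screening band power uses variance of the band-passed signal (a
  design choice among equivalent narrowband power estimators); frequency
  selection codifies a rule
  ("highest and most similar responses, ≥ 4 Hz apart") that was originally a
  manual judgement.
* Online operation (causal filtering, incremental classifier updates,
  feedback presentation) is out of scope; all analyses are offline.
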