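# Methods

`assrkit` quantifies the 40 Hz auditory steady-state response (ASSR) as it is
measured by three sensor technologies — scalp EEG, on-scalp optically pumped
magnetometers (OPM) and cryogenic SQUID gradiometers — and provides the full
analysis chain used to compare them: a synthetic session generator,
preprocessing, a canonical-correlation spatial filter, spectral SNR and
inter-trial phase-coherence (ITPC) statistics over trial counts, and
repeated-measures inference. This note documents the models, the defaults and
the reasoning behind the choices that were genuinely open.

## Paradigm and data model

A session contains 108 amplitude-modulated 1 s tones: 100 at a 40 Hz
modulation rate plus 4 each at 20 and 60 Hz (rare task trials that the ASSR
pipeline excludes), in random order with a uniformly jittered 1.3–1.7 s
inter-trial interval. The 1 kHz carrier is never synthesized: it lies far
above every analysis band, so only the modulation-rate response matters.
Epochs span −1 to +3 s around tone onset (half-open at the right edge, giving
exactly 4 × f_s samples).

## Synthetic session generator (`synthgen`)

The generator is a parametric model of the statistical structure the pipeline
assumes, not a biophysical head model. Per trial the source waveform is

* a damped onset transient (10 Hz, amplitude 2× the steady state, τ = 80 ms),
* a 40 Hz steady-state sinusoid over 0–1 s, phase-locked to onset up to a
  Gaussian trial-phase jitter (default SD 0.3 rad), with 50 ms on/off ramps.

The source is projected to sensors through a fixed per-modality mixing
pattern: a bilateral dipolar profile over the temporal sensor clusters
(sign-flipping across each cluster; for dual-axis OPMs the second axis sees
the same field at 0.6 gain with a mid-cluster profile), and for EEG a broad,
spatially smeared fronto-central topography. Channel layouts carry nominal
position tags (`temporal_left`, `frontocentral`, `eog`, …) that downstream
subset selection matches on.

Noise has four seeded components: (i) white sensor noise with a configurable
one-sided amplitude spectral density (ASD), calibrated so a periodogram of
the output reproduces the configured value; (ii) a 1/f background mixed
through 24 random spatial patterns (smoothed across channels for EEG to mimic
volume conduction), anchored by its ASD at 10 Hz; (iii) a 50 Hz line
component; (iv) artifacts — blinks with a fast-rise/slow-decay template
(~50 ms rise, 0.35 s total, frontal/EOG-weighted) and 0.3 s muscle bursts
band-limited to 110–140 Hz on random channel subsets. Generation is a pure
function of (config, seed); injected artifacts are logged with ground-truth
sample indices so detector tests have an oracle.

Default modality presets (chosen once; amplitudes at the peak channel):

| preset                  | EEG          | OPM          | SQUID       |
|-------------------------|--------------|--------------|-------------|
| channels                | 56 + EOG     | 2 × 10 sites | 124         |
| native rate (Hz)        | 500          | 4000         | 4000        |
| evoked peak             | 0.6 µV       | 100 fT (2.5×)| 40 fT       |
| white noise ASD         | 1.0 µV/√Hz   | 20 fT/√Hz    | 2.5 fT/√Hz  |
| 1/f background @ 10 Hz  | 2.5 µV/√Hz   | 75 fT/√Hz    | 120 fT/√Hz  |

The OPM evoked amplitude is the SQUID value times a proximity factor
(default 2.5, configurable 2–3). The background deliberately does **not**
scale with that factor: it aggregates distant sources and room noise, and the
SQUID session is modeled with a higher background because it takes place in a
separate, less heavily shielded room. These two choices are what make the
modality ordering OPM > SQUID > EEG hold by construction, both for the best
single channel and after spatial filtering. What the generator does *not*
emulate: realistic head geometry and channel covariance, inter-individual
topography differences, heartbeat and eye-movement artifacts, movement
through background gradients, or amplitude nonstationarity across a session —
so passing tests demonstrate the pipeline's estimator properties under the
assumed structure, not performance on real recordings.

A closed-form helper estimates the magnetic interference of an EEG electrode
cable at a co-located OPM cell, B = µ0·I/(2πr) with I = U/R; with worst-case
constants (U = 100 µV, R = 1 GΩ, r = 5 mm) the field is ~4×10⁻¹⁸ T, orders of
magnitude below OPM noise floors.

## Preprocessing (`preprocess`)

Fixed stage order: epoch → muscle screen → resample to 500 Hz → average
re-reference (EEG only; EOG/earlobe excluded from the mean) → 49–51 Hz notch
→ variance screen → drop flagged trials/channels → ICA cleanup → 5–60 Hz
band-pass. The 110–140 Hz muscle screen must precede downsampling (its band
would exceed the post-resampling Nyquist), which pins the order. All filters
are zero-phase 4th-order Butterworth IIR run forward-reverse
(`sosfiltfilt`); resampling is polyphase with built-in anti-aliasing.

Screening replaces visual inspection with thresholded robust statistics:
per-trial RMS of a 110–140 Hz pseudo-dataset and per-trial/per-channel
variance of a 0.5–80 Hz pseudo-dataset, flagged at robust z > 4
(median/1.4826·MAD); channels below 10⁻⁶× the median variance are flat. EOG
channels are exempt from channel screening — large ocular deflections are
their job. On default simulated sessions this removes a handful to a few
dozen trials, the same order as typical real sessions.

ICA (FastICA, scikit-learn) is fitted on a 5–40 Hz pseudo-dataset with up to
20 components (at least 16 channels required). Components are removed when
(a) their activation correlates with the EOG channel at |r| > 0.7 in a
1–10 Hz ocular band of the unrestricted data — blinks carry most variance
below the pseudo-dataset's 5 Hz edge, so the correlation is evaluated there,
as labs do — or (b) their mixing topography loads on frontal/EOG channels
more than 3× the remaining channels. Flagged components are subtracted as
their activation × mixing contribution, leaving variance outside the ICA
subspace untouched.

## Spatial filter (`spatialfilter`)

Channel weights maximize the covariance between band-limited (39–41 Hz)
single trials and the band-limited trial average within 0.25–1 s: a canonical
correlation with X = channels × (time·trials) single-trial data and Y = the
time-locked average tiled per trial; only the first canonical pair is used.
The solution comes from the symmetric generalized eigenvalue form with a
ridge term (default 10⁻⁶ × mean covariance trace) on both channel
covariances, needed e.g. for rank-deficient average-referenced EEG. Weights
are unit-norm; the filter is applied to the full 5–60 Hz data, not the fit
band. A brute-force maximizer over the unit sphere serves as the test oracle.

Because the canonical weights are sign-blind, polarity is fixed against an
extrema template built from the plain grand average over participants and
channels (no spatial filter): local extrema within 0–1 s by first-difference
sign change (flat runs backward-filled so an extremum falling exactly between
samples is kept), with same-type extrema closer than one 40 Hz cycle (25 ms,
half-sample tolerance) merged keeping the larger deviation. If the
individual's virtual-channel average is higher at template minima than
maxima, the series is multiplied by −1. The rule is idempotent; a diagnostic
plot hook replaces per-participant manual confirmation.

Sensor-subset comparisons use 10 positions per modality: the 5 + 5
temporal-tagged sites for OPM/SQUID (both OPM axes of a selected site are
retained, so 10 sites = 20 channels), and for EEG the 10 electrodes with the
highest group-average 40 Hz amplitude. The filter is fitted once on all
retained trials and then evaluated per trial-count bin (fitting per bin is
possible but not the default).

## Spectral metrics (`spectral`)

Power of the trial average: average the selected trials first, then a sliding
Hanning taper whose duration is 7 cycles of the analysis frequency (rounded
to an odd sample count), on a 1–60 Hz × 0.25–1 s grid (0.5 Hz / 50 ms steps).
ITPC: per-trial complex coefficients from a Gaussian (Morlet-family) wavelet
with σ_t = 7/(2πf), truncated at ±3σ_t, on a 1–60 Hz (0.1 Hz) × −1…2 s
(0.25 s) grid; ITPC(f,t) is the magnitude of the across-trial mean unit
phasor. Cells whose window does not fit inside the epoch are NaN, never
imputed (this invalidates f ≲ 2 Hz; the ≥ 20 Hz noise bands are unaffected).

SNR = power(40 Hz) / mean power over 20–38 ∪ 42–48 Hz, after averaging each
over the valid time points (the SNR of time-means, a deliberate choice).
ITPC-ratio = ITPC(40 Hz) / mean ITPC over 20–30 Hz at the stimulation-phase
grid points {0.25, 0.5, 0.75, 1.0} s; the noise band stops at 30 Hz to keep
spectral smearing of the signal out of the denominator, and no symmetric
upper band is used.

A property worth knowing: with a 7-cycle taper the 40 Hz component leaks
substantially into bins up to ~±8 Hz away (closed form: relative power 0.85
at ±2 Hz, 0.25 at ±5 Hz), so the noise-band mean contains ~0.2 of the signal
power and the SNR has an intrinsic ceiling of ≈ 4.7 regardless of noise
level. High-amplitude modalities compress against this ceiling; differences
between them appear mainly at low trial counts and in the ITPC-ratio, whose
20–30 Hz noise band is leakage-free.

Trial-count curves evaluate each metric on the first k retained trials in
chronological order, k ∈ {1, 10, 20, …, 80} (ITPC from k = 10; it is
undefined for one trial). Percent increases between modalities are
(V₁ − V₂)/V_ref × 100 with the comparison value as the default reference —
the scale on which multi-hundred-percent increases are expressed — and the
literal first-value normalization available via `baseline="mod1"`.

## Statistics (`stats`)

Two-factor fully-within ANOVA (e.g. modality × trial count) with each effect
tested against its own effect-by-subject interaction; η²p = SS_effect /
(SS_effect + SS_residual), which identically equals F·df₁/(F·df₁ + df₂).
Sphericity per effect via Mauchly's W on the orthonormal contrast space
(Helmert contrasts; Kronecker products for the interaction) with the
chi-square approximation; when Mauchly rejects at α = 0.05 (configurable) the
effect's dfs are multiplied by the Greenhouse-Geisser ε̂ = (Σλ)²/(d·Σλ²) of
the contrast-space covariance eigenvalues, clamped to [1/d, 1]. Corrected
dfs preserve the df_residual/df_effect = n − 1 pattern. A caveat verified
numerically: the common claim that GG correction never increases
significance holds throughout the decision-relevant region (uncorrected
p ≤ 0.1) but can fail marginally for clearly null effects (F < 1), where
shrinking both dfs may lower p without affecting any decision.

Tukey HSD post hocs use the studentized-range distribution with the
within-subject residual mean square of the relevant effect as the error term
(the convention is not uniquely determined in a repeated-measures context;
for two levels it reduces exactly to the paired t-test). Pairwise modality
contrasts are separate 2 × trial-count ANOVAs plus per-bin paired-t
significance flags for plotting.

Calibration, verified by simulation: under exchangeable nulls both the ANOVA
(n = 15) and Mauchly's test (n = 100, k = 3) reject at ~5% (within 2–10%
over 500 simulations).

## Study orchestration (`pipeline`)

`run_study` executes all stages per participant × modality with
deterministically derived per-participant seeds, in two passes: the first
preprocesses every session and accumulates the cross-participant grand
average (polarity template) and the EEG 40 Hz topography (electrode subset);
the second fits the filter per participant/modality/channel-set and computes
both metrics' trial-count curves, for the 10-position subset and (optionally)
the whole array. Participants with fewer retained trials than
max(min_retained_trials, largest bin) in any modality are excluded from group
curves and ANOVAs, mirroring a ≥ 70-retained-trials inclusion rule with bins
up to 80. Outputs are CSV tables, JSON statistics, an optional group-curve
figure, and a manifest (config, seeds, retained-trial counts, exclusions)
sufficient for bit-identical re-runs.

### Problem sizes

`SimulationConfig` defaults are the full study conditions (56 + EOG EEG
channels, 124 SQUID gradiometers, 10–16 dual-axis OPMs, 4 kHz native MEG
rates, 23 participants). The package's own demo/acceptance study
(`demo_study_config`) runs 8 participants with 28 + EOG EEG channels, 40
SQUID channels, 10 OPM sites and a 500 Hz native rate — which keeps the
110–140 Hz muscle band below Nyquist while making a full multi-modality
study a minutes-scale computation. Group-level numbers from the demo study
are qualitative (direction and rough magnitude), not calibrated to any real
recording; the acceptance script reports them together with the problem
sizes used.

## Known limitations

* The generator's evoked morphology, phase-jitter model, artifact templates
  and 1/f slope are inventions with documented defaults; none are calibrated
  to a real figure or dataset.
* Channel "positions" are nominal tags, not geometry; topographic matching
  between arrays is by tag, and EEG smearing is a wide mixing kernel, not a
  conductor model.
* The SNR definition's leakage ceiling (above) limits contrast between
  high-SNR modalities at large trial counts.
* BrainVision/EDF reading is delegated to `mne` when present; EDF export is
  not provided.
* No baseline-period analysis, no source localization, no single-best-sensor
  comparison beyond the diagnostic in the test suite.
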