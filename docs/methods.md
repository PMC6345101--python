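# Methods

## Signal model and analysis chain

The pipeline targets monopolar cortical EEG sampled at 1,024 Hz with
channels named by cortical site and hemisphere (`Pf-r`, `Pp-l`, …). State
scoring arrives as ordered 10-s epochs (AW, QW, NREM, REM, or a ketamine
dose K5/K10/K15) plus point events (stimuli, injections, artifact bounds).
Per state, twelve artifact-free 100-s windows (1,200 s total) are selected
inside contiguous same-state runs; windows may abut but never overlap, never
intersect artifact intervals, and — when stimulus-clear windows are required,
as for the ketamine analysis — keep a 300-s guard on both sides of every
sound/visual event. Eligible placements are sampled uniformly: window
counts are allocated across eligible intervals with probability proportional
to remaining capacity, and positions within an interval use the
sorted-uniform-gaps construction, so selection is exactly reproducible from
the generator state.

Coherence between two channels over one window is the Welch
magnitude-squared coherence on 2,048-sample Hann blocks with 50% overlap
(0.5 Hz grid; a 100-s window yields 99 overlapping blocks, matching the
nominal "100 blocks per window" configuration). Bins where either channel
has zero power are assigned MSC 0. For averaging and parametric statistics
the coherence magnitude is variance-stabilized,

    z' = atanh( sqrt(MSC) ),

the standard Fisher transform of the coherence magnitude; it is
non-negative, strictly increasing, and diverges as MSC → 1, so inputs are
clipped at 1 − 1e-12 with a warning. (`z_transform_alt` provides the
`atanh(MSC)` convention for comparison; all shipped summaries use the
magnitude form.) Band summaries average z′ over grid frequencies with
30 ≤ f ≤ 45 inclusive (31 points). Coherograms apply the same estimator on
a sliding 100-s segment with a 10-s step, stamped at segment centers.

Band power uses the same Welch configuration with density scaling;
"gamma power" in tables is the PSD integrated over the band (μV²).
Time-frequency maps come in two flavors: a multitaper spectrogram (2-s
windows, 0.5-s step, time-bandwidth 3, 5 Slepian tapers — eigenspectrum
averaging cuts single-taper variance roughly by the taper count) and a
complex-Morlet map (7 cycles per frequency, via mne) when time localization
of individual bursts matters.

## Surrogate null

The channel-shuffle surrogate cuts the second channel into non-overlapping
2,048-sample blocks, permutes their order, and re-estimates the band z′
against the intact first channel. Because the block-averaged periodogram is
a function of the block multiset only, the shuffled channel's Welch PSD
(non-overlap convention) is *exactly* invariant, while any true
cross-channel alignment is destroyed — so the null distribution isolates
coupling from spectral content. Non-overlapping blocks are used here even
though the estimator default is 50% overlap, precisely to keep that
invariance exact; the invariance diagnostic sums periodograms in value
order so the identity holds to the last bit in floating point.

## Burst analysis

Gamma bursts are detected on the 30–45 Hz envelope (analytic-signal
magnitude by default; rectify-and-50-ms-smooth as an alternative) as maximal
runs above mean + 2 SD lasting ≥ 100 ms; threshold statistics are computed
over the analyzed window. The detection rule is an explicit stand-in for
by-eye selection, and both knobs are configurable. The trigger is the
extremum of the band-passed trace within the run. Triggered averages align
up to 100 randomly chosen bursts at their triggers with the trigger extremum
made positive, over trigger ± 0.25 s; averaging may be done on the
band-passed trace or on a wider-band (e.g. 3 Hz high-pass) trace.

Filtering is a windowed-sinc (Hamming) FIR with a 4 Hz transition band,
−6 dB at the band edges, >50 dB stopband 10 Hz outside the band and <0.2%
passband ripple. The symmetric filter is applied in a single FFT
convolution pass with the integer group delay compensated; for a
linear-phase FIR this is zero-phase (verified by burst-lag tests), which
matters because cross-channel comparisons must not introduce differential
delay.

## Synthetic generator

Per state, each channel is a sum of

- **gamma bursts**: Hann-enveloped sinusoids, duration uniform in
  200–500 ms, carrier uniform in 35–40 Hz, random phase, peak amplitude at
  the state's `burst_amp` (with optional per-copy scatter). A Poisson
  stream of rate `burst_rate × coupling_fraction` is *shared* — one source
  copied to every channel with independent timing jitter — and the
  remaining rate is drawn independently per channel;
- **band-limited Gaussian background** components synthesized in the
  frequency domain and normalized to their specified variance per segment
  (exact realized in-band power, which keeps the coherence oracle tight);
- state extras: NREM/ketamine slow waves (0.5–4 Hz, variance `amp²/2`), a
  ketamine beta peak (±2 Hz band around 20 Hz) and elevated 45–60 Hz
  content scaled to the in-band burst power.

Because shared and independent bursts are spectrally identical, the
two-channel model has closed-form band coherence
`MSC = (S/(S+N))²` with `S = coupling × P_burst` and
`N = (1−coupling) × P_burst + P_background(band)`, where
`P_burst = rate × (3/16) × amp² × mean_duration` (Hann² × sin² power
fraction = 3/16). The formula assumes zero jitter and scatter and is an
upper bound otherwise: uniform jitter on ±j seconds multiplies the
cross-spectral amplitude by sinc(2πfj) per channel
(`jitter_attenuation`). The default jitter is ±2 ms — enough to avoid the
unphysiological perfect alignment that would make coherence trivially 1,
while attenuating band MSC by only ~14%. Larger jitters are configurable
but quickly destructive: at a 37.5 Hz carrier, ±10 ms randomizes phase by
±2.4 rad and collapses even fully coupled channels to near-zero coherence,
which no longer resembles coupled cortical gamma.

### State presets

No quantitative per-state burst rate is established for this preparation,
so rates and amplitudes are free parameters chosen once to reproduce the
qualitative state contrast; couplings encode the headline result.

| state | rate (/s) | amp (μV) | coupling | extras |
|-------|-----------|----------|----------|--------|
| AW    | 2.0       | 25       | 0.80     | — |
| QW    | 1.2       | 18       | 0.45     | — |
| NREM  | 0.8       | 15       | 0.35     | slow waves 150 μV |
| REM   | 1.2       | 18       | 0.05     | — |
| K5    | 1.2       | 18       | 0.30     | slow waves, beta, high gamma |
| K10   | 1.2       | 18       | 0.15     | slow waves, beta, high gamma |
| K15   | 1.2       | 18       | 0.05     | slow waves, beta, high gamma |

These give expected band MSC ≈ 0.51 (AW), 0.12 (QW), 0.05 (NREM), ~0.001
(REM ≈ K15), i.e. in-band power comparable across QW/REM/K15, maximal in
AW, minimal in NREM, with coherence ordered AW > QW > NREM > REM ≈ K15 and
a monotone dose–response K5 > K10 > K15. The ketamine states are parameter
presets, not a pharmacokinetic model.

## Statistics

Within a subject, states are compared by classical one-way ANOVA
(F = MS_between/MS_within, df = (k−1, N−k)) over the per-window band z′
replicates, with Tamhane T2 post-hoc: Welch t per pair,
Welch–Satterthwaite df, Sidák-style familywise adjustment
`1 − (1−p)^m` over the m pairs (T2 is the variant assumed where only
"Tamhane" is specified). Across subjects, a one-way repeated-measures
ANOVA blocks on subject, df = (c−1, (c−1)(s−1)), uncorrected for sphericity
by default, with Bonferroni-adjusted paired t post-hocs. Reported group
analyses of this design are sometimes published with a pooled error df
(c−1, N−c); `rm_anova` reports the blocked convention as primary and the
pooled one in `extras["df_pooled"]` without asserting either as canonical.

## Numerical conventions and edge cases

- MSC of a zero-power bin is 0; self-coherence is 1 to machine precision.
- MSC with a single block is degenerate (identically 1) and rejected.
- z′ inputs ≥ 1 − 1e-12 are clipped with a warning.
- Degenerate ANOVA inputs (zero total variance) return a flagged NaN F;
  zero-variance Tamhane pairs resolve by the exact tie.
- EDF is written as 16-bit with per-channel symmetric physical range
  (round-trip error ≤ range/2¹⁶); non-integer-second recordings are
  zero-padded to whole 1-s records with a warning.
- Annotation epochs are fixed at 10 s; a trailing shorter epoch is
  tolerated on load.

## Problem sizes

Tests and the acceptance script run at the study's stated scale where it is
cheap (twelve 100-s windows per state at 1,024 Hz; 10,000 null simulations
for ANOVA calibration; 200-permutation surrogates) and at reduced scale
elsewhere (e.g. 300–600 s records for coupling recovery, 20–50 Monte-Carlo
seeds for estimator-bias checks), sizes chosen so Monte-Carlo error is
small against each tolerance.

## Limitations

The generator is a phenomenological mixture, not a cortical model: real EEG
has continuous 1/f background, within-state nonstationarity, volume
conduction and reference effects (which inflate coherence without genuine
coupling), movement/EMG/ECG artifacts, and state transitions that are not
step functions. Passing the recovery tests therefore demonstrates that the
estimators and pipeline are correct and unbiased under the stated mixing
model — not that real recordings would be artifact-free or that reference
choices are innocuous. Artifact handling is annotation-driven (an optional
±500 μV amplitude pre-flagger is off by default); no sleep scoring, ICA, or
high-gamma/HFO analysis is included.
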