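# Methods

This note documents the models, numerical choices and limitations behind
`neoegg`. It is written for someone who wants to trust (or challenge) the
numbers the pipeline produces.

## Signal model and preprocessing

The raw input is a single-channel cutaneous EGG voltage series in µV.
Gastric slow-wave content lives below 9 cpm = 0.15 Hz, so the whole
analysis band is more than four orders of magnitude below a 2000-Hz
acquisition rate. Preprocessing is a fixed four-step chain:

1. **Decimation** by keeping every k-th sample (default ×4, 2000 → 500 Hz).
   No anti-alias filter is applied; this is a deliberate fidelity-over-
   hygiene choice. Any content aliased from above 250 Hz is broadband
   instrument noise, which the subsequent 1-Hz low-pass and the 0.15-Hz
   analysis ceiling render negligible.
2. **Cubic detrend** fitted by least squares over the *entire* recording,
   before any segmentation. The abscissa is rescaled to [−1, 1]: a
   multi-hour series expressed in seconds makes the order-3 Vandermonde
   system badly conditioned, and the rescaling removes that without
   changing the fitted trend. `order=0` degenerates to mean removal.
3. **Trend subtraction.**
4. **Zero-phase low-pass** at 1 Hz. The filter family is a 3rd-order
   Butterworth applied forward-backward (effective order 6, exactly zero
   phase). Phase fidelity matters because the percent-time partition is a
   per-minute labelling: a phase-shifting filter would displace rhythm
   transitions in time.

Idempotence of the detrend and the zero-lag property of the filters are
asserted by tests.

## Sub-feeding segmentation

A session brackets two enteral feeds. The During windows equal the actual
administration intervals. Pre-feed 1 is the 30 min before feed 1 and
post-feed 2 the 30 min after feed 2, truncated at the recording edges. The
inter-feed gap is split at its midpoint into a post-feed-1 half and a
pre-feed-2 half. When the gap exceeds 60 min the two readings of
"half, nominally 30 min" diverge; the default (`halves_mode='capped'`)
caps each window at the 30 min adjacent to its feed boundary, preserving
the nominal duration, and `'full'` keeps the complete halves. Windows
shorter than 30 min are kept and flagged `truncated`. All intervals are
half-open minutes; boundaries map to sample indices by flooring, so a
30-min window at 500 Hz is exactly 900 000 samples.

## Welch band means (mPSD)

Each window's PSD is estimated with Hamming-tapered 4-min segments and
2-min overlap, one-sided density scaling, giving a 1/240 s ≈ 0.004-Hz
grid — about six bins inside bradygastria, eight in normogastria and
twenty in tachygastria. Per-segment detrending is off by default because
the global cubic detrend has already run (a switch exists).

`mPSD_GR` is the **arithmetic mean of the density over the bins** whose
centres fall in the band (half-open `[lo, hi)`), not the integral: an
average density keeps the unit µV²/Hz and makes bands of different widths
comparable. The bin-count-weighted mean of the three band means therefore
equals the mean over the whole 0.5–9 cpm range — a conservation identity
the tests assert.

Windows shorter than one Welch segment are estimated with a single
full-length segment (degraded resolution) and a warning; a 125-s floor
guarantees at least one bradygastria bin. Phase values (pre/during/post)
are unweighted means of the two same-phase windows; a missing window
requires an explicit `allow_single` opt-in and is flagged.

## Wavelet partition and percent time in band

The non-stationary rhythm is tracked with an analytic CWT computed in the
frequency domain on a log-spaced grid (12 voices/octave over 0.5–15 cpm).
Two families are provided: analytic Morlet (ω₀ = 6) and generalized Morse
(γ = 3, β = 20, time-bandwidth product 60). Responses are L1-normalised
(peak 2), so a unit tone yields |coefficient| ≈ 1 at every frequency and
band power ratios are comparable across the grid.

Before the transform the signal is band-passed to 0.5–15 cpm with a
zero-phase 3rd-order Butterworth and resampled to a 4-Hz analysis rate:
the content ceiling is 0.25 Hz, so 4 Hz is still 8× oversampled while
making repeated cohort transforms cheap. On test tones the band ratios at
4 Hz differ from full-rate results by well under 1%.

**Cone of influence.** Coefficients within one e-folding time of the
wavelet's temporal envelope from either segment edge are flagged and
excluded from every average (numerator and denominator alike). The
e-folding time is measured numerically from each family's time-domain
envelope — for the Morlet it equals the closed form √2·ω₀/2π ≈ 1.35
periods of the analysed frequency, and the same numerical rule covers the
Morse family. At 0.5 cpm the cone spans ~2.7 min per edge.

**Minute labelling.** For each whole minute and band, the mean non-COI
power over (band rows × minute columns) is divided by the same-minute mean
over the full 0.5–9 cpm range; the dominant band is the largest ratio.
Because the denominator is shared, using a mean rather than a sum cannot
change the ordering. Ties break toward the lower-frequency band
(deterministic; probability zero on real signals). A minute with no valid
cells at all is `unclassified`; partial trailing minutes are dropped.
Note that near segment edges the low-frequency rows enter the cone first,
so an edge minute may be labelled from its higher bands only — recovery
metrics in the tests are therefore computed over fully-COI-free minutes.

`%T_GR = 100 · (dominant-minute count) / denominator`. The default
denominator is all whole minutes in the window; `'classified'` uses only
labelled minutes, in which case the three percentages sum to exactly 100.
Phase averages are unweighted means of the two same-phase windows.

## Cohort statistics

Features are assembled into a tidy table (subject × phase × band ×
feature). Within each GA group, band and feature, a one-way ANOVA
compares the three phases, followed by Tukey's HSD for the three phase
pairs; each feature is also regressed on gestational age (OLS; slope,
intercept, r², two-sided slope p). α = 0.05 throughout; no correction
beyond Tukey's is applied by default (a Benjamini–Hochberg helper exists).
When a subject contributes several sessions they should be averaged per
phase before regression to avoid pseudo-replication; the pipeline analyses
one session per subject.

## The synthetic cohort

No public neonatal EGG dataset exists, so the test bed is simulated with
exact ground truth:

- **Rhythm process**: a three-state Markov chain over the bands, quantised
  to whole minutes so true minute labels are unambiguous. Transitions keep
  the current state with probability 1 − 1/d (nominal mean dwell d = 4 min)
  and otherwise redraw from the stationary distribution, which therefore
  equals the configured occupancy exactly.
- **Waveform**: a single sinusoid for the active band, frequency drawn
  uniformly within the band per dwell, phase-continuous across switches.
  This is deliberately *not* a mechanistic interstitial-cell model; one
  tone per minute is what makes the ground-truth label well defined.
- **Amplitudes**: 60/80/40 µV for brady/normo/tachy. Neonatal EGG
  amplitude is not well standardised; these are plausible placeholders,
  fully configurable, and nothing downstream depends on their absolute
  scale.
- **Maturation trends** (the recoverable ground truth): normogastria
  occupancy rises with GA — group anchors (brady, normo, tachy) =
  (0.45, 0.25, 0.30) early, (0.33, 0.45, 0.22) mid, (0.16, 0.70, 0.14)
  term, interpolated continuously in GA and renormalised — and a
  during-feed amplitude gain 1 + 0.05·(GA − 24 wk).
- **Noise and artifacts**: 20 µV broadband Gaussian noise plus 2–5-s
  Hann-shaped 300-µV low-frequency bursts at 4/h. Artifacts are never
  removed downstream (mirroring bedside practice), so the Welch averaging
  must tolerate them.
- **Cohort design**: 25 early (< 29 wk), 22 mid (29–33 wk), 4 term
  (≥ 37 wk); the 34–36.9-wk range is never generated. GA is uniform
  within each group's range.

What the simulator does **not** emulate: respiratory and cardiac
interference, electrode drift and impedance changes, multi-channel
geometry, harmonics or waveform asymmetry of real slow waves, and
within-subject longitudinal correlation. Passing tests therefore show the
*pipeline* is correct and sensitive to the injected effect sizes, not that
real neonatal EGG carries those effect sizes.

## Problem sizes

Repeated-cohort experiments (trend recovery, null calibration) simulate
216-min two-feed sessions at an 8-Hz acquisition rate with the wavelet
stage at 4 Hz. Since all analysis happens below 0.15 Hz, results are
indistinguishable from the 2000-Hz path once past the low-pass, and a
51-subject cohort analyses in a few seconds, letting the recovery
experiment run 50 independent cohorts. The full 2000 → 500 Hz chain is
exercised directly by the preprocessing tests and available throughout
(`egg run-all --full`).

## Known limitations

- Exactly two feeds per session; multi-feed recordings are rejected.
- Band-mean ratios on a log frequency grid slightly favour narrow bands
  for tones within roughly one wavelet bandwidth of a band edge
  (documented edge blur; tones ≥ 0.1 cpm inside a band classify
  correctly, and simulator dwell frequencies are drawn from the full band
  so the effect is a small labelling noise, not a bias of %normo trends).
- Minutes straddling a rhythm switch blend two tones; with ~4-min dwells
  this caps noiseless label agreement around 97–99%, which is why
  recovery thresholds are set at 95%.
- EDF input is not implemented; CSV is the interchange format.
- No mixed-effects modelling of repeated sessions and no covariate
  adjustment (feed type, calories).
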