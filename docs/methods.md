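# Methods

This note documents the models and procedures implemented in `meapipe`, the
assumptions they make, the defaults and why, and the numerical choices that
are not visible from the API.

## Data model

A plate recording is per-well, per-electrode voltage in volts at a single
sampling rate (default 12.5 kHz), stored in an HDF5 file with `/Data/<well>/
<electrode>` datasets and a `/DataInfo` group carrying `ExcludedWells`,
`InactiveChannels` and the five attributes `SamplingFrequencyInHz`,
`DurationInSec`, `RecordingUnits` ("Volts"), `DIV` and `Plate type` (12 or
48). Well labels follow standard plate geometry (3×4 → `A1…C4`, 6×8 →
`A1…F8`); electrodes are two-digit row-column grid labels (`11…88` for
64-electrode wells, `11…44` for 16-electrode wells). Traces are stored as
32-bit floats — lossless at extracellular dynamic range and half the size of
doubles. Times are 0-based seconds from recording start; intervals are
half-open `[start, end)`. Requesting an excluded well or inactive channel
raises a lookup error rather than returning silence, so analysis code cannot
silently treat unrecorded channels as quiet ones.

## Spike detection

The detector assumes extracellular action potentials are brief (~1 ms)
transients riding on approximately Gaussian background noise whose spectrum
overlaps the 200–3000 Hz band.

1. **Filtering.** 4th-order elliptic band-pass, 0.1 dB passband ripple,
   40 dB stopband attenuation, 200–3000 Hz, applied forward-backward
   (`sosfiltfilt`) for zero phase. Only the band edges are fixed design
   points; order and ripple are conventional values for this application.
2. **Noise estimate.** `median(|x|)/0.6745`, the classic robust estimator:
   the median is essentially blind to sparse spikes, so the threshold tracks
   the noise floor, not the signal. On spike-free Gaussian noise it is
   consistent for the true SD.
3. **Thresholding.** Events where `|x| > 4.5·σ̂` (both polarities). Each
   suprathreshold crossing is aligned to the absolute-amplitude extremum in
   the 1 ms window after the crossing; events closer than the 1 ms dead time
   collapse to the larger one. The returned threshold/σ̂ ratio is exactly
   4.5 for every input. `threshold_detect` accepts a σ override for fixtures
   where the true noise SD is known.
4. **SWTTEO confirmation.** Stationary (undecimated) wavelet transform,
   `sym2`, level 2; Teager energy `ψ(n) = d(n)² − d(n−1)d(n+1)` on each
   detail band; negative values clipped to zero; each band smoothed with a
   0.5 ms Hamming window and summed. The N strongest energy maxima (N = the
   threshold-stage count, minimum 1 ms apart) are the SWTTEO events; a
   threshold candidate survives only if an SWTTEO event lies within 1 ms.
   The intersection can only cancel putative false positives, never add
   events. The raw Teager operator is exposed separately (`teager_energy`)
   and satisfies the closed form `ψ = A² sin²(2πf/fs)` on a sinusoid, which
   the tests use as its oracle.
5. **Activity rule.** An electrode is active iff it fires strictly more than
   10 spikes per minute (10 spikes in 60 s is inactive; 11 is active).

Numerical notes: the SWT requires a length divisible by 2^level, so traces
are edge-padded and trimmed after; clipping negative Teager values before
smoothing is what guarantees a non-negative energy signal (the raw operator
can be pointwise negative on noise).

## Burst detection (logISI)

Bursting electrodes show a bimodal log-ISI distribution: an intra-burst mode
(≲100 ms, typically ~5–20 ms) and a slower between-burst mode. The threshold
is derived per electrode:

* histogram of `log10(ISI)` with 10 bins per decade over whole decades,
  smoothed with a centred 3-bin moving average;
* peaks are local maxima of the smoothed histogram (plateau-aware, via
  `find_peaks`, with zero-padding so single-bin histograms still peak);
* the intra-burst peak is the tallest peak below the 100 ms cap, and must
  reach at least `min_fast_peak_fraction` (default 0.1) of the tallest peak
  overall — without this floor, the two or three chance sub-100 ms ISIs of a
  slow tonic train would masquerade as an intra-burst mode;
* scanning the slower peaks in ISI order, the threshold is the ISI at the
  histogram minimum between the intra-burst peak and the first peak whose
  void parameter `1 − h_min/√(h₁h₂)` reaches 0.7; with a fast peak but no
  qualifying valley the cap (100 ms) itself is used; with no qualifying fast
  peak the electrode gets no burst detection at all.

Bursts are maximal runs of consecutive ISIs strictly below the threshold
with at least 5 spikes (the minimum-spike filter is applied before merging;
merging only grows counts, so the order is immaterial to the result).
Consecutive bursts whose gap — last spike of one to first spike of the next
— is strictly below 100 ms merge; the merge pass is idempotent. Trains with
fewer spikes than a minimal burst return no threshold.

All strict `<` comparisons on times use a 1 ns guard (`TIME_EPS_S`):
boundary cases like an exactly-100 ms gap can binary-represent a hair below
their nominal value, and without the guard representation error, not the
rule, would decide them. 1 ns is five orders of magnitude below the 80 µs
sampling period, so no genuinely quantised interval is affected.

Statistics per electrode: bursts/min; mean burst duration; mean in-burst
frequency (spikes per burst duration, with zero durations floored at one
sample period); mean spikes per burst; percentage of spikes in bursts.
Electrodes without bursts have *undefined* (NaN) burst means, never zeros —
zeros would drag well averages toward silence. Per well: the number of
active electrodes (nae), the mean firing rate over active electrodes only,
and burst features averaged over electrodes exhibiting bursts; noisy-listed
electrodes are dropped before anything else; wells with no active electrode
are omitted from output tables entirely.

## Synchrony

**STTC** (±50 ms default window) is computed with exact interval-union
arithmetic for the tiled fractions `T` (windows clipped at the analysis
interval) and sorted nearest-neighbour searches for the proportions `P` —
no grid discretisation. Degenerate inputs (an empty train, or `P·T = 1`)
yield NaN, which is excluded from well means rather than imputed. The test
suite cross-checks the implementation against an independent dense-grid
(0.1 ms) brute-force oracle. Well-level STTC averages over active
electrodes only, consistent with the activity-based inclusion rule
(configurable).

**CorSE** slides 1 s Hann windows with 50% overlap over each raw trace,
takes the periodogram, normalises it to a probability distribution, and
computes Shannon entropy normalised by `ln K` so every window lands in
[0, 1]; a flat (noise-like) spectrum gives entropy near 1, a pure tone near
0, and an all-zero window is assigned 0. The CorSE value of a pair is the
Pearson correlation of the two entropy series; its magnitude is the
connectivity strength. A constant entropy series (e.g. a dead channel) makes
the pair undefined (NaN), so dead channels do not move well means. The well
mean averages the signed values over all defined pairs; the 0.7 threshold
applies only to connectivity maps, which keep pairs with strength strictly
above threshold and carry electrode-grid coordinates for plotting.

## Features and PCA

Exactly seven features per well/timepoint (MFR by active electrodes, bursts
per minute, mean burst duration, mean in-burst frequency, mean spikes per
burst, percent spikes in bursts, STTC); the number of active electrodes is
deliberately excluded, as it only feeds other parameters. Observations with
any undefined feature are dropped (with a logged count), not imputed — the
embedding targets timepoints where activity is developed enough for every
feature to exist. Z-scoring uses the sample SD (n−1) and pools all
observations entering one embedding, since the point of the PCA is to
compare groups in a single space; a zero-variance feature is an error naming
the feature. The PCA keeps the three major components; each loading column's
sign is fixed so its largest-magnitude entry is positive, making scores
deterministic up to machine precision across runs and observation orderings.

## Synthetic data generator

The generator emulates what the analysis consumes: Gaussian background noise
(default SD 3 µV), a 1.2 ms biphasic template (sharp negative peak, smaller
positive rebound) scaled to per-electrode peak amplitudes drawn from
15–60 µV — the low-SNR regime of human stem-cell-derived cultures — tonic
Poisson trains, bursting trains (Poisson burst onsets, default 10/min, eight
10 ms-ISI spikes per burst, matching mature culture bursting), correlated
channel groups built by thinning (participation 0.7) and jittering (Gaussian,
2 ms, truncated in-range) a mother train, and a tetrodotoxin-style silencing
factor of 0.01 on designated wells. Default recording length is 600 s, the
standard spontaneous-activity session; tests and examples use shorter
durations, which changes nothing but statistical power. Randomness is
hierarchical (`SeedSequence` keyed by seed, well and electrode index), so
every generator is a pure function of configuration and seed and individual
electrodes are reproducible in isolation.

What it does **not** emulate — and what passing tests therefore do not show
about real data: no biophysical membrane or network dynamics, no
developmental drift within a recording, no electrode impedance variation or
1/f noise, no movement or stimulation artifacts, no spike-waveform diversity
within an electrode (one template per plate), and spike amplitudes do not
fluctuate spike to spike. Detector performance on real low-SNR recordings
will be worse than on these fixtures; the fixtures establish correctness of
the computations, not field performance.

## Problem sizes used in tests

The test and acceptance suites run on deliberately small instances — single
wells, 16–64 electrodes, 0.5–60 s of signal, hundreds of spikes — chosen so
each statistical check retains power (e.g. Poisson counts tested at 3 SD on
means of 3000; STTC oracle equivalence on 100 random pairs of ≤50 spikes).
Scaling to full 12-well, 600 s plates changes run time, not code paths.

## Known limitations

* The logISI histogram resolution, smoothing and peak-acceptance floor are
  conventional but not canonical; all are exposed on `BurstParams`.
* The SWT wavelet/level and the smoothing window follow the SWTTEO
  literature's typical choices and are configurable; other choices shift
  the detector's operating point slightly.
* CorSE windowing (1 s, 50% overlap, periodogram) is a declared default;
  entropy series are sensitive to window length on strongly non-stationary
  signals.
* Network-level burst detection (across electrodes) and directed
  connectivity are out of scope.
* The HDF5 dialect is self-consistent and round-trips exactly, but string
  datasets written by other toolchains may need dtype coercion on read.
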