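"""Spike detection: band-pass filtering, amplitude thresholding and SWTTEO.

The detector follows a two-stage hybrid scheme.  Candidate spikes are first
found by absolute-amplitude thresholding of the band-pass filtered trace at
4.5x a robust estimate of the noise standard deviation.  A stationary wavelet
transform-based Teager energy operator (SWTTEO) then re-detects the same
number of events from the wavelet energy signal, and only candidates found by
both stages are kept as true positives.  Electrodes firing at more than
10 spikes per minute are classified as active.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal

from .trains import SpikeTrain

logger = logging.getLogger(__name__)


@dataclass
class DetectionParams:
    """Spike-detection parameters.

    The passband edges (200-3000 Hz), threshold multiplier (4.5x noise SD)
    and activity criterion (>10 spikes/min, strict) are the pipeline's fixed
    operating points; the remaining knobs control the SWTTEO stage and event
    bookkeeping.
    """

    passband_low_hz: float = 200.0
    passband_high_hz: float = 3000.0
    filter_order: int = 4
    passband_ripple_db: float = 0.1
    stopband_atten_db: float = 40.0
    threshold_multiplier: float = 4.5
    dead_time_s: float = 1e-3
    align_window_s: float = 1e-3
    match_tolerance_s: float = 1e-3
    swt_level: int = 2
    swt_wavelet: str = "sym2"
    teo_smooth_window_s: float = 0.5e-3
    min_active_rate_spm: float = 10.0

    def validate(self, fs_hz: float | None = None) -> None:
        if not 0 < self.passband_low_hz < self.passband_high_hz:
            raise ValueError("require 0 < passband_low_hz < passband_high_hz")
        if fs_hz is not None and self.passband_high_hz >= fs_hz / 2:
            raise ValueError(
                f"sampling rate {fs_hz} Hz too low for passband edge "
                f"{self.passband_high_hz} Hz"
            )
        if self.threshold_multiplier <= 0:
            raise ValueError("threshold_multiplier must be positive")


@dataclass
class ThresholdEvents:
    """Output of the amplitude-threshold stage."""

    times_s: np.ndarray
    amplitudes_v: np.ndarray
    sigma_v: float
    threshold_v: float


@dataclass
class WaveformSet:
    """Fixed-window spike cutouts around each detected spike."""

    cutouts: np.ndarray  # (n_spikes, n_samples)
    times_s: np.ndarray
    window_pre_ms: float
    window_post_ms: float
    n_dropped_edge: int = 0


def bandpass_filter(trace, fs_hz: float, params: DetectionParams | None = None):
    """Zero-phase elliptic band-pass filter (forward-backward)."""
    params = params or DetectionParams()
    params.validate(fs_hz)
    sos = signal.ellip(
        params.filter_order,
        params.passband_ripple_db,
        params.stopband_atten_db,
        [params.passband_low_hz, params.passband_high_hz],
        btype="bandpass",
        fs=fs_hz,
        output="sos",
    )
    return signal.sosfiltfilt(sos, np.asarray(trace, dtype=float))


def estimate_noise_sd(trace) -> float:
    """Robust noise SD estimate: ``median(|x|) / 0.6745``.

    The median of absolute amplitudes is insensitive to the sparse
    high-amplitude spikes riding on the noise floor, so the estimate tracks
    the background noise rather than the signal.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("cannot estimate noise SD of an empty trace")
    return float(np.median(np.abs(trace)) / 0.6745)


def threshold_detect(
    trace, fs_hz: float, params: DetectionParams | None = None, sigma_v: float | None = None
) -> ThresholdEvents:
    """Absolute-amplitude thresholding at ``k * sigma_hat``.

    Each suprathreshold crossing is aligned to the local absolute-amplitude
    extremum within ``align_window_s`` after the crossing; events closer than
    ``dead_time_s`` collapse to the larger one.  ``sigma_v`` overrides the
    internal noise estimate (useful when the true noise SD is known).
    """
    params = params or DetectionParams()
    trace = np.asarray(trace, dtype=float)
    sigma = estimate_noise_sd(trace) if sigma_v is None else float(sigma_v)
    threshold = params.threshold_multiplier * sigma
    absx = np.abs(trace)
    above = absx > threshold
    if not above.any():
        return ThresholdEvents(np.empty(0), np.empty(0), sigma, threshold)
    # rising edges of the suprathreshold mask
    starts = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    align = max(int(round(params.align_window_s * fs_hz)), 1)
    idx, amps = [], []
    for s in starts:
        window = absx[s : s + align + 1]
        peak = s + int(np.argmax(window))
        idx.append(peak)
        amps.append(trace[peak])
    # collapse events within the dead time, keeping the larger amplitude
    dead = int(round(params.dead_time_s * fs_hz))
    kept_idx: list[int] = []
    kept_amp: list[float] = []
    for i, a in zip(idx, amps):
        if kept_idx and i - kept_idx[-1] < dead:
            if abs(a) > abs(kept_amp[-1]):
                kept_idx[-1], kept_amp[-1] = i, a
        else:
            kept_idx.append(i)
            kept_amp.append(a)
    return ThresholdEvents(
        np.asarray(kept_idx, dtype=float) / fs_hz,
        np.asarray(kept_amp, dtype=float),
        sigma,
        threshold,
    )


def teager_energy(x) -> np.ndarray:
    """Raw Teager energy operator ``psi[x](n) = x(n)^2 - x(n-1) x(n+1)``.

    Output has the input length; the two boundary samples are zero.
    """
    x = np.asarray(x, dtype=float)
    psi = np.zeros_like(x)
    if x.size >= 3:
        psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    return psi


def swtteo_energy(trace, fs_hz: float, params: DetectionParams | None = None):
    """SWTTEO energy signal: undecimated wavelet detail energy, smoothed.

    The trace is decomposed with a stationary wavelet transform to
    ``swt_level``, the Teager energy operator is applied to each detail band,
    negative values are clipped to zero, each band is smoothed with a short
    Hamming window and the bands are summed.  Output is non-negative and has
    the input length.
    """
    params = params or DetectionParams()
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    if n < 2**params.swt_level:
        raise ValueError(
            f"trace of {n} samples too short for SWT level {params.swt_level}"
        )
    # SWT needs a length divisible by 2**level; pad at the end and trim after
    block = 2**params.swt_level
    pad = (-n) % block
    padded = np.pad(trace, (0, pad), mode="edge") if pad else trace
    coeffs = pywt.swt(padded, params.swt_wavelet, level=params.swt_level)
    win_len = max(int(round(params.teo_smooth_window_s * fs_hz)), 1)
    window = np.hamming(win_len) if win_len > 1 else np.ones(1)
    energy = np.zeros(padded.size)
    for _approx, detail in coeffs:
        psi = np.clip(teager_energy(detail), 0.0, None)
        energy += np.convolve(psi, window, mode="same")
    return energy[:n]


def _energy_event_times(
    energy, fs_hz: float, n_events: int, params: DetectionParams
) -> np.ndarray:
    """Times of the ``n_events`` highest energy maxima, dead-time separated."""
    if n_events <= 0:
        return np.empty(0)
    dead = max(int(round(params.dead_time_s * fs_hz)), 1)
    peaks, props = signal.find_peaks(energy, distance=dead)
    if peaks.size == 0:
        return np.empty(0)
    order = np.argsort(energy[peaks])[::-1][:n_events]
    return np.sort(peaks[order]) / fs_hz


def detect_spikes(
    trace,
    fs_hz: float,
    params: DetectionParams | None = None,
    electrode: str = "",
    well: str = "",
    prefiltered: bool = False,
) -> SpikeTrain:
    """Hybrid threshold + SWTTEO spike detection on one electrode trace.

    The amplitude-threshold stage proposes N candidates; the SWTTEO stage
    independently picks the N strongest wavelet-energy events; only
    candidates confirmed by an SWTTEO event within ``match_tolerance_s``
    survive, so the intersection can only remove putative false positives,
    never add events.
    """
    params = params or DetectionParams()
    params.validate(fs_hz)
    trace = np.asarray(trace, dtype=float)
    duration_s = trace.size / fs_hz
    filtered = trace if prefiltered else bandpass_filter(trace, fs_hz, params)
    cand = threshold_detect(filtered, fs_hz, params)
    if cand.times_s.size == 0:
        return SpikeTrain(np.empty(0), duration_s, electrode=electrode, well=well)
    energy_times = _energy_event_times(
        swtteo_energy(filtered, fs_hz, params), fs_hz, cand.times_s.size, params
    )
    if energy_times.size:
        nearest = np.searchsorted(energy_times, cand.times_s)
        dist = np.full(cand.times_s.size, np.inf)
        for shift in (0, -1):
            j = np.clip(nearest + shift, 0, energy_times.size - 1)
            dist = np.minimum(dist, np.abs(cand.times_s - energy_times[j]))
        keep = dist <= params.match_tolerance_s
    else:
        keep = np.zeros(cand.times_s.size, dtype=bool)
    times = cand.times_s[keep]
    amps = cand.amplitudes_v[keep]
    logger.debug(
        "detect_spikes %s/%s: sigma=%.3g V, %d candidates, %d confirmed",
        well,
        electrode,
        cand.sigma_v,
        cand.times_s.size,
        times.size,
    )
    return SpikeTrain(
        times, duration_s, electrode=electrode, well=well, amplitudes_v=amps
    )


def classify_active(
    train: SpikeTrain, params: DetectionParams | None = None
) -> bool:
    """True iff the electrode fires at strictly more than 10 spikes/minute."""
    params = params or DetectionParams()
    return 60.0 * len(train) / train.duration_s > params.min_active_rate_spm


def extract_waveforms(
    trace,
    train: SpikeTrain,
    fs_hz: float,
    window_pre_ms: float = 1.0,
    window_post_ms: float = 2.0,
) -> WaveformSet:
    """Cut fixed-length waveform windows around each spike.

    Spikes whose window would run past either end of the trace are dropped;
    the number dropped is recorded and logged.
    """
    trace = np.asarray(trace, dtype=float)
    length = int(round((window_pre_ms + window_post_ms) * 1e-3 * fs_hz))
    pre = int(round(window_pre_ms * 1e-3 * fs_hz))
    post = length - pre
    cutouts, times = [], []
    dropped = 0
    for t in train.times_s:
        center = int(round(t * fs_hz))
        lo, hi = center - pre, center + post
        if lo < 0 or hi > trace.size:
            dropped += 1
            continue
        cutouts.append(trace[lo:hi])
        times.append(t)
    if dropped:
        logger.info("extract_waveforms: dropped %d edge spike(s)", dropped)
    cut = np.asarray(cutouts, dtype=float).reshape(len(cutouts), length)
    return WaveformSet(cut, np.asarray(times), window_pre_ms, window_post_ms, dropped)
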