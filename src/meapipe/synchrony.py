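"""Pairwise network synchronization: STTC and correlated spectral entropy.

Two complementary estimators are provided.  The spike time tiling
coefficient (STTC) works on detected spike trains and is insensitive to
firing rate: with coincidence window +-dt,

    STTC = 1/2 [ (P_A - T_B)/(1 - P_A T_B) + (P_B - T_A)/(1 - P_B T_A) ]

where ``T_X`` is the fraction of the recording tiled by +-dt windows around
X's spikes and ``P_X`` the proportion of X's spikes falling within +-dt of
any spike of the other train.  CorSE works on the raw voltage traces: it
tracks the spectral entropy of each channel in sliding windows and reports
the Pearson correlation of the two entropy time series, whose magnitude is
the connectivity strength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .detection import DetectionParams, classify_active
from .layout import electrode_position
from .trains import SpikeTrain


@dataclass
class SttcParams:
    """STTC coincidence window; the pipeline default is dt = 50 ms."""

    dt_s: float = 0.050

    def validate(self, duration_s: float) -> None:
        if not 0 < self.dt_s < duration_s / 2:
            raise ValueError("require 0 < dt_s < duration_s / 2")


@dataclass
class CorseParams:
    """CorSE windowing and mapping parameters.

    Spectral entropy is computed in Hann windows of ``window_s`` seconds with
    ``overlap_fraction`` overlap using a periodogram; connectivity maps keep
    pairs with strength strictly above ``map_threshold`` (default 0.7).
    """

    window_s: float = 1.0
    overlap_fraction: float = 0.5
    map_threshold: float = 0.7

    def validate(self, fs_hz: float) -> None:
        if not 0 < self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must lie in (0, 1)")
        if self.window_s * fs_hz < 8:
            raise ValueError("window_s too short: need at least 8 samples")


@dataclass
class ConnectivityMatrix:
    """Symmetric pairwise synchronization values over a well's electrodes."""

    labels: list[str]
    values: np.ndarray
    estimator: str

    def pair_values(self) -> np.ndarray:
        """Upper-triangle (unordered pair) values, NaNs included."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def mean(self) -> float:
        """Mean over defined unordered pairs (NaN if none defined)."""
        pairs = self.pair_values()
        defined = pairs[~np.isnan(pairs)]
        return float(defined.mean()) if defined.size else float("nan")


# ---------------------------------------------------------------------------
# STTC


def _tiled_fraction(times: np.ndarray, dt: float, t0: float, t1: float) -> float:
    """Fraction of [t0, t1] within +-dt of any spike (exact interval union)."""
    if times.size == 0:
        return 0.0
    starts = np.maximum(times - dt, t0)
    ends = np.minimum(times + dt, t1)
    total = 0.0
    cur_start, cur_end = starts[0], ends[0]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= cur_end:
            cur_end = max(cur_end, e)
        else:
            total += cur_end - cur_start
            cur_start, cur_end = s, e
    total += cur_end - cur_start
    return total / (t1 - t0)


def _proportion_within(times: np.ndarray, other: np.ndarray, dt: float) -> float:
    """Proportion of ``times`` lying within +-dt of any spike of ``other``."""
    idx = np.searchsorted(other, times)
    dist = np.full(times.size, np.inf)
    for shift in (0, -1):
        j = np.clip(idx + shift, 0, other.size - 1)
        dist = np.minimum(dist, np.abs(times - other[j]))
    return float(np.mean(dist <= dt))


def sttc(
    train_a: SpikeTrain,
    train_b: SpikeTrain,
    params: SttcParams | None = None,
    interval: tuple[float, float] | None = None,
) -> float:
    """Spike time tiling coefficient of two trains; NaN when undefined.

    Undefined cases (either train empty, or a degenerate ``P T = 1``
    denominator) propagate as NaN and are excluded from well means.
    """
    params = params or SttcParams()
    if interval is None:
        interval = (0.0, min(train_a.duration_s, train_b.duration_s))
    t0, t1 = interval
    params.validate(t1 - t0)
    a, b = train_a.times_s, train_b.times_s
    if a.size == 0 or b.size == 0:
        return float("nan")
    dt = params.dt_s
    ta = _tiled_fraction(a, dt, t0, t1)
    tb = _tiled_fraction(b, dt, t0, t1)
    pa = _proportion_within(a, b, dt)
    pb = _proportion_within(b, a, dt)
    total = 0.0
    for p, t in ((pa, tb), (pb, ta)):
        denom = 1.0 - p * t
        if denom == 0.0:
            return float("nan")
        total += (p - t) / denom
    return 0.5 * total


def sttc_matrix(
    trains: dict[str, SpikeTrain],
    params: SttcParams | None = None,
    active_only: bool = True,
    detection_params: DetectionParams | None = None,
) -> ConnectivityMatrix:
    """Pairwise STTC over one well's electrodes.

    By default only active electrodes (>10 spikes/min) enter the matrix,
    matching the pipeline's inclusion rule; the well mean is the mean of the
    defined unordered pair values.
    """
    params = params or SttcParams()
    if active_only:
        trains = {
            e: t for e, t in trains.items() if classify_active(t, detection_params)
        }
    labels = sorted(trains)
    n = len(labels)
    values = np.full((n, n), np.nan)
    for i in range(n):
        values[i, i] = 1.0
        for j in range(i + 1, n):
            v = sttc(trains[labels[i]], trains[labels[j]], params)
            values[i, j] = values[j, i] = v
    return ConnectivityMatrix(labels, values, "STTC")


# ---------------------------------------------------------------------------
# CorSE


def spectral_entropy_series(
    trace, fs_hz: float, params: CorseParams | None = None
) -> np.ndarray:
    """Normalised spectral entropy in sliding windows; values in [0, 1].

    Per window the periodogram power spectrum is normalised to a probability
    distribution p_k and the Shannon entropy ``-sum p_k ln p_k / ln K``
    computed; a flat (white) spectrum gives entropy near 1, a pure tone near
    0.  An all-zero window yields entropy 0.
    """
    params = params or CorseParams()
    params.validate(fs_hz)
    trace = np.asarray(trace, dtype=float)
    win = int(round(params.window_s * fs_hz))
    if trace.size < win:
        raise ValueError(
            f"trace of {trace.size} samples shorter than one {win}-sample window"
        )
    hop = max(int(round(win * (1.0 - params.overlap_fraction))), 1)
    starts = range(0, trace.size - win + 1, hop)
    entropies = np.empty(len(starts))
    for i, s in enumerate(starts):
        _f, pxx = signal.periodogram(
            trace[s : s + win], fs=fs_hz, window="hann", detrend=False
        )
        total = pxx.sum()
        if total <= 0:
            entropies[i] = 0.0
            continue
        p = pxx / total
        p = p[p > 0]
        entropies[i] = float(-(p * np.log(p)).sum() / np.log(pxx.size))
    return entropies


def corse(
    trace_a, trace_b, fs_hz: float, params: CorseParams | None = None
) -> float:
    """Correlated spectral entropy of two equal-length traces.

    Pearson correlation of the two spectral-entropy time series; NaN when
    either series is constant (e.g. a dead channel).  Connectivity strength
    is the magnitude of the returned value.
    """
    trace_a, trace_b = np.asarray(trace_a), np.asarray(trace_b)
    if trace_a.size != trace_b.size:
        raise ValueError("traces must have equal length")
    ha = spectral_entropy_series(trace_a, fs_hz, params)
    hb = spectral_entropy_series(trace_b, fs_hz, params)
    if ha.std() == 0 or hb.std() == 0:
        return float("nan")
    return float(np.corrcoef(ha, hb)[0, 1])


def well_corse(
    traces: dict[str, np.ndarray],
    fs_hz: float,
    params: CorseParams | None = None,
) -> tuple[float, ConnectivityMatrix]:
    """Mean CorSE over all defined unordered channel pairs of one well."""
    params = params or CorseParams()
    labels = sorted(traces)
    series = {}
    for label in labels:
        series[label] = spectral_entropy_series(traces[label], fs_hz, params)
    n = len(labels)
    values = np.full((n, n), np.nan)
    for i in range(n):
        values[i, i] = 1.0
        for j in range(i + 1, n):
            ha, hb = series[labels[i]], series[labels[j]]
            if ha.std() == 0 or hb.std() == 0:
                v = float("nan")
            else:
                v = float(np.corrcoef(ha, hb)[0, 1])
            values[i, j] = values[j, i] = v
    matrix = ConnectivityMatrix(labels, values, "CorSE")
    return matrix.mean(), matrix


def connectivity_map(
    matrix: ConnectivityMatrix, threshold: float = 0.7
) -> list[dict]:
    """Edges between the most robust network participants.

    Keeps unordered pairs whose connectivity strength (|value|) is strictly
    above ``threshold``; each edge carries the electrode-grid positions of
    its endpoints for plotting.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    edges = []
    n = len(matrix.labels)
    for i in range(n):
        for j in range(i + 1, n):
            v = matrix.values[i, j]
            if np.isnan(v):
                continue
            strength = abs(float(v))
            if strength > threshold:
                a, b = matrix.labels[i], matrix.labels[j]
                edges.append(
                    {
                        "a": a,
                        "b": b,
                        "strength": strength,
                        "value": float(v),
                        "a_pos": electrode_position(a),
                        "b_pos": electrode_position(b),
                    }
                )
    return edges
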