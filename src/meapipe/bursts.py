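"""Burst detection with the logISI method and per-electrode/per-well statistics.

The logISI detector derives a data-driven inter-spike-interval (ISI)
threshold from the histogram of log10(ISI): neuronal cultures that burst
show a bimodal ISI distribution, with a fast intra-burst peak below 100 ms
separated from the slow between-burst peak by a pronounced valley.  Spike
runs whose consecutive ISIs all fall below the threshold, with at least
5 spikes, become bursts; bursts closer than 100 ms (last spike to first
spike) are merged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .detection import DetectionParams, classify_active
from .trains import SpikeTrain

#: guard on strict "<" interval comparisons: 1 ns, far below the sampling
#: period, so representation error cannot flip a boundary case
TIME_EPS_S = 1e-9


@dataclass
class BurstParams:
    """logISI burst-detection parameters.

    ``min_spikes_in_burst`` (5) and ``merge_max_ibi_s`` (100 ms) are the
    pipeline's operating points; ``isi_max_s`` caps the intra-burst peak
    search at 100 ms; the histogram uses ``bins_per_decade`` log-spaced bins
    and the valley between peaks must reach ``void_threshold`` to qualify.
    """

    min_spikes_in_burst: int = 5
    merge_max_ibi_s: float = 0.100
    isi_max_s: float = 0.100
    bins_per_decade: int = 10
    void_threshold: float = 0.7
    min_fast_peak_fraction: float = 0.1
    min_duration_s: float = 1.0 / 12_500.0  # one sample period at 12.5 kHz

    def validate(self) -> None:
        if self.min_spikes_in_burst < 2:
            raise ValueError("min_spikes_in_burst must be >= 2")
        if self.merge_max_ibi_s <= 0 or self.isi_max_s <= 0:
            raise ValueError("merge_max_ibi_s and isi_max_s must be positive")


@dataclass
class Burst:
    start_s: float
    end_s: float
    n_spikes: int

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class ElectrodeBurstStats:
    """Per-electrode burst statistics; burst means are NaN without bursts."""

    bursts_per_min: float
    mean_dur_s: float
    mean_freq_in_burst: float
    mean_spikes_in_burst: float
    per_spikes_in_burst: float


@dataclass
class WellStats:
    """Per-well aggregates over the electrodes of one well."""

    nae: int
    mfr_by_active_electrodes: float
    bursts_per_min: float
    mean_dur_s: float
    mean_freq_in_burst: float
    mean_spikes_in_burst: float
    per_spikes_in_burst: float
    n_electrodes_with_bursts: int = 0
    dropped_noisy: list[str] = field(default_factory=list)


def logisi_threshold(
    train: SpikeTrain, params: BurstParams | None = None
) -> float | None:
    """Derive the ISI threshold from the log-ISI histogram.

    Returns ``None`` (no burst detection possible) when the train has fewer
    than two spikes or its ISI histogram has no peak below ``isi_max_s``.
    When a fast peak exists but no valley towards a slower peak reaches the
    void threshold, the cap ``isi_max_s`` itself is returned.
    """
    params = params or BurstParams()
    params.validate()
    # fewer spikes than a minimal burst: no histogram worth interrogating
    if len(train) < params.min_spikes_in_burst:
        return None
    isis = train.isis()
    isis = isis[isis > 0]
    if isis.size == 0:
        return None
    log_isi = np.log10(isis)
    lo = math.floor(log_isi.min())
    hi = max(math.ceil(log_isi.max()), lo + 1)
    n_bins = (hi - lo) * params.bins_per_decade
    counts, edges = np.histogram(log_isi, bins=n_bins, range=(lo, hi))
    smooth = np.convolve(counts, np.full(3, 1 / 3), mode="same")
    # pad with zeros so peaks at the histogram edges are detectable
    padded = np.concatenate(([0.0], smooth, [0.0]))
    peaks, _ = signal.find_peaks(padded)
    peaks = peaks - 1  # undo padding offset
    if peaks.size == 0:
        return None
    centers = 10 ** ((edges[:-1] + edges[1:]) / 2)
    # a handful of chance short ISIs in a tonic train must not count as an
    # intra-burst mode: the fast peak has to reach a minimum fraction of the
    # tallest histogram peak
    floor = params.min_fast_peak_fraction * smooth.max()
    fast = [
        p for p in peaks if centers[p] < params.isi_max_s and smooth[p] >= floor
    ]
    if not fast:
        return None
    # intra-burst peak: the tallest peak below the cap
    p1 = max(fast, key=lambda p: smooth[p])
    for p2 in sorted(p for p in peaks if p > p1):
        valley = p1 + int(np.argmin(smooth[p1 : p2 + 1]))
        denom = math.sqrt(smooth[p1] * smooth[p2])
        void = 1.0 - smooth[valley] / denom if denom > 0 else 0.0
        if void >= params.void_threshold:
            return float(centers[valley])
    return params.isi_max_s


def detect_bursts(
    train: SpikeTrain, params: BurstParams | None = None
) -> list[Burst]:
    """Detect bursts: sub-threshold ISI runs of >= 5 spikes, then merging.

    Maximal runs of consecutive ISIs strictly below the logISI threshold
    with at least ``min_spikes_in_burst`` spikes become bursts; consecutive
    bursts whose inter-burst interval (last spike to first spike) is
    strictly below ``merge_max_ibi_s`` are merged until stable.
    """
    params = params or BurstParams()
    threshold = logisi_threshold(train, params)
    if threshold is None:
        return []
    times = train.times_s
    below = np.diff(times) < threshold - TIME_EPS_S
    bursts: list[Burst] = []
    i = 0
    while i < below.size:
        if below[i]:
            j = i
            while j < below.size and below[j]:
                j += 1
            n = j - i + 1  # spikes in the run
            if n >= params.min_spikes_in_burst:
                bursts.append(Burst(float(times[i]), float(times[j]), n))
            i = j
        else:
            i += 1
    return merge_bursts(bursts, params)


def merge_bursts(bursts: list[Burst], params: BurstParams | None = None) -> list[Burst]:
    """Merge consecutive bursts with gaps strictly below the merge limit."""
    params = params or BurstParams()
    merged: list[Burst] = []
    for b in sorted(bursts, key=lambda b: b.start_s):
        if merged and b.start_s - merged[-1].end_s < params.merge_max_ibi_s - TIME_EPS_S:
            prev = merged[-1]
            merged[-1] = Burst(
                prev.start_s, max(prev.end_s, b.end_s), prev.n_spikes + b.n_spikes
            )
        else:
            merged.append(Burst(b.start_s, b.end_s, b.n_spikes))
    return merged


def electrode_stats(
    bursts: list[Burst],
    train: SpikeTrain,
    params: BurstParams | None = None,
) -> ElectrodeBurstStats:
    """Burst statistics for one electrode.

    Burst means are NaN (undefined, not zero) when the electrode has no
    bursts; a zero-length burst duration is floored at one sample period so
    the in-burst frequency stays finite.
    """
    params = params or BurstParams()
    duration_s = train.duration_s
    bursts_per_min = 60.0 * len(bursts) / duration_s
    if not bursts:
        nan = float("nan")
        return ElectrodeBurstStats(bursts_per_min, nan, nan, nan, nan)
    durs = np.array([max(b.duration_s, params.min_duration_s) for b in bursts])
    n_spikes = np.array([b.n_spikes for b in bursts], dtype=float)
    total = len(train)
    per = 100.0 * n_spikes.sum() / total if total else float("nan")
    return ElectrodeBurstStats(
        bursts_per_min=bursts_per_min,
        mean_dur_s=float(durs.mean()),
        mean_freq_in_burst=float((n_spikes / durs).mean()),
        mean_spikes_in_burst=float(n_spikes.mean()),
        per_spikes_in_burst=float(per),
    )


def well_stats(
    trains: dict[str, SpikeTrain],
    noisy: list[str] | None = None,
    burst_params: BurstParams | None = None,
    detection_params: DetectionParams | None = None,
) -> WellStats:
    """Aggregate burst/firing statistics over one well's electrodes.

    Noisy electrodes are dropped first; the number of active electrodes and
    the mean firing rate use the >10 spikes/min rule; burst means average
    only over electrodes that exhibit bursts.
    """
    burst_params = burst_params or BurstParams()
    noisy = set(noisy or [])
    kept = {e: t for e, t in trains.items() if e not in noisy}
    active = {
        e: t for e, t in kept.items() if classify_active(t, detection_params)
    }
    nae = len(active)
    mfr = (
        float(np.mean([t.firing_rate_hz() for t in active.values()]))
        if active
        else float("nan")
    )
    per_electrode = []
    for e, t in active.items():
        bursts = detect_bursts(t, burst_params)
        if bursts:
            per_electrode.append(electrode_stats(bursts, t, burst_params))
    if per_electrode:
        agg = {
            name: float(np.mean([getattr(s, name) for s in per_electrode]))
            for name in (
                "bursts_per_min",
                "mean_dur_s",
                "mean_freq_in_burst",
                "mean_spikes_in_burst",
                "per_spikes_in_burst",
            )
        }
    else:
        nan = float("nan")
        agg = {
            "bursts_per_min": 0.0 if active else nan,
            "mean_dur_s": nan,
            "mean_freq_in_burst": nan,
            "mean_spikes_in_burst": nan,
            "per_spikes_in_burst": nan,
        }
    return WellStats(
        nae=nae,
        mfr_by_active_electrodes=mfr,
        n_electrodes_with_bursts=len(per_electrode),
        dropped_noisy=sorted(noisy & set(trains)),
        **agg,
    )
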