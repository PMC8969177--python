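"""Independent brute-force oracles used to cross-check the implementations.

These deliberately use different algorithms from the package: dense-grid
tiling and exhaustive pair scans for the STTC, and direct enumeration of
sub-threshold ISI runs for burst detection.
"""

from __future__ import annotations

import numpy as np


def sttc_brute_force(
    times_a: np.ndarray,
    times_b: np.ndarray,
    dt: float,
    t0: float,
    t1: float,
    grid_step: float = 1e-4,
) -> float:
    """STTC via dense-grid tiling (T terms) and exhaustive scans (P terms)."""
    a = np.asarray(times_a, dtype=float)
    b = np.asarray(times_b, dtype=float)
    if a.size == 0 or b.size == 0:
        return float("nan")
    grid = np.arange(t0 + grid_step / 2, t1, grid_step)

    def tiled(times):
        covered = np.zeros(grid.size, dtype=bool)
        for t in times:
            covered |= np.abs(grid - t) <= dt
        return covered.mean()

    def prop(times, other):
        hits = 0
        for t in times:
            if any(abs(t - o) <= dt for o in other):
                hits += 1
        return hits / times.size

    ta, tb = tiled(a), tiled(b)
    pa, pb = prop(a, b), prop(b, a)
    total = 0.0
    for p, t in ((pa, tb), (pb, ta)):
        denom = 1.0 - p * t
        if denom == 0.0:
            return float("nan")
        total += (p - t) / denom
    return 0.5 * total


def bursts_brute_force(
    times: np.ndarray,
    isi_threshold: float,
    min_spikes: int,
    merge_max_ibi: float,
    eps: float = 1e-9,
) -> list[tuple[float, float, int]]:
    """Enumerate maximal sub-threshold runs directly, then merge greedily.

    For every start index, extend while the next ISI is below threshold and
    keep only maximal runs — an O(n^2) enumeration independent of the
    vectorised implementation.
    """
    times = np.asarray(times, dtype=float)
    n = times.size
    runs = []
    for i in range(n):
        j = i
        while j + 1 < n and times[j + 1] - times[j] < isi_threshold - eps:
            j += 1
        if j > i:
            runs.append((i, j))
    # maximal runs only: drop runs contained in an earlier run
    maximal = []
    for i, j in runs:
        if not any(i2 <= i and j <= j2 for i2, j2 in maximal):
            maximal.append((i, j))
    bursts = [
        (float(times[i]), float(times[j]), j - i + 1)
        for i, j in maximal
        if j - i + 1 >= min_spikes
    ]
    merged: list[tuple[float, float, int]] = []
    for start, end, count in bursts:
        if merged and start - merged[-1][1] < merge_max_ibi - eps:
            s, e, c = merged[-1]
            merged[-1] = (s, max(e, end), c + count)
        else:
            merged.append((start, end, count))
    return merged
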