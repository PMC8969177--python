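"""Ground-truthed synthetic multiwell MEA recordings.

The generator emulates the statistical structure of extracellular multiwell
MEA recordings of developing neuronal cultures: Gaussian background noise,
embedded biphasic spike waveforms at known times, tonic (Poisson) and
bursting spike trains, correlated channel pairs, and the two supported plate
layouts (12 wells x 64 electrodes, 48 wells x 16 electrodes) sampled at
12.5 kHz.  Every generator is a pure function of its configuration and seed,
and returns the ground truth (true spike times, true burst intervals,
dependency flags) alongside the signal, so every analysis stage can be
benchmarked without access to real recordings.

Defaults target the low signal-to-noise regime typical of human stem-cell
derived networks: background noise SD 3 uV and spike peak amplitudes of
15-60 uV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import layout
from .io import PlateRecording, RecordingMetadata
from .trains import SpikeTrain

DEFAULT_FS_HZ = 12_500.0
DEFAULT_NOISE_SD_V = 3e-6
DEFAULT_AMPLITUDE_RANGE_V = (15e-6, 60e-6)
DEFAULT_TTX_FACTOR = 0.01


@dataclass
class SpikeTemplate:
    """A short biphasic extracellular spike waveform (volts)."""

    waveform: np.ndarray
    peak_index: int

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if np.argmax(np.abs(self.waveform)) != self.peak_index:
            raise ValueError("|waveform| must be maximal at peak_index")

    @property
    def peak_amplitude_v(self) -> float:
        return float(np.abs(self.waveform[self.peak_index]))


def default_template(fs_hz: float = DEFAULT_FS_HZ) -> SpikeTemplate:
    """1.2 ms biphasic template: sharp negative peak, smaller positive rebound.

    Normalised to unit peak amplitude; scale with the ``amplitude_v`` argument
    of :func:`synthesize_trace`.
    """
    duration_s = 1.2e-3
    n = max(int(round(duration_s * fs_hz)), 5)
    t = np.arange(n) / fs_hz
    t_neg, t_pos = 0.3e-3, 0.65e-3
    w = -np.exp(-0.5 * ((t - t_neg) / 0.08e-3) ** 2) + 0.45 * np.exp(
        -0.5 * ((t - t_pos) / 0.16e-3) ** 2
    )
    w /= np.max(np.abs(w))
    return SpikeTemplate(w, int(np.argmax(np.abs(w))))


@dataclass
class TrainModel:
    """Point-process model of one electrode's firing.

    ``tonic_poisson`` emits a homogeneous Poisson train at ``tonic_rate_hz``.
    ``bursting`` emits burst onsets as a Poisson process at
    ``burst_rate_per_min`` with ``spikes_per_burst`` fixed-ISI spikes per
    burst, on top of an optional tonic Poisson background.
    """

    mode: str = "tonic_poisson"
    tonic_rate_hz: float = 0.5
    burst_rate_per_min: float = 10.0
    intra_burst_isi_s: float = 0.010
    spikes_per_burst: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("tonic_poisson", "bursting"):
            raise ValueError(f"unknown train mode {self.mode!r}")
        if self.tonic_rate_hz < 0 or self.burst_rate_per_min < 0:
            raise ValueError("rates must be non-negative")
        if self.intra_burst_isi_s <= 0:
            raise ValueError("intra_burst_isi_s must be positive")
        if self.spikes_per_burst < 1:
            raise ValueError("spikes_per_burst must be >= 1")


@dataclass
class GroundTruth:
    """True event times underlying a synthetic plate."""

    spike_times: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    burst_intervals: dict[tuple[str, str], list[tuple[float, float]]] = field(
        default_factory=dict
    )
    correlated_pairs: list[tuple[tuple[str, str], tuple[str, str]]] = field(
        default_factory=list
    )


def _poisson_times(rng: np.random.Generator, rate_hz: float, duration_s: float):
    if rate_hz <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def generate_train(
    model: TrainModel, duration_s: float, seed: int | None = None
) -> tuple[SpikeTrain, list[tuple[float, float]]]:
    """Draw one spike train; returns the train and its true burst intervals."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    times = _poisson_times(rng, model.tonic_rate_hz, duration_s)
    bursts: list[tuple[float, float]] = []
    if model.mode == "bursting":
        onsets = _poisson_times(rng, model.burst_rate_per_min / 60.0, duration_s)
        burst_len = (model.spikes_per_burst - 1) * model.intra_burst_isi_s
        for onset in onsets:
            burst = onset + np.arange(model.spikes_per_burst) * model.intra_burst_isi_s
            burst = burst[burst <= duration_s]
            if burst.size:
                times = np.concatenate([times, burst])
                bursts.append((float(onset), float(min(onset + burst_len, duration_s))))
    train = SpikeTrain(np.sort(times), duration_s)
    return train, bursts


def generate_correlated_trains(
    model: TrainModel,
    n_channels: int,
    duration_s: float,
    jitter_s: float = 0.0,
    participation_prob: float = 1.0,
    seed: int = 0,
) -> list[SpikeTrain]:
    """Thin and jitter one mother train into ``n_channels`` dependent trains.

    Each channel keeps each mother spike independently with probability
    ``participation_prob`` and perturbs it by zero-mean Gaussian jitter of
    scale ``jitter_s`` (truncated to the recording).  Pairwise dependence
    decreases with jitter and thinning.
    """
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    if jitter_s < 0:
        raise ValueError("jitter_s must be non-negative")
    if not 0.0 <= participation_prob <= 1.0:
        raise ValueError("participation_prob must lie in [0, 1]")
    mother, _ = generate_train(model, duration_s, seed=seed)
    rng = np.random.default_rng(seed)
    out = []
    for _channel in range(n_channels):
        keep = rng.random(len(mother)) < participation_prob
        times = mother.times_s[keep]
        if jitter_s > 0 and times.size:
            times = times + rng.normal(0.0, jitter_s, size=times.size)
            times = np.clip(times, 0.0, duration_s)
        out.append(SpikeTrain(np.sort(times), duration_s))
    return out


def synthesize_trace(
    train: SpikeTrain,
    template: SpikeTemplate,
    amplitude_v: float,
    noise_sd_v: float,
    fs_hz: float = DEFAULT_FS_HZ,
    duration_s: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Embed the template at each spike time in Gaussian background noise.

    The template is scaled so its peak absolute amplitude equals
    ``amplitude_v`` and aligned so the peak sample falls on the spike time.
    """
    if amplitude_v < 0:
        raise ValueError("amplitude_v must be non-negative")
    if fs_hz <= 0:
        raise ValueError("fs_hz must be positive")
    duration_s = train.duration_s if duration_s is None else duration_s
    n = int(round(duration_s * fs_hz))
    if train.times_s.size and train.times_s[-1] > duration_s:
        raise ValueError("spike time beyond trace duration")
    rng = np.random.default_rng(seed)
    trace = rng.normal(0.0, noise_sd_v, size=n)
    if amplitude_v > 0 and len(train):
        w = template.waveform * (amplitude_v / template.peak_amplitude_v)
        for t in train.times_s:
            start = int(round(t * fs_hz)) - template.peak_index
            lo, hi = max(start, 0), min(start + w.size, n)
            if hi > lo:
                trace[lo:hi] += w[lo - start : hi - start]
    return trace


@dataclass
class PlateScenario:
    """Configuration of one synthetic plate.

    ``wells`` maps well labels to :class:`TrainModel`; valid wells not listed
    are written as excluded.  ``ttx_wells`` are silenced by multiplying all
    spike rates by ``ttx_factor``, emulating tetrodotoxin application.
    ``correlated_wells`` share a per-well mother train across electrodes so
    that within-well pairs are synchronized.
    """

    plate_type: int = 12
    duration_s: float = 600.0
    fs_hz: float = DEFAULT_FS_HZ
    div: int = 21
    wells: dict[str, TrainModel] = field(default_factory=dict)
    ttx_wells: list[str] = field(default_factory=list)
    ttx_factor: float = DEFAULT_TTX_FACTOR
    correlated_wells: list[str] = field(default_factory=list)
    jitter_s: float = 0.002
    participation_prob: float = 0.7
    noise_sd_v: float = DEFAULT_NOISE_SD_V
    amplitude_range_v: tuple[float, float] = DEFAULT_AMPLITUDE_RANGE_V
    inactive_channels: list[tuple[str, str]] = field(default_factory=list)


def default_scenario(plate_type: int = 12, **overrides) -> PlateScenario:
    """A mixed tonic/bursting scenario covering every well of the plate."""
    wells = {}
    for i, well in enumerate(layout.wells_for_plate(plate_type)):
        if i % 2 == 0:
            wells[well] = TrainModel(mode="bursting", tonic_rate_hz=0.3)
        else:
            wells[well] = TrainModel(mode="tonic_poisson", tonic_rate_hz=1.0)
    return PlateScenario(plate_type=plate_type, wells=wells, **overrides)


def _silenced(model: TrainModel, factor: float) -> TrainModel:
    return replace(
        model,
        tonic_rate_hz=model.tonic_rate_hz * factor,
        burst_rate_per_min=model.burst_rate_per_min * factor,
    )


def generate_plate(
    scenario: PlateScenario, seed: int = 0
) -> tuple[PlateRecording, GroundTruth]:
    """Generate a full conforming plate recording plus its ground truth."""
    layout._check_plate_type(scenario.plate_type)
    all_wells = layout.wells_for_plate(scenario.plate_type)
    electrodes = layout.electrodes_for_plate(scenario.plate_type)
    for well in scenario.wells:
        layout.validate_well(well, scenario.plate_type)
    excluded = [w for w in all_wells if w not in scenario.wells]
    inactive = set(scenario.inactive_channels)
    md = RecordingMetadata(
        sampling_frequency_hz=scenario.fs_hz,
        duration_s=scenario.duration_s,
        div=scenario.div,
        plate_type=scenario.plate_type,
        excluded_wells=excluded,
        inactive_channels=sorted(inactive),
    )
    truth = GroundTruth()
    wells: dict[str, dict[str, np.ndarray]] = {}
    template = default_template(scenario.fs_hz)
    for wi, well in enumerate(sorted(scenario.wells)):
        model = scenario.wells[well]
        if well in scenario.ttx_wells:
            model = _silenced(model, scenario.ttx_factor)
        well_seed = np.random.SeedSequence([seed, wi])
        amp_rng = np.random.default_rng(well_seed.spawn(1)[0])
        present = [e for e in electrodes if (well, e) not in inactive]
        if well in scenario.correlated_wells:
            trains = generate_correlated_trains(
                model,
                n_channels=len(present),
                duration_s=scenario.duration_s,
                jitter_s=scenario.jitter_s,
                participation_prob=scenario.participation_prob,
                seed=int(well_seed.generate_state(1)[0] % 2**31),
            )
            train_map = dict(zip(present, trains))
            burst_map = {e: [] for e in present}
            for a in range(len(present)):
                for b in range(a + 1, len(present)):
                    truth.correlated_pairs.append(
                        ((well, present[a]), (well, present[b]))
                    )
        else:
            train_map, burst_map = {}, {}
            for ei, electrode in enumerate(present):
                ss = np.random.SeedSequence([seed, wi, ei])
                train, bursts = generate_train(
                    model, scenario.duration_s, seed=int(ss.generate_state(1)[0] % 2**31)
                )
                train_map[electrode] = train
                burst_map[electrode] = bursts
        lo, hi = scenario.amplitude_range_v
        traces = {}
        for ei, electrode in enumerate(present):
            amplitude = float(amp_rng.uniform(lo, hi))
            ss = np.random.SeedSequence([seed, wi, ei, 1])
            traces[electrode] = synthesize_trace(
                train_map[electrode],
                template,
                amplitude_v=amplitude,
                noise_sd_v=scenario.noise_sd_v,
                fs_hz=scenario.fs_hz,
                duration_s=scenario.duration_s,
                seed=int(ss.generate_state(1)[0] % 2**31),
            )
            truth.spike_times[(well, electrode)] = train_map[electrode].times_s
            truth.burst_intervals[(well, electrode)] = burst_map.get(electrode, [])
        wells[well] = traces
    plate = PlateRecording(metadata=md, wells=wells)
    plate.validate()
    return plate, truth


def scenario_from_dict(cfg: dict) -> PlateScenario:
    """Build a scenario from a plain-dict config (e.g. parsed YAML)."""
    cfg = dict(cfg)
    wells_cfg = cfg.pop("wells", None)
    plate_type = int(cfg.pop("plate_type", 12))
    if wells_cfg is None:
        scenario = default_scenario(plate_type)
    else:
        wells = {w: TrainModel(**(m or {})) for w, m in wells_cfg.items()}
        scenario = PlateScenario(plate_type=plate_type, wells=wells)
    for key, value in cfg.items():
        if not hasattr(scenario, key):
            raise ValueError(f"unknown scenario key {key!r}")
        setattr(scenario, key, value)
    if "inactive_channels" in cfg:
        scenario.inactive_channels = [tuple(x) for x in scenario.inactive_channels]
    if "amplitude_range_v" in cfg:
        scenario.amplitude_range_v = tuple(scenario.amplitude_range_v)
    return scenario
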