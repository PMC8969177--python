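"""Reading and writing plate recordings and analysis side files.

A plate recording is stored in an HDF5 file with two top-level groups:

* ``/Data`` — one subgroup per recorded well (``/Data/A3``), one dataset per
  electrode (``/Data/A3/22``) holding the voltage time series in volts.
* ``/DataInfo`` — two datasets, ``ExcludedWells`` and ``InactiveChannels``,
  and five attributes: ``SamplingFrequencyInHz``, ``DurationInSec``,
  ``RecordingUnits`` (``"Volts"``), ``DIV`` and ``Plate type`` (12 or 48).

All HDF5 paths use forward slashes.  Spike tables, noisy-electrode lists,
experiment logs and per-feature well tables are plain CSV (UTF-8, comma
separated, header row).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from . import layout

#: feature-table names used for the per-well output CSVs
FEATURE_NAMES = (
    "meanfiringrate_by_active_electrodes",
    "nae",
    "STTC",
    "bursts_per_min",
    "mean_dur",
    "mean_freq_in_burst",
    "per_spikes_in_burst",
    "mean_spikes_in_burst",
)

SPIKE_CSV_COLUMNS = ("well", "electrode", "time_s")


class FormatError(ValueError):
    """Raised when a file does not conform to the expected dialect."""


@dataclass
class RecordingMetadata:
    """Acquisition metadata stored under ``/DataInfo``."""

    sampling_frequency_hz: float
    duration_s: float
    div: int
    plate_type: int
    recording_units: str = "Volts"
    excluded_wells: list[str] = field(default_factory=list)
    inactive_channels: list[tuple[str, str]] = field(default_factory=list)

    def validate(self) -> None:
        layout._check_plate_type(self.plate_type)
        if self.sampling_frequency_hz <= 0:
            raise ValueError("sampling_frequency_hz must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.div < 0:
            raise ValueError("DIV must be non-negative")
        valid_wells = set(layout.wells_for_plate(self.plate_type))
        for well in self.excluded_wells:
            if well not in valid_wells:
                raise ValueError(
                    f"excluded well {well!r} is not a valid well for a "
                    f"{self.plate_type}-well plate"
                )
        for well, electrode in self.inactive_channels:
            layout.validate_well(well, self.plate_type)
            layout.validate_electrode(electrode, self.plate_type)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_frequency_hz))


@dataclass
class PlateRecording:
    """A full multiwell recording: per-well, per-electrode voltage traces."""

    metadata: RecordingMetadata
    wells: dict[str, dict[str, np.ndarray]]

    def validate(self) -> None:
        md = self.metadata
        md.validate()
        excluded = set(md.excluded_wells)
        inactive = set(md.inactive_channels)
        n_samples = md.n_samples
        valid_wells = set(layout.wells_for_plate(md.plate_type))
        valid_electrodes = set(layout.electrodes_for_plate(md.plate_type))
        for well, traces in self.wells.items():
            if well not in valid_wells:
                raise ValueError(f"well {well!r} invalid for plate type {md.plate_type}")
            if well in excluded:
                raise ValueError(f"excluded well {well!r} must not carry traces")
            for electrode, trace in traces.items():
                if electrode not in valid_electrodes:
                    raise ValueError(
                        f"electrode {electrode!r} of well {well!r} invalid for "
                        f"plate type {md.plate_type}"
                    )
                if (well, electrode) in inactive:
                    raise ValueError(
                        f"inactive channel ({well!r}, {electrode!r}) must not "
                        "carry a trace"
                    )
                if len(trace) != n_samples:
                    raise ValueError(
                        f"trace {well}/{electrode} has {len(trace)} samples, "
                        f"expected {n_samples}"
                    )

    def get_trace(self, well: str, electrode: str) -> np.ndarray:
        """Voltage trace of one electrode; excluded/inactive lookups raise."""
        md = self.metadata
        if well in md.excluded_wells:
            raise LookupError(f"well {well!r} is excluded and was not recorded")
        if (well, electrode) in md.inactive_channels:
            raise LookupError(f"channel ({well!r}, {electrode!r}) was inactive")
        if well not in self.wells or electrode not in self.wells[well]:
            raise LookupError(f"no trace stored for {well}/{electrode}")
        return self.wells[well][electrode]


# ---------------------------------------------------------------------------
# HDF5 plate files


def write_plate(plate: PlateRecording, path) -> None:
    """Write a plate recording to ``path`` in the HDF5 dialect above."""
    plate.validate()
    md = plate.metadata
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        data = f.create_group("Data")
        for well in sorted(plate.wells):
            g = data.create_group(well)
            for electrode in sorted(plate.wells[well]):
                g.create_dataset(
                    electrode,
                    data=np.asarray(plate.wells[well][electrode], dtype=np.float32),
                )
        info = f.create_group("DataInfo")
        info.create_dataset(
            "ExcludedWells", data=np.array(md.excluded_wells, dtype=object), dtype=str_dt
        )
        inactive = np.array(
            [[w, e] for w, e in md.inactive_channels], dtype=object
        ).reshape(-1, 2)
        info.create_dataset("InactiveChannels", data=inactive, dtype=str_dt)
        info.attrs["SamplingFrequencyInHz"] = float(md.sampling_frequency_hz)
        info.attrs["DurationInSec"] = float(md.duration_s)
        info.attrs["RecordingUnits"] = md.recording_units
        info.attrs["DIV"] = int(md.div)
        info.attrs["Plate type"] = int(md.plate_type)


def read_plate(path) -> PlateRecording:
    """Read a plate recording written by :func:`write_plate`."""
    with h5py.File(path, "r") as f:
        for group in ("Data", "DataInfo"):
            if group not in f:
                raise FormatError(f"missing required group '/{group}'")
        info = f["DataInfo"]
        for attr in (
            "SamplingFrequencyInHz",
            "DurationInSec",
            "RecordingUnits",
            "DIV",
            "Plate type",
        ):
            if attr not in info.attrs:
                raise FormatError(f"missing '/DataInfo' attribute {attr!r}")
        units = _decode(info.attrs["RecordingUnits"])
        if units != "Volts":
            warnings.warn(
                f"RecordingUnits is {units!r}, expected 'Volts'", stacklevel=2
            )
        excluded = [_decode(w) for w in info["ExcludedWells"][()]]
        inactive = [
            (_decode(w), _decode(e)) for w, e in np.asarray(info["InactiveChannels"][()])
        ]
        md = RecordingMetadata(
            sampling_frequency_hz=float(info.attrs["SamplingFrequencyInHz"]),
            duration_s=float(info.attrs["DurationInSec"]),
            div=int(info.attrs["DIV"]),
            plate_type=int(info.attrs["Plate type"]),
            recording_units=units,
            excluded_wells=excluded,
            inactive_channels=inactive,
        )
        wells: dict[str, dict[str, np.ndarray]] = {}
        for well in f["Data"]:
            wells[well] = {
                electrode: f["Data"][well][electrode][()]
                for electrode in f["Data"][well]
            }
    plate = PlateRecording(metadata=md, wells=wells)
    plate.validate()
    return plate


def _decode(value) -> str:
    return value.decode() if isinstance(value, bytes) else str(value)


# ---------------------------------------------------------------------------
# Spike tables


def spike_table(rows) -> pd.DataFrame:
    """Build a canonical spike table (well, electrode, time_s), sorted."""
    df = pd.DataFrame(rows, columns=list(SPIKE_CSV_COLUMNS))
    df["time_s"] = df["time_s"].astype(float)
    return df.sort_values(list(SPIKE_CSV_COLUMNS), kind="stable").reset_index(drop=True)


def spike_table_from_trains(trains) -> pd.DataFrame:
    """Assemble a spike table from an iterable of :class:`SpikeTrain`."""
    rows = [
        (t.well, t.electrode, float(time)) for t in trains for time in t.times_s
    ]
    return spike_table(rows)


def write_spike_csv(spikes: pd.DataFrame, path) -> None:
    """Write a spike table as long-format CSV with 6-decimal times."""
    missing = set(SPIKE_CSV_COLUMNS) - set(spikes.columns)
    if missing:
        raise ValueError(f"spike table is missing columns {sorted(missing)}")
    out = spikes.loc[:, list(SPIKE_CSV_COLUMNS)]
    out.to_csv(path, index=False, float_format="%.6f")


def read_spike_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"well": str, "electrode": str})
    missing = set(SPIKE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"spike CSV {path} is missing columns {sorted(missing)}")
    bad = pd.to_numeric(df["time_s"], errors="coerce").isna() & df["time_s"].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise FormatError(f"unparseable spike time at line {line} of {path}")
    return spike_table(df[list(SPIKE_CSV_COLUMNS)].itertuples(index=False, name=None))


def spike_trains_from_table(
    spikes: pd.DataFrame, duration_s: float
) -> dict[str, dict[str, "object"]]:
    """Group a spike table into per-well, per-electrode :class:`SpikeTrain`."""
    from .trains import SpikeTrain

    out: dict[str, dict[str, SpikeTrain]] = {}
    for (well, electrode), group in spikes.groupby(["well", "electrode"], sort=True):
        out.setdefault(well, {})[electrode] = SpikeTrain(
            np.sort(group["time_s"].to_numpy()),
            duration_s,
            electrode=electrode,
            well=well,
        )
    return out


# ---------------------------------------------------------------------------
# Noisy-electrode lists and experiment logs


def read_noisy_electrodes(path, plate_type: int | None = None) -> list[tuple[str, str]]:
    """Read the noisy-electrode list; entries are deduplicated, order kept."""
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    if not {"well", "electrode"} <= set(df.columns):
        raise FormatError(f"noisy-electrode CSV {path} needs 'well' and 'electrode'")
    seen: list[tuple[str, str]] = []
    for well, electrode in df[["well", "electrode"]].itertuples(index=False):
        if plate_type is not None:
            layout.validate_well(well, plate_type)
            layout.validate_electrode(electrode, plate_type)
        if (well, electrode) not in seen:
            seen.append((well, electrode))
    return seen


def write_noisy_electrodes(entries, path) -> None:
    pd.DataFrame(entries, columns=["well", "electrode"]).to_csv(path, index=False)


def read_explog(path, plate_type: int | None = None) -> pd.DataFrame:
    """Read the experiment log mapping wells to treatment/group labels."""
    df = pd.read_csv(path, dtype=str)
    if not {"well", "treatment"} <= set(df.columns):
        raise FormatError(f"expLog CSV {path} needs 'well' and 'treatment' columns")
    if plate_type is not None:
        for well in df["well"]:
            layout.validate_well(well, plate_type)
    return df[["well", "treatment"]]


def write_explog(log: pd.DataFrame, path) -> None:
    log[["well", "treatment"]].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Per-feature well tables


def feature_table_path(out_dir, data_label: str, feature: str):
    from pathlib import Path

    if feature not in FEATURE_NAMES:
        raise ValueError(
            f"unknown feature {feature!r}; valid names: {', '.join(FEATURE_NAMES)}"
        )
    return Path(out_dir) / f"{data_label}_{feature}.csv"


def write_feature_table(values: pd.DataFrame, feature: str, path) -> None:
    """Write one per-well (rows) by per-DIV (columns) feature table.

    Wells whose every entry is missing (all electrodes eliminated) are
    omitted from the file.
    """
    if feature not in FEATURE_NAMES:
        raise ValueError(
            f"unknown feature {feature!r}; valid names: {', '.join(FEATURE_NAMES)}"
        )
    out = values.dropna(how="all")
    out.to_csv(path, index=True, index_label="well")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="well")
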