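"""End-to-end orchestration: simulate -> detect -> bursts -> synchrony -> PCA.

Holds the single serialisable configuration object whose defaults are the
pipeline's operating points, the per-stage helpers that turn a plate
recording into the analysis tables, and :func:`run_pipeline`, which writes
every output CSV plus a manifest recording the configuration hash, seed and
library versions needed to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .bursts import BurstParams, well_stats
from .detection import DetectionParams, detect_spikes
from .features import FEATURE_ORDER, assemble_features, pca, scores_frame, zscore
from .io import PlateRecording
from .synchrony import CorseParams, SttcParams, connectivity_map, sttc_matrix, well_corse
from .trains import SpikeTrain

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, serialisable to one file."""

    detection: DetectionParams = field(default_factory=DetectionParams)
    bursts: BurstParams = field(default_factory=BurstParams)
    sttc: SttcParams = field(default_factory=SttcParams)
    corse: CorseParams = field(default_factory=CorseParams)
    n_components: int = 3
    data_label: str = "synthetic_plate"
    seed: int = 0

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        cfg = dict(cfg)
        kwargs = {}
        for name, sub_cls in (
            ("detection", DetectionParams),
            ("bursts", BurstParams),
            ("sttc", SttcParams),
            ("corse", CorseParams),
        ):
            if name in cfg:
                kwargs[name] = sub_cls(**cfg.pop(name))
        unknown = set(cfg) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs, **cfg)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# Stage helpers


def detect_plate_spikes(
    plate: PlateRecording, params: DetectionParams | None = None
) -> dict[str, dict[str, SpikeTrain]]:
    """Run spike detection on every recorded electrode of a plate."""
    params = params or DetectionParams()
    fs = plate.metadata.sampling_frequency_hz
    out: dict[str, dict[str, SpikeTrain]] = {}
    for well in sorted(plate.wells):
        out[well] = {}
        for electrode in sorted(plate.wells[well]):
            out[well][electrode] = detect_spikes(
                plate.wells[well][electrode],
                fs,
                params,
                electrode=electrode,
                well=well,
            )
        counts = sum(len(t) for t in out[well].values())
        logger.info("well %s: %d spikes on %d electrodes", well, counts, len(out[well]))
    return out


#: WellStats attribute backing each output feature table
_FEATURE_ATTR = {
    "meanfiringrate_by_active_electrodes": "mfr_by_active_electrodes",
    "nae": "nae",
    "bursts_per_min": "bursts_per_min",
    "mean_dur": "mean_dur_s",
    "mean_freq_in_burst": "mean_freq_in_burst",
    "per_spikes_in_burst": "per_spikes_in_burst",
    "mean_spikes_in_burst": "mean_spikes_in_burst",
}


def well_feature_tables(
    trains_by_well: dict[str, dict[str, SpikeTrain]],
    div: int,
    noisy: list[tuple[str, str]] | None = None,
    burst_params: BurstParams | None = None,
    detection_params: DetectionParams | None = None,
    sttc_params: SttcParams | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-feature well x DIV tables for one recording.

    Noisy electrodes are dropped before any statistic; wells whose every
    electrode is eliminated (no active electrodes) are omitted from the
    tables entirely.
    """
    noisy = noisy or []
    tables: dict[str, dict[str, float]] = {name: {} for name in io.FEATURE_NAMES}
    for well, trains in trains_by_well.items():
        noisy_here = [e for w, e in noisy if w == well]
        stats = well_stats(
            trains,
            noisy=noisy_here,
            burst_params=burst_params,
            detection_params=detection_params,
        )
        if stats.nae == 0:
            logger.info("well %s: no active electrodes; omitted from outputs", well)
            continue
        for feature, attr in _FEATURE_ATTR.items():
            tables[feature][well] = float(getattr(stats, attr))
        kept = {e: t for e, t in trains.items() if e not in noisy_here}
        matrix = sttc_matrix(kept, sttc_params, detection_params=detection_params)
        tables["STTC"][well] = matrix.mean()
    col = str(div)
    return {
        feature: pd.DataFrame.from_dict(values, orient="index", columns=[col])
        .rename_axis("well")
        .sort_index()
        for feature, values in tables.items()
    }


def corse_results(
    plate: PlateRecording, params: CorseParams | None = None
) -> tuple[pd.Series, dict[str, "object"]]:
    """Well-mean CorSE and per-well connectivity matrices for a plate."""
    params = params or CorseParams()
    fs = plate.metadata.sampling_frequency_hz
    means, matrices = {}, {}
    for well in sorted(plate.wells):
        mean, matrix = well_corse(plate.wells[well], fs, params)
        means[well] = mean
        matrices[well] = matrix
    return pd.Series(means, name="corse_mean").rename_axis("well"), matrices


def features_from_tables(
    tables: dict[str, pd.DataFrame], group: str | None = None
) -> pd.DataFrame:
    """Melt per-feature well x DIV tables into one observation table."""
    frames = []
    renames = {**{k: v for k, v in _FEATURE_ATTR.items() if k != "nae"}, "STTC": "sttc"}
    for feature, attr in renames.items():
        melted = (
            tables[feature]
            .reset_index()
            .melt(id_vars="well", var_name="div", value_name=attr)
        )
        frames.append(melted.set_index(["well", "div"]))
    obs = pd.concat(frames, axis=1).reset_index()
    if group is not None:
        obs["group"] = group
    return obs


# ---------------------------------------------------------------------------
# Full pipeline


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    plate: PlateRecording | None = None,
    plate_path=None,
    scenario=None,
    noisy: list[tuple[str, str]] | None = None,
    group: str | None = None,
) -> dict:
    """Run every stage on one plate and write all outputs under ``out_dir``.

    Exactly one of ``plate``, ``plate_path`` or ``scenario`` must be given.
    Returns the manifest (also written as ``manifest.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    label = config.data_label
    manifest: dict = {
        "data_label": label,
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "seed": config.seed,
        "versions": _versions(),
        "stages": {},
        "outputs": [],
        "status": "running",
    }

    def _done(stage: str, **info) -> None:
        manifest["stages"][stage] = {"status": "ok", **info}
        _write_manifest(out_dir, manifest)

    try:
        if sum(x is not None for x in (plate, plate_path, scenario)) != 1:
            raise ValueError("give exactly one of plate, plate_path, scenario")
        if scenario is not None:
            from .synthetic import generate_plate

            plate, truth = generate_plate(scenario, seed=config.seed)
            plate_file = out_dir / f"{label}.h5"
            io.write_plate(plate, plate_file)
            truth_table = io.spike_table(
                [
                    (well, electrode, t)
                    for (well, electrode), times in truth.spike_times.items()
                    for t in times
                ]
            )
            io.write_spike_csv(truth_table, out_dir / f"{label}_true_spikes.csv")
            manifest["outputs"] += [str(plate_file), f"{label}_true_spikes.csv"]
            _done("simulate", wells=len(plate.wells))
        elif plate_path is not None:
            plate = io.read_plate(plate_path)
            _done("load", path=str(plate_path))

        trains = detect_plate_spikes(plate, config.detection)
        spikes = io.spike_table_from_trains(
            t for well in trains.values() for t in well.values()
        )
        spike_path = out_dir / f"{label}_spikes.csv"
        io.write_spike_csv(spikes, spike_path)
        manifest["outputs"].append(str(spike_path))
        _done("detect_spikes", n_spikes=int(len(spikes)))

        tables = well_feature_tables(
            trains,
            div=plate.metadata.div,
            noisy=noisy,
            burst_params=config.bursts,
            detection_params=config.detection,
            sttc_params=config.sttc,
        )
        for feature, table in tables.items():
            path = io.feature_table_path(out_dir, label, feature)
            io.write_feature_table(table, feature, path)
            manifest["outputs"].append(str(path))
        _done("burst_and_sttc", wells_reported=int(len(tables["nae"])))

        corse_means, corse_matrices = corse_results(plate, config.corse)
        corse_path = out_dir / f"{label}_corse_mean.csv"
        corse_means.to_csv(corse_path)
        edges = []
        for well, matrix in corse_matrices.items():
            for edge in connectivity_map(matrix, config.corse.map_threshold):
                edges.append({"well": well, **{k: edge[k] for k in ("a", "b", "strength")}})
        edge_path = out_dir / f"{label}_corse_edges.csv"
        pd.DataFrame(edges, columns=["well", "a", "b", "strength"]).to_csv(
            edge_path, index=False
        )
        manifest["outputs"] += [str(corse_path), str(edge_path)]
        _done("corse", wells=len(corse_means), edges=len(edges))

        obs = features_from_tables(tables, group=group)
        obs["plate"] = label
        complete = obs.dropna(subset=list(FEATURE_ORDER))
        if len(complete) >= max(config.n_components, 2):
            matrix, labels = assemble_features(obs)
            result = pca(zscore(matrix), config.n_components, labels=labels)
            scores_path = out_dir / f"{label}_pca_scores.csv"
            scores_frame(result).to_csv(scores_path, index=False)
            manifest["outputs"].append(str(scores_path))
            _done(
                "pca",
                n_observations=int(len(complete)),
                explained_variance_ratio=[
                    float(v) for v in result.explained_variance_ratio
                ],
            )
        else:
            manifest["stages"]["pca"] = {
                "status": "skipped",
                "reason": f"only {len(complete)} complete observation(s)",
            }
        manifest["status"] = "ok"
    except Exception as exc:  # partial outputs stay on disk with the manifest
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(out_dir, manifest)
        raise
    _write_manifest(out_dir, manifest)
    return manifest


def _versions() -> dict[str, str]:
    import h5py
    import pywt
    import scipy
    import sklearn

    from . import __version__

    return {
        "meapipe": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "h5py": h5py.__version__,
        "pywavelets": pywt.__version__,
        "scikit-learn": sklearn.__version__,
    }


def _write_manifest(out_dir: Path, manifest: dict) -> None:
    (Path(out_dir) / "manifest.json").write_text(json.dumps(manifest, indent=2))
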