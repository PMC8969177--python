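"""Well-level feature assembly, z-scoring and PCA embedding.

Each well/timepoint observation is summarised by exactly 7 features drawn
from the firing, burst and synchrony analyses: mean firing rate by active
electrodes, burst rate per minute, mean burst duration, mean spike frequency
in bursts, mean number of spikes in a burst, percentage of spikes in bursts
and the STTC.  The number of active electrodes is deliberately excluded — it
is only used to compute other parameters.  Observations are z-scored
feature-wise (pooled across all groups entering one embedding) and projected
onto the three major principal components for classification-style
visualisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

logger = logging.getLogger(__name__)

#: the 7 classification features, in fixed column order
FEATURE_ORDER = (
    "mfr_by_active_electrodes",
    "bursts_per_min",
    "mean_dur_s",
    "mean_freq_in_burst",
    "mean_spikes_in_burst",
    "per_spikes_in_burst",
    "sttc",
)

ID_COLUMNS = ("well", "plate", "div", "group")


@dataclass
class PcaResult:
    """Scores, loadings and explained-variance fractions of a PCA."""

    scores: np.ndarray  # (n_obs, n_components)
    loadings: np.ndarray  # (n_features, n_components)
    explained_variance_ratio: np.ndarray
    labels: pd.DataFrame | None = None


def assemble_features(
    table: pd.DataFrame, group_labels: pd.Series | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Build the (n_obs, 7) feature matrix from a well-stats table.

    Observations with any missing feature (e.g. wells without bursts) are
    dropped and the drop count logged; the column order is fixed regardless
    of the input table's order.
    """
    missing_cols = set(FEATURE_ORDER) - set(table.columns)
    if missing_cols:
        raise ValueError(f"feature table is missing columns {sorted(missing_cols)}")
    table = table.copy()
    if group_labels is not None:
        table["group"] = np.asarray(group_labels)
    complete = table.dropna(subset=list(FEATURE_ORDER))
    dropped = len(table) - len(complete)
    if dropped:
        logger.info("assemble_features: dropped %d incomplete observation(s)", dropped)
    if complete.empty:
        raise ValueError("no observation has all 7 features defined")
    matrix = complete.loc[:, list(FEATURE_ORDER)].to_numpy(dtype=float)
    id_cols = [c for c in ID_COLUMNS if c in complete.columns]
    return matrix, complete.loc[:, id_cols].reset_index(drop=True)


def zscore(matrix: np.ndarray) -> np.ndarray:
    """Standard-score each column to mean 0 and sample SD 1 (ddof=1)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("z-scoring needs at least 2 observations")
    sd = matrix.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [
            FEATURE_ORDER[i] if i < len(FEATURE_ORDER) else str(i) for i in zero
        ]
        raise ValueError(f"zero-variance feature column(s): {', '.join(names)}")
    return (matrix - matrix.mean(axis=0)) / sd


def pca(
    matrix: np.ndarray,
    n_components: int = 3,
    labels: pd.DataFrame | None = None,
) -> PcaResult:
    """PCA of a (normalised) feature matrix, keeping ``n_components`` PCs.

    Components are the top right-singular vectors of the centred matrix; each
    loading column's sign is fixed so its largest-magnitude entry is
    positive, preventing run-to-run mirror flips.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < n_components:
        raise ValueError(
            f"need at least {n_components} observations, got {matrix.shape[0]}"
        )
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(matrix)
    loadings = model.components_.T.copy()  # (n_features, n_components)
    for k in range(loadings.shape[1]):
        pivot = np.argmax(np.abs(loadings[:, k]))
        if loadings[pivot, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    return PcaResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=model.explained_variance_ratio_.copy(),
        labels=labels,
    )


def scores_frame(result: PcaResult) -> pd.DataFrame:
    """Scores as a DataFrame (PC1..PCk) with any observation labels."""
    cols = [f"PC{i + 1}" for i in range(result.scores.shape[1])]
    df = pd.DataFrame(result.scores, columns=cols)
    if result.labels is not None:
        df = pd.concat([result.labels.reset_index(drop=True), df], axis=1)
    return df
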