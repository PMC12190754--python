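"""Conformational states from PC scores and selection of the top loadings.

Frames are clustered in the PC1/PC2 score plane with K-means; the number of
states is picked by scanning k and maximizing the mean silhouette.  Two
loading-selection rules extract the structurally dominant variables: an
absolute threshold (|loading| >= cutoff on any considered component) and a
per-cluster top-decile rule ranked by Euclidean distance from the origin of
the loading plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .exceptions import DataError

__all__ = [
    "ClusterModel",
    "LoadingSelection",
    "silhouette_scan",
    "map_clusters_to_frames",
    "select_loadings_threshold",
    "select_loadings_top_decile",
]

logger = logging.getLogger(__name__)

#: below this mean silhouette the partition is reported but flagged as weak
WEAK_STRUCTURE_SILHOUETTE = 0.4


@dataclass
class ClusterModel:
    k: int
    labels: np.ndarray
    centers: np.ndarray
    mean_silhouette: float
    silhouette_by_k: pd.DataFrame
    seed: int
    weak_structure: bool = False


@dataclass
class LoadingSelection:
    method: str
    variables: pd.DataFrame
    per_cluster: dict[int, pd.DataFrame] | None = None
    tie_note: str | None = None


def silhouette_scan(
    scores: np.ndarray,
    k_range: range = range(2, 11),
    n_init: int = 25,
    seed: int = 0,
) -> ClusterModel:
    """Fit K-means for each k and keep the k with the best mean silhouette.

    ``scores`` is frames x d (d = 2 by default upstream: PC1/PC2).  The full
    silhouette-by-k table is retained; a best silhouette below
    ``WEAK_STRUCTURE_SILHOUETTE`` sets the ``weak_structure`` flag, meaning
    the score cloud shows no strongly separated states.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    k_values = list(k_range)
    if not k_values:
        raise ValueError("empty k range")
    if scores.shape[0] < max(k_values) + 1:
        raise DataError(
            f"need at least {max(k_values) + 1} frames to scan k up to {max(k_values)}"
        )
    rows = []
    best = None
    for k in k_values:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(scores)
        sil = float(silhouette_score(scores, labels))
        rows.append({"k": k, "mean_silhouette": sil})
        if best is None or sil > best[1]:
            best = (k, sil, labels, km.cluster_centers_)
    table = pd.DataFrame(rows)
    k, sil, labels, centers = best
    return ClusterModel(
        k=k,
        labels=labels,
        centers=centers,
        mean_silhouette=sil,
        silhouette_by_k=table,
        seed=seed,
        weak_structure=sil < WEAK_STRUCTURE_SILHOUETTE,
    )


def map_clusters_to_frames(
    model: ClusterModel, frame_labels: list[tuple[int, float]]
) -> dict[int, dict]:
    """Associate each cluster with its timestamp runs and replica makeup.

    Contiguous global-frame-index runs are compressed to (start, end) pairs;
    per cluster the replica composition and the dominant replica's share are
    reported, since conformational states often track individual replicas.
    """
    if model.labels.size == 0:
        raise DataError("cluster model has no labels")
    if len(frame_labels) != model.labels.size:
        raise DataError("frame label count differs from label count")
    out: dict[int, dict] = {}
    labels = model.labels
    for c in range(model.k):
        idx = np.flatnonzero(labels == c)
        runs: list[tuple[int, int]] = []
        start = prev = int(idx[0])
        for i in idx[1:]:
            i = int(i)
            if i == prev + 1:
                prev = i
            else:
                runs.append((start, prev))
                start = prev = i
        runs.append((start, prev))
        reps = [frame_labels[i][0] for i in idx]
        counts = pd.Series(reps).value_counts()
        out[c] = {
            "n_frames": int(idx.size),
            "runs": runs,
            "run_labels": [
                (frame_labels[a], frame_labels[b]) for a, b in runs
            ],
            "replica_counts": counts.to_dict(),
            "dominant_replica": int(counts.idxmax()),
            "dominant_replica_fraction": float(counts.max() / idx.size),
        }
    return out


def _loading_frame(
    loadings: np.ndarray, column_labels: list[tuple[int, str]]
) -> pd.DataFrame:
    df = pd.DataFrame(
        loadings, columns=[f"pc{i + 1}_loading" for i in range(loadings.shape[1])]
    )
    df.insert(0, "axis", [ax for _, ax in column_labels])
    df.insert(0, "residue_index", [res for res, _ in column_labels])
    df["distance"] = np.linalg.norm(loadings, axis=1)
    return df


def select_loadings_threshold(
    loadings: np.ndarray,
    column_labels: list[tuple[int, str]],
    cutoff: float = 0.7,
) -> LoadingSelection:
    """Select variables with |loading| >= cutoff on any considered component.

    The bound is inclusive: a loading exactly at the cutoff is selected.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    loadings = np.atleast_2d(np.asarray(loadings, dtype=float))
    df = _loading_frame(loadings, column_labels)
    mask = np.any(np.abs(loadings) >= cutoff, axis=1)
    return LoadingSelection(method="threshold", variables=df[mask].reset_index(drop=True))


def select_loadings_top_decile(
    loadings: np.ndarray,
    column_labels: list[tuple[int, str]],
    n_clusters: int,
    fraction: float = 0.10,
    seed: int = 0,
    n_init: int = 25,
) -> LoadingSelection:
    """Per-cluster top fraction of loading points by distance from the origin.

    Loading points (one per variable, coordinates = loadings on the
    considered components) are first grouped with K-means using the same k as
    the score clustering; within each group the top ``fraction`` by Euclidean
    distance from the origin is kept, with all boundary ties included.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    loadings = np.atleast_2d(np.asarray(loadings, dtype=float))
    if loadings.shape[0] < 10:
        raise DataError("need loadings for at least 10 variables")
    df = _loading_frame(loadings, column_labels)
    km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
    df["cluster"] = km.fit_predict(loadings)
    per_cluster: dict[int, pd.DataFrame] = {}
    tie_notes: list[str] = []
    selected_parts = []
    for c in sorted(df["cluster"].unique()):
        sub = df[df["cluster"] == c]
        m = int(np.ceil(fraction * len(sub)))
        ranked = sub.sort_values("distance", ascending=False, kind="mergesort")
        boundary = ranked["distance"].iloc[m - 1]
        take = ranked[ranked["distance"] >= boundary - 1e-15]
        if len(take) > m:
            tie_notes.append(
                f"cluster {c}: {len(take) - m} boundary tie(s) included"
            )
        per_cluster[int(c)] = take.reset_index(drop=True)
        selected_parts.append(take)
    note = "; ".join(tie_notes) or None
    if note:
        logger.info("top-decile selection ties: %s", note)
    return LoadingSelection(
        method="top-decile",
        variables=pd.concat(selected_parts).reset_index(drop=True),
        per_cluster=per_cluster,
        tie_note=note,
    )
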