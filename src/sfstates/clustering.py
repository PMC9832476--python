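"""Ion-configuration clustering of trajectory frames with silhouette model
selection.

Frames are described by the K+ occupancies of binding sites S0–S4 (five
features; cavity metrics are descriptive, not clustering features). Frames
are partitioned by agglomerative clustering with Euclidean distances and the
Ward linkage criterion, the number of clusters is chosen as the maximum of
the silhouette score over a candidate range, and clusters are characterized
by their feature quartiles, probabilities and a feature-space medoid
representative.

The model-fitting surface follows the statsmodels convention: build a
:class:`SiteOccupancyModel` from a feature table, call :meth:`fit`, and read
estimates off the returned :class:`StateClusteringResults` (which also
renders a ``summary()`` table). The underlying operations are plain
functions — :func:`cluster_frames`, :func:`select_k`,
:func:`summarize_clusters`, :func:`export_cluster_report` — usable on bare
arrays.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .errors import ArgumentError
from .features import FEATURE_COLUMNS, K_OCCUPANCY_COLUMNS

__all__ = [
    "FeatureMatrix", "ClusterModel", "ClusterSummary",
    "cluster_frames", "select_k", "summarize_clusters",
    "export_cluster_report", "load_cluster_report",
    "SiteOccupancyModel", "StateClusteringResults",
]

#: below this maximum silhouette the cluster structure is considered weak
LOW_CONFIDENCE_SILHOUETTE = 0.25

#: silhouette is evaluated on at most this many rows (fixed-seed subsample,
#: stratified by replica when provenance is available); exact above via
#: ``subsample=None``
DEFAULT_SILHOUETTE_SUBSAMPLE = 20_000

#: clusters larger than this use a centroid-nearest representative instead of
#: the exact (quadratic) medoid
EXACT_MEDOID_LIMIT = 4000


@dataclass
class FeatureMatrix:
    """Clustering features: one row per frame, five S0–S4 K+ occupancies.

    ``row_provenance`` records ``(replica_id, frame_index)`` per row so rows
    pooled across replicas of one system stay traceable.
    """

    values: np.ndarray
    row_provenance: list[tuple[int, int]] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 5:
            raise ArgumentError(
                f"feature matrix must be (n_frames, 5), got "
                f"{self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ArgumentError("occupancy features must be non-negative")
        if self.row_provenance is None:
            self.row_provenance = [(0, i) for i in range(len(self.values))]
        elif len(self.row_provenance) != len(self.values):
            raise ArgumentError("row_provenance length must match rows")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       replica_column: str = "replica") -> "FeatureMatrix":
        values = df[K_OCCUPANCY_COLUMNS].to_numpy(dtype=float)
        replicas = (df[replica_column] if replica_column in df.columns
                    else pd.Series(0, index=df.index))
        frames = (df["frame"] if "frame" in df.columns
                  else pd.Series(range(len(df)), index=df.index))
        provenance = list(zip(replicas.astype(int), frames.astype(int)))
        return cls(values, provenance)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ClusterModel:
    """A fitted clustering: silhouette curve, chosen k and hard labels."""

    k_candidates: list[int]
    silhouette_by_k: np.ndarray
    selected_k: int
    labels: np.ndarray
    probabilities: np.ndarray
    row_provenance: list[tuple[int, int]]
    low_confidence: bool = False

    def __post_init__(self):
        total = float(self.probabilities.sum())
        if abs(total - 1.0) > 1e-9:
            raise ArgumentError(
                f"cluster probabilities must sum to 1, got {total}")
        best = int(np.flatnonzero(
            self.silhouette_by_k == self.silhouette_by_k.max())[0])
        if self.k_candidates and self.selected_k != self.k_candidates[best]:
            raise ArgumentError(
                "selected_k must be the argmax of the silhouette curve")


@dataclass
class ClusterSummary:
    """Per-cluster characterization over the full twelve-feature table."""

    table: pd.DataFrame                 # cluster, feature, mean, q1, q3
    probabilities: np.ndarray
    representatives: list[tuple[int, int]]  # provenance of each medoid

    def cluster_frame(self) -> pd.DataFrame:
        """Wide per-cluster view: one row per cluster, mean of each feature."""
        wide = self.table.pivot(index="cluster", columns="feature",
                                values="mean")
        wide["probability"] = self.probabilities
        return wide


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..k-1 by order of first appearance (deterministic
    under any permutation of the linkage's arbitrary cluster ids)."""
    mapping: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def cluster_frames(features: FeatureMatrix | np.ndarray, k: int,
                   ) -> np.ndarray:
    """Hard partition into ``k`` clusters by Euclidean/Ward agglomeration."""
    x = features.values if isinstance(features, FeatureMatrix) else \
        np.asarray(features, dtype=float)
    n = x.shape[0]
    if k < 1 or k > n:
        raise ArgumentError(f"k must be in [1, {n}], got {k}")
    if k == n:
        return np.arange(n)
    z = linkage(x, method="ward")
    return _canonical_labels(fcluster(z, t=k, criterion="maxclust"))


def _silhouette_rows(n: int, provenance: list[tuple[int, int]],
                     subsample: int | None, seed: int) -> np.ndarray:
    if subsample is None or n <= subsample:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    replicas = np.array([p[0] for p in provenance])
    chosen: list[np.ndarray] = []
    unique = np.unique(replicas)
    per = subsample // len(unique)
    for rep in unique:
        rows = np.flatnonzero(replicas == rep)
        take = min(per, rows.size)
        chosen.append(rng.choice(rows, size=take, replace=False))
    return np.sort(np.concatenate(chosen))


def select_k(features: FeatureMatrix | np.ndarray,
             k_candidates: Sequence[int] = range(2, 16),
             subsample: int | None = DEFAULT_SILHOUETTE_SUBSAMPLE,
             random_state: int = 0) -> ClusterModel:
    """Choose the number of clusters by the maximum of the silhouette score.

    The Ward dendrogram is built once and cut at every candidate k. Ties are
    broken toward the smaller k (parsimony). When the best silhouette is
    below :data:`LOW_CONFIDENCE_SILHOUETTE` the model is flagged (and a
    warning emitted): the data do not show well-separated ion configurations.
    """
    if not isinstance(features, FeatureMatrix):
        features = FeatureMatrix(np.asarray(features, dtype=float))
    x = features.values
    n = x.shape[0]
    k_candidates = sorted(int(k) for k in k_candidates)
    if not k_candidates:
        raise ArgumentError("k_candidates must be non-empty")
    if k_candidates[0] < 2 or k_candidates[-1] > n - 1:
        raise ArgumentError(
            f"k candidates must lie within [2, n_rows-1] = [2, {n - 1}]")

    z = linkage(x, method="ward")
    rows = _silhouette_rows(n, features.row_provenance, subsample,
                            random_state)
    sub = x[rows]
    # reuse one pairwise-distance matrix across candidates when it fits
    # comfortably in memory; fall back to sklearn's chunked computation
    precomputed = len(rows) <= 8000
    if precomputed:
        dist_sq = squareform(pdist(sub), checks=False)

    labels_by_k: dict[int, np.ndarray] = {}
    scores = np.empty(len(k_candidates))
    for i, k in enumerate(k_candidates):
        labels = _canonical_labels(fcluster(z, t=k, criterion="maxclust"))
        labels_by_k[k] = labels
        sub_labels = labels[rows]
        if np.unique(sub_labels).size < 2:
            scores[i] = -1.0  # degenerate cut on the subsample
        elif precomputed:
            scores[i] = silhouette_score(dist_sq, sub_labels,
                                         metric="precomputed")
        else:
            scores[i] = silhouette_score(sub, sub_labels)

    best = int(np.flatnonzero(scores == scores.max())[0])  # tie -> smaller k
    selected_k = k_candidates[best]
    labels = labels_by_k[selected_k]
    counts = np.bincount(labels, minlength=selected_k)
    low = bool(scores[best] < LOW_CONFIDENCE_SILHOUETTE)
    if low:
        warnings.warn(
            f"maximum silhouette {scores[best]:.3f} < "
            f"{LOW_CONFIDENCE_SILHOUETTE}: weak cluster structure, the "
            f"selected k={selected_k} has low confidence",
            UserWarning, stacklevel=2,
        )
    return ClusterModel(
        k_candidates=k_candidates, silhouette_by_k=scores,
        selected_k=selected_k, labels=labels,
        probabilities=counts / counts.sum(),
        row_provenance=list(features.row_provenance),
        low_confidence=low,
    )


def _medoid_row(block: np.ndarray) -> int:
    """Index (within block) of the row minimizing total distance to the
    others; falls back to nearest-to-centroid for very large clusters."""
    m = block.shape[0]
    if m > EXACT_MEDOID_LIMIT:
        centroid = block.mean(axis=0)
        return int(np.argmin(np.linalg.norm(block - centroid, axis=1)))
    d = np.linalg.norm(block[:, None, :] - block[None, :, :], axis=-1)
    return int(np.argmin(d.sum(axis=1)))


def summarize_clusters(model: ClusterModel,
                       full_features: pd.DataFrame) -> ClusterSummary:
    """Quartile/probability characterization of each cluster.

    ``full_features`` holds one row per clustered frame with the twelve
    feature columns (five K+ occupancies, five oxygen coordinations, cavity
    K+ presence, cavity hydration). Quartiles use linear interpolation; the
    representative frame is the medoid in the five-dimensional clustering
    feature space.
    """
    if len(full_features) != len(model.labels):
        raise ArgumentError(
            f"feature rows ({len(full_features)}) do not align with labels "
            f"({len(model.labels)})"
        )
    missing = [c for c in FEATURE_COLUMNS if c not in full_features.columns]
    if missing:
        raise ArgumentError(f"full feature table lacks columns {missing}")

    x_cluster = full_features[K_OCCUPANCY_COLUMNS].to_numpy(dtype=float)
    records = []
    representatives = []
    for cluster in range(model.selected_k):
        rows = np.flatnonzero(model.labels == cluster)
        block = full_features.iloc[rows]
        for feature in FEATURE_COLUMNS:
            v = block[feature].to_numpy(dtype=float)
            records.append({
                "cluster": cluster, "feature": feature,
                "mean": float(v.mean()),
                "q1": float(np.percentile(v, 25)),
                "q3": float(np.percentile(v, 75)),
            })
        medoid = rows[_medoid_row(x_cluster[rows])]
        representatives.append(tuple(model.row_provenance[medoid]))
    return ClusterSummary(pd.DataFrame.from_records(records),
                          model.probabilities.copy(), representatives)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def export_cluster_report(summary: ClusterSummary, directory: str,
                          ) -> dict[str, str]:
    """Write the cluster summary as JSON (exact) and CSV (tabular).

    The JSON file round-trips exactly through :func:`load_cluster_report`.
    """
    os.makedirs(directory, exist_ok=True)
    json_path = os.path.join(directory, "cluster_summary.json")
    csv_path = os.path.join(directory, "cluster_summary.csv")
    payload = {
        "probabilities": [float(p) for p in summary.probabilities],
        "representatives": [list(map(int, r))
                            for r in summary.representatives],
        "table": summary.table.to_dict(orient="records"),
    }
    try:
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1)
        summary.table.to_csv(csv_path, index=False)
    except OSError as exc:
        raise ArgumentError(f"cannot write report to {directory}: {exc}"
                            ) from exc
    return {"json": json_path, "csv": csv_path}


def load_cluster_report(json_path: str) -> ClusterSummary:
    with open(json_path) as fh:
        payload = json.load(fh)
    table = pd.DataFrame.from_records(payload["table"])
    if len(table):
        table = table[["cluster", "feature", "mean", "q1", "q3"]]
    return ClusterSummary(
        table, np.asarray(payload["probabilities"], dtype=float),
        [tuple(r) for r in payload["representatives"]],
    )


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class SiteOccupancyModel:
    """Ion-configuration state model over a per-frame feature table.

    Parameters
    ----------
    features : pandas.DataFrame
        Per-frame feature table with (at least) the five S0–S4 K+ occupancy
        columns; the full twelve-column table enables cluster summaries.
    k_candidates : sequence of int
        Cluster counts scored by silhouette (default 2–15).
    """

    def __init__(self, features: pd.DataFrame,
                 k_candidates: Sequence[int] = range(2, 16)):
        missing = [c for c in K_OCCUPANCY_COLUMNS
                   if c not in features.columns]
        if missing:
            raise ArgumentError(
                f"feature table lacks occupancy columns {missing}")
        self.features = features.reset_index(drop=True)
        self.k_candidates = list(k_candidates)
        self.feature_matrix = FeatureMatrix.from_dataframe(self.features)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs):
        return cls(df, **kwargs)

    def fit(self, subsample: int | None = DEFAULT_SILHOUETTE_SUBSAMPLE,
            random_state: int = 0) -> "StateClusteringResults":
        model = select_k(self.feature_matrix, self.k_candidates,
                         subsample=subsample, random_state=random_state)
        summary = None
        if all(c in self.features.columns for c in FEATURE_COLUMNS):
            summary = summarize_clusters(model, self.features)
        return StateClusteringResults(self, model, summary)


class StateClusteringResults:
    """Fitted state-clustering results.

    Attributes
    ----------
    cluster_model : ClusterModel
        Labels, silhouette curve, selected k, probabilities.
    cluster_summary : ClusterSummary or None
        Quartile characterization (present when the model was built from the
        full twelve-feature table).
    """

    def __init__(self, model: SiteOccupancyModel,
                 cluster_model: ClusterModel,
                 cluster_summary: ClusterSummary | None):
        self.model = model
        self.cluster_model = cluster_model
        self.cluster_summary = cluster_summary

    @property
    def selected_k(self) -> int:
        return self.cluster_model.selected_k

    @property
    def labels(self) -> np.ndarray:
        return self.cluster_model.labels

    @property
    def probabilities(self) -> np.ndarray:
        return self.cluster_model.probabilities

    @property
    def silhouette_curve(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.cluster_model.k_candidates,
            "silhouette": self.cluster_model.silhouette_by_k,
        })

    def summary(self) -> str:
        """Human-readable fit summary (silhouette curve and cluster table)."""
        cm = self.cluster_model
        lines = [
            "Selectivity-filter ion-configuration clustering",
            "=" * 47,
            f"frames: {len(cm.labels)}    candidates: "
            f"{cm.k_candidates[0]}..{cm.k_candidates[-1]}",
            f"selected k (max silhouette): {cm.selected_k}"
            + ("   [low confidence]" if cm.low_confidence else ""),
            "",
            "k    silhouette",
        ]
        for k, s in zip(cm.k_candidates, cm.silhouette_by_k):
            marker = "  <-- selected" if k == cm.selected_k else ""
            lines.append(f"{k:<4d} {s: .4f}{marker}")
        lines.append("")
        lines.append("cluster  probability  mean occupancy S0..S4")
        x = self.model.feature_matrix.values
        for c in range(cm.selected_k):
            occ = x[cm.labels == c].mean(axis=0)
            occ_str = " ".join(f"{v:5.2f}" for v in occ)
            lines.append(f"{c:<8d} {cm.probabilities[c]:<12.4f} {occ_str}")
        return "\n".join(lines)

    def export(self, directory: str) -> dict[str, str]:
        """Write model JSON, labels CSV, silhouette CSV and summary files."""
        os.makedirs(directory, exist_ok=True)
        cm = self.cluster_model
        paths = {}
        model_path = os.path.join(directory, "cluster_model.json")
        with open(model_path, "w") as fh:
            json.dump({
                "k_candidates": cm.k_candidates,
                "silhouette_by_k": [float(s) for s in cm.silhouette_by_k],
                "selected_k": int(cm.selected_k),
                "probabilities": [float(p) for p in cm.probabilities],
                "low_confidence": cm.low_confidence,
            }, fh, indent=1)
        paths["model"] = model_path
        labels_path = os.path.join(directory, "labels.csv")
        pd.DataFrame({
            "replica": [p[0] for p in cm.row_provenance],
            "frame": [p[1] for p in cm.row_provenance],
            "cluster": cm.labels,
        }).to_csv(labels_path, index=False)
        paths["labels"] = labels_path
        curve_path = os.path.join(directory, "silhouette_curve.csv")
        self.silhouette_curve.to_csv(curve_path, index=False)
        paths["silhouette"] = curve_path
        if self.cluster_summary is not None:
            paths.update(export_cluster_report(self.cluster_summary,
                                               directory))
        return paths
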