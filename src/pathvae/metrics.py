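"""Integration quality metrics: ARI, NMI, cell-type ASW, isolated-label F1
and silhouette.

ARI and NMI compare a k-means clustering of the embedding against the
cell-type labels; ASW rescales the mean cell-type silhouette to [0, 1] via
(1 + s) / 2; isolated-label F1 measures whether dataset-specific cell types
(those present in the fewest batches) form their own clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    silhouette_samples,
)

__all__ = [
    "MetricsReport",
    "adjusted_rand_index",
    "normalized_mutual_info",
    "silhouette_per_cell",
    "asw_celltype",
    "isolated_label_f1",
    "evaluate_all",
]


def _check_lengths(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b)
    if len(a) != len(b):
        raise ValueError(f"labelings differ in length: {len(a)} vs {len(b)}")
    return a, b


def adjusted_rand_index(truth, pred) -> float:
    """Chance-adjusted pair-counting agreement, (RI - E[RI]) / (max RI - E[RI]),
    via the standard contingency-table closed form.  Symmetric and invariant
    to label renaming; 1 for identical partitions."""
    truth, pred = _check_lengths(truth, pred)
    return float(adjusted_rand_score(truth, pred))


def normalized_mutual_info(truth, pred) -> float:
    """Mutual information normalized by the geometric mean of the Shannon
    entropies, I(P;T) / sqrt(H(P) H(T)).

    If either labeling has a single category the normalizer vanishes; the
    value is defined as 1 when both partitions are the (identical) trivial
    one-block partition and 0 otherwise, with a warning.
    """
    truth, pred = _check_lengths(truth, pred)
    one_t = len(np.unique(truth)) == 1
    one_p = len(np.unique(pred)) == 1
    if one_t or one_p:
        if one_t and one_p:
            return 1.0
        warnings.warn(
            "single-category labeling: NMI normalizer is zero; returning 0",
            stacklevel=2,
        )
        return 0.0
    return float(
        normalized_mutual_info_score(truth, pred, average_method="geometric")
    )


def silhouette_per_cell(
    embedding: np.ndarray, labels, metric: str = "euclidean"
) -> np.ndarray:
    """Per-cell silhouette s_i = (b - a) / max(a, b) with a the mean
    intra-cluster and b the mean nearest-cluster distance; cells in singleton
    clusters score 0."""
    embedding = np.asarray(embedding, dtype=np.float64)
    labels = np.asarray(labels)
    if len(labels) != embedding.shape[0]:
        raise ValueError("labels length must equal the number of cells")
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return silhouette_samples(embedding, labels, metric=metric)


def asw_celltype(embedding: np.ndarray, celltype_labels) -> float:
    """Cell-type average silhouette width rescaled to [0, 1]:
    (1 + mean silhouette) / 2."""
    s = silhouette_per_cell(embedding, celltype_labels)
    return float((1.0 + s.mean()) / 2.0)


def _default_k_grid(n_types: int) -> list[int]:
    return list(range(max(2, n_types - 2), n_types + 3))


def isolated_label_f1(
    embedding: np.ndarray,
    celltype_labels,
    batch_labels,
    k_grid: list[int] | None = None,
    seed: int = 0,
) -> float:
    """F1 score for dataset-specific ("isolated") cell types.

    Isolated labels are the cell types present in the fewest batches (if all
    types share the minimum they are all treated as isolated).  The embedding
    is clustered by k-means for each k in ``k_grid``; for each isolated label
    the F1 of "cell is in this cluster" as a predictor of "cell has this
    label" is maximized over clusters and over k.  The score is the mean over
    isolated labels; 1 means every dataset-specific type sits in its own pure
    cluster.
    """
    embedding = np.asarray(embedding, dtype=np.float64)
    celltype_labels = np.asarray(celltype_labels)
    if batch_labels is None:
        raise ValueError("batch labels are required: isolation is undefined")
    batch_labels = np.asarray(batch_labels)
    if not (len(celltype_labels) == len(batch_labels) == embedding.shape[0]):
        raise ValueError("labels must match the number of cells")

    presence = (
        pd.DataFrame({"type": celltype_labels, "batch": batch_labels})
        .groupby("type", observed=True)["batch"]
        .nunique()
    )
    isolated = presence.index[presence == presence.min()]
    types = np.unique(celltype_labels)
    if k_grid is None:
        k_grid = _default_k_grid(len(types))

    n = embedding.shape[0]
    best = {lab: 0.0 for lab in isolated}
    for k in k_grid:
        k = min(k, n)
        clusters = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(
            embedding
        )
        for lab in isolated:
            truth = celltype_labels == lab
            for c in range(k):
                pred = clusters == c
                tp = np.sum(truth & pred)
                if tp == 0:
                    continue
                precision = tp / pred.sum()
                recall = tp / truth.sum()
                f1 = 2 * precision * recall / (precision + recall)
                best[lab] = max(best[lab], f1)
    return float(np.mean(list(best.values())))


@dataclass
class MetricsReport:
    """The five integration metrics plus the configuration that produced them."""

    ari: float
    nmi: float
    asw_celltype: float
    isolated_f1: float
    silhouette: float
    config: dict

    def to_frame(self) -> pd.DataFrame:
        d = asdict(self)
        d.pop("config")
        return pd.DataFrame(
            {"metric": list(d), "value": [d[k] for k in d]}
        )


def evaluate_all(
    embedding: np.ndarray,
    celltype_labels,
    batch_labels,
    n_clusters: int | None = None,
    k_grid: list[int] | None = None,
    seed: int = 0,
) -> MetricsReport:
    """Compute the full metric panel on an embedding.

    ARI and NMI compare the cell-type labels with a k-means clustering of the
    embedding (k = number of cell types unless overridden, fixed seed); ASW
    and silhouette use the cell-type labels directly; isolated-label F1 uses
    both label sets.
    """
    embedding = np.asarray(getattr(embedding, "values", embedding), dtype=np.float64)
    celltype_labels = np.asarray(celltype_labels)
    types = np.unique(celltype_labels)
    k = n_clusters or len(types)
    clusters = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(
        embedding
    )
    sil = silhouette_per_cell(embedding, celltype_labels)
    return MetricsReport(
        ari=adjusted_rand_index(celltype_labels, clusters),
        nmi=normalized_mutual_info(celltype_labels, clusters),
        asw_celltype=float((1.0 + sil.mean()) / 2.0),
        isolated_f1=isolated_label_f1(
            embedding, celltype_labels, batch_labels, k_grid=k_grid, seed=seed
        ),
        silhouette=float(sil.mean()),
        config={
            "clustering": "kmeans",
            "n_clusters": int(k),
            "seed": int(seed),
            "k_grid": k_grid or _default_k_grid(len(types)),
        },
    )
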