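"""Cross-batch cell-type annotation by KNN label transfer in the latent
space, plus confusion-matrix reporting."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = ["knn_transfer", "confusion"]


def knn_transfer(
    reference_embedding: np.ndarray,
    reference_labels,
    query_embedding: np.ndarray,
    k: int = 15,
) -> np.ndarray:
    """Predict each query cell's type from its k Euclidean nearest reference
    cells by majority vote.

    Ties in vote count are broken by the smaller summed neighbor distance,
    then by lexicographic label order.
    """
    ref = np.asarray(getattr(reference_embedding, "values", reference_embedding),
                     dtype=np.float64)
    qry = np.asarray(getattr(query_embedding, "values", query_embedding),
                     dtype=np.float64)
    labels = np.asarray(reference_labels)
    if ref.shape[0] == 0:
        raise ValueError("reference embedding is empty")
    if len(labels) != ref.shape[0]:
        raise ValueError("reference labels must match the reference size")
    if ref.shape[1] != qry.shape[1]:
        raise ValueError("reference and query dimensions differ")
    if k < 1 or k > ref.shape[0]:
        raise ValueError(f"k={k} must be in [1, {ref.shape[0]}]")

    nn = NearestNeighbors(n_neighbors=k, metric="euclidean").fit(ref)
    dist, idx = nn.kneighbors(qry)

    out = np.empty(qry.shape[0], dtype=labels.dtype)
    for i in range(qry.shape[0]):
        neigh_labels = labels[idx[i]]
        neigh_dist = dist[i]
        # sort key: (-count, summed distance, label) — all ascending
        scores: dict = {}
        for lab in np.unique(neigh_labels):
            sel = neigh_labels == lab
            scores[lab] = (-int(sel.sum()), float(neigh_dist[sel].sum()), str(lab))
        out[i] = min(scores, key=scores.get)
    return out


def confusion(true_labels, predicted_labels) -> pd.DataFrame:
    """Confusion matrix of counts, rows = true types, columns = predicted
    types, both axes sorted lexicographically; per-class recall is the row
    normalization."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors differ in length")
    cats = sorted(set(map(str, true_labels)) | set(map(str, predicted_labels)))
    table = pd.crosstab(
        pd.Categorical(true_labels.astype(str), categories=cats),
        pd.Categorical(predicted_labels.astype(str), categories=cats),
        dropna=False,
    )
    table.index.name = "true"
    table.columns.name = "predicted"
    return table
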