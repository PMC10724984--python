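"""Pathway-level interpretability.

Because each latent dimension is a pathway and the decoder is linear, the
posterior mean embedding reads as a per-cell pathway activity table, subsets
of pathway columns are themselves valid embeddings, and sorting a pathway's
decoder weights ranks genes by their contribution to it — including genes
the prior did not annotate to that pathway.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from anndata import AnnData

from .knowledge import PathwayGeneMatrix
from .model import PathwayVAE

__all__ = ["pathway_activity", "select_pathways", "rank_genes_for_pathway"]


def pathway_activity(model: PathwayVAE, adata: AnnData,
                     batch_key: str = "batch") -> pd.DataFrame:
    """Per-cell pathway activities: the transform output (posterior means)
    with pathway-named columns; cell-type labels, when present, are attached
    as ``attrs["cell_type"]`` for downstream grouping."""
    table = model.transform(adata, adata.obs[batch_key].astype(str).to_numpy())
    if "cell_type" in adata.obs:
        table.attrs["cell_type"] = adata.obs["cell_type"].astype(str).tolist()
    return table


def select_pathways(table: pd.DataFrame, patterns: list[str]) -> pd.DataFrame:
    """Restrict an activity table to pathways whose name contains any of the
    given patterns (case-insensitive substring), preserving column order.
    The result is a valid embedding for the metrics module."""
    if not patterns:
        raise ValueError("at least one pattern is required")
    pats = [p.upper() for p in patterns]
    keep = [c for c in table.columns if any(p in c.upper() for p in pats)]
    if not keep:
        raise ValueError(
            f"no pathway matches {patterns!r}; available: {list(table.columns)}"
        )
    out = table[keep]
    out.attrs = dict(table.attrs)
    return out


def rank_genes_for_pathway(
    weights: np.ndarray | PathwayVAE,
    adjacency: PathwayGeneMatrix,
    pathway: str,
    top_k: int = 20,
    mode: str = "signed",
) -> pd.DataFrame:
    """Rank genes by their decoder weight for one pathway.

    ``mode="signed"`` sorts by the weight itself, ``"absolute"`` by its
    magnitude; ties keep input gene order.  Each row carries an ``in_prior``
    flag marking whether the adjacency annotates the gene to the pathway, so
    high-ranking unannotated genes stand out as candidate novel members.
    """
    if isinstance(weights, PathwayVAE):
        weights = weights.decoder_weights
    w = np.asarray(weights)
    if mode not in ("signed", "absolute"):
        raise ValueError("mode must be 'signed' or 'absolute'")
    if top_k < 1:
        raise ValueError("top_k must be positive")
    try:
        p = adjacency.pathway_names.index(pathway)
    except ValueError:
        raise KeyError(
            f"unknown pathway {pathway!r}; available: {adjacency.pathway_names}"
        ) from None
    row = w[p]
    key = row if mode == "signed" else np.abs(row)
    order = np.argsort(-key, kind="stable")[:top_k]
    return pd.DataFrame(
        {
            "pathway": pathway,
            "rank": np.arange(1, len(order) + 1),
            "gene": [adjacency.gene_symbols[j] for j in order],
            "weight": row[order],
            "in_prior": adjacency.matrix[p, order] > 0,
        }
    )
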