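"""Shared fixtures: one default synthetic study (two batches, four cell
types, ten pathway programs) and models trained on it.

Training-based fixtures are session-scoped because several test modules and
the acceptance suite score the same trained models.
"""

from __future__ import annotations

import numpy as np
import pytest

import pathvae as pv
from pathvae.model import PathwayVAE, TrainConfig
from pathvae.preprocess import PreprocessConfig, run_pipeline

SEED = 1


@pytest.fixture(scope="session")
def truth():
    return pv.make_truth(seed=SEED)


@pytest.fixture(scope="session")
def counts(truth):
    return pv.simulate_counts(truth, n_cells_per_type_per_batch=100, seed=SEED)


def preprocess_small(adata):
    """Preprocess the 200-gene fixture: thresholds scaled to its size
    (the genome-scale defaults assume >20k genes)."""
    return run_pipeline(
        adata, PreprocessConfig(min_genes=0, min_cells=3, n_top_hvg=200)
    )


@pytest.fixture(scope="session")
def processed(counts):
    return preprocess_small(counts)


def align_truth(truth, adjacency):
    """A_true reindexed to a built adjacency's pathway/gene order."""
    gidx = {g: i for i, g in enumerate(truth.adjacency.gene_symbols)}
    pidx = {p: i for i, p in enumerate(truth.adjacency.pathway_names)}
    rows = [pidx[p] for p in adjacency.pathway_names]
    cols = [gidx[g] for g in adjacency.gene_symbols]
    return truth.adjacency.matrix[np.ix_(rows, cols)]


@pytest.fixture(scope="session")
def adjacency(truth, processed):
    return pv.build_adjacency(
        truth.adjacency.to_gene_sets(), list(processed.var_names), min_overlap=5
    )


@pytest.fixture(scope="session")
def a_true(truth, adjacency):
    return align_truth(truth, adjacency)


def train(adjacency, adata, mode="l2", seed=SEED, **kw):
    lam = kw.pop("lambda_k", 0.0 if mode == "none" else 1.0)
    cfg = TrainConfig(knowledge_mode=mode, lambda_k=lam, seed=seed, **kw)
    return PathwayVAE(adjacency, cfg).fit(adata)


@pytest.fixture(scope="session")
def model_l2(adjacency, processed):
    return train(adjacency, processed, "l2")


@pytest.fixture(scope="session")
def model_none(adjacency, processed):
    return train(adjacency, processed, "none")


@pytest.fixture(scope="session")
def embedding_l2(model_l2, processed):
    return model_l2.transform(processed)
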