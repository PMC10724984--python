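"""Synthetic multi-batch scRNA-seq generator with known ground truth.

Emulates the study conditions the model is meant for: several cell types
whose identity is driven by pathway-level gene programs, measured across
batches that differ by multiplicative per-gene technical factors, with
negative-binomial counting noise.  The ground truth (pathway-gene adjacency,
per-type programs, batch factors) is retained so parameter recovery and
integration quality can be scored exactly.

Also provides the robustness perturbations: binomial count downsampling,
cell subsampling, and per-batch cell-type holdout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from .knowledge import GeneSet, PathwayGeneMatrix, write_gmt

__all__ = [
    "SyntheticTruth",
    "make_truth",
    "simulate_counts",
    "downsample_counts",
    "subsample_cells",
    "holdout_cell_types",
    "write_fixture",
]


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated study.

    adjacency
        True pathway-gene membership A_true (P x G binary).
    type_programs
        T x P nonnegative pathway activities per cell type.
    gene_baseline
        Per-gene log baseline expression.
    batch_factors
        B x G positive multiplicative technical factors.
    dispersion
        Shared negative-binomial dispersion (inverse overdispersion);
        ``inf`` gives the Poisson limit.
    """

    adjacency: PathwayGeneMatrix
    type_programs: np.ndarray
    gene_baseline: np.ndarray
    batch_factors: np.ndarray
    dispersion: float
    seed: int
    type_names: list[str]
    batch_names: list[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.adjacency.matrix.sum(axis=1) < 1).any():
            raise ValueError("every true pathway needs at least one gene")
        if (np.asarray(self.type_programs).sum(axis=1) <= 0).any():
            raise ValueError("every cell type needs at least one active pathway")


def make_truth(
    n_pathways: int = 10,
    n_genes: int = 200,
    n_types: int = 4,
    n_batches: int = 2,
    genes_per_pathway: int = 15,
    pathways_per_type: int = 3,
    batch_sigma: float = 0.7,
    dispersion: float = 10.0,
    seed: int = 0,
) -> SyntheticTruth:
    """Draw a reproducible ground truth.

    Pathways occupy disjoint blocks of ``genes_per_pathway`` genes over a
    random gene permutation (so Σ A_true = n_pathways * genes_per_pathway);
    each cell type activates ``pathways_per_type`` pathways — one unique
    anchor pathway per type plus random extras — with activities ~ U(0.8,
    1.5); batch factors are log-normal with stdev ``batch_sigma``.
    """
    if n_pathways * genes_per_pathway > n_genes:
        raise ValueError("pathway blocks exceed the gene universe")
    if n_types > n_pathways:
        raise ValueError("need at least one anchor pathway per cell type")
    rng = np.random.default_rng(seed)

    genes = [f"G{j:04d}" for j in range(n_genes)]
    pathways = [f"PW{p:02d}" for p in range(n_pathways)]
    perm = rng.permutation(n_genes)
    A = np.zeros((n_pathways, n_genes))
    for p in range(n_pathways):
        block = perm[p * genes_per_pathway:(p + 1) * genes_per_pathway]
        A[p, block] = 1.0

    programs = np.zeros((n_types, n_pathways))
    for t in range(n_types):
        extra = rng.choice(
            [p for p in range(n_pathways) if p != t],
            size=max(0, pathways_per_type - 1),
            replace=False,
        )
        active = np.concatenate([[t], extra]).astype(int)
        programs[t, active] = rng.uniform(0.8, 1.5, size=len(active))

    baseline = rng.uniform(np.log(0.5), np.log(3.0), size=n_genes)
    factors = np.exp(rng.normal(0.0, batch_sigma, size=(n_batches, n_genes)))

    return SyntheticTruth(
        adjacency=PathwayGeneMatrix(A, pathways, genes),
        type_programs=programs,
        gene_baseline=baseline,
        batch_factors=factors,
        dispersion=float(dispersion),
        seed=seed,
        type_names=[f"type{t}" for t in range(n_types)],
        batch_names=[f"batch{b}" for b in range(n_batches)],
        params={
            "n_pathways": n_pathways,
            "n_genes": n_genes,
            "n_types": n_types,
            "n_batches": n_batches,
            "genes_per_pathway": genes_per_pathway,
            "pathways_per_type": pathways_per_type,
            "batch_sigma": batch_sigma,
            "dispersion": dispersion,
            "seed": seed,
        },
    )


def simulate_counts(
    truth: SyntheticTruth,
    n_cells_per_type_per_batch: int = 100,
    seed: int = 0,
) -> AnnData:
    """Draw a count matrix from the truth.

    The per-cell mean is exp(baseline + program(type) . A_true) scaled by the
    batch factor; counts are negative-binomial with the truth's dispersion
    (gamma-Poisson mixture; Poisson in the infinite-dispersion limit).
    """
    rng = np.random.default_rng(seed)
    A = truth.adjacency.matrix
    T, B = len(truth.type_names), len(truth.batch_names)
    n = n_cells_per_type_per_batch

    rows, batches, types = [], [], []
    for b in range(B):
        for t in range(T):
            mean = np.exp(truth.gene_baseline + truth.type_programs[t] @ A)
            mean = mean * truth.batch_factors[b]
            lam = np.broadcast_to(mean, (n, len(mean)))
            if np.isinf(truth.dispersion):
                counts = rng.poisson(lam)
            else:
                shape = truth.dispersion
                lam = rng.gamma(shape, lam / shape)
                counts = rng.poisson(lam)
            rows.append(counts)
            batches += [truth.batch_names[b]] * n
            types += [truth.type_names[t]] * n

    X = np.vstack(rows).astype(np.float64)
    adata = AnnData(
        X=X,
        obs=pd.DataFrame(
            {"batch": batches, "cell_type": types},
            index=[f"cell{i:05d}" for i in range(X.shape[0])],
        ),
        var=pd.DataFrame(index=truth.adjacency.gene_symbols),
    )
    adata.layers["counts"] = X.copy()
    return adata


def _raw_counts(adata: AnnData) -> np.ndarray:
    X = adata.layers["counts"] if "counts" in adata.layers else adata.X
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    return X


def downsample_counts(
    adata: AnnData, keep_fraction: float, seed: int = 0
) -> AnnData:
    """Binomial thinning: each raw count is replaced by
    Binomial(count, keep_fraction), emulating random loss of sequenced
    molecules.  Expected total = keep_fraction x input total."""
    if not 0.0 <= keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    counts = _raw_counts(adata).astype(np.int64)
    thinned = rng.binomial(counts, keep_fraction).astype(np.float64)
    out = adata.copy()
    out.X = thinned.copy()
    out.layers["counts"] = thinned.copy()
    return out


def subsample_cells(
    adata: AnnData,
    keep_fraction: float,
    seed: int = 0,
    stratify_by: str | None = None,
) -> AnnData:
    """Sample cells without replacement, optionally stratified by an obs
    column so per-group proportions are preserved to rounding."""
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = adata.n_obs
    if stratify_by is None:
        keep = np.sort(rng.choice(n, size=round(keep_fraction * n), replace=False))
    else:
        groups = adata.obs[stratify_by].astype(str).to_numpy()
        picked = []
        for g in np.unique(groups):
            idx = np.flatnonzero(groups == g)
            picked.append(
                rng.choice(idx, size=round(keep_fraction * len(idx)), replace=False)
            )
        keep = np.sort(np.concatenate(picked))
    return adata[keep].copy()


def holdout_cell_types(adata: AnnData, plan: dict[str, str]) -> AnnData:
    """Remove every cell whose (batch, cell type) pair appears in the plan —
    the dataset-specific-type stress test.  The plan maps batch name to the
    cell type to drop from that batch."""
    batches = adata.obs["batch"].astype(str).to_numpy()
    types = adata.obs["cell_type"].astype(str).to_numpy()
    known = set(batches)
    for b in plan:
        if b not in known:
            raise ValueError(f"plan references unknown batch {b!r}")
    drop = np.zeros(adata.n_obs, dtype=bool)
    for b, t in plan.items():
        drop |= (batches == b) & (types == t)
    return adata[~drop].copy()


def write_fixture(truth: SyntheticTruth, adata: AnnData,
                  directory: str | Path) -> Path:
    """Write a self-contained pipeline input: Matrix Market counts, TSV cell
    and gene metadata, a GMT file expressing A_true, and a manifest with all
    generator parameters."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    counts = sp.csr_matrix(_raw_counts(adata).astype(np.int64))
    scipy.io.mmwrite(str(directory / "matrix.mtx"), counts)
    adata.obs[["batch", "cell_type"]].rename_axis("cell_id").to_csv(
        directory / "cells.tsv", sep="\t"
    )
    pd.DataFrame({"gene": adata.var_names}).to_csv(
        directory / "genes.tsv", sep="\t", index=False
    )
    write_gmt(truth.adjacency.to_gene_sets(), directory / "pathways.gmt")
    (directory / "manifest.json").write_text(
        json.dumps(truth.params, indent=2) + "\n"
    )
    return directory
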