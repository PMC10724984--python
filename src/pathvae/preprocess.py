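"""The preprocessing recipe: cell filter, gene filter, total-count
normalization, log1p, and top-n highly-variable-gene selection.

All operations take and return :class:`anndata.AnnData`; raw counts are kept
in ``layers["counts"]`` from normalization onward so count-level perturbations
(e.g. binomial downsampling) can still operate on integers.  Cell metadata
columns ``batch`` and ``cell_type`` are carried through untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "PreprocessConfig",
    "filter_cells",
    "filter_genes",
    "normalize_total",
    "log1p",
    "select_hvg",
    "run_pipeline",
]


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing recipe (defaults follow the standard
    scanpy workflow for genome-scale data)."""

    min_genes: int = 600
    min_cells: int = 3
    n_top_hvg: int = 2000
    hvg_bins: int = 20

    def to_dict(self) -> dict:
        return asdict(self)


def _dense(x) -> np.ndarray:
    return x.toarray() if sp.issparse(x) else np.asarray(x)


def filter_cells(adata: AnnData, min_genes: int = 600) -> AnnData:
    """Keep cells expressing at least ``min_genes`` genes (count > 0).

    Inclusive threshold; cell order preserved; labels subset consistently.
    """
    if min_genes < 0:
        raise ValueError("min_genes must be nonnegative")
    n_genes_per_cell = np.asarray((_counts_layer(adata) > 0).sum(axis=1)).ravel()
    keep = n_genes_per_cell >= min_genes
    if not keep.any():
        raise ValueError(
            f"min_genes={min_genes} removes every cell; observed per-cell "
            f"gene counts range from {int(n_genes_per_cell.min())} to "
            f"{int(n_genes_per_cell.max())}"
        )
    return adata[keep].copy()


def filter_genes(adata: AnnData, min_cells: int = 3) -> AnnData:
    """Keep genes expressed (count > 0) in at least ``min_cells`` cells."""
    if min_cells < 0:
        raise ValueError("min_cells must be nonnegative")
    n_cells_per_gene = np.asarray((_counts_layer(adata) > 0).sum(axis=0)).ravel()
    keep = n_cells_per_gene >= min_cells
    if not keep.any():
        raise ValueError(
            f"min_cells={min_cells} removes every gene; observed per-gene "
            f"cell counts range from {int(n_cells_per_gene.min())} to "
            f"{int(n_cells_per_gene.max())}"
        )
    return adata[:, keep].copy()


def _counts_layer(adata: AnnData):
    return adata.layers["counts"] if "counts" in adata.layers else adata.X


def normalize_total(adata: AnnData) -> AnnData:
    """Scale each cell so its total equals the median of per-cell totals.

    The raw counts are retained in ``layers["counts"]``.  A zero-total cell is
    an error (it should have been removed by the cell filter).
    """
    out = adata.copy()
    totals = np.asarray(out.X.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        n_zero = int((totals <= 0).sum())
        raise ValueError(
            f"{n_zero} cell(s) have zero total counts; filter cells first"
        )
    if "counts" not in out.layers:
        out.layers["counts"] = out.X.copy()
    sc.pp.normalize_total(out)
    return out


def log1p(adata: AnnData) -> AnnData:
    """Natural-log(1 + x), elementwise."""
    out = adata.copy()
    # scanpy marks log1p in uns; keep that behaviour for downstream tools
    sc.pp.log1p(out)
    return out


def select_hvg(
    adata: AnnData, n_top: int = 2000, n_bins: int = 20
) -> pd.DataFrame:
    """Dispersion-based highly-variable-gene selection on log data.

    Per-gene mean and dispersion (variance/mean) are computed on expm1 of the
    log-normalized values; genes are binned by mean into ``n_bins``
    equal-frequency bins and the dispersion is z-scored within each bin
    (scanpy's "seurat" flavor).  The top ``n_top`` genes by normalized
    dispersion are flagged, ties broken by input gene order; if fewer than
    ``n_top`` genes exist, all are flagged with a warning.

    Returns a per-gene report with columns ``means``, ``dispersions``,
    ``dispersions_norm`` and ``highly_variable``, indexed by gene.
    """
    if n_top < 1:
        raise ValueError("n_top must be a positive integer")
    stats = sc.pp.highly_variable_genes(
        adata, flavor="seurat", n_bins=n_bins, inplace=False
    )
    stats = pd.DataFrame(
        {
            "means": np.asarray(stats["means"]),
            "dispersions": np.asarray(stats["dispersions"]),
            "dispersions_norm": np.asarray(stats["dispersions_norm"]),
        },
        index=adata.var_names,
    )
    disp = stats["dispersions_norm"].to_numpy(dtype=float, na_value=-np.inf)
    n_genes = len(disp)
    if n_genes < n_top:
        warnings.warn(
            f"only {n_genes} genes available for n_top={n_top}; flagging all",
            stacklevel=2,
        )
    # stable sort keeps input gene order on ties
    order = np.argsort(-disp, kind="stable")
    flags = np.zeros(n_genes, dtype=bool)
    eligible = order[np.isfinite(disp[order])]
    flags[eligible[: min(n_top, len(eligible))]] = True
    stats["highly_variable"] = flags
    return stats


def run_pipeline(
    adata: AnnData, config: PreprocessConfig | None = None
) -> AnnData:
    """Full recipe: filter cells -> filter genes -> normalize -> log1p ->
    select HVGs -> restrict columns, in that order.

    A provenance record (cell/gene counts before and after each step plus the
    configuration) is stored in ``uns["preprocess_provenance"]``.
    """
    cfg = config or PreprocessConfig()
    steps: list[dict] = []

    def record(name: str, x: AnnData) -> None:
        steps.append({"step": name, "n_cells": x.n_obs, "n_genes": x.n_vars})

    record("input", adata)
    out = filter_cells(adata, cfg.min_genes)
    record("filter_cells", out)
    out = filter_genes(out, cfg.min_cells)
    record("filter_genes", out)
    out = normalize_total(out)
    record("normalize_total", out)
    out = log1p(out)
    record("log1p", out)
    report = select_hvg(out, n_top=cfg.n_top_hvg, n_bins=cfg.hvg_bins)
    out = out[:, report["highly_variable"].to_numpy()].copy()
    out.var = out.var.join(report.loc[out.var_names])
    record("select_hvg", out)
    out.uns["preprocess_provenance"] = {
        "config": cfg.to_dict(),
        "steps": pd.DataFrame(steps),  # h5ad-serializable
    }
    return out
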