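"""Pathway gene-set priors: GMT parsing and the pathway-gene adjacency matrix.

A gene-set collection (MSigDB / WikiPathways GMT dialect) is turned into a
binary pathways x genes adjacency matrix aligned to an expression gene
universe.  Each surviving pathway later becomes one latent dimension of the
model, so the number of rows of the adjacency defines the embedding size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GeneSet",
    "PathwayGeneMatrix",
    "GMTParseError",
    "parse_gmt",
    "write_gmt",
    "build_adjacency",
]


class GMTParseError(ValueError):
    """Raised when a GMT line cannot be parsed."""


def _canonicalize(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass
class GeneSet:
    """A named gene set: name, free-text description, ordered gene symbols.

    Symbols are canonicalized to uppercase; duplicates within one set are
    collapsed, keeping first occurrence.
    """

    name: str
    description: str = ""
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be nonempty")
        seen: dict[str, None] = {}
        for g in self.genes:
            cg = _canonicalize(g)
            if cg and cg not in seen:
                seen[cg] = None
        self.genes = list(seen)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} has no genes")


@dataclass
class PathwayGeneMatrix:
    """Binary P x G pathway-gene adjacency aligned to an expression gene order."""

    matrix: np.ndarray
    pathway_names: list[str]
    gene_symbols: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("adjacency must be 2-D")
        p, g = self.matrix.shape
        if len(self.pathway_names) != p or len(self.gene_symbols) != g:
            raise ValueError("adjacency shape does not match its labels")
        if len(set(self.pathway_names)) != p:
            raise ValueError("pathway names must be unique")
        if len(set(self.gene_symbols)) != g:
            raise ValueError("gene symbols must be unique")
        vals = np.unique(self.matrix)
        if not np.isin(vals, [0.0, 1.0]).all():
            raise ValueError("adjacency entries must be binary")

    @property
    def n_pathways(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def to_gene_sets(self) -> list[GeneSet]:
        """Express each adjacency row as a GeneSet over the gene universe."""
        sets = []
        genes = np.asarray(self.gene_symbols)
        for i, name in enumerate(self.pathway_names):
            members = genes[self.matrix[i] > 0].tolist()
            sets.append(GeneSet(name=name, description="", genes=members))
        return sets


def parse_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file into gene sets, one per line, order preserved.

    Each line holds name, description, then gene symbols, tab-separated.
    Trailing empty fields are tolerated.  An empty file yields an empty list;
    a line with fewer than three fields is a parse error naming the line.
    """
    path = Path(path)
    gene_sets: list[GeneSet] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            while fields and fields[-1] == "":
                fields.pop()
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path.name}: line {lineno} has {len(fields)} field(s); "
                    "expected name, description and at least one gene"
                )
            gene_sets.append(
                GeneSet(name=fields[0], description=fields[1], genes=fields[2:])
            )
    return gene_sets


def write_gmt(gene_sets: list[GeneSet], path: str | Path) -> None:
    """Write gene sets in the same tab-separated dialect parse_gmt reads."""
    path = Path(path)
    with path.open("w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def build_adjacency(
    gene_sets: list[GeneSet],
    gene_universe: list[str],
    min_overlap: int = 5,
) -> PathwayGeneMatrix:
    """Build the binary pathway-gene adjacency over a gene universe.

    Entry [p, g] is 1 iff universe gene g belongs to pathway p.  Pathways
    overlapping the universe in fewer than ``min_overlap`` genes (inclusive
    threshold) are dropped; genes outside every pathway keep all-zero columns
    so the decoder still reconstructs them.  Column order equals the supplied
    universe order and row count defines the model's latent dimension.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be a positive integer")
    universe = [_canonicalize(g) for g in gene_universe]
    if not universe:
        raise ValueError("gene universe must be nonempty")
    if len(set(universe)) != len(universe):
        raise ValueError("gene universe contains duplicate symbols")
    index = {g: i for i, g in enumerate(universe)}

    rows: list[np.ndarray] = []
    names: list[str] = []
    for gs in gene_sets:
        row = np.zeros(len(universe), dtype=np.float64)
        hits = [index[g] for g in gs.genes if g in index]
        if len(hits) < min_overlap:
            continue
        row[hits] = 1.0
        rows.append(row)
        names.append(gs.name)
    if not rows:
        raise ValueError(
            "no pathway overlaps the gene universe in at least "
            f"{min_overlap} genes; use a different knowledge database or a "
            "lower min_overlap"
        )
    return PathwayGeneMatrix(
        matrix=np.vstack(rows), pathway_names=names, gene_symbols=universe
    )
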