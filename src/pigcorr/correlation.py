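"""Gene–pigmentation correlation and the |r| ranking fed to enrichment.

For each gene, the Pearson correlation r between its scaled expression
row and the per-cell normalized brightness Ynorm is computed; genes are
then ranked by |r| descending (ties broken lexicographically by gene id)
to form the preranked input of the gene-set enrichment stage. Because
Pearson correlation is invariant to per-gene affine maps, r is identical
whether computed on log-normalized or z-scored expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ScaledMatrix

__all__ = [
    "GeneColorCorrelation",
    "RankedGeneList",
    "gene_brightness_correlation",
    "rank_genes",
    "top_tables",
    "write_rnk",
    "read_rnk",
]


@dataclass(frozen=True)
class GeneColorCorrelation:
    gene_id: str
    r: float
    n_cells: int
    lineage: str | None = None


@dataclass
class RankedGeneList:
    """Genes ordered by ranking statistic (|r|), non-increasing."""

    genes: np.ndarray
    stats: np.ndarray  # |r|, descending
    r: np.ndarray  # signed r in ranking order
    tie_break: str = "abs_r_desc,gene_id_asc"

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.stats = np.asarray(self.stats, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if len(self.genes) == 0:
            raise ValueError("empty ranking")
        if np.any(np.diff(self.stats) > 1e-12):
            raise ValueError("ranking statistic must be non-increasing")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranking")

    def __len__(self) -> int:
        return len(self.genes)

    def positions(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


def gene_brightness_correlation(
    scaled: ScaledMatrix,
    ynorm,
    lineage: str | None = None,
) -> pd.DataFrame:
    """Per-gene Pearson r between scaled expression and Ynorm.

    ``ynorm`` is either an array aligned with ``scaled.cells`` or a
    pandas Series indexed by cell id. Genes with zero expression variance
    get r = NaN (recorded missing, excluded from the ranking downstream).

    Returns a DataFrame with columns gene_id, r, n_cells, lineage.
    """
    if isinstance(ynorm, pd.Series):
        missing = [c for c in scaled.cells if c not in ynorm.index]
        if missing:
            raise ValueError(f"Ynorm missing for cells: {missing[:5]}")
        y = ynorm.loc[list(scaled.cells)].to_numpy(dtype=float)
    else:
        y = np.asarray(ynorm, dtype=float)
        if len(y) != len(scaled.cells):
            raise ValueError(
                f"Ynorm length {len(y)} != number of cells {len(scaled.cells)}"
            )
    n = len(y)
    if n < 3:
        raise ValueError("correlation needs at least 3 cells")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite Ynorm values")
    y_sd = y.std()
    if y_sd == 0:
        raise ValueError("Ynorm is constant; correlation undefined")

    x = np.asarray(scaled.values, dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    x_sd = x.std(axis=1)
    yc = y - y.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (n * x_sd * y_sd)
    r[x_sd == 0] = np.nan
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(
        {
            "gene_id": list(scaled.genes),
            "r": r,
            "n_cells": n,
            "lineage": lineage,
        }
    )


def rank_genes(correlations: pd.DataFrame) -> RankedGeneList:
    """Order genes by |r| descending; ties by gene id; NaN r excluded."""
    finite = correlations["r"].notna()
    dropped = int((~finite).sum())
    if dropped:
        warnings.warn(f"excluding {dropped} genes with undefined r", stacklevel=2)
    df = correlations[finite]
    if df.empty:
        raise ValueError("no genes with finite correlation to rank")
    genes = df["gene_id"].to_numpy(dtype=object)
    r = df["r"].to_numpy(dtype=float)
    order = np.lexsort((genes, -np.abs(r)))
    return RankedGeneList(genes=genes[order], stats=np.abs(r[order]), r=r[order])


def top_tables(
    correlations: pd.DataFrame, k: int = 20
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k positively and top-k negatively correlated genes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    df = correlations[correlations["r"].notna()]
    if k > len(df):
        warnings.warn(
            f"k={k} exceeds {len(df)} ranked genes; truncating", stacklevel=2
        )
        k = len(df)
    pos = df.sort_values(["r", "gene_id"], ascending=[False, True]).head(k)
    neg = df.sort_values(["r", "gene_id"], ascending=[True, True]).head(k)
    return pos.reset_index(drop=True), neg.reset_index(drop=True)


def write_rnk(ranked: RankedGeneList, path: str) -> None:
    """Two-column gene/statistic file, interoperable with preranked tools."""
    with open(path, "w") as fh:
        for g, s in zip(ranked.genes, ranked.stats):
            fh.write(f"{g}\t{s:.10g}\n")


def read_rnk(path: str) -> RankedGeneList:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "stat"])
    order = np.lexsort((df["gene_id"].to_numpy(dtype=object), -df["stat"].to_numpy()))
    genes = df["gene_id"].to_numpy(dtype=object)[order]
    stats = df["stat"].to_numpy(dtype=float)[order]
    return RankedGeneList(genes=genes, stats=stats, r=stats.copy())
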