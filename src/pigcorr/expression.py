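"""Count-matrix ingestion, normalization, and graph-based clustering.

The transcriptome side of the pipeline consumes a gene × cell matrix of
molecule counts and reproduces a standard single-cell workflow: library-
size log-normalization (scale factor 1e4), per-gene z-scoring, PCA, a
shared-nearest-neighbor (SNN) graph on the top principal components, and
Louvain modularity clustering. Defaults mirror the analysis this package
models: 6 components, resolution 0.4, k = 20 neighbors, SNN edges pruned
below Jaccard 1/15.

Determinism: PCA signs are fixed by convention (the largest-|loading|
gene of each component is positive) and clustering canonicalizes the cell
order before building the graph, so the partition is identical under any
permutation of the input cells.
"""

from __future__ import annotations

import os
import random
import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "ScaledMatrix",
    "ClusteringParams",
    "ClusterAssignment",
    "read_counts",
    "write_counts",
    "log_normalize",
    "scale_genes",
    "pca",
    "PCAResult",
    "snn_cluster",
    "cluster_color_summary",
    "marker_fraction",
]


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), set()
        for i in ids:
            (dups if i in seen else seen).add(i)
        raise ValueError(f"duplicate {what} IDs: {sorted(dups)[:5]} ...")


@dataclass
class CountMatrix:
    """Gene × cell molecule counts (dense int64; small-cohort scale)."""

    genes: list[str]
    cells: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.cells = [str(c) for c in self.cells]
        _check_unique(self.genes, "gene")
        _check_unique(self.cells, "cell")
        arr = np.asarray(self.counts)
        if sp.issparse(self.counts):
            arr = np.asarray(self.counts.todense())
        if arr.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {arr.shape} != ({len(self.genes)}, {len(self.cells)})"
            )
        if arr.size:
            if np.any(arr < 0):
                raise ValueError("negative counts")
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("non-integer counts")
        self.counts = arr.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.cells)


@dataclass
class ExpressionMatrix:
    """Gene × cell real-valued expression (log-normalized)."""

    genes: list[str]
    cells: list[str]
    values: np.ndarray


@dataclass
class ScaledMatrix:
    """Per-gene standardized expression; constant genes zeroed and flagged."""

    genes: list[str]
    cells: list[str]
    values: np.ndarray
    zero_variance: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))


def read_counts(path: str, fmt: str | None = None) -> CountMatrix:
    """Read a count matrix.

    ``fmt="mtx"``: ``path`` is a directory holding ``matrix.mtx`` with
    ``features.tsv``/``barcodes.tsv`` sidecars (or a ``.mtx`` file with
    the sidecars next to it). ``fmt="csv"``: dense CSV, genes as rows
    (first column), cells as header. ``fmt=None`` autodetects.
    """
    if fmt is None:
        if os.path.isdir(path) or path.endswith(".mtx"):
            fmt = "mtx"
        elif path.endswith(".csv"):
            fmt = "csv"
        else:
            raise ValueError(f"cannot autodetect format of {path!r}")
    if fmt == "mtx":
        if os.path.isdir(path):
            mtx = os.path.join(path, "matrix.mtx")
            base = path
        else:
            mtx = path
            base = os.path.dirname(path)
        mat = scipy.io.mmread(mtx)
        genes = pd.read_csv(
            os.path.join(base, "features.tsv"), sep="\t", header=None
        )[0].tolist()
        cells = pd.read_csv(
            os.path.join(base, "barcodes.tsv"), sep="\t", header=None
        )[0].tolist()
        return CountMatrix(genes=genes, cells=cells, counts=mat)
    if fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        return CountMatrix(
            genes=df.index.tolist(), cells=df.columns.tolist(), counts=df.to_numpy()
        )
    raise ValueError(f"unknown format {fmt!r}")


def write_counts(cm: CountMatrix, path: str, fmt: str = "mtx") -> None:
    """Write MTX triplet + sidecars (``path`` is a directory) or dense CSV."""
    if fmt == "mtx":
        os.makedirs(path, exist_ok=True)
        scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), sp.coo_matrix(cm.counts))
        with open(os.path.join(path, "features.tsv"), "w") as fh:
            fh.writelines(f"{g}\n" for g in cm.genes)
        with open(os.path.join(path, "barcodes.tsv"), "w") as fh:
            fh.writelines(f"{c}\n" for c in cm.cells)
    elif fmt == "csv":
        cm.to_frame().to_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def log_normalize(cm: CountMatrix, scale_factor: float = 1e4) -> ExpressionMatrix:
    """Library-size normalization: ln(1 + count · scale_factor / cell_total)."""
    totals = cm.counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        bad = [c for c, z in zip(cm.cells, zero) if z]
        raise ValueError(f"cells with zero total count: {bad[:10]}")
    values = np.log1p(cm.counts * (scale_factor / totals[None, :]))
    return ExpressionMatrix(genes=list(cm.genes), cells=list(cm.cells), values=values)


def scale_genes(expr: ExpressionMatrix, clip: float | None = None) -> ScaledMatrix:
    """Per-gene z-score across cells (population SD).

    Zero-variance genes become all-zero rows and are flagged; ``clip``
    optionally truncates |z| (off by default).
    """
    if len(expr.cells) < 2:
        raise ValueError("scaling needs at least two cells")
    v = np.asarray(expr.values, dtype=float)
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)
    zero_var = sd[:, 0] == 0
    sd[zero_var, :] = 1.0
    z = (v - mean) / sd
    z[zero_var, :] = 0.0
    if clip is not None:
        z = np.clip(z, -clip, clip)
    return ScaledMatrix(
        genes=list(expr.genes), cells=list(expr.cells), values=z, zero_variance=zero_var
    )


@dataclass
class PCAResult:
    scores: np.ndarray  # cells × components
    loadings: np.ndarray  # genes × components
    explained_variance_ratio: np.ndarray


def pca(scaled: ScaledMatrix, n_components: int = 6) -> PCAResult:
    """Top principal components of cells in gene space.

    Deterministic: full SVD, and each component's sign is fixed so its
    largest-|loading| gene has a positive loading.
    """
    x = np.asarray(scaled.values, dtype=float).T  # cells × genes
    if n_components > min(x.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(genes, cells)={min(x.shape)}"
        )
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    loadings = model.components_.T  # genes × components
    for j in range(n_components):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=model.explained_variance_ratio_,
    )


@dataclass(frozen=True)
class ClusteringParams:
    n_components: int = 6
    resolution: float = 0.4
    k_neighbors: int = 20
    snn_prune: float = 1.0 / 15.0

    def __post_init__(self) -> None:
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")
        if not self.resolution > 0:
            raise ValueError("resolution must be positive")


@dataclass
class ClusterAssignment:
    cells: list[str]
    labels: np.ndarray  # int, 0-based, decreasing cluster size

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.cells) != len(self.labels):
            raise ValueError("one label per cell required")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cells, "cluster": self.labels})


def snn_cluster(
    scores: np.ndarray,
    cells,
    params: ClusteringParams | None = None,
    seed: int = 0,
) -> ClusterAssignment:
    """Shared-nearest-neighbor Louvain clustering of cells.

    kNN (Euclidean, on the first ``n_components`` score columns, neighbor
    lists include the cell itself) → Jaccard SNN edge weights, pruned
    below ``snn_prune`` → Louvain modularity communities at the given
    resolution. Labels are 0..K−1 by decreasing cluster size.

    The cells are reordered canonically (lexicographic on scores, cell id
    as tiebreak) before graph construction, making the partition exactly
    invariant to the order the cells arrive in.
    """
    params = params or ClusteringParams()
    cells = [str(c) for c in cells]
    x = np.asarray(scores, dtype=float)[:, : params.n_components]
    n = x.shape[0]
    if n != len(cells):
        raise ValueError("scores/cells length mismatch")
    if n < params.k_neighbors + 1:
        raise ValueError(
            f"need at least k_neighbors+1={params.k_neighbors + 1} cells, got {n}"
        )

    keys = [np.asarray(cells)] + [x[:, j] for j in range(x.shape[1] - 1, -1, -1)]
    order = np.lexsort(tuple(keys))
    xc = x[order]

    nn = NearestNeighbors(n_neighbors=params.k_neighbors).fit(xc)
    idx = nn.kneighbors(return_distance=False)  # excludes self
    rows = np.repeat(np.arange(n), params.k_neighbors)
    indicator = sp.csr_matrix(
        (np.ones(n * params.k_neighbors), (rows, idx.ravel())), shape=(n, n)
    )
    indicator = indicator.maximum(sp.identity(n, format="csr"))  # self-inclusive lists
    sizes = np.asarray(indicator.sum(axis=1)).ravel()
    inter = (indicator @ indicator.T).tocoo()
    union = sizes[inter.row] + sizes[inter.col] - inter.data
    jacc = inter.data / union
    keep = (jacc >= params.snn_prune) & (inter.row < inter.col)
    edges = np.column_stack([inter.row[keep], inter.col[keep]])
    weights = jacc[keep]

    g = ig.Graph(n=n, edges=[tuple(e) for e in edges])
    if any(d == 0 for d in g.degree()):
        warnings.warn(
            "SNN graph has isolated cells; each becomes its own cluster", stacklevel=2
        )
    random.seed(seed)  # python-igraph draws randomness from the random module
    membership = np.array(
        g.community_multilevel(
            weights=list(weights), resolution=params.resolution
        ).membership
    )

    # relabel by decreasing size, ties by first canonical appearance
    comm_ids, counts = np.unique(membership, return_counts=True)
    first_seen = {c: int(np.argmax(membership == c)) for c in comm_ids}
    ranked = sorted(comm_ids, key=lambda c: (-counts[c == comm_ids][0], first_seen[c]))
    remap = {c: i for i, c in enumerate(ranked)}
    canon_labels = np.array([remap[c] for c in membership])

    labels = np.empty(n, dtype=int)
    labels[order] = canon_labels
    return ClusterAssignment(cells=cells, labels=labels)


def cluster_color_summary(
    assignment: ClusterAssignment, brightness: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster brightness distribution (the violin-plot table).

    ``brightness`` must carry ``cell_id``, ``Y`` and ``Ynorm`` for every
    clustered cell.
    """
    b = brightness.set_index("cell_id")
    missing = [c for c in assignment.cells if c not in b.index]
    if missing:
        raise ValueError(f"missing brightness for clustered cells: {missing[:5]}")
    df = assignment.to_frame().join(b[["Y", "Ynorm"]], on="cell_id")
    rows = []
    for cluster, grp in df.groupby("cluster"):
        row = {"cluster": int(cluster), "n": len(grp)}
        for col in ("Ynorm", "Y"):
            v = grp[col].to_numpy()
            row.update(
                {
                    f"{col}_mean": v.mean(),
                    f"{col}_median": np.median(v),
                    f"{col}_q25": np.quantile(v, 0.25),
                    f"{col}_q75": np.quantile(v, 0.75),
                }
            )
        rows.append(row)
    return pd.DataFrame(rows).sort_values("cluster").reset_index(drop=True)


def marker_fraction(
    cm: CountMatrix, assignment: ClusterAssignment, gene_id: str
) -> pd.Series:
    """Fraction of cells per cluster with count > 0 for ``gene_id``."""
    try:
        gi = cm.genes.index(gene_id)
    except ValueError:
        raise KeyError(f"gene {gene_id!r} not in matrix") from None
    cell_pos = {c: j for j, c in enumerate(cm.cells)}
    detected = cm.counts[gi] > 0
    frac = {}
    for cluster in range(assignment.n_clusters):
        members = [
            cell_pos[c]
            for c, lab in zip(assignment.cells, assignment.labels)
            if lab == cluster
        ]
        frac[cluster] = float(detected[members].mean()) if members else 0.0
    return pd.Series(frac, name=gene_id)
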