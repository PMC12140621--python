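"""Build spot-spot similarity networks from expression and spatial coordinates.

High-throughput spatial transcriptomics platforms (10x Visium, NanoString
CosMx) measure a gene expression profile at each of N spatially indexed
spots.  This module turns those measurements into the two-layer binary
graph the block model consumes: one K-nearest-neighbor layer built in gene
expression principal-component space and one built from the 2-D spatial
coordinates.  Each layer is an undirected, self-loop-free 0/1 adjacency
matrix over the same N spots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA

__all__ = [
    "ExpressionMatrix",
    "SpatialCoords",
    "Embedding",
    "MultiLayerGraph",
    "PreprocessConfig",
    "select_hvg",
    "pca_embed",
    "default_neighbors",
    "knn_graph",
    "build_multilayer",
]


@dataclass
class ExpressionMatrix:
    """Spots x genes non-negative expression values with aligned identifiers."""

    counts: np.ndarray
    spot_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D spots x genes matrix")
        if self.counts.size == 0:
            raise ValueError("expression matrix is empty")
        if np.any(self.counts < 0):
            raise ValueError("expression counts contain negative entries")
        n, g = self.counts.shape
        if len(self.spot_ids) != n or len(self.gene_ids) != g:
            raise ValueError("identifier lists do not match matrix dimensions")
        if len(set(self.spot_ids)) != n:
            raise ValueError("spot_ids are not unique")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids are not unique")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class SpatialCoords:
    """Spots x 2 spatial coordinates in platform units."""

    xy: np.ndarray
    spot_ids: list[str]

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.spot_ids = [str(s) for s in self.spot_ids]
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("coordinates must be a spots x 2 array")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("coordinates contain non-finite values")
        if len(self.spot_ids) != self.xy.shape[0]:
            raise ValueError("spot_ids do not match coordinate rows")
        if len(set(self.spot_ids)) != len(self.spot_ids):
            raise ValueError("spot_ids are not unique")

    @property
    def n_spots(self) -> int:
        return self.xy.shape[0]


@dataclass
class Embedding:
    """Spots x d principal-component embedding of expression profiles."""

    matrix: np.ndarray
    spot_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] < 1:
            raise ValueError("embedding must be a spots x d array with d >= 1")

    @property
    def d(self) -> int:
        return self.matrix.shape[1]


@dataclass
class MultiLayerGraph:
    """An ordered list of L binary symmetric adjacency layers over N spots.

    Layer 1 is conventionally the gene-expression similarity network and
    layer 2 the spatial one, but any L >= 1 layers sharing one node set are
    accepted.
    """

    layers: list[sp.csr_matrix]
    spot_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("at least one layer is required")
        layers = []
        for a in self.layers:
            a = sp.csr_matrix(a, dtype=np.int8)
            a.eliminate_zeros()
            layers.append(a)
        self.layers = layers
        self.validate()
        if not self.spot_ids:
            self.spot_ids = [str(i) for i in range(self.n_spots)]

    def validate(self) -> None:
        n = self.layers[0].shape[0]
        for idx, a in enumerate(self.layers):
            if a.shape != (n, n):
                raise ValueError(f"layer {idx + 1} is not {n}x{n}")
            if a.nnz and not np.all(a.data == 1):
                raise ValueError(f"layer {idx + 1} has non-binary entries")
            if a.diagonal().any():
                raise ValueError(f"layer {idx + 1} has self-loops")
            if (a != a.T).nnz != 0:
                raise ValueError(f"layer {idx + 1} is not symmetric")

    @property
    def n_spots(self) -> int:
        return self.layers[0].shape[0]

    @property
    def n_layers(self) -> int:
        return len(self.layers)


@dataclass
class PreprocessConfig:
    """Switches for the expression-side preprocessing pipeline.

    ``normalize`` divides each spot by its total count and rescales to the
    median library size, ``log1p`` applies log(1 + x), and ``scale``
    standardizes each gene to zero mean / unit variance before PCA.  HVG
    selection uses the normalized, log-transformed (but unscaled) values.
    """

    normalize: bool = True
    log1p: bool = True
    scale: bool = True
    n_top_genes: int = 2000
    n_components: int = 15


def _normalized_values(counts: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if config.normalize:
        totals = x.sum(axis=1)
        target = np.median(totals[totals > 0]) if np.any(totals > 0) else 1.0
        safe = np.where(totals > 0, totals, 1.0)
        x = x / safe[:, None] * target
    if config.log1p:
        x = np.log1p(x)
    return x


def select_hvg(
    expr: ExpressionMatrix,
    n_top: int | None = None,
    config: PreprocessConfig | None = None,
) -> ExpressionMatrix:
    """Keep the ``n_top`` most variable genes (default 2000).

    Variance is computed on library-normalized, log1p-transformed values
    (per ``config``); the returned matrix keeps the original counts of the
    selected genes, ordered by decreasing variance.  If ``n_top`` is at
    least the gene count, all genes are returned (still variance-ordered).
    """
    config = config or PreprocessConfig()
    if n_top is None:
        n_top = config.n_top_genes
    if n_top < 1:
        raise ValueError("n_top must be a positive integer")
    x = _normalized_values(expr.counts, config)
    variances = x.var(axis=0)
    # stable sort so equal-variance genes keep their input order
    order = np.argsort(-variances, kind="stable")[: min(n_top, expr.n_genes)]
    return ExpressionMatrix(
        counts=expr.counts[:, order],
        spot_ids=expr.spot_ids,
        gene_ids=[expr.gene_ids[j] for j in order],
    )


def pca_embed(
    expr: ExpressionMatrix,
    n_components: int | None = None,
    config: PreprocessConfig | None = None,
) -> Embedding:
    """Project spots into principal-component space of the expression data.

    The input is normalized/log-transformed/scaled per ``config`` and then
    decomposed with a deterministic full SVD; components are ordered by
    decreasing explained variance.
    """
    config = config or PreprocessConfig()
    if n_components is None:
        n_components = min(config.n_components, expr.n_spots - 1, expr.n_genes)
    bound = min(expr.n_spots, expr.n_genes)
    if not 1 <= n_components <= bound:
        raise ValueError(
            f"n_components={n_components} outside valid range [1, {bound}]"
        )
    x = _normalized_values(expr.counts, config)
    if config.scale:
        sd = x.std(axis=0)
        x = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=n_components, svd_solver="full")
    return Embedding(matrix=pca.fit_transform(x), spot_ids=list(expr.spot_ids))


def default_neighbors(N: int) -> int:
    """Default neighbor count R: the closest odd integer to sqrt(N).

    Ties (sqrt(N) exactly midway between two odd integers) are broken
    downward.  For typical tissue sections of 2000-3000 spots this yields
    R of about 45-55, i.e. roughly third- to fourth-order neighborhoods on
    a hexagonal spot lattice.
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    root = math.sqrt(N)
    lower = int(math.floor(root))
    if lower % 2 == 0:
        lower -= 1
    lower = max(lower, 1)
    upper = lower + 2
    return lower if root - lower <= upper - root else upper


def _points_array(points) -> np.ndarray:
    if isinstance(points, Embedding):
        return points.matrix
    if isinstance(points, SpatialCoords):
        return points.xy
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be a 2-D array")
    return pts


def knn_graph(points, R: int) -> sp.csr_matrix:
    """Symmetric binary KNN adjacency: edge i~j if j is among i's R nearest
    neighbors (Euclidean) or vice versa.

    The union symmetrization guarantees every node degree >= R.  Distance
    ties are broken by ascending node index (stable sort), so the graph is
    fully deterministic; duplicate points are allowed.
    """
    pts = _points_array(points)
    n = pts.shape[0]
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite values")
    if not 1 <= R < n:
        raise ValueError(f"R must satisfy 1 <= R < N (got R={R}, N={n})")
    # exact pairwise distances with a stable argsort: deterministic
    # index-order tie-breaking, which approximate KNN backends do not give
    sq = np.einsum("ij,ij->i", pts, pts)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (pts @ pts.T)
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")[:, :R]
    rows = np.repeat(np.arange(n), R)
    cols = order.ravel()
    a = sp.coo_matrix((np.ones(rows.size, dtype=np.int8), (rows, cols)), shape=(n, n))
    a = a.tocsr()
    a = a.maximum(a.T)  # union symmetrization
    a.setdiag(0)
    a.eliminate_zeros()
    a.data[:] = 1
    return a.astype(np.int8)


def build_multilayer(
    expr: ExpressionMatrix,
    coords: SpatialCoords,
    R: int | None = None,
    config: PreprocessConfig | None = None,
) -> MultiLayerGraph:
    """Assemble the two-layer spot-spot similarity graph.

    Layer 1 = KNN in PCA space of the highly variable genes; layer 2 = KNN
    of the spatial coordinates; both use the same R, defaulting to
    :func:`default_neighbors`.
    """
    if expr.spot_ids != coords.spot_ids:
        bad = sorted(set(expr.spot_ids) ^ set(coords.spot_ids))
        raise ValueError(
            "expression and coordinate spot_ids are not aligned; offending ids: "
            + ", ".join(bad[:10] if bad else ["(same set, different order)"])
        )
    config = config or PreprocessConfig()
    n = expr.n_spots
    if R is None:
        R = default_neighbors(n)
    emb = pca_embed(select_hvg(expr, config=config), config=config)
    expr_layer = knn_graph(emb, R)
    spatial_layer = knn_graph(coords, R)
    return MultiLayerGraph(layers=[expr_layer, spatial_layer], spot_ids=list(expr.spot_ids))
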