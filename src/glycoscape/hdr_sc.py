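"""Unsupervised pixel clustering and matrix-cluster removal.

Pixels are clustered spatially agnostically: a k-nearest-neighbor graph is
built on log1p-transformed, TIC-normalized feature rows (Euclidean metric)
and partitioned by Leiden modularity optimization.  A 2-D UMAP embedding is
provided for visualization only.  Clusters dominated by MALDI matrix signal
are flagged automatically from the panel's matrix-class features and can be
removed, optionally reclustering the remaining tissue pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import igraph as ig
import leidenalg
import numpy as np
from sklearn.neighbors import NearestNeighbors

from .msi_io import MSIDataset, write_label_map
from .preprocess import FeatureMatrix

__all__ = [
    "ClusterResult",
    "cluster_pixels",
    "embed_2d",
    "flag_matrix_clusters",
    "remove_and_finalize",
    "spatial_map",
]

log = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    """Per-pixel cluster labels plus bookkeeping for matrix removal.

    ``labels`` aligns with ``pixel_index`` rows of the feature matrix it was
    computed from; after removal, ``retained`` holds the surviving row
    indices of the *original* matrix.
    """

    labels: np.ndarray
    retained: np.ndarray              # row indices into the source matrix
    params: dict = field(default_factory=dict)
    embedding: np.ndarray | None = None
    matrix_cluster_ids: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.retained = np.asarray(self.retained, dtype=np.int64)
        if len(self.labels) != len(self.retained):
            raise ValueError("labels/retained length mismatch")
        observed = set(np.unique(self.labels).tolist())
        if not set(self.matrix_cluster_ids) <= observed:
            raise ValueError("matrix_cluster_ids outside observed labels")

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def _feature_array(fm: FeatureMatrix) -> np.ndarray:
    if not fm.normalized:
        raise ValueError("feature matrix must be TIC-normalized first")
    return np.log1p(fm.values.to_numpy())


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Dense-code labels 0..C-1 by descending cluster size.

    Ties broken by the smallest member row index, ascending, so the coding
    is stable under permutation-free reruns.
    """
    ids, inverse, counts = np.unique(
        labels, return_inverse=True, return_counts=True
    )
    first_member = np.full(len(ids), len(labels), dtype=np.int64)
    for row, c in enumerate(inverse):
        if row < first_member[c]:
            first_member[c] = row
    order = sorted(range(len(ids)), key=lambda c: (-counts[c], first_member[c]))
    rank = np.empty(len(ids), dtype=np.int64)
    for new, old in enumerate(order):
        rank[old] = new
    return rank[inverse]


def _knn_graph(X: np.ndarray, k: int) -> ig.Graph:
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    edges = set()
    for i in range(len(X)):
        for j in idx[i, 1:]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            edges.add((a, b))
    g = ig.Graph(n=len(X), edges=sorted(edges))
    return g


def cluster_pixels(
    fm: FeatureMatrix,
    k_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> ClusterResult:
    """Leiden community detection on the pixel kNN graph.

    Labels are dense-coded by descending cluster size; deterministic for a
    fixed seed and input.
    """
    X = _feature_array(fm)
    n = len(X)
    if n < 2:
        raise ValueError("need at least 2 pixels")
    if k_neighbors >= n:
        raise ValueError(
            f"k_neighbors={k_neighbors} must be < n_pixels={n}"
        )
    # identical rows make the kNN graph arbitrary; short-circuit the
    # degenerate single-point case
    if np.allclose(X, X[0]):
        labels = np.zeros(n, dtype=np.int64)
    else:
        g = _knn_graph(X, k_neighbors)
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=-1,
        )
        labels = _relabel_by_size(np.asarray(part.membership))
    return ClusterResult(
        labels=labels,
        retained=np.arange(n),
        params={
            "k_neighbors": k_neighbors,
            "resolution": resolution,
            "seed": seed,
        },
    )


def embed_2d(fm: FeatureMatrix, seed: int = 0, n_neighbors: int = 15) -> np.ndarray:
    """2-D UMAP of the pixels, deterministic for a fixed seed.

    Visualization only — nothing downstream consumes the coordinates.
    """
    import umap  # deferred: slow numba-backed import

    X = _feature_array(fm)
    if len(X) < 4:
        raise ValueError("need at least 4 pixels to embed")
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, len(X) - 1),
        random_state=seed,
    )
    return np.asarray(reducer.fit_transform(X), dtype=np.float64)


def flag_matrix_clusters(
    cr: ClusterResult,
    fm: FeatureMatrix,
    matrix_fraction_threshold: float = 0.5,
) -> frozenset[int]:
    """Flag clusters whose mean matrix-signal fraction exceeds the threshold.

    Matrix fraction of a pixel = (sum of matrix-class panel values) /
    (sum of all panel values); a cluster's fraction is the mean over its
    member pixels.
    """
    matrix_cols = fm.matrix_feature_columns()
    if not matrix_cols:
        raise ValueError("panel has no matrix-class entries")
    V = fm.values.to_numpy()
    m = fm.values[matrix_cols].to_numpy().sum(axis=1)
    total = V.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, m / total, 0.0)
    frac = frac[cr.retained]

    flagged = set()
    for cid in np.unique(cr.labels):
        cluster_frac = float(frac[cr.labels == cid].mean())
        if cluster_frac >= matrix_fraction_threshold:
            flagged.add(int(cid))
    if not flagged:
        log.warning(
            "flag_matrix_clusters: no cluster reached matrix fraction %.2f",
            matrix_fraction_threshold,
        )
    return frozenset(flagged)


def remove_and_finalize(
    cr: ClusterResult,
    fm: FeatureMatrix,
    mode: str = "recluster",
) -> ClusterResult:
    """Drop matrix-cluster pixels; keep labels or recluster the remainder.

    ``keep_labels`` retains the existing labels on surviving pixels
    (re-densified); ``recluster`` reruns :func:`cluster_pixels` on the
    retained rows with the original parameters (default — mirrors replotting
    after matrix removal).
    """
    if mode not in ("keep_labels", "recluster"):
        raise ValueError(f"unknown mode {mode!r}")
    keep = ~np.isin(cr.labels, list(cr.matrix_cluster_ids))
    if not keep.any():
        raise ValueError("matrix removal would drop every pixel")
    retained = cr.retained[keep]
    if mode == "keep_labels" or not cr.matrix_cluster_ids:
        labels = cr.labels[keep]
        if cr.matrix_cluster_ids:
            labels = _relabel_by_size(labels)
        return ClusterResult(
            labels=labels,
            retained=retained,
            params=dict(cr.params),
            embedding=None if cr.embedding is None else cr.embedding[keep],
        )
    sub = FeatureMatrix(
        values=fm.values.iloc[retained].reset_index(drop=True),
        tic=fm.tic[retained],
        frame=fm.frame.iloc[retained].reset_index(drop=True),
        panel=fm.panel,
        normalized=fm.normalized,
    )
    sub_cr = cluster_pixels(
        sub,
        k_neighbors=cr.params.get("k_neighbors", 15),
        resolution=cr.params.get("resolution", 1.0),
        seed=cr.params.get("seed", 0),
    )
    return replace(sub_cr, retained=retained, params=dict(cr.params))


def spatial_map(
    cr: ClusterResult, ds_or_fm, out_prefix
) -> "Path":
    """Render cluster labels back onto the acquisition grid (CSV + PNG).

    Removed pixels are background.  Accepts the dataset or the feature
    matrix the clustering came from; their pixel frames must match.
    """
    from pathlib import Path  # noqa: F401  (return type)

    if isinstance(ds_or_fm, MSIDataset):
        coords = ds_or_fm.coords
    elif isinstance(ds_or_fm, FeatureMatrix):
        coords = ds_or_fm.coords
    else:
        raise TypeError("expected MSIDataset or FeatureMatrix")
    if cr.retained.max(initial=-1) >= len(coords):
        raise ValueError("cluster result does not match the pixel frame")
    return write_label_map(
        cr.labels, coords[cr.retained], out_prefix, categorical=True
    )
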