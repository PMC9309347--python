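"""Module detection: K-means on a spectral embedding, K chosen by the elbow.

Nodes are embedded with the first nontrivial eigenvectors of the symmetric
normalized Laplacian (rows scaled to unit length), K-means with k-means++
restarts is run over a candidate K range, and the selected K is the point of
maximum curvature of the inertia curve — the largest discrete second
difference I(K-1) - 2 I(K) + I(K+1), ties going to the smallest K. The
criterion is affine-invariant in the inertia scale and parameter-free, which
makes the otherwise informal elbow rule reproducible.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import networkx as nx
from scipy import linalg
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from .network import InteractionNetwork


def _adjacency(net) -> tuple[np.ndarray, list[str]]:
    if isinstance(net, InteractionNetwork):
        net = net.graph
    if isinstance(net, nx.Graph):
        nodes = sorted(net.nodes)
        return nx.to_numpy_array(net, nodelist=nodes, weight=None), [str(n) for n in nodes]
    a = np.asarray(net, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    return a, [str(i) for i in range(a.shape[0])]


def spectral_embedding(net, dim: int) -> pd.DataFrame:
    """Row-normalized eigenvector embedding of the normalized Laplacian.

    Takes the ``dim`` eigenvectors following the trivial leading one of
    L = I - D^{-1/2} A D^{-1/2} (additional zero-eigenvalue vectors of a
    disconnected graph are kept: they indicate components), fixes each sign
    by making its largest-magnitude entry positive, and scales rows to unit
    length (all-zero rows of isolated nodes are left at zero). Deterministic
    for a given graph.
    """
    a, nodes = _adjacency(net)
    n = a.shape[0]
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if dim >= n:
        raise ValueError(f"dim must be < number of nodes ({n})")

    deg = a.sum(axis=1)
    inv_sqrt = np.zeros(n)
    nz = deg > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(deg[nz])
    lap = np.eye(n) - inv_sqrt[:, None] * a * inv_sqrt[None, :]
    lap[~nz, ~nz] = 0.0  # isolated nodes: trivial zero eigenvalue

    w, v = linalg.eigh(lap)
    # only the leading (constant-like) eigenvector is trivial; further
    # zero-eigenvalue vectors are component indicators and carry structure
    emb = v[:, 1:1 + dim].copy()
    for j in range(dim):
        if emb[np.argmax(np.abs(emb[:, j])), j] < 0:
            emb[:, j] = -emb[:, j]
    norms = np.linalg.norm(emb, axis=1)
    emb[norms > 0] /= norms[norms > 0, None]
    return pd.DataFrame(emb, index=nodes)


def kmeans_fit(
    coords,
    k: int,
    n_restarts: int = 20,
    seed: int | None = None,
) -> tuple[np.ndarray, float]:
    """K-means with k-means++ restarts; returns (labels, best inertia)."""
    x = coords.to_numpy() if isinstance(coords, pd.DataFrame) else np.asarray(coords)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds number of points ({x.shape[0]})")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed)
    with warnings.catch_warnings():
        # duplicate embedding rows (twin nodes) can leave fewer distinct
        # centroids than k; that is expected on small graphs
        warnings.simplefilter("ignore", ConvergenceWarning)
        labels = km.fit_predict(x)
    return labels, float(km.inertia_)


def elbow_select(inertia_curve: dict[int, float] | pd.Series) -> int:
    """K at the maximum discrete second difference of the inertia curve.

    The curve must cover a contiguous K range with at least 4 points; ties
    resolve to the smallest K. Affine rescaling of the inertia leaves the
    selection unchanged.
    """
    if isinstance(inertia_curve, pd.Series):
        inertia_curve = inertia_curve.to_dict()
    ks = sorted(inertia_curve)
    if len(ks) < 4:
        raise ValueError("elbow selection needs >= 4 K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("inertia curve must cover a contiguous K range")
    inertia = np.array([inertia_curve[k] for k in ks], dtype=float)
    d2 = inertia[:-2] - 2.0 * inertia[1:-1] + inertia[2:]
    return int(ks[1 + int(np.argmax(d2))])


class SpectralKMeans(ClusterMixin, BaseEstimator):
    """Spectral K-means clusterer with elbow-based K selection.

    ``fit(X)`` accepts a graph, an :class:`InteractionNetwork` or a square
    adjacency matrix. When ``n_clusters`` is None the K range
    ``k_min..k_max`` is scanned and the elbow criterion picks
    ``k_selected_``; otherwise the given K is used directly. Fitted
    attributes: ``labels_``, ``k_selected_``, ``inertia_curve_``,
    ``embedding_`` and ``nodes_``.
    """

    def __init__(self, n_clusters: int | None = None, k_min: int = 2,
                 k_max: int = 20, dim: int = 12, n_restarts: int = 20,
                 random_state: int | None = None):
        self.n_clusters = n_clusters
        self.k_min = k_min
        self.k_max = k_max
        self.dim = dim
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        emb = spectral_embedding(X, dim=self.dim)
        self.embedding_ = emb
        self.nodes_ = list(emb.index)
        n = len(self.nodes_)

        if self.n_clusters is not None:
            labels, inertia = kmeans_fit(
                emb, self.n_clusters, self.n_restarts, self.random_state
            )
            self.k_selected_ = int(self.n_clusters)
            self.inertia_curve_ = {self.k_selected_: inertia}
            self.labels_ = labels
            return self

        k_max = min(self.k_max, n - 1)
        if k_max - self.k_min + 1 < 4:
            raise ValueError("K range too short for elbow selection (>= 4 values)")
        curve: dict[int, float] = {}
        fits: dict[int, np.ndarray] = {}
        for k in range(self.k_min, k_max + 1):
            fits[k], curve[k] = kmeans_fit(emb, k, self.n_restarts, self.random_state)
        self.k_selected_ = elbow_select(curve)
        self.inertia_curve_ = curve
        self.labels_ = fits[self.k_selected_]
        return self

    def assignment(self) -> pd.Series:
        """Node id -> cluster label for the selected K."""
        if not hasattr(self, "labels_"):
            raise ValueError("SpectralKMeans is not fitted yet")
        return pd.Series(self.labels_, index=self.nodes_, name="cluster")


def cluster_network(
    net,
    k_min: int = 2,
    k_max: int = 20,
    dim: int = 12,
    n_restarts: int = 20,
    seed: int | None = None,
) -> SpectralKMeans:
    """Fit the full module-detection stage on a disease network."""
    return SpectralKMeans(
        k_min=k_min, k_max=k_max, dim=dim, n_restarts=n_restarts, random_state=seed
    ).fit(net)
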