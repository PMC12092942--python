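"""UMAP embedding + HDBSCAN density clustering with validity-based tuning.

The binary feature vectors of one EDSS stratum are embedded into 2 or 3
dimensions with UMAP (Jaccard distance by default — impairment profiles are
sparse bit vectors) and clustered with HDBSCAN, which labels low-density
rows as noise (−1).  Hyperparameter combinations are compared by a
*relative validity* score, a simplified Density-Based Cluster Validity
(DBCV) computed on the embedding: per cluster, the largest edge of its
Euclidean minimum spanning tree (density sparseness) is traded against its
distance to the nearest other cluster (separation), and scores are averaged
with cluster-size weights.  :func:`dbcv_check` implements the full DBCV
definition (all-points core distances, mutual reachability) independently,
as a small-scale oracle for ranking checks.

Trained models are applied to held-out folds by embedding the new rows with
the fitted UMAP map and assigning each to the majority cluster among its
nearest training neighbours (approximate membership); rows far from every
training point become noise.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import HDBSCAN
from sklearn.neighbors import NearestNeighbors

import umap

from .binarize import feature_columns

NOISE = -1


@dataclass(frozen=True)
class EmbedParams:
    n_neighbors: int = 15
    min_dist: float = 0.0
    n_components: int = 2
    metric: str = "jaccard"
    seed: int = 0

    def __post_init__(self):
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if self.n_components not in (2, 3):
            raise ValueError("n_components must be 2 or 3")


@dataclass(frozen=True)
class ClusterParams:
    min_cluster_size: int = 25
    min_samples: int | None = None

    def __post_init__(self):
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")


@dataclass
class TunedModel:
    embed_params: EmbedParams
    cluster_params: ClusterParams
    reducer: umap.UMAP = field(repr=False)
    embedding: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    relative_validity: float
    score_table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels != NOISE])))

    @property
    def noise_fraction(self) -> float:
        return float((self.labels == NOISE).mean())


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features[feature_columns(features)].to_numpy(dtype=float)
    return np.asarray(features, dtype=float)


def _fit_umap(X: np.ndarray, p: EmbedParams) -> umap.UMAP:
    reducer = umap.UMAP(n_neighbors=p.n_neighbors, min_dist=p.min_dist,
                        n_components=p.n_components, metric=p.metric,
                        random_state=p.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap chatters about n_jobs/gradients
        reducer.fit(X)
    return reducer


def _cluster(embedding: np.ndarray, p: ClusterParams) -> np.ndarray:
    clusterer = HDBSCAN(min_cluster_size=p.min_cluster_size,
                        min_samples=p.min_samples, copy=True)
    return clusterer.fit_predict(embedding)


def fit_embed_cluster(features, embed_params: EmbedParams | None = None,
                      cluster_params: ClusterParams | None = None) -> TunedModel:
    """Embed with UMAP, cluster the embedding with HDBSCAN, score it."""
    embed_params = embed_params or EmbedParams()
    cluster_params = cluster_params or ClusterParams()
    X = _as_matrix(features)
    if len(X) < cluster_params.min_cluster_size:
        raise ValueError(f"{len(X)} rows is fewer than min_cluster_size "
                         f"{cluster_params.min_cluster_size}")
    if len(X) <= embed_params.n_neighbors:
        raise ValueError(f"{len(X)} rows is not more than n_neighbors "
                         f"{embed_params.n_neighbors}")
    reducer = _fit_umap(X, embed_params)
    embedding = np.asarray(reducer.embedding_, dtype=float)
    labels = _cluster(embedding, cluster_params)
    return TunedModel(embed_params, cluster_params, reducer, embedding, labels,
                      relative_validity(embedding, labels))


def relative_validity(embedding: np.ndarray, labels: np.ndarray) -> float:
    """Simplified DBCV of a labelling on its embedding (noise excluded).

    Returns −1.0 when fewer than two clusters exist (worst possible score;
    the full DBCV is undefined there).
    """
    labels = np.asarray(labels)
    ids = sorted(set(labels[labels != NOISE]))
    if len(ids) < 2:
        return -1.0
    points = {c: embedding[labels == c] for c in ids}

    sparseness = {}
    for c, pts in points.items():
        if len(pts) < 2:
            sparseness[c] = 0.0
            continue
        mst = minimum_spanning_tree(squareform(pdist(pts)))
        sparseness[c] = float(mst.data.max()) if mst.nnz else 0.0

    score = 0.0
    total = sum(len(p) for p in points.values())
    for c, pts in points.items():
        sep = min(float(cdist(pts, points[o]).min()) for o in ids if o != c)
        denom = max(sep, sparseness[c])
        v = 0.0 if denom == 0 else (sep - sparseness[c]) / denom
        score += len(pts) / total * v
    return float(score)


def _all_points_core_distances(pts: np.ndarray, dim: int) -> np.ndarray:
    """Moulavi et al.'s a-pts core distance within one cluster."""
    d = squareform(pdist(pts))
    n = len(pts)
    with np.errstate(divide="ignore"):
        inv = np.where(d > 0, 1.0 / d, 0.0) ** dim
    # pairs at distance zero (duplicate rows) give unbounded density -> core 0
    dup = (d == 0) & ~np.eye(n, dtype=bool)
    s = inv.sum(axis=1)
    core = np.where(dup.any(axis=1), 0.0, (s / (n - 1)) ** (-1.0 / dim))
    return core


def dbcv_check(embedding: np.ndarray, labels: np.ndarray) -> float:
    """Independent full-DBCV implementation for small instances (n ≤ 2000).

    Density sparseness uses the maximum edge of each cluster's mutual-
    reachability minimum spanning tree restricted to internal nodes;
    separation is the minimum mutual-reachability distance between
    clusters.  Noise points count in the denominator, per the original
    definition.
    """
    embedding = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    if len(embedding) > 2000:
        raise ValueError("dbcv_check is an oracle for n <= 2000")
    ids = sorted(set(labels[labels != NOISE]))
    if len(ids) < 2:
        raise ValueError("DBCV is undefined for fewer than two clusters")
    dim = embedding.shape[1]

    core: dict[int, np.ndarray] = {}
    sparseness: dict[int, float] = {}
    for c in ids:
        pts = embedding[labels == c]
        if len(pts) < 2:
            core[c] = np.zeros(len(pts))
            sparseness[c] = 0.0
            continue
        ac = _all_points_core_distances(pts, dim)
        core[c] = ac
        d = squareform(pdist(pts))
        mreach = np.maximum(d, np.maximum.outer(ac, ac))
        np.fill_diagonal(mreach, 0.0)
        mst = minimum_spanning_tree(mreach).toarray()
        mst = mst + mst.T
        degree = (mst > 0).sum(axis=1)
        internal = degree > 1
        edges = mst[np.ix_(internal, internal)]
        if edges.any():
            sparseness[c] = float(edges.max())
        else:  # tiny clusters: no internal-internal edge, fall back to max edge
            sparseness[c] = float(mst.max())

    def separation(a: int, b: int) -> float:
        pa, pb = embedding[labels == a], embedding[labels == b]
        d = cdist(pa, pb)
        m = np.maximum(d, np.maximum.outer(core[a], core[b]))
        return float(m.min())

    validity = 0.0
    n_total = len(labels)
    for c in ids:
        sep = min(separation(c, o) for o in ids if o != c)
        denom = max(sep, sparseness[c])
        v = 0.0 if denom == 0 else (sep - sparseness[c]) / denom
        validity += (labels == c).sum() / n_total * v
    return float(validity)


def default_grid(n_rows: int, seed: int = 0,
                 metric: str = "jaccard") -> list[tuple[EmbedParams, ClusterParams]]:
    """The engine's reference grid: 3 neighbour sizes × 2 min_dist × 2 output
    dims × cluster sizes at 1%, 2.5% and 5% of the stratum."""
    sizes = sorted({max(5, int(round(f * n_rows))) for f in (0.01, 0.025, 0.05)})
    grid = []
    for nn, md, nc, mcs in itertools.product((15, 30, 50), (0.0, 0.1), (2, 3), sizes):
        if nn < n_rows:
            grid.append((EmbedParams(nn, md, nc, metric, seed),
                         ClusterParams(mcs)))
    return grid


def small_grid(n_rows: int, seed: int = 0,
               metric: str = "jaccard") -> list[tuple[EmbedParams, ClusterParams]]:
    """Compact grid for routine runs: one embedding, three cluster sizes."""
    sizes = sorted({max(5, int(round(f * n_rows))) for f in (0.025, 0.05)})
    return [(EmbedParams(30, 0.0, 2, metric, seed), ClusterParams(mcs))
            for mcs in sizes]


def tune(features, grid: list[tuple[EmbedParams, ClusterParams]]) -> TunedModel:
    """Fit every grid point, score by relative validity, return the argmax.

    Embeddings are computed once per distinct :class:`EmbedParams`.  Ties
    break by grid order.  Raises if no combination yields ≥ 2 clusters.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    X = _as_matrix(features)
    embeddings: dict[EmbedParams, tuple[umap.UMAP, np.ndarray]] = {}
    rows, results = [], []
    for ep, cp in grid:
        if ep not in embeddings:
            reducer = _fit_umap(X, ep)
            embeddings[ep] = (reducer, np.asarray(reducer.embedding_, dtype=float))
        reducer, emb = embeddings[ep]
        labels = _cluster(emb, cp)
        rv = relative_validity(emb, labels)
        n_clusters = len(set(labels[labels != NOISE]))
        rows.append({**asdict(ep), "min_cluster_size": cp.min_cluster_size,
                     "min_samples": cp.min_samples, "relative_validity": rv,
                     "n_clusters": n_clusters,
                     "noise_fraction": float((labels == NOISE).mean())})
        results.append((rv, n_clusters, ep, cp, reducer, emb, labels))
    table = pd.DataFrame(rows)
    usable = [r for r in results if r[1] >= 2]
    if not usable:
        raise ValueError("no grid point produced >= 2 clusters; revise the grid")
    best = max(usable, key=lambda r: r[0])  # max is stable: first argmax wins
    rv, _, ep, cp, reducer, emb, labels = best
    return TunedModel(ep, cp, reducer, emb, labels, rv, score_table=table)


def apply_model(model: TunedModel, features) -> np.ndarray:
    """Assign held-out rows via the trained embedding map.

    New rows are projected with the fitted UMAP transform and take the
    majority label of their 5 nearest training points in the embedding;
    rows whose nearest training point is farther than a radius calibrated
    on the training set (99th-percentile nearest-neighbour distance × 3)
    are left as noise.
    """
    X = _as_matrix(features)
    if len(X) == 0:
        return np.empty(0, dtype=int)
    expected = np.asarray(model.reducer._raw_data).shape[1]
    if X.shape[1] != expected:
        raise ValueError(f"feature dimension {X.shape[1]} does not match "
                         f"the trained model ({expected})")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emb = model.reducer.transform(X)

    train = model.embedding
    k = min(5, len(train))
    nn = NearestNeighbors(n_neighbors=k).fit(train)
    dist, idx = nn.kneighbors(emb)

    self_nn = NearestNeighbors(n_neighbors=2).fit(train)
    self_dist = self_nn.kneighbors(train)[0][:, 1]
    radius = 3.0 * float(np.percentile(self_dist, 99)) if len(train) > 1 else np.inf

    out = np.empty(len(X), dtype=int)
    neigh_labels = model.labels[idx]
    for i in range(len(X)):
        if dist[i, 0] > radius:
            out[i] = NOISE
            continue
        votes: dict[int, int] = {}
        for lab in neigh_labels[i]:
            votes[int(lab)] = votes.get(int(lab), 0) + 1
        best = max(votes.items(), key=lambda kv: (kv[1], kv[0] == neigh_labels[i][0]))
        out[i] = best[0]
    return out
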