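"""Self-organizing-map clustering, metaclustering and cluster profiling.

The clustering backbone is a rectangular-grid batch SOM: the codebook is
trained for ``rlen`` epochs under a Gaussian neighborhood whose radius
shrinks linearly, and the final event assignment is the exact
nearest-codebook-vector rule under the Euclidean metric.  SOM nodes are then
consolidated into metaclusters by average-linkage hierarchical clustering of
the codebook vectors cut at a target ``k`` (two presets in the study design:
an activation-focused k = 25 run on effector markers plus the 2-D embedding,
and a full-marker k = 50 run consolidated to 35).

Cluster profiling follows the published convention: per-marker mean
fluorescence intensity across clusters is min-max scaled to [0, 1] (a
constant marker scales to 0), protein presence is called at a scaled
threshold of 0.58, and rows/columns are ordered by average-linkage
dendrograms of the scaled matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "SelfOrganizingMap",
    "MetaclusteredSOM",
    "metacluster",
    "cluster_abundance",
    "ClusterProfile",
    "profile_clusters",
    "delta_mean_abundance",
    "outcome_association",
    "embed_2d",
    "DEFAULT_SOM_SEED",
    "DEFAULT_UMAP_SEED",
    "PRESENCE_THRESHOLD",
]

DEFAULT_SOM_SEED = 3421
DEFAULT_UMAP_SEED = 2553
PRESENCE_THRESHOLD = 0.58


class SelfOrganizingMap(ClusterMixin, BaseEstimator):
    """Batch-trained SOM on a rectangular grid.

    Parameters
    ----------
    xdim, ydim : int
        Grid dimensions; the codebook has ``xdim * ydim`` nodes.
    rlen : int
        Training epochs.  Each epoch assigns every event to its best-matching
        unit and recomputes each node as the neighborhood-weighted mean of
        the data, with the Gaussian neighborhood radius shrinking linearly
        from ``max(xdim, ydim) / 2`` to ``0.5``.
    seed : int
        Seeds the codebook initialization (random events without
        replacement where possible); training itself is deterministic.

    Attributes
    ----------
    codebook_ : ndarray of shape (xdim * ydim, n_features)
    labels_ : ndarray of node indices per training event (exact
        nearest-codebook assignment).
    grid_ : ndarray of shape (n_nodes, 2), node coordinates on the grid.
    """

    def __init__(self, xdim: int = 10, ydim: int = 10, rlen: int = 10, seed: int = DEFAULT_SOM_SEED):
        self.xdim = xdim
        self.ydim = ydim
        self.rlen = rlen
        self.seed = seed

    @property
    def n_nodes(self) -> int:
        return self.xdim * self.ydim

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        n, d = X.shape
        n_nodes = self.n_nodes
        if n < n_nodes:
            warnings.warn(
                f"fewer events ({n}) than SOM nodes ({n_nodes}); empty nodes allowed",
                stacklevel=2,
            )
        rng = np.random.default_rng(self.seed)
        gx, gy = np.meshgrid(np.arange(self.xdim), np.arange(self.ydim), indexing="ij")
        grid = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
        grid_d2 = cdist(grid, grid, metric="sqeuclidean")

        if n >= n_nodes:
            codebook = X[rng.choice(n, size=n_nodes, replace=False)].copy()
        else:
            codebook = X[rng.choice(n, size=n_nodes, replace=True)].copy()
            codebook += rng.normal(0.0, 1e-6, codebook.shape)  # break exact ties

        sigma0 = max(self.xdim, self.ydim) / 2.0
        sigma_end = 0.5
        for epoch in range(self.rlen):
            frac = epoch / max(self.rlen - 1, 1)
            sigma = sigma0 + (sigma_end - sigma0) * frac
            bmu = cdist(X, codebook, metric="sqeuclidean").argmin(axis=1)
            h = np.exp(-grid_d2 / (2.0 * sigma * sigma))  # nodes x nodes
            w = h[:, bmu]  # nodes x events
            denom = w.sum(axis=1)
            numer = w @ X
            occupied = denom > 1e-12
            codebook[occupied] = numer[occupied] / denom[occupied, None]

        self.codebook_ = codebook
        self.grid_ = grid
        self.n_features_in_ = d
        self.labels_ = self._nearest(X)
        return self

    def _nearest(self, X: np.ndarray) -> np.ndarray:
        return cdist(np.asarray(X, dtype=float), self.codebook_, metric="sqeuclidean").argmin(axis=1)

    def predict(self, X):
        check_is_fitted(self, "codebook_")
        X = check_array(X, dtype=float)
        return self._nearest(X)

    def occupied_nodes(self) -> np.ndarray:
        """Node indices with at least one assigned training event."""
        check_is_fitted(self, "labels_")
        return np.unique(self.labels_)


def metacluster(
    codebook: np.ndarray,
    k: int,
    occupied: np.ndarray | None = None,
    method: str = "average",
) -> np.ndarray:
    """Consolidate SOM nodes into ``k`` metaclusters.

    Average-linkage hierarchical clustering of the codebook vectors cut at
    ``k`` clusters.  Only ``occupied`` nodes participate when given; empty
    nodes map to -1.  Metacluster labels run 1..k.  ``k`` equal to the number
    of participating nodes yields the identity partition.
    """
    codebook = np.asarray(codebook, dtype=float)
    n_nodes = codebook.shape[0]
    idx = np.arange(n_nodes) if occupied is None else np.asarray(occupied)
    if not 1 <= k <= len(idx):
        raise ValueError(f"k must lie in [1, {len(idx)}], got {k}")
    mapping = np.full(n_nodes, -1, dtype=int)
    if k == len(idx):
        mapping[idx] = np.arange(1, k + 1)
        return mapping
    Z = linkage(codebook[idx], method=method, metric="euclidean")
    mapping[idx] = fcluster(Z, t=k, criterion="maxclust")
    return mapping


class MetaclusteredSOM(ClusterMixin, BaseEstimator):
    """SOM followed by average-linkage metaclustering of the codebook.

    ``fit`` trains the SOM and cuts the codebook dendrogram at
    ``n_metaclusters``; ``predict`` maps events to metacluster labels 1..k
    via their nearest codebook node.
    """

    def __init__(
        self,
        n_metaclusters: int = 35,
        xdim: int = 10,
        ydim: int = 10,
        rlen: int = 10,
        seed: int = DEFAULT_SOM_SEED,
        linkage_method: str = "average",
    ):
        self.n_metaclusters = n_metaclusters
        self.xdim = xdim
        self.ydim = ydim
        self.rlen = rlen
        self.seed = seed
        self.linkage_method = linkage_method

    def fit(self, X, y=None):
        self.som_ = SelfOrganizingMap(self.xdim, self.ydim, self.rlen, self.seed).fit(X)
        occupied = self.som_.occupied_nodes()
        self.node_map_ = metacluster(
            self.som_.codebook_, self.n_metaclusters, occupied=occupied, method=self.linkage_method
        )
        self.labels_ = self.node_map_[self.som_.labels_]
        return self

    def predict(self, X):
        check_is_fitted(self, "node_map_")
        return self.node_map_[self.som_.predict(X)]


def cluster_abundance(
    assignments: Sequence,
    sample_ids: Sequence,
    samples: Sequence | None = None,
) -> pd.DataFrame:
    """Sample x cluster percentage table; every non-empty row sums to 100.

    ``samples`` may list expected sample ids; a sample with zero events gets
    a row of NaN.
    """
    assignments = np.asarray(assignments)
    sample_ids = np.asarray(sample_ids)
    if len(assignments) != len(sample_ids):
        raise ValueError("assignments and sample_ids must align")
    counts = pd.crosstab(pd.Series(sample_ids, name="sample"), pd.Series(assignments, name="cluster"))
    if samples is not None:
        counts = counts.reindex(list(samples), fill_value=0)
    totals = counts.sum(axis=1)
    abund = counts.div(totals, axis=0) * 100.0
    abund[totals == 0] = np.nan
    return abund


@dataclass
class ClusterProfile:
    """Cluster x marker expression profile.

    ``mfi``: raw mean intensity per cluster and marker; ``scaled``: the
    per-marker min-max scaled twin in [0, 1] (constant marker -> 0);
    ``presence``: boolean calls at ``threshold``; ``row_order`` /
    ``col_order``: dendrogram leaf orders from average-linkage clustering of
    the scaled matrix.
    """

    mfi: pd.DataFrame
    scaled: pd.DataFrame
    presence: pd.DataFrame
    threshold: float
    row_order: list = field(default_factory=list)
    col_order: list = field(default_factory=list)


def minmax_scale_profiles(mfi: pd.DataFrame) -> pd.DataFrame:
    """Per-marker (column) min-max scaling across clusters; ties map to 0."""
    lo = mfi.min(axis=0)
    rng = mfi.max(axis=0) - lo
    scaled = (mfi - lo).div(rng.where(rng > 0, 1.0), axis=1)
    scaled.loc[:, rng <= 0] = 0.0
    return scaled


def profile_clusters(
    X,
    assignments: Sequence,
    channel_names: Sequence[str] | None = None,
    threshold: float = PRESENCE_THRESHOLD,
    linkage_method: str = "average",
) -> ClusterProfile:
    """Mean-intensity profile per cluster with min-max scaling and presence calls."""
    if isinstance(X, pd.DataFrame):
        channel_names = list(X.columns) if channel_names is None else list(channel_names)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if channel_names is None:
            channel_names = [f"ch{i}" for i in range(X.shape[1])]
    assignments = np.asarray(assignments)
    clusters = np.unique(assignments)
    if len(clusters) < 2:
        raise ValueError("profiling requires at least 2 clusters for min-max scaling")
    mfi = pd.DataFrame(
        np.vstack([X[assignments == c].mean(axis=0) for c in clusters]),
        index=pd.Index(clusters, name="cluster"),
        columns=channel_names,
    )
    scaled = minmax_scale_profiles(mfi)
    presence = scaled >= threshold

    row_order = list(mfi.index[leaves_list(linkage(scaled.to_numpy(), method=linkage_method))])
    col_order = list(mfi.columns[leaves_list(linkage(scaled.to_numpy().T, method=linkage_method))]) if scaled.shape[1] >= 2 else list(mfi.columns)
    return ClusterProfile(mfi=mfi, scaled=scaled, presence=presence, threshold=threshold,
                          row_order=row_order, col_order=col_order)


def delta_mean_abundance(
    abundance: pd.DataFrame,
    groups: Mapping,
    group_a: str = "C7R",
    group_b: str = "GD2",
) -> pd.Series:
    """Per-cluster difference of group mean abundances: mean(a) - mean(b).

    Sign convention (C7R minus CAR-only by default) is recorded on the
    result's ``attrs``.  Because every sample's abundances sum to 100, the
    deltas sum to 0 across clusters.
    """
    labels = pd.Series({s: groups[s] for s in abundance.index})
    a = abundance.loc[labels == group_a]
    b = abundance.loc[labels == group_b]
    if a.empty or b.empty:
        raise ValueError(f"both groups must be non-empty ({group_a}: {len(a)}, {group_b}: {len(b)})")
    delta = a.mean(axis=0) - b.mean(axis=0)
    delta.name = "delta_mean_abundance"
    delta.attrs["convention"] = f"mean({group_a}) - mean({group_b})"
    return delta


def outcome_association(abundance: pd.DataFrame, outcomes: Mapping) -> pd.DataFrame:
    """Spearman rank correlation of each cluster's abundance with ordinal outcome.

    Outcomes are ordinal clinical scores (PD=0 < SD=1 < PR=2).  Clusters with
    constant abundance yield an undefined (NaN) rho, flagged in the output.
    """
    y = np.asarray([outcomes[s] for s in abundance.index], dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 samples with outcomes")
    rows = []
    for cluster in abundance.columns:
        x = abundance[cluster].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            rows.append((cluster, np.nan, np.nan, True))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, p = spearmanr(x, y)
        rows.append((cluster, float(rho), float(p), False))
    return pd.DataFrame(rows, columns=["cluster", "rho", "p", "undefined"]).set_index("cluster")


def embed_2d(
    X,
    n_neighbors: int = 15,
    min_dist: float = 0.4,
    seed: int = DEFAULT_UMAP_SEED,
    n_epochs: int = 200,
):
    """2-D neighbor embedding of events (delegated to umap-learn).

    Euclidean metric, spectral initialization, fixed seed; used for
    visualization and optionally appended as clustering features.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < n_neighbors + 1:
        raise ValueError(f"need at least n_neighbors + 1 = {n_neighbors + 1} events, got {X.shape[0]}")
    import umap  # deferred: heavy import

    reducer = umap.UMAP(
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        n_components=2,
        metric="euclidean",
        learning_rate=1.0,
        n_epochs=n_epochs,
        init="spectral",
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return reducer.fit_transform(X)
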