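"""Base clustering algorithms and cluster-ensemble generation.

Five clusterers of deliberately different persuasions build the ensemble:
k-means (centroid), unsupervised LVQ (competitive prototypes), EM on a
diagonal Gaussian mixture (distribution), MDB (density reassignment of a
k-means partition, in the style of Weka's MakeDensityBasedClusterer) and
agglomerative hierarchical clustering (pairwise distance).  Under the
default grid the ensemble holds 31 partitions: k-means x10, EM x10,
LVQ x4 (learning rates 0.05/0.07/0.09/0.1), MDB x1 and AH x6
(complete/average linkage x Euclidean/Manhattan/Minkowski-3 distances).
The number of clusters is fixed at 2 (epithelium vs stroma) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.mixture import GaussianMixture

from .errors import InsufficientDataError

#: range the per-run count of random initial centre candidates is drawn from
SEED_COUNT_RANGE = (10, 200)
LVQ_LEARNING_RATES = (0.05, 0.07, 0.09, 0.1)
AH_GRID = tuple(
    (link, metric)
    for link in ("complete", "average")
    for metric in ("euclidean", "manhattan", "minkowski3")
)


@dataclass(frozen=True)
class Partition:
    """A clustering of n objects with provenance.

    Cluster ids are arbitrary symbols: two partitions that differ only by
    a label permutation represent the same clustering.
    """

    labels: np.ndarray
    algorithm: str
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "labels", np.asarray(self.labels))

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def k(self) -> int:
        return len(np.unique(self.labels))


class Ensemble(list):
    """Ordered collection of Partitions over the same objects."""

    def __init__(self, partitions=()):
        partitions = list(partitions)
        ns = {p.n for p in partitions}
        if len(ns) > 1:
            raise InsufficientDataError(f"partitions disagree on n: {sorted(ns)}")
        super().__init__(partitions)

    @property
    def n(self) -> int:
        return self[0].n if self else 0

    def labels_matrix(self) -> np.ndarray:
        """(n, C) matrix, one column per partition."""
        return np.stack([p.labels for p in self], axis=1)


def _check_data(x: np.ndarray, k: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or len(x) < k:
        raise InsufficientDataError(f"need >= {k} rows of 2-D data, got shape {x.shape}")
    return x


def kmeans_cluster(x, k=2, n_seed_candidates=10, rng_seed=0) -> Partition:
    """k-means with ``n_seed_candidates`` random initialisations (best by inertia)."""
    x = _check_data(x, k)
    km = KMeans(n_clusters=k, init="random", n_init=n_seed_candidates,
                random_state=rng_seed)
    labels = km.fit_predict(x)
    return Partition(labels, "kmeans",
                     {"n_seed_candidates": n_seed_candidates}, rng_seed)


def em_cluster(x, k=2, n_seed_candidates=10, rng_seed=0,
               max_iter=100, tol=1e-6) -> Partition:
    """EM on a diagonal-covariance Gaussian mixture, random initialisation."""
    x = _check_data(x, k)
    gm = GaussianMixture(n_components=k, covariance_type="diag",
                         init_params="random", n_init=n_seed_candidates,
                         max_iter=max_iter, tol=tol, reg_covar=1e-6,
                         random_state=rng_seed)
    labels = gm.fit_predict(x)
    return Partition(labels, "em",
                     {"n_seed_candidates": n_seed_candidates}, rng_seed)


def lvq_cluster(x, k=2, learning_rate=0.05, epochs=100, rng_seed=0,
                restarts=5) -> Partition:
    """Unsupervised LVQ: winner-take-all competitive prototype learning.

    k prototypes start at random data rows; at every sample presentation
    the nearest prototype moves toward the sample by rate*(x - w), the
    rate decaying linearly to 0 over the epochs.  The final partition
    assigns each object to its nearest prototype.  Winner-take-all
    learning can strand a prototype (a "dead unit") when all starts fall
    in one cluster, so the run is restarted from fresh random rows and
    the restart with the lowest quantisation error is kept.
    """
    x = _check_data(x, k)
    if not 0 <= learning_rate < 1:
        raise InsufficientDataError(f"learning rate must be in [0, 1), got {learning_rate}")
    rng = np.random.default_rng(rng_seed)
    total = epochs * len(x)
    best_labels, best_sse = None, np.inf
    for _ in range(max(restarts, 1)):
        protos = x[rng.choice(len(x), size=k, replace=False)].copy()
        step = 0
        for _ in range(epochs):
            order = rng.permutation(len(x))
            for i in order:
                rate = learning_rate * (1.0 - step / total)
                d = ((protos - x[i]) ** 2).sum(axis=1)
                w = int(np.argmin(d))
                protos[w] += rate * (x[i] - protos[w])
                step += 1
        d = ((x[:, None, :] - protos[None, :, :]) ** 2).sum(axis=2)
        sse = float(d.min(axis=1).sum())
        if sse < best_sse:
            best_sse, best_labels = sse, np.argmin(d, axis=1)
    return Partition(best_labels, "lvq", {"learning_rate": learning_rate,
                                          "epochs": epochs}, rng_seed)


def mdb_cluster(x, k=2, rng_seed=0, variance_floor_frac=1e-6) -> Partition:
    """Make-Density-Based clustering: k-means, then Gaussian reassignment.

    Each k-means cluster is modelled by independent per-feature normal
    densities and a prior equal to its relative size; every object is
    reassigned to the cluster of maximal posterior density.  Cluster
    variances are floored at ``variance_floor_frac`` of the global
    feature variance; posterior ties go to the lower cluster index.
    """
    x = _check_data(x, k)
    base = kmeans_cluster(x, k=k, n_seed_candidates=10, rng_seed=rng_seed)
    labels = base.labels
    global_var = x.var(axis=0)
    floor = np.maximum(variance_floor_frac * global_var, 1e-12)
    log_post = np.empty((len(x), k))
    for c in range(k):
        members = x[labels == c]
        if len(members) == 0:
            log_post[:, c] = -np.inf
            continue
        mu = members.mean(axis=0)
        var = np.maximum(members.var(axis=0), floor)
        prior = len(members) / len(x)
        ll = -0.5 * (np.log(2 * np.pi * var) + (x - mu) ** 2 / var).sum(axis=1)
        log_post[:, c] = np.log(prior) + ll
    new_labels = np.argmax(log_post, axis=1)  # argmax takes the lower index on ties
    return Partition(new_labels, "mdb", {}, rng_seed)


def ah_cluster(x, k=2, linkage="average", metric="euclidean") -> Partition:
    """Agglomerative hierarchical clustering cut at k clusters.

    Distances are precomputed so Manhattan and Minkowski p=3 runs share
    one code path with Euclidean.
    """
    x = _check_data(x, k)
    if metric == "minkowski3":
        d = squareform(pdist(x, metric="minkowski", p=3))
    elif metric == "manhattan":
        d = squareform(pdist(x, metric="cityblock"))
    else:
        d = squareform(pdist(x, metric=metric))
    model = AgglomerativeClustering(n_clusters=k, metric="precomputed",
                                    linkage=linkage)
    labels = model.fit_predict(d)
    return Partition(labels, "ah", {"linkage": linkage, "metric": metric})


def _rerun(algorithm: str, params: dict, x, k, rng):
    """Fresh stochastic run of one algorithm (used for selection replacement)."""
    seed = int(rng.integers(0, 2**31 - 1))
    if algorithm == "kmeans":
        n_cand = int(rng.integers(SEED_COUNT_RANGE[0], SEED_COUNT_RANGE[1] + 1))
        return kmeans_cluster(x, k, n_cand, seed)
    if algorithm == "em":
        n_cand = int(rng.integers(SEED_COUNT_RANGE[0], SEED_COUNT_RANGE[1] + 1))
        return em_cluster(x, k, n_cand, seed)
    if algorithm == "lvq":
        return lvq_cluster(x, k, params["learning_rate"], params.get("epochs", 100), seed)
    if algorithm == "mdb":
        return mdb_cluster(x, k, seed)
    return None  # AH runs are deterministic per configuration


def generate_ensemble(x, k=2, rng_seed=0,
                      n_kmeans=10, n_em=10,
                      lvq_rates=LVQ_LEARNING_RATES,
                      ah_grid=AH_GRID) -> Ensemble:
    """The default clustering ensemble (31 partitions under the standard grid).

    ``x`` should already be z-standardised.  Per stochastic run, the
    count of random initial centre candidates is drawn uniformly from
    [10, 200]; all randomness flows from ``rng_seed``.
    """
    x = _check_data(x, k)
    rng = np.random.default_rng(rng_seed)
    parts = []
    for _ in range(n_kmeans):
        n_cand = int(rng.integers(SEED_COUNT_RANGE[0], SEED_COUNT_RANGE[1] + 1))
        parts.append(kmeans_cluster(x, k, n_cand, int(rng.integers(2**31 - 1))))
    for _ in range(n_em):
        n_cand = int(rng.integers(SEED_COUNT_RANGE[0], SEED_COUNT_RANGE[1] + 1))
        parts.append(em_cluster(x, k, n_cand, int(rng.integers(2**31 - 1))))
    for rate in lvq_rates:
        parts.append(lvq_cluster(x, k, rate, rng_seed=int(rng.integers(2**31 - 1))))
    parts.append(mdb_cluster(x, k, rng_seed=int(rng.integers(2**31 - 1))))
    for link, metric in ah_grid:
        parts.append(ah_cluster(x, k, link, metric))
    return Ensemble(parts)
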