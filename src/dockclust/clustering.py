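"""Density-based clustering with automatic neighborhood-radius selection.

DBSCAN is implemented from its definition rather than wrapped from a
library, because the whole selection machinery around it needs pinned,
reproducible semantics:

* a *core point* has at least ``k`` points (itself included) within
  distance <= eps;
* clusters are the maximal density-connected sets: connected components of
  the eps-neighborhood graph restricted to core points, plus border points
  attached to the first cluster whose expansion reaches them (points are
  processed in row order, so the labeling is deterministic for a fixed
  input order);
* everything else is noise, labeled 0 ("Cluster 0").

The radius eps is chosen automatically: candidate values are percentiles of
the k-distance profile (distance of each point to its k-th nearest
neighbor), each candidate is clustered and scored by four cluster-validity
indexes — Davies-Bouldin (x -1), Calinski-Harabasz, Hubert-Levine C-index
(x -1) and Silhouette, all oriented so larger is better — and the candidate
with the best mean rank across the four indexes wins.  Finally, clusters
smaller than ``min_cluster_size`` are discarded to noise and the survivors
relabeled 1..G by decreasing size.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .embedding import FeatureMatrix
from .errors import InputError

INDEX_NAMES = ("davies_bouldin_neg", "calinski_harabasz", "c_index_neg", "silhouette")


@dataclass(frozen=True)
class ClusteringParams:
    """DBSCAN tuning parameters.

    k
        Minimum neighbor count defining a core point (MinPts), self
        included.  Default 15.
    eps
        Neighborhood radius; ``None`` requests automatic selection.
    min_cluster_size
        Clusters with fewer members are discarded to noise.  Default 15.
    """

    k: int = 15
    eps: float | None = None
    min_cluster_size: int = 15

    def __post_init__(self) -> None:
        if self.k < 2:
            raise InputError(f"k must be >= 2, got {self.k}")
        if self.eps is not None and not self.eps > 0:
            raise InputError(f"eps must be positive when fixed, got {self.eps}")
        if self.min_cluster_size < 1:
            raise InputError("min_cluster_size must be >= 1")


def _feature_values(features) -> np.ndarray:
    return features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)


def dbscan(features, params: ClusteringParams) -> np.ndarray:
    """Label points by density connectivity at a fixed radius.

    Returns a length-n integer vector: 0 for noise, 1..G for clusters in
    discovery (row) order.  ``n < k`` cannot produce any core point, so all
    points are noise (with a warning).
    """
    X = _feature_values(features)
    n = X.shape[0]
    if params.eps is None:
        raise InputError("dbscan requires a fixed eps; use select_epsilon first")
    eps = float(params.eps)
    labels = np.zeros(n, dtype=int)
    if n < params.k:
        warnings.warn(
            f"n={n} < k={params.k}: no core point possible, all points are noise",
            stacklevel=2,
        )
        return labels
    D = squareform(pdist(X))
    neighbor_counts = (D <= eps).sum(axis=1)  # includes self (diagonal is 0)
    core = neighbor_counts >= params.k
    cluster_id = 0
    for seed in range(n):
        if labels[seed] != 0 or not core[seed]:
            continue
        cluster_id += 1
        labels[seed] = cluster_id
        queue = deque([seed])
        while queue:
            p = queue.popleft()
            if not core[p]:
                continue  # border points do not expand the cluster
            for q in np.flatnonzero(D[p] <= eps):
                if labels[q] == 0:
                    labels[q] = cluster_id
                    queue.append(q)
    return labels


def kdist_profile(features, k: int) -> np.ndarray:
    """Sorted (ascending) distances of every point to its k-th nearest
    neighbor, self excluded — the classic device for proposing eps."""
    X = _feature_values(features)
    n = X.shape[0]
    if n <= k:
        raise InputError(f"kdist_profile needs n > k (n={n}, k={k})")
    D = squareform(pdist(X))
    kth = np.sort(D, axis=1)[:, k]  # column 0 is the self-distance 0
    return np.sort(kth)


def epsilon_candidates(profile: np.ndarray) -> np.ndarray:
    """Eps candidates: nearest-rank percentiles 5, 10, ..., 95 of the
    positive k-distances, deduplicated, ascending; never empty."""
    profile = np.sort(np.asarray(profile, dtype=float))
    positive = profile[profile > 0]
    if positive.size == 0:
        warnings.warn(
            "all k-distances are zero; falling back to a machine-epsilon radius",
            stacklevel=2,
        )
        return np.array([np.finfo(float).eps])
    m = positive.size
    # nearest-rank percentile index ceil(p*m/100) - 1, in exact integer math
    ranks = np.array([-((-p * m) // 100) - 1 for p in range(5, 100, 5)], dtype=int)
    return np.unique(positive[ranks])


@dataclass
class QualityIndexes:
    """The four cluster-validity indexes, all oriented larger-is-better."""

    davies_bouldin_neg: float
    calinski_harabasz: float
    c_index_neg: float
    silhouette: float
    eligible: bool = True

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (
            self.davies_bouldin_neg,
            self.calinski_harabasz,
            self.c_index_neg,
            self.silhouette,
        )


INELIGIBLE = QualityIndexes(np.nan, np.nan, np.nan, np.nan, eligible=False)


def clustering_quality(
    features, labels: np.ndarray, noise_as_group: bool = True
) -> QualityIndexes:
    """Evaluate a labeling with the four validity indexes.

    Euclidean distances in feature space throughout.  Fewer than two real
    clusters make a labeling ineligible (returned as a marker, not an
    exception).  With ``noise_as_group=True`` (the default) the noise
    points enter the computation as one extra diffuse group, so radii that
    shed much of the data as noise are penalized; with ``False`` noise
    points are dropped, which systematically favors the tightest cores and
    hence the smallest radius.
    """
    X = _feature_values(features)
    labels = np.asarray(labels)
    if np.unique(labels[labels > 0]).size < 2:
        return INELIGIBLE
    mask = np.ones(len(labels), bool) if noise_as_group else labels > 0
    y = labels[mask]
    P = X[mask]
    groups = np.unique(y)
    G = groups.size
    np_ = P.shape[0]

    members = [np.flatnonzero(y == g) for g in groups]
    centroids = np.array([P[m].mean(axis=0) for m in members])
    grand = P.mean(axis=0)

    # Davies-Bouldin: mean over clusters of the worst (S_i + S_j) / d(c_i, c_j)
    S = np.array(
        [np.linalg.norm(P[m] - c, axis=1).mean() for m, c in zip(members, centroids)]
    )
    cdist = squareform(pdist(centroids))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (S[:, None] + S[None, :]) / cdist
    np.fill_diagonal(ratio, -np.inf)
    db = float(np.max(ratio, axis=1).mean())

    # Calinski-Harabasz: between/within variance ratio
    sizes = np.array([len(m) for m in members])
    trace_b = float((sizes * ((centroids - grand) ** 2).sum(axis=1)).sum())
    trace_w = float(
        sum(((P[m] - c) ** 2).sum() for m, c in zip(members, centroids))
    )
    if trace_w > 0 and np_ > G:
        ch = (trace_b / (G - 1)) / (trace_w / (np_ - G))
    else:
        ch = np.inf if trace_b > 0 else 0.0

    # Hubert-Levine C-index on within-cluster pair distances
    d_all = pdist(P)
    iu, ju = np.triu_indices(np_, k=1)
    d_within = d_all[y[iu] == y[ju]]
    n_w = d_within.size
    d_sorted = np.sort(d_all)
    s_w = float(d_within.sum())
    s_min = float(d_sorted[:n_w].sum())
    s_max = float(d_sorted[-n_w:].sum()) if n_w else 0.0
    c_index = (s_w - s_min) / (s_max - s_min) if s_max > s_min else 0.0

    # Silhouette: mean of (b - a) / max(a, b); singleton members score 0
    D = squareform(d_all)
    sil = np.zeros(np_)
    for gi, m in enumerate(members):
        size = len(m)
        if size == 1:
            continue
        a = D[np.ix_(m, m)].sum(axis=1) / (size - 1)
        b = np.full(size, np.inf)
        for gj, mj in enumerate(members):
            if gj == gi:
                continue
            b = np.minimum(b, D[np.ix_(m, mj)].mean(axis=1))
        denom = np.maximum(a, b)
        sil[m] = np.where(denom > 0, (b - a) / denom, 0.0)
    silhouette = float(sil.mean())

    return QualityIndexes(-db, float(ch), -float(c_index), silhouette)


@dataclass
class CandidateEvaluation:
    """Scorecard of one eps candidate in the automatic selection."""

    eps: float
    n_clusters: int
    noise_count: int
    indexes: QualityIndexes
    ranks: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    mean_rank: float = 0.0
    eligible: bool = False
    chosen: bool = False


def select_epsilon(
    features, candidates, params: ClusteringParams
) -> tuple[float, list[CandidateEvaluation]]:
    """Run DBSCAN for every eps candidate and pick the consensus winner.

    Candidates are ranked per index (best value -> highest rank number,
    ties share the mean of the tied ranks; candidates with fewer than two
    clusters get rank 0 on every index); the score is the mean of the four
    ranks and the highest score wins, smaller eps breaking ties.  If no
    candidate yields two clusters the fallback maximizes the non-noise
    fraction.
    """
    candidates = np.sort(np.asarray(list(candidates), dtype=float))
    if candidates.size == 0:
        raise InputError("no eps candidates supplied")
    evals: list[CandidateEvaluation] = []
    for eps in candidates:
        labels = dbscan(features, replace(params, eps=float(eps)))
        q = clustering_quality(features, labels)
        evals.append(
            CandidateEvaluation(
                eps=float(eps),
                n_clusters=int(labels.max()),
                noise_count=int((labels == 0).sum()),
                indexes=q,
                eligible=q.eligible,
            )
        )
    eligible = np.array([e.eligible for e in evals])
    ranks = np.zeros((len(evals), 4))
    if eligible.any():
        values = np.array([e.indexes.as_tuple() for e in evals])
        for j in range(4):
            col = values[eligible, j]
            # +inf ties with +inf share the top rank; rankdata handles it
            ranks[eligible, j] = rankdata(col, method="average")
        scores = ranks.mean(axis=1)
        scores[~eligible] = 0.0
        best = int(np.argmax(scores))  # argmax takes the first = smallest eps
    else:
        warnings.warn(
            "no eps candidate produced >= 2 clusters; "
            "falling back to the largest non-noise fraction",
            stacklevel=2,
        )
        n = _feature_values(features).shape[0]
        non_noise = np.array([n - e.noise_count for e in evals])
        best = int(np.argmax(non_noise))
        scores = np.zeros(len(evals))
    for e, r, s in zip(evals, ranks, scores):
        e.ranks = tuple(float(x) for x in r)
        e.mean_rank = float(s)
    evals[best].chosen = True
    return evals[best].eps, evals


def finalize_labels(labels: np.ndarray, params: ClusteringParams) -> np.ndarray:
    """Discard clusters below ``min_cluster_size`` to noise and relabel the
    survivors 1..G by decreasing size (ties: earlier first-member row)."""
    labels = np.asarray(labels)
    out = np.zeros_like(labels)
    survivors = []
    for g in np.unique(labels[labels > 0]):
        members = np.flatnonzero(labels == g)
        if members.size >= params.min_cluster_size:
            survivors.append((-members.size, members[0], g))
    survivors.sort()
    for new_label, (_, _, g) in enumerate(survivors, start=1):
        out[labels == g] = new_label
    return out


def write_eps_selection(evals: list[CandidateEvaluation], path) -> None:
    """TSV report of the eps selection: one row per candidate."""
    from pathlib import Path

    header = (
        ["eps", "n_clusters", "noise_count"]
        + list(INDEX_NAMES)
        + [f"rank_{n}" for n in INDEX_NAMES]
        + ["mean_rank", "eligible", "chosen"]
    )
    lines = ["\t".join(header)]
    for e in evals:
        vals = e.indexes.as_tuple()
        lines.append(
            "\t".join(
                [format(e.eps, ".10g"), str(e.n_clusters), str(e.noise_count)]
                + [format(v, ".10g") for v in vals]
                + [format(r, ".10g") for r in e.ranks]
                + [format(e.mean_rank, ".10g"), str(int(e.eligible)), str(int(e.chosen))]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
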