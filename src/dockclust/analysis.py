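"""Cluster summaries, representative poses, outcome flag and marker lookup.

After clustering, each surviving cluster is condensed to a single
*representative solution* — a member that is both central (close to its
co-members in feature space) and strongly scored.  Centrality and score are
combined by rank averaging: within a cluster every member gets an ascending
centrality rank (1 = medoid, the member with the smallest summed distance
to co-members) and an ascending energy rank (1 = best score); the member
with the smallest mean of the two ranks is the representative.  Rank
averaging is scale-free, so neither quantity dominates by units.

A whole run is then flagged: *satisfactory* when at least one cluster is
significant (large and well-scored), *static_candidate* when the top-scored
solutions are concentrated in the noise (a tightly constrained binding site
produces high-energy contacts that never grow into a dense cluster),
*unsatisfactory* when only weak, low-energy clusters exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .embedding import FeatureMatrix
from .errors import InputError
from .io_docking import DockingTable


@dataclass(frozen=True)
class AnalysisThresholds:
    """Tunable constants of the significance and outcome heuristics.

    significant cluster: size >= max(min_cluster_size, min_size_fraction*n)
    AND mean member score >= the ``score_percentile``-th percentile of all
    solution scores.  static candidate: at least ``static_noise_min`` of the
    ``static_top_n`` best-scored solutions are noise.
    """

    min_size_fraction: float = 0.05
    score_percentile: float = 75.0
    static_top_n: int = 10
    static_noise_min: int = 3


@dataclass
class ClusterSummary:
    cluster: int
    size: int
    mean_score: float
    median_score: float
    representative_id: int | None
    significant: bool


@dataclass
class MarkedSolution:
    id: int
    cluster: int
    score: float
    is_representative: bool


@dataclass
class AnalysisReport:
    summaries: list[ClusterSummary]
    outcome: str
    marked: list[MarkedSolution] = field(default_factory=list)
    noise_count: int = 0


def summarize_clusters(
    table: DockingTable,
    labels: np.ndarray,
    representatives: dict[int, int] | None = None,
    min_cluster_size: int = 15,
    thresholds: AnalysisThresholds = AnalysisThresholds(),
) -> list[ClusterSummary]:
    """One summary per finalized cluster 1..G, in label (hence size) order."""
    labels = np.asarray(labels)
    scores = table.scores()
    cutoff = float(np.percentile(scores, thresholds.score_percentile))
    min_size = max(min_cluster_size, thresholds.min_size_fraction * table.n)
    reps = representatives or {}
    summaries = []
    for g in range(1, int(labels.max()) + 1 if labels.size else 1):
        members = np.flatnonzero(labels == g)
        if members.size == 0:
            continue
        mean = float(scores[members].mean())
        summaries.append(
            ClusterSummary(
                cluster=int(g),
                size=int(members.size),
                mean_score=mean,
                median_score=float(np.median(scores[members])),
                representative_id=reps.get(int(g)),
                significant=bool(members.size >= min_size and mean >= cutoff),
            )
        )
    return summaries


def select_representatives(
    features: FeatureMatrix, table: DockingTable, labels: np.ndarray
) -> dict[int, int]:
    """Pick the representative solution of every cluster.

    Returns ``{cluster label: solution id}``.  Ties on the mean rank go to
    the better score, then to the lower solution id.
    """
    labels = np.asarray(labels)
    X = features.values
    ids = table.ids()
    scores = table.scores()
    reps: dict[int, int] = {}
    for g in np.unique(labels[labels > 0]):
        members = np.flatnonzero(labels == g)
        sub = X[members]
        summed = squareform(pdist(sub)).sum(axis=1) if members.size > 1 else np.zeros(1)
        centrality_rank = rankdata(summed, method="average")
        energy_rank = rankdata(-scores[members], method="average")
        mean_rank = (centrality_rank + energy_rank) / 2.0
        order = sorted(
            range(members.size),
            key=lambda i: (mean_rank[i], -scores[members[i]], ids[members[i]]),
        )
        reps[int(g)] = int(ids[members[order[0]]])
    return reps


def flag_outcome(
    summaries: list[ClusterSummary],
    table: DockingTable,
    labels: np.ndarray,
    thresholds: AnalysisThresholds = AnalysisThresholds(),
) -> str:
    """Classify the docking run.

    ``satisfactory`` — at least one significant cluster; else
    ``static_candidate`` — >= static_noise_min of the static_top_n
    best-scored solutions are noise; else ``unsatisfactory`` — clusters
    exist but every cluster mean is below the global median score; else
    ``indeterminate``.
    """
    labels = np.asarray(labels)
    if any(s.significant for s in summaries):
        return "satisfactory"
    scores = table.scores()
    # stable tie-break so the top-N set is reproducible
    order = np.lexsort((table.ids(), -scores))
    top = order[: thresholds.static_top_n]
    if (labels[top] == 0).sum() >= thresholds.static_noise_min:
        return "static_candidate"
    if summaries and all(s.mean_score < float(np.median(scores)) for s in summaries):
        return "unsatisfactory"
    return "indeterminate"


def locate_markers(
    table: DockingTable,
    labels: np.ndarray,
    marked_ids,
    representatives: dict[int, int] | None = None,
) -> list[MarkedSolution]:
    """Look up user-marked solution ids: cluster, score, representative flag."""
    labels = np.asarray(labels)
    rep_ids = set((representatives or {}).values())
    out = []
    for sid in marked_ids:
        idx = table.index_of(int(sid))  # raises InputError naming unknown ids
        out.append(
            MarkedSolution(
                id=int(sid),
                cluster=int(labels[idx]),
                score=float(table.solutions[idx].score),
                is_representative=int(sid) in rep_ids,
            )
        )
    return out


def write_clusters(summaries: list[ClusterSummary], path) -> None:
    from pathlib import Path

    lines = ["cluster\tsize\tmean_score\tmedian_score\trepresentative_id\tsignificant"]
    for s in summaries:
        lines.append(
            f"{s.cluster}\t{s.size}\t{s.mean_score:.10g}\t{s.median_score:.10g}"
            f"\t{s.representative_id if s.representative_id is not None else ''}"
            f"\t{int(s.significant)}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_representatives(
    table: DockingTable, representatives: dict[int, int], path
) -> None:
    """TSV of representative solutions, one row per cluster, label order."""
    from pathlib import Path

    lines = ["cluster\tsolution_id\tscore"]
    for g in sorted(representatives):
        sid = representatives[g]
        idx = table.index_of(sid)
        lines.append(f"{g}\t{sid}\t{table.solutions[idx].score:.10g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
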