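"""Synthetic docking tables with planted ground truth.

Rigid-body docking output is emulated as a mixture on the angle-torus x
translation-box: each planted binding mode is a cluster center (an angle
triple on [0, 2*pi)^3 and a translation inside a cubic box) around which
members scatter with wrapped-Gaussian angular noise and Gaussian
translational noise; outliers are uniform over the whole space.  Scores are
Gaussian per group, with outliers drawn from a lower-mean distribution, so
clusters are both dense and well scored — the structure the clustering
pipeline is meant to find.

The generator is fully deterministic given its seed: the same spec always
produces a byte-identical table.  Defaults describe a well-separated
docking run: four binding modes of 50 solutions each, angular noise
0.1 rad, translational noise 0.5 angstrom in a 30 angstrom box, centers at
least 10 noise standard deviations apart, and a 20% outlier load.  One
center sits exactly at angle (0, 0, 0) so that its members straddle the
0/2*pi wrap — the case that breaks naive Euclidean treatment of angles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .angular import solution_angle_distance
from .errors import ConfigError
from .io_docking import TWO_PI, DockingSolution, DockingTable


@dataclass(frozen=True)
class ScoreModel:
    """Per-group Gaussian interaction-score model (larger = better).

    ``cluster_means=None`` auto-assigns decreasing means 100 + 10*G, ...,
    110 so cluster 1 scores best; outliers score well below any cluster.
    """

    cluster_means: tuple[float, ...] | None = None
    cluster_sd: float = 5.0
    outlier_mean: float = 60.0
    outlier_sd: float = 10.0

    def means_for(self, n_clusters: int) -> np.ndarray:
        if self.cluster_means is not None:
            if len(self.cluster_means) != n_clusters:
                raise ConfigError(
                    f"score model has {len(self.cluster_means)} cluster means "
                    f"for {n_clusters} clusters"
                )
            return np.asarray(self.cluster_means, dtype=float)
        return 100.0 + 10.0 * np.arange(n_clusters, 0, -1, dtype=float)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic docking table with known labels."""

    n_clusters: int = 4
    members_per_cluster: tuple[int, ...] | None = None  # default 50 each
    angular_noise_sd: float = 0.1
    translation_noise_sd: float = 0.5
    box_size: float = 30.0
    outlier_fraction: float = 0.2
    score_model: ScoreModel = field(default_factory=ScoreModel)
    wrap_straddle: bool = True
    min_separation_factor: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ConfigError("need at least one cluster")
        if self.members_per_cluster is not None:
            if len(self.members_per_cluster) != self.n_clusters:
                raise ConfigError(
                    f"{len(self.members_per_cluster)} member counts for "
                    f"{self.n_clusters} clusters"
                )
            if any(m < 1 for m in self.members_per_cluster):
                raise ConfigError("member counts must be >= 1")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ConfigError("outlier_fraction must be in [0, 1)")
        if self.angular_noise_sd < 0 or self.translation_noise_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if self.box_size <= 0:
            raise ConfigError("box_size must be positive")

    @property
    def members(self) -> tuple[int, ...]:
        if self.members_per_cluster is not None:
            return tuple(self.members_per_cluster)
        return (50,) * self.n_clusters

    @property
    def n_outliers(self) -> int:
        """Outlier count such that outliers make up ``outlier_fraction`` of
        the final table: round(f/(1-f) x member total), half away from zero."""
        f = self.outlier_fraction
        return int(math.floor(f / (1.0 - f) * sum(self.members) + 0.5))


@dataclass
class SyntheticTruth:
    """Planted labels (0 = outlier) and the generating cluster centers."""

    labels: np.ndarray
    center_angles: np.ndarray
    center_translations: np.ndarray


def _draw_centers(spec: SyntheticSpec, rng: np.random.Generator):
    """Rejection-sample cluster centers separated by at least
    ``min_separation_factor`` noise sds in both the angular and the
    translational component."""
    min_ang = spec.min_separation_factor * spec.angular_noise_sd
    min_trans = spec.min_separation_factor * spec.translation_noise_sd
    half = spec.box_size / 2.0
    angles, trans = [], []
    for g in range(spec.n_clusters):
        for attempt in range(10_000):
            if g == 0 and spec.wrap_straddle:
                a = np.zeros(3)
            else:
                a = rng.uniform(0.0, TWO_PI, size=3)
            t = rng.uniform(-half, half, size=3)
            ok = all(
                solution_angle_distance(a, a2) >= min_ang
                and float(np.linalg.norm(t - t2)) >= min_trans
                for a2, t2 in zip(angles, trans)
            )
            if ok:
                angles.append(a)
                trans.append(t)
                break
            if g == 0:  # the pinned wrap center cannot be resampled
                angles.append(a)
                trans.append(t)
                break
        else:
            raise ConfigError(
                "could not place separated cluster centers; "
                "reduce n_clusters, separation factor or noise"
            )
    return np.array(angles), np.array(trans)


def generate_table(spec: SyntheticSpec) -> tuple[DockingTable, SyntheticTruth]:
    """Draw a docking table from the spec; returns the table and its truth.

    Rows are shuffled deterministically by the seed and ids are assigned
    1..n in shuffled order, mimicking an engine's arbitrary output ranking.
    """
    rng = np.random.default_rng(spec.seed)
    center_angles, center_trans = _draw_centers(spec, rng)
    score_means = spec.score_model.means_for(spec.n_clusters)

    rows_angles, rows_trans, rows_scores, rows_labels = [], [], [], []
    for g, count in enumerate(spec.members):
        a = center_angles[g] + rng.normal(0.0, spec.angular_noise_sd, size=(count, 3))
        t = center_trans[g] + rng.normal(0.0, spec.translation_noise_sd, size=(count, 3))
        s = rng.normal(score_means[g], spec.score_model.cluster_sd, size=count)
        rows_angles.append(np.mod(a, TWO_PI))
        rows_trans.append(t)
        rows_scores.append(s)
        rows_labels.append(np.full(count, g + 1, dtype=int))
    n_out = spec.n_outliers
    if n_out:
        half = spec.box_size / 2.0
        rows_angles.append(rng.uniform(0.0, TWO_PI, size=(n_out, 3)))
        rows_trans.append(rng.uniform(-half, half, size=(n_out, 3)))
        rows_scores.append(
            rng.normal(spec.score_model.outlier_mean, spec.score_model.outlier_sd, n_out)
        )
        rows_labels.append(np.zeros(n_out, dtype=int))

    angles = np.vstack(rows_angles)
    trans = np.vstack(rows_trans)
    scores = np.concatenate(rows_scores)
    truth_labels = np.concatenate(rows_labels)

    perm = rng.permutation(len(truth_labels))
    solutions = [
        DockingSolution(
            id=i + 1,
            angles=tuple(angles[p]),
            translation=tuple(trans[p]),
            score=float(scores[p]),
        )
        for i, p in enumerate(perm)
    ]
    table = DockingTable(solutions, dialect="synthetic")
    truth = SyntheticTruth(truth_labels[perm], center_angles, center_trans)
    return table, truth


def write_truth(truth: SyntheticTruth, table: DockingTable, path) -> None:
    """TSV of planted labels aligned with the table's row order."""
    from pathlib import Path

    lines = ["id\tplanted_label"]
    for s, lab in zip(table.solutions, truth.labels):
        lines.append(f"{s.id}\t{int(lab)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
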