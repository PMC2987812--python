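"""Diagnostic plots: PCA cluster map, all-pairs axis panels, k-dist curve.

Images are rendered with matplotlib; every plot can also emit its
underlying data as a TSV table (``data_path``), which is the surface the
tests exercise — plots are smoke-tested, tables are checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .embedding import FeatureMatrix
from .errors import InputError


@dataclass
class ProjectionResult:
    """Low-dimensional view of the feature space.

    coordinates: (n, j) scores on the leading principal axes;
    explained_variance_ratio: per-component share of total variance,
    non-increasing.
    """

    coordinates: np.ndarray
    explained_variance_ratio: np.ndarray


def pca_projection(features, n_components: int = 2) -> ProjectionResult:
    """Project the (already standardized) feature matrix onto its leading
    principal axes.

    Component signs are fixed so the largest-magnitude loading of each axis
    is positive, making the projection deterministic across BLAS builds.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    n, p = X.shape
    if n_components > p:
        raise InputError(f"n_components={n_components} > {p} feature columns")
    Xc = X - X.mean(axis=0)
    total_var = float((Xc ** 2).sum()) / max(n - 1, 1)
    if total_var <= 0:
        return ProjectionResult(np.zeros((n, n_components)), np.zeros(n_components))
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest |loading| of each component positive
    for j in range(Vt.shape[0]):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    coords = (U * s)[:, :n_components]
    evr = (s ** 2) / (s ** 2).sum()
    return ProjectionResult(coords, evr[:n_components])


def panel_pairs(n_columns: int) -> list[tuple[int, int]]:
    """Column pairs shown by the pairwise-axes view: all C(j, 2) of them."""
    return list(combinations(range(n_columns), 2))


def _colors(labels: np.ndarray):
    cmap = plt.get_cmap("tab10")
    return [
        (0.6, 0.6, 0.6, 0.6) if lab == 0 else cmap((lab - 1) % 10)
        for lab in labels
    ]


def _write_plot_data(path, header: list[str], rows) -> None:
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(str(x) for x in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def render_cluster_plot(
    projection: ProjectionResult,
    labels: np.ndarray,
    ids: np.ndarray,
    representative_ids=(),
    marked_ids=(),
    out: str | Path = "clusters.png",
    data_path: str | Path | None = None,
) -> Path:
    """Scatter of the first two principal components, clusters colored,
    noise gray, representatives over-plotted, marked solutions annotated."""
    labels = np.asarray(labels)
    ids = np.asarray(ids)
    if not (len(labels) == len(ids) == projection.coordinates.shape[0]):
        raise InputError("projection, labels and ids must have equal length")
    xy = projection.coordinates[:, :2]
    reps = set(int(i) for i in representative_ids)
    marked = set(int(i) for i in marked_ids)

    fig, ax = plt.subplots(figsize=(7, 6))
    ax.scatter(xy[:, 0], xy[:, 1], c=_colors(labels), s=14, linewidths=0)
    is_rep = np.array([int(i) in reps for i in ids])
    if is_rep.any():
        ax.scatter(
            xy[is_rep, 0], xy[is_rep, 1], marker="*", s=220,
            facecolors="none", edgecolors="black", linewidths=1.2,
            label="representative",
        )
    for i, sid in enumerate(ids):
        if int(sid) in marked:
            ax.annotate(
                str(int(sid)), xy[i], textcoords="offset points", xytext=(4, 4),
                fontsize=8, fontweight="bold",
            )
    evr = projection.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f}% var)" if evr.size > 0 else "PC1")
    ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f}% var)" if evr.size > 1 else "PC2")
    ax.set_title("Docking solutions: clusters and representatives")
    if is_rep.any():
        ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=120)
    plt.close(fig)

    if data_path is not None:
        _write_plot_data(
            data_path,
            ["id", "x", "y", "cluster", "is_representative", "is_marked"],
            (
                [int(sid), repr(float(x)), repr(float(y)), int(lab),
                 int(int(sid) in reps), int(int(sid) in marked)]
                for sid, (x, y), lab in zip(ids, xy, labels)
            ),
        )
    return out


def render_pairwise_axes(
    values: np.ndarray,
    labels: np.ndarray,
    out: str | Path = "pairwise.png",
    data_path: str | Path | None = None,
    column_names=None,
) -> Path:
    """Grid of scatter panels for every pair of columns, cluster-colored.

    With j columns there are j*(j-1)/2 panels; this is the view that
    unmasks outliers appearing spuriously close to cluster centers in the
    two-component projection.
    """
    X = values.values if isinstance(values, FeatureMatrix) else np.asarray(values, float)
    labels = np.asarray(labels)
    j = X.shape[1]
    if j < 2:
        raise InputError("pairwise axes view needs at least 2 columns")
    names = list(column_names) if column_names else [f"c{i + 1}" for i in range(j)]
    pairs = panel_pairs(j)
    ncols = min(len(pairs), 4)
    nrows = (len(pairs) + ncols - 1) // ncols
    colors = _colors(labels)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.0 * ncols, 2.8 * nrows), squeeze=False
    )
    for ax in axes.ravel():
        ax.set_visible(False)
    for ax, (a, b) in zip(axes.ravel(), pairs):
        ax.set_visible(True)
        ax.scatter(X[:, a], X[:, b], c=colors, s=6, linewidths=0)
        ax.set_xlabel(names[a], fontsize=7)
        ax.set_ylabel(names[b], fontsize=7)
        ax.tick_params(labelsize=6)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=110)
    plt.close(fig)

    if data_path is not None:
        _write_plot_data(
            data_path,
            ["row", "cluster"] + names,
            (
                [i, int(lab)] + [repr(float(v)) for v in X[i]]
                for i, lab in enumerate(labels)
            ),
        )
    return out


def render_kdist_plot(
    profile: np.ndarray,
    k: int,
    chosen_eps: float | None = None,
    out: str | Path = "kdist.png",
) -> Path:
    """Sorted k-distance curve with the selected eps marked."""
    profile = np.asarray(profile, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(np.arange(1, profile.size + 1), profile, lw=1.2)
    if chosen_eps is not None:
        ax.axhline(chosen_eps, color="crimson", ls="--", lw=1,
                   label=f"chosen eps = {chosen_eps:.4g}")
        ax.legend(fontsize=8)
    ax.set_xlabel("points (sorted)")
    ax.set_ylabel(f"distance to {k}-th nearest neighbor")
    ax.set_title("k-distance profile")
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=110)
    plt.close(fig)
    return out
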