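"""End-to-end orchestration: table -> distances -> MDS -> features ->
eps selection -> DBSCAN -> summaries, representatives, plots, poses.

:func:`run_pipeline` is the single entry point behind the command line; it
executes every stage in order, writes all tabular and graphical outputs
into one directory and records an auditable run log (configuration, chosen
eps, cluster count, outcome, library versions)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .angular import angle_distance_matrix
from .analysis import (
    AnalysisThresholds,
    AnalysisReport,
    flag_outcome,
    locate_markers,
    select_representatives,
    summarize_clusters,
    write_clusters,
    write_representatives,
)
from .clustering import (
    ClusteringParams,
    CandidateEvaluation,
    QualityIndexes,
    clustering_quality,
    dbscan,
    epsilon_candidates,
    finalize_labels,
    kdist_profile,
    select_epsilon,
    write_eps_selection,
)
from .embedding import MDSRetention, build_feature_matrix, classical_mds
from .errors import DockclustError
from .io_docking import DockingTable, read_docking_table, write_assignments
from .visualization import (
    pca_projection,
    render_cluster_plot,
    render_kdist_plot,
    render_pairwise_axes,
)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, with the package defaults."""

    input: str
    outdir: str = "dockclust_out"
    dialect: str = "generic"
    angle_units: str = "deg"
    score_direction: str = "higher_better"
    k: int = 15
    min_cluster_size: int = 15
    eps: float | None = None  # None = automatic selection
    mds_variance_share: float = 0.95
    mds_max_dims: int = 6
    convention: str = "zyz"
    origin_mode: str = "centroid"
    ligand: str | None = None
    marked_ids: tuple[int, ...] = ()
    thresholds: AnalysisThresholds = field(default_factory=AnalysisThresholds)
    emit_plot_data: bool = False
    seed: int = 0


@dataclass
class RunResult:
    outdir: Path
    table: DockingTable
    labels: np.ndarray
    chosen_eps: float
    evaluations: list[CandidateEvaluation]
    report: AnalysisReport
    representatives: dict[int, int]
    degenerate: bool  # True when every solution ended up as noise


def cluster_docking_table(
    table: DockingTable,
    k: int = 15,
    min_cluster_size: int = 15,
    eps: float | None = None,
    retention: MDSRetention = MDSRetention(),
):
    """Distances -> MDS -> features -> (auto) eps -> DBSCAN -> finalize,
    without touching the filesystem.

    Returns ``(labels, chosen_eps, evaluations, features)``.  This is the
    computational core of :func:`run_pipeline`; use it when the tables,
    plots and run log are not needed.
    """
    D = angle_distance_matrix(table)
    features = build_feature_matrix(classical_mds(D, retention), table)
    params = ClusteringParams(k=k, eps=eps, min_cluster_size=min_cluster_size)
    if eps is None:
        candidates = epsilon_candidates(kdist_profile(features, k))
        chosen_eps, evals = select_epsilon(features, candidates, params)
    else:
        chosen_eps, evals = float(eps), []
    labels_raw = dbscan(features, replace(params, eps=chosen_eps))
    labels = finalize_labels(labels_raw, params)
    return labels, chosen_eps, evals, features


class _Stage:
    """Context manager that renames any error with the failing stage."""

    def __init__(self, name: str, log: dict):
        self.name = name
        self.log = log

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            self.log.setdefault("failed_stage", self.name)
            if isinstance(exc, DockclustError) and not getattr(exc, "_staged", False):
                exc._staged = True
                exc.args = (f"[{self.name}] {exc.args[0] if exc.args else ''}",)
        return False


def run_pipeline(config: RunConfig, table: DockingTable | None = None) -> RunResult:
    """Run the whole clustering pipeline and write every output.

    ``table`` may be passed directly (e.g. a synthetic table) to skip the
    read stage; otherwise ``config.input`` is read with the configured
    dialect.  Outputs: assignments.tsv, clusters.tsv, representatives.tsv,
    eps_selection.tsv, cluster_plot.png, pairwise_axes.png,
    kdist_profile.png, run_log.yaml and, when a ligand is given, poses/
    plus trajectory.pdb.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": _config_dict(config), "warnings": []}

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        with _Stage("read", log):
            if table is None:
                table = read_docking_table(
                    config.input, config.dialect, config.angle_units,
                    config.score_direction,
                )
        with _Stage("angular-distances", log):
            D = angle_distance_matrix(table)
        with _Stage("mds", log):
            mds = classical_mds(
                D, MDSRetention(config.mds_variance_share, config.mds_max_dims)
            )
            log["mds"] = {
                "retained_dims": mds.m,
                "negative_eigenvalue_mass": float(mds.negative_mass),
            }
        with _Stage("features", log):
            features = build_feature_matrix(mds, table)
        params = ClusteringParams(
            k=config.k, eps=config.eps, min_cluster_size=config.min_cluster_size
        )
        with _Stage("eps-selection", log):
            profile = kdist_profile(features, config.k)
            if config.eps is not None:
                chosen_eps = float(config.eps)
                labels_raw = dbscan(features, params)
                q = clustering_quality(features, labels_raw)
                evals = [
                    CandidateEvaluation(
                        eps=chosen_eps,
                        n_clusters=int(labels_raw.max()),
                        noise_count=int((labels_raw == 0).sum()),
                        indexes=q,
                        eligible=q.eligible,
                        chosen=True,
                    )
                ]
            else:
                candidates = epsilon_candidates(profile)
                chosen_eps, evals = select_epsilon(features, candidates, params)
                labels_raw = dbscan(features, replace(params, eps=chosen_eps))
        with _Stage("finalize", log):
            labels = finalize_labels(labels_raw, params)
            degenerate = int(labels.max()) == 0
        with _Stage("analysis", log):
            representatives = select_representatives(features, table, labels)
            summaries = summarize_clusters(
                table, labels, representatives,
                config.min_cluster_size, config.thresholds,
            )
            outcome = flag_outcome(summaries, table, labels, config.thresholds)
            marked = locate_markers(table, labels, config.marked_ids, representatives)
            report = AnalysisReport(
                summaries, outcome, marked, noise_count=int((labels == 0).sum())
            )
        with _Stage("write-tables", log):
            write_assignments(
                table, labels, outdir / "assignments.tsv",
                representative_ids=representatives.values(),
            )
            write_clusters(summaries, outdir / "clusters.tsv")
            write_representatives(table, representatives, outdir / "representatives.tsv")
            write_eps_selection(evals, outdir / "eps_selection.tsv")
        with _Stage("plots", log):
            projection = pca_projection(features, n_components=min(2, features.n_columns))
            render_cluster_plot(
                projection, labels, table.ids(),
                representative_ids=representatives.values(),
                marked_ids=config.marked_ids,
                out=outdir / "cluster_plot.png",
                data_path=(outdir / "cluster_plot.tsv") if config.emit_plot_data else None,
            )
            if features.n_columns >= 2:
                render_pairwise_axes(
                    features, labels,
                    out=outdir / "pairwise_axes.png",
                    data_path=(outdir / "pairwise_axes.tsv") if config.emit_plot_data else None,
                    column_names=features.column_roles,
                )
            render_kdist_plot(
                profile, config.k, chosen_eps, out=outdir / "kdist_profile.png"
            )
        if config.ligand:
            with _Stage("poses", log):
                _export_poses(config, table, labels, representatives, outdir)

        log["warnings"] = sorted({str(w.message) for w in caught})

    log.update(
        chosen_eps=float(chosen_eps),
        n_clusters=int(labels.max()),
        noise_count=int((labels == 0).sum()),
        outcome=report.outcome,
        degenerate=bool(degenerate),
        versions=_versions(),
    )
    (outdir / "run_log.yaml").write_text(
        yaml.safe_dump(log, sort_keys=False), encoding="utf-8"
    )
    return RunResult(
        outdir, table, labels, float(chosen_eps), evals, report,
        representatives, degenerate,
    )


def _export_poses(config, table, labels, representatives, outdir: Path) -> None:
    from .poses import apply_pose, export_cluster_poses, merge_trajectory, read_structure

    ligand = read_structure(config.ligand)
    for g in sorted(representatives):
        export_cluster_poses(
            ligand, table, labels, g, outdir / "poses" / f"cluster_{g}",
            config.convention, config.origin_mode,
        )
    rep_poses = [
        apply_pose(
            ligand, table.solutions[table.index_of(representatives[g])],
            config.convention, config.origin_mode,
        )
        for g in sorted(representatives)
    ]
    if rep_poses:
        merge_trajectory(
            rep_poses, outdir / "trajectory.pdb",
            remarks=[
                "PSEUDO-TRAJECTORY OF CLUSTER REPRESENTATIVES",
                f"EULER CONVENTION {config.convention.upper()}, "
                f"ORIGIN {config.origin_mode.upper()}",
            ],
        )


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["marked_ids"] = list(d["marked_ids"])
    return d


def _versions() -> dict:
    import numpy, scipy, matplotlib

    return {
        "dockclust": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "matplotlib": matplotlib.__version__,
    }
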