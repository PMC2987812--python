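"""Classical MDS of the angular distance matrix and clustering feature space.

The angular distances are turned into Euclidean "principal coordinates" by
Torgerson scaling: square the distances, double-center, eigendecompose, and
scale the leading eigenvectors by the square roots of their (positive)
eigenvalues.  The retained coordinates are concatenated with the three
translation columns and every column is standardized to zero mean and unit
sample variance, so each rotational and positional variable carries the same
weight in the Euclidean distances the clustering operates on.

The torus metric is not exactly Euclidean-embeddable, so some eigenvalues
come out negative; they are dropped and their total magnitude is kept as an
embedding-distortion diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .angular import AngularDistanceMatrix
from .errors import InputError
from .io_docking import DockingTable


@dataclass(frozen=True)
class MDSRetention:
    """How many principal coordinates to keep.

    Positive-eigenvalue components are retained, largest first, until their
    cumulative share of the positive eigenvalue mass reaches
    ``variance_share``, but never more than ``max_dims``.
    """

    variance_share: float = 0.95
    max_dims: int = 6


@dataclass
class MDSResult:
    """Principal coordinates of a distance matrix.

    Attributes
    ----------
    coordinates
        (n, m) array; columns ordered by descending eigenvalue.
    eigenvalues
        All n eigenvalues of the doubly-centered matrix, descending.
    m
        Number of retained (positive) components.
    negative_mass
        Sum of |negative eigenvalues| — distortion incurred by forcing the
        non-Euclidean angular metric into Euclidean coordinates.
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    m: int
    negative_mass: float = 0.0


def classical_mds(
    D: AngularDistanceMatrix | np.ndarray, retention: MDSRetention = MDSRetention()
) -> MDSResult:
    """Torgerson principal-coordinates analysis of a distance matrix.

    For a Euclidean-embeddable matrix the pairwise distances of the
    full-rank coordinates reproduce the input exactly (up to round-off).
    An all-zero matrix yields zero retained components.
    """
    values = D.values if isinstance(D, AngularDistanceMatrix) else np.asarray(D, float)
    n = values.shape[0]
    if n < 2 or values.shape != (n, n):
        raise InputError(f"invalid distance matrix of shape {values.shape}")
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (values ** 2) @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    scale = float(np.max(np.abs(eigvals))) if n else 0.0
    tol = max(scale, 1.0) * n * np.finfo(float).eps
    positive = eigvals > tol
    negative_mass = float(-eigvals[eigvals < -tol].sum())
    if not positive.any():
        return MDSResult(np.zeros((n, 0)), eigvals, 0, negative_mass)

    pos_vals = eigvals[positive]
    cum_share = np.cumsum(pos_vals) / pos_vals.sum()
    m = int(np.searchsorted(cum_share, retention.variance_share - 1e-12) + 1)
    m = min(m, retention.max_dims, len(pos_vals))
    coords = eigvecs[:, :m] * np.sqrt(eigvals[:m])
    return MDSResult(coords, eigvals, m, negative_mass)


@dataclass
class FeatureMatrix:
    """Standardized clustering feature space: m angle-derived principal
    coordinates followed by the three translation columns, each centered and
    scaled to unit sample variance (constant columns zeroed)."""

    values: np.ndarray
    column_roles: list[str]
    means: np.ndarray
    scales: np.ndarray
    constant_mask: np.ndarray = field(default=None)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def standardize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Center and scale each column to unit sample variance (ddof=1).

    Returns (standardized, means, scales, constant_mask); constant columns
    are set to all-zero and flagged rather than divided by ~0.
    """
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    span = np.maximum(np.abs(X).max(axis=0), 1.0) if X.size else np.ones(X.shape[1])
    constant = sds <= span * 1e-12
    scales = np.where(constant, 1.0, sds)
    Z = (X - means) / scales
    Z[:, constant] = 0.0
    return Z, means, scales, constant


def build_feature_matrix(mds: MDSResult, table: DockingTable) -> FeatureMatrix:
    """Concatenate principal coordinates with translations and standardize."""
    if mds.coordinates.shape[0] != table.n:
        raise InputError(
            f"MDS rows {mds.coordinates.shape[0]} != table size {table.n}"
        )
    raw = np.hstack([mds.coordinates, table.translations()])
    Z, means, scales, constant = standardize_columns(raw)
    roles = [f"mds{i + 1}" for i in range(mds.m)] + ["tx", "ty", "tz"]
    return FeatureMatrix(Z, roles, means, scales, constant)
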