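"""Wrap-aware distances between the rotation-angle triples of docking poses.

Rotation angles live on a circle: 1 degree and 359 degrees are 2 degrees
apart, not 358.  For two poses with angle triples A = (a1, a2, a3) and
B = (b1, b2, b3) each coordinate contributes

    d_i = min(|b_i - a_i|, |b_i - a_i + 2*pi|, |b_i - a_i - 2*pi|)

which lies in [0, pi], and the triples are compared with the Euclidean
combination d(A, B) = sqrt(d1^2 + d2^2 + d3^2), bounded by pi*sqrt(3).
This is the torus (flat product-of-circles) metric on the angle space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .io_docking import TWO_PI, DockingTable

#: Largest possible distance between two angle triples.
MAX_TRIPLE_DISTANCE = math.pi * math.sqrt(3.0)


def circular_distance(a: float, b: float) -> float:
    """Shortest arc length between two angles in radians; result in [0, pi]."""
    if not (math.isfinite(a) and math.isfinite(b)):
        raise InputError(f"non-finite angle in circular_distance: {a!r}, {b!r}")
    d = math.fmod(abs(b - a), TWO_PI)
    return min(d, TWO_PI - d)


def solution_angle_distance(A, B) -> float:
    """Torus distance between two angle triples: sqrt(sum of squared per-axis
    circular distances); in [0, pi*sqrt(3)]."""
    return math.sqrt(
        sum(circular_distance(a, b) ** 2 for a, b in zip(A, B, strict=True))
    )


@dataclass
class AngularDistanceMatrix:
    """Symmetric n x n matrix of pairwise torus distances between the angle
    triples of a docking table, in row order."""

    values: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n, self.n):
            raise InputError(
                f"distance matrix shape {self.values.shape} != ({self.n}, {self.n})"
            )


def pairwise_angle_distances(angles: np.ndarray) -> np.ndarray:
    """Vectorised all-pairs torus distance for an (n, 3) angle array (rad)."""
    angles = np.asarray(angles, dtype=float)
    diff = np.abs(angles[:, None, :] - angles[None, :, :]) % TWO_PI
    diff = np.minimum(diff, TWO_PI - diff)
    D = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    # exact zero diagonal and symmetry despite floating-point noise
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def angle_distance_matrix(table: DockingTable) -> AngularDistanceMatrix:
    """All-pairs angular distances between the solutions of a docking table."""
    if table.n < 2:
        raise InputError("need at least 2 solutions for a distance matrix")
    return AngularDistanceMatrix(pairwise_angle_distances(table.angles()), table.n)
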