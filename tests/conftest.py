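import math

import numpy as np
import pytest

import biotite.structure as struc

from dockclust import DockingSolution, DockingTable, SyntheticSpec, generate_table

TWO_PI = 2.0 * math.pi


def make_table(angles, translations, scores, ids=None):
    """Build a DockingTable from raw arrays (angles in radians)."""
    n = len(angles)
    ids = ids if ids is not None else range(1, n + 1)
    return DockingTable(
        [
            DockingSolution(
                id=int(i), angles=tuple(a), translation=tuple(t), score=float(s)
            )
            for i, a, t, s in zip(ids, angles, translations, scores)
        ]
    )


@pytest.fixture
def small_synthetic():
    """Well-separated 3-cluster table, ~115 rows, fast to cluster."""
    spec = SyntheticSpec(
        n_clusters=3, members_per_cluster=(40, 35, 25), outlier_fraction=0.15,
        seed=7,
    )
    return generate_table(spec)


@pytest.fixture
def ligand():
    """A tiny synthetic ligand: 8 atoms of a fake dipeptide, built in code."""
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.5, 0.0, 0.0],
            [2.1, 1.3, 0.2],
            [3.6, 1.4, 0.3],
            [1.4, 2.5, 0.1],
            [4.3, 2.6, 0.8],
            [0.3, -1.2, 0.9],
            [2.2, -0.9, -1.1],
        ],
        dtype=np.float32,
    )
    atoms = struc.AtomArray(len(coords))
    atoms.coord = coords
    atoms.atom_name = np.array(["N", "CA", "C", "O", "CB", "N", "CA", "C"])
    atoms.element = np.array(["N", "C", "C", "O", "C", "N", "C", "C"])
    atoms.res_name = np.array(["ALA"] * 5 + ["GLY"] * 3)
    atoms.res_id = np.array([1] * 5 + [2] * 3)
    atoms.chain_id = np.array(["A"] * 8)
    atoms.hetero = np.zeros(8, dtype=bool)
    return atoms
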