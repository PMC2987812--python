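"""Rigid-body pose export: ligand transforms, per-cluster PDB files and
multi-MODEL pseudo-trajectories.

Each docking solution encodes a rigid transform: a rotation built from its
angle triple under a named Euler convention (default ``zyz``, i.e.
R = Rz(a1) @ Ry(a2) @ Rz(a3)) and a translation in angstrom.  The rotation
is applied about the ligand centroid by default (``origin_mode="centroid"``),
or about the coordinate origin; docking engines disagree silently on both
conventions, so the choice is explicit, configurable and stamped into the
REMARK records of every written file.

PDB reading/writing goes through biotite; coordinates survive the
fixed-column round trip to the format's 3-decimal precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import ConfigError, InputError
from .io_docking import DockingSolution, DockingTable

EULER_CONVENTIONS = ("zyz", "zyx", "xyz")


def _axis_rotation(axis: str, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def rotation_matrix(angles: Sequence[float], convention: str = "zyz") -> np.ndarray:
    """3x3 proper rotation from an Euler-angle triple.

    ``convention`` names the axis sequence, applied left to right:
    ``zyz`` gives R = Rz(a1) @ Ry(a2) @ Rz(a3).
    """
    if convention not in EULER_CONVENTIONS:
        raise ConfigError(
            f"unknown Euler convention {convention!r}; choose from {EULER_CONVENTIONS}"
        )
    a1, a2, a3 = angles
    axes = convention
    return (
        _axis_rotation(axes[0], a1)
        @ _axis_rotation(axes[1], a2)
        @ _axis_rotation(axes[2], a3)
    )


@dataclass
class RigidTransform:
    """Rotation + translation of a docking solution, ready to apply."""

    rotation: np.ndarray
    translation: np.ndarray
    origin_mode: str = "centroid"

    @classmethod
    def from_solution(
        cls, solution: DockingSolution, convention: str = "zyz",
        origin_mode: str = "centroid",
    ) -> "RigidTransform":
        if origin_mode not in ("origin", "centroid"):
            raise ConfigError(f"origin_mode must be 'origin' or 'centroid', got {origin_mode!r}")
        return cls(
            rotation=rotation_matrix(solution.angles, convention),
            translation=np.asarray(solution.translation, dtype=float),
            origin_mode=origin_mode,
        )


def read_structure(path: str | Path) -> struc.AtomArray:
    """Read the first model of a PDB file as a biotite AtomArray."""
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1)
    if atoms.array_length() == 0:
        raise InputError(f"{path}: no atoms")
    return atoms


def apply_pose(
    atoms: struc.AtomArray,
    solution: DockingSolution,
    convention: str = "zyz",
    origin_mode: str = "centroid",
) -> struc.AtomArray:
    """Place the ligand according to one docking solution.

    x' = R @ (x - c) + c + t, with c the ligand centroid when
    ``origin_mode="centroid"`` and the zero point otherwise.  All
    non-coordinate annotations are copied unchanged.
    """
    if atoms.array_length() == 0:
        raise InputError("empty structure")
    tf = RigidTransform.from_solution(solution, convention, origin_mode)
    coords = atoms.coord
    c = coords.mean(axis=0) if tf.origin_mode == "centroid" else np.zeros(3)
    out = atoms.copy()
    out.coord = (coords - c) @ tf.rotation.T + c + tf.translation
    return out


def _write_pdb(atoms, path: Path, remarks: Sequence[str]) -> None:
    pdb = PDBFile()
    pdb.set_structure(atoms)
    remark_lines = [f"REMARK 250 {r}"[:80] for r in remarks]
    pdb.lines = remark_lines + pdb.lines
    if not pdb.lines or not pdb.lines[-1].startswith("END"):
        pdb.lines.append("END")
    pdb.write(str(path))


def export_cluster_poses(
    atoms: struc.AtomArray,
    table: DockingTable,
    labels: np.ndarray,
    cluster: int,
    outdir: str | Path,
    convention: str = "zyz",
    origin_mode: str = "centroid",
) -> list[Path]:
    """Write one ``pose_<solution id>.pdb`` per member of a cluster."""
    labels = np.asarray(labels)
    members = np.flatnonzero(labels == cluster)
    if members.size == 0:
        raise InputError(f"no such cluster: {cluster}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    remarks = [
        f"EULER CONVENTION {convention.upper()}, ROTATION ORIGIN {origin_mode.upper()}",
        f"CLUSTER {cluster}",
    ]
    paths = []
    for idx in members:
        sol = table.solutions[idx]
        posed = apply_pose(atoms, sol, convention, origin_mode)
        path = outdir / f"pose_{sol.id}.pdb"
        _write_pdb(posed, path, remarks + [f"SOLUTION {sol.id} SCORE {sol.score:.4f}"])
        paths.append(path)
    return paths


def merge_trajectory(
    poses: Sequence[struc.AtomArray], out: str | Path,
    remarks: Sequence[str] = (),
) -> Path:
    """Merge posed ligand copies into one multi-MODEL PDB pseudo-trajectory.

    The models appear in the given order (e.g. representative poses in
    cluster order), so a viewer can page through them as frames.
    """
    if len(poses) == 0:
        raise InputError("no poses to merge")
    counts = {p.array_length() for p in poses}
    if len(counts) != 1:
        raise InputError(f"atom-count mismatch across poses: {sorted(counts)}")
    stack = struc.stack(list(poses))
    pdb = PDBFile()
    pdb.set_structure(stack)
    remark_lines = [f"REMARK 250 {r}"[:80] for r in remarks]
    pdb.lines = remark_lines + pdb.lines
    if not pdb.lines[-1].startswith("END"):
        pdb.lines.append("END")
    out = Path(out)
    pdb.write(str(out))
    return out


def split_trajectory(path: str | Path) -> list[struc.AtomArray]:
    """Read a multi-MODEL PDB back as a list of AtomArrays (test helper)."""
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    if isinstance(stack, struc.AtomArray):
        return [stack]
    return [stack[i] for i in range(stack.stack_depth())]


def pose_rmsd(a: struc.AtomArray, b: struc.AtomArray) -> float:
    """Coordinate RMSD between two poses with identical atom order (no
    superposition — poses are compared in the docking frame)."""
    if a.array_length() != b.array_length():
        raise InputError("atom-count mismatch")
    return float(np.sqrt(((a.coord - b.coord) ** 2).sum(axis=1).mean()))
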