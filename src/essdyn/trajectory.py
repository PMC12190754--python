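"""Trajectory containers, multi-model PDB I/O, superposition and the PCA matrix.

The universal input of the pipeline is a :class:`Trajectory`: an ordered
sequence of frames, each holding one C-alpha atom per residue (full-atom
frames are accepted; analyses operate on the C-alpha subset).  Frames carry a
replica label and a snapshot time so that concatenated multi-replica runs
remain traceable.  All downstream analyses assume frames have been superposed
onto a common reference with :func:`superpose_trajectory`.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field, replace
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile

from .exceptions import (
    ConsistencyError,
    FormatOverflowError,
    InsufficientPointsError,
    StructuralError,
)

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "SuperpositionResult",
    "CoordinateMatrix",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "concatenate_replicas",
    "kabsch_fit",
    "superpose_trajectory",
    "build_coordinate_matrix",
    "coordinate_matrix_to_csv",
    "coordinate_matrix_from_csv",
]

_MAX_PDB_COORD = 9999.999


@dataclass(frozen=True)
class AtomRecord:
    """One atom: 1-based residue index, names, element and position in Angstrom."""

    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    position: tuple[float, float, float]


@dataclass(eq=False)
class Frame:
    """A single snapshot: atoms plus (replica, time) provenance."""

    atoms: tuple[AtomRecord, ...]
    time_ns: float = 0.0
    replica_id: int = 0

    @cached_property
    def ca_records(self) -> tuple[AtomRecord, ...]:
        recs = tuple(a for a in self.atoms if a.atom_name.strip() == "CA")
        idx = [a.residue_index for a in recs]
        if len(set(idx)) != len(idx):
            raise StructuralError("duplicate CA atoms for a residue index")
        if idx != sorted(idx):
            recs = tuple(sorted(recs, key=lambda a: a.residue_index))
        return recs

    @cached_property
    def ca_coords(self) -> np.ndarray:
        """(N, 3) array of C-alpha positions, residues ascending."""
        return np.asarray([a.position for a in self.ca_records], dtype=float)

    @cached_property
    def residue_indices(self) -> tuple[int, ...]:
        return tuple(a.residue_index for a in self.ca_records)

    @property
    def n_residues(self) -> int:
        return len(self.ca_records)

    @classmethod
    def from_ca_coords(
        cls,
        coords: np.ndarray,
        time_ns: float = 0.0,
        replica_id: int = 0,
        residue_indices: Sequence[int] | None = None,
        residue_names: Sequence[str] | None = None,
    ) -> "Frame":
        coords = np.asarray(coords, dtype=float)
        n = coords.shape[0]
        if residue_indices is None:
            residue_indices = range(1, n + 1)
        if residue_names is None:
            residue_names = ["ALA"] * n
        atoms = tuple(
            AtomRecord(int(i), str(rn), "CA", "C", (float(x), float(y), float(z)))
            for i, rn, (x, y, z) in zip(residue_indices, residue_names, coords)
        )
        return cls(atoms=atoms, time_ns=float(time_ns), replica_id=int(replica_id))

    def with_ca_coords(self, coords: np.ndarray) -> "Frame":
        """Copy of this frame with C-alpha coordinates replaced (CA-only frames)."""
        if len(self.atoms) != self.n_residues:
            raise ConsistencyError(
                "with_ca_coords only supported on CA-only frames"
            )
        return Frame.from_ca_coords(
            coords,
            time_ns=self.time_ns,
            replica_id=self.replica_id,
            residue_indices=self.residue_indices,
            residue_names=[a.residue_name for a in self.ca_records],
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Frame":
        """Apply x -> R x + t to every atom."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        atoms = tuple(
            replace(a, position=tuple((R @ np.asarray(a.position) + t).tolist()))
            for a in self.atoms
        )
        return Frame(atoms=atoms, time_ns=self.time_ns, replica_id=self.replica_id)


@dataclass
class Trajectory:
    """Ordered frames sharing one residue set.

    Ordering is (replica_id ascending, time ascending); the global frame
    index is 0-based.  ``aligned`` records whether the frames have been
    superposed onto a reference (set by :func:`superpose_trajectory`).
    """

    frames: list[Frame]
    n_residues: int
    snapshot_interval_ns: float = 1.0
    aligned: bool = False
    reference_label: str | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ConsistencyError("trajectory must contain at least one frame")
        ref_idx = self.frames[0].residue_indices
        for i, f in enumerate(self.frames):
            if f.residue_indices != ref_idx:
                raise ConsistencyError(
                    f"frame {i} residue set differs from frame 0"
                )
        if len(ref_idx) != self.n_residues:
            raise ConsistencyError(
                f"n_residues={self.n_residues} but frames have {len(ref_idx)} residues"
            )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_labels(self) -> list[tuple[int, float]]:
        return [(f.replica_id, f.time_ns) for f in self.frames]

    @property
    def replica_ids(self) -> list[int]:
        return sorted({f.replica_id for f in self.frames})

    def ca_array(self) -> np.ndarray:
        """(n_frames, n_residues, 3) stacked C-alpha coordinates."""
        return np.stack([f.ca_coords for f in self.frames])


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid-body fit: x_mobile -> R x + t, with the residual RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class CoordinateMatrix:
    """Frames x 3N matrix of aligned C-alpha coordinates.

    Columns are ordered x, y, z per residue with residues ascending, so a
    449-residue chain yields 1347 columns.  Row r reshaped to (N, 3) recovers
    frame r exactly.
    """

    values: np.ndarray
    column_labels: list[tuple[int, str]]
    frame_labels: list[tuple[int, float]]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConsistencyError("coordinate matrix must be 2-D")
        if self.values.shape[1] != len(self.column_labels):
            raise ConsistencyError("column label count mismatch")
        if self.values.shape[0] != len(self.frame_labels):
            raise ConsistencyError("frame label count mismatch")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    @property
    def n_residues(self) -> int:
        return self.values.shape[1] // 3

    def frame_coords(self, row: int) -> np.ndarray:
        return self.values[row].reshape(-1, 3)


# ---------------------------------------------------------------------------
# Multi-model PDB I/O
# ---------------------------------------------------------------------------

def read_multimodel_pdb(
    path: str | Path,
    snapshot_interval_ns: float = 1.0,
    replica_id: int = 0,
) -> Trajectory:
    """Read a MODEL/ENDMDL multi-model PDB into a :class:`Trajectory`.

    One frame per MODEL in file order; every model must provide a C-alpha for
    every residue and all models must agree on the residue set.  Altloc 'A'
    (or blank) is taken; insertion codes are rejected — simulation snapshots
    do not carry them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise StructuralError(f"{path}: no MODEL records or atoms found")

    frames: list[Frame] = []
    ref_residues: tuple[int, ...] | None = None
    for m in range(1, n_models + 1):
        arr = pdb.get_structure(model=m, altloc="first")
        if np.any(arr.ins_code != ""):
            bad = arr.res_id[arr.ins_code != ""][0]
            raise StructuralError(
                f"model {m}: insertion code on residue {bad} is not supported"
            )
        atoms = tuple(
            AtomRecord(
                residue_index=int(arr.res_id[i]),
                residue_name=str(arr.res_name[i]),
                atom_name=str(arr.atom_name[i]),
                element=str(arr.element[i]),
                position=tuple(float(c) for c in arr.coord[i]),
            )
            for i in range(arr.array_length())
        )
        frame = Frame(
            atoms=atoms,
            time_ns=(m - 1) * snapshot_interval_ns,
            replica_id=replica_id,
        )
        ca_res = set(frame.residue_indices)
        all_res = {a.residue_index for a in atoms}
        missing = sorted(all_res - ca_res)
        if missing:
            raise StructuralError(
                f"model {m}: missing CA atom for residue {missing[0]}"
            )
        if ref_residues is None:
            ref_residues = frame.residue_indices
        elif frame.residue_indices != ref_residues:
            raise ConsistencyError(
                f"model {m}: residue set differs from model 1"
            )
        frames.append(frame)
    return Trajectory(
        frames=frames,
        n_residues=frames[0].n_residues,
        snapshot_interval_ns=snapshot_interval_ns,
    )


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a standard multi-model PDB (coordinates %8.3f)."""
    if traj.n_frames == 0:
        raise ConsistencyError("cannot write an empty trajectory")
    coords = np.stack(
        [np.asarray([a.position for a in f.atoms], dtype=float) for f in traj.frames]
    )
    if np.max(np.abs(coords)) > _MAX_PDB_COORD:
        raise FormatOverflowError(
            "coordinate magnitude exceeds 9999.999 A; cannot encode in %8.3f"
        )
    template = traj.frames[0]
    n_atoms = len(template.atoms)
    array = AtomArray(n_atoms)
    array.coord = coords[0]
    array.chain_id[:] = "A"
    array.res_id[:] = [a.residue_index for a in template.atoms]
    array.res_name[:] = [a.residue_name for a in template.atoms]
    array.atom_name[:] = [a.atom_name for a in template.atoms]
    array.element[:] = [a.element for a in template.atoms]
    array.hetero[:] = False
    stack = AtomArrayStack(traj.n_frames, n_atoms)
    for cat in ("chain_id", "res_id", "res_name", "atom_name", "element", "hetero"):
        stack.set_annotation(cat, array.get_annotation(cat))
    stack.coord = coords
    out = PDBFile()
    out.set_structure(stack)
    out.write(str(path))


# ---------------------------------------------------------------------------
# Replica concatenation
# ---------------------------------------------------------------------------

def concatenate_replicas(replicas: Sequence[Trajectory]) -> Trajectory:
    """Concatenate replicas replica-by-replica into one global trajectory.

    Replica ids are reassigned to 0..R-1 in input order so frame ordering
    (replica asc, time asc) is unambiguous; with three 101-frame replicas the
    0 ns frames land at global indices 0, 101 and 202 and the result has 303
    frames.
    """
    if not replicas:
        raise ConsistencyError("no replicas given")
    ref = replicas[0]
    for i, rep in enumerate(replicas[1:], start=1):
        if rep.frames[0].residue_indices != ref.frames[0].residue_indices:
            raise ConsistencyError(
                f"replica {i} residue set differs from replica 0 "
                f"({rep.n_residues} vs {ref.n_residues} residues)"
            )
        if not math.isclose(rep.snapshot_interval_ns, ref.snapshot_interval_ns):
            raise ConsistencyError(f"replica {i} snapshot interval differs")
    frames: list[Frame] = []
    for rid, rep in enumerate(replicas):
        for f in sorted(rep.frames, key=lambda fr: fr.time_ns):
            frames.append(Frame(atoms=f.atoms, time_ns=f.time_ns, replica_id=rid))
    return Trajectory(
        frames=frames,
        n_residues=ref.n_residues,
        snapshot_interval_ns=ref.snapshot_interval_ns,
        aligned=all(r.aligned for r in replicas),
    )


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid fit of ``mobile`` onto ``reference`` (Kabsch, SVD).

    Returns the proper rotation R (det = +1) and translation t minimising the
    RMSD of ``R x + t`` to the reference, with the residual RMSD.  Requires at
    least 3 points; a collinear point set yields a degeneracy warning and a
    best-effort fit.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ConsistencyError("mobile and reference must both be (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise InsufficientPointsError(f"need >= 3 points, got {n}")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    m = mobile - mc
    r = reference - rc
    if np.linalg.matrix_rank(m, tol=1e-8) < 2:
        warnings.warn(
            "collinear point set: superposition is not unique; best-effort fit",
            RuntimeWarning,
            stacklevel=2,
        )
    H = m.T @ r
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    resid = mobile @ R.T + t - reference
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def superpose_trajectory(
    traj: Trajectory,
    reference: Frame | None = None,
    residue_mask: Sequence[int] | None = None,
) -> Trajectory:
    """Superpose every frame onto a reference by C-alpha Kabsch fit.

    ``reference`` defaults to the first frame of the trajectory (i.e. the
    first frame of the first replica after concatenation).  ``residue_mask``
    restricts the fitting set to the given residue indices; the transform is
    applied to all atoms either way.
    """
    if reference is None:
        reference = traj.frames[0]
    if reference.residue_indices != traj.frames[0].residue_indices:
        raise ConsistencyError("reference residue set differs from trajectory")
    ref_coords = reference.ca_coords
    if residue_mask is not None:
        mask = np.isin(reference.residue_indices, list(residue_mask))
        if mask.sum() < 3:
            raise InsufficientPointsError("residue mask selects fewer than 3 CAs")
    else:
        mask = slice(None)
    fitted: list[Frame] = []
    for i, f in enumerate(traj.frames):
        try:
            fit = kabsch_fit(f.ca_coords[mask], ref_coords[mask])
        except InsufficientPointsError as exc:
            raise InsufficientPointsError(f"frame {i}: {exc}") from exc
        fitted.append(f.transformed(fit.rotation, fit.translation))
    return Trajectory(
        frames=fitted,
        n_residues=traj.n_residues,
        snapshot_interval_ns=traj.snapshot_interval_ns,
        aligned=True,
        reference_label=f"replica {reference.replica_id} @ {reference.time_ns} ns",
    )


# ---------------------------------------------------------------------------
# Coordinate matrix
# ---------------------------------------------------------------------------

def build_coordinate_matrix(traj: Trajectory) -> CoordinateMatrix:
    """Flatten C-alpha coordinates into the frames x 3N PCA input matrix."""
    if not traj.aligned:
        warnings.warn(
            "building coordinate matrix from a trajectory without alignment "
            "provenance; PCA on unaligned frames mixes internal and rigid-body "
            "motion",
            UserWarning,
            stacklevel=2,
        )
    arr = traj.ca_array()  # (F, N, 3)
    values = arr.reshape(arr.shape[0], -1)
    residue_indices = traj.frames[0].residue_indices
    column_labels = [
        (int(res), axis) for res in residue_indices for axis in ("x", "y", "z")
    ]
    return CoordinateMatrix(
        values=values,
        column_labels=column_labels,
        frame_labels=traj.frame_labels,
    )


def coordinate_matrix_to_csv(m: CoordinateMatrix, path: str | Path) -> None:
    """CSV dialect: replica_id, time_ns, then r{index}_{x|y|z} columns."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["replica_id", "time_ns"]
            + [f"r{res}_{ax}" for res, ax in m.column_labels]
        )
        for (rep, t), row in zip(m.frame_labels, m.values):
            w.writerow([rep, repr(float(t))] + [repr(float(v)) for v in row])


def coordinate_matrix_from_csv(path: str | Path) -> CoordinateMatrix:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[:2] != ["replica_id", "time_ns"]:
            raise ConsistencyError(
                "coordinate CSV must start with replica_id, time_ns columns"
            )
        column_labels: list[tuple[int, str]] = []
        for name in header[2:]:
            res, ax = name.rsplit("_", 1)
            column_labels.append((int(res[1:]), ax))
        frame_labels: list[tuple[int, float]] = []
        rows: list[list[float]] = []
        for row in reader:
            frame_labels.append((int(row[0]), float(row[1])))
            rows.append([float(v) for v in row[2:]])
    return CoordinateMatrix(
        values=np.asarray(rows, dtype=float),
        column_labels=column_labels,
        frame_labels=frame_labels,
    )
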