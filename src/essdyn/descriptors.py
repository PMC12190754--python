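"""Per-residue and per-frame structural descriptors: RMSF, Rg, SASA, stats.

RMSF quantifies per-residue positional fluctuation about the trajectory mean
(after superposition); the radius of gyration tracks overall compactness per
frame; SASA is computed with the Shrake-Rupley rolling-probe quadrature on a
Fibonacci sphere lattice.  Descriptive statistics mirror the layout of a
per-series summary table: overall mean +/- sd, min, max, per-replica means.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import DataError, EssdynError
from .trajectory import Frame, Trajectory

__all__ = [
    "ResidueProfile",
    "FrameSeries",
    "SeriesStats",
    "rmsf",
    "radius_of_gyration",
    "sasa_shrake_rupley",
    "sasa_series",
    "rg_series",
    "series_stats",
    "write_profile_csv",
    "write_series_csv",
    "write_bfactor_pdb",
    "VDW_RADII",
    "ATOMIC_MASSES",
]

# Van der Waals radii (Angstrom) for the elements a CA-level or heavy-atom
# protein trajectory can contain.
VDW_RADII: dict[str, float] = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2}

ATOMIC_MASSES: dict[str, float] = {
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "H": 1.008,
}


@dataclass
class ResidueProfile:
    """One value per residue (e.g. RMSF in Angstrom)."""

    residue_index: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.value = np.asarray(self.value, dtype=float)
        if self.residue_index.shape != self.value.shape:
            raise DataError("residue_index and value must have equal length")


@dataclass
class FrameSeries:
    """One scalar per frame, labelled by (replica_id, time_ns)."""

    frame_labels: list[tuple[int, float]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.frame_labels) != self.values.shape[0]:
            raise DataError("one value per frame required")


@dataclass
class SeriesStats:
    mean: float
    sd: float
    min: float
    max: float
    per_replica_means: list[float]
    per_replica_sds: list[float]
    replica_ids: list[int]


def rmsf(traj: Trajectory, scope: str = "per-replica-combined") -> ResidueProfile:
    """Root-mean-square fluctuation of each residue's C-alpha.

    ``scope='whole-concatenation'`` measures fluctuation about the global
    per-residue mean.  ``scope='per-replica-combined'`` (default) measures
    each replica's fluctuation about that replica's own mean and combines
    them as the root of the frame-weighted mean of squared deviations —
    basin offsets between replicas then do not inflate the profile.
    """
    if traj.n_frames < 2:
        raise DataError("RMSF undefined for fewer than 2 frames")
    coords = traj.ca_array()  # (F, N, 3)
    if scope == "whole-concatenation":
        dev = coords - coords.mean(axis=0)
        msf = np.mean(np.sum(dev**2, axis=2), axis=0)
    elif scope == "per-replica-combined":
        reps = np.asarray([f.replica_id for f in traj.frames])
        sq_sum = np.zeros(traj.n_residues)
        for rid in np.unique(reps):
            sub = coords[reps == rid]
            dev = sub - sub.mean(axis=0)
            sq_sum += np.sum(np.sum(dev**2, axis=2), axis=0)
        msf = sq_sum / coords.shape[0]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return ResidueProfile(
        residue_index=np.asarray(traj.frames[0].residue_indices),
        value=np.sqrt(msf),
    )


def radius_of_gyration(frame: Frame, weighting: str = "uniform") -> float:
    """Rg = sqrt(sum w |r - r_cm|^2 / sum w) over the frame's atoms."""
    if not frame.atoms:
        raise DataError("empty frame")
    coords = np.asarray([a.position for a in frame.atoms], dtype=float)
    if weighting == "uniform":
        w = np.ones(len(coords))
    elif weighting == "mass":
        try:
            w = np.asarray([ATOMIC_MASSES[a.element.strip()] for a in frame.atoms])
        except KeyError as exc:
            raise LookupError(f"no atomic mass for element {exc.args[0]!r}") from exc
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    cm = np.average(coords, axis=0, weights=w)
    return float(np.sqrt(np.average(np.sum((coords - cm) ** 2, axis=1), weights=w)))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere lattice (golden-angle spiral)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa_shrake_rupley(
    frame: Frame,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area.

    Each atom is inflated by the probe radius and covered with a Fibonacci
    lattice of test points; a point is exposed if it lies outside every other
    inflated sphere.  Per-atom area = (exposed / total) * 4 pi (r + probe)^2.
    Returns (per-atom areas, total), both in Angstrom^2.
    """
    try:
        radii = np.asarray(
            [VDW_RADII[a.element.strip()] for a in frame.atoms], dtype=float
        )
    except KeyError as exc:
        raise LookupError(
            f"no van der Waals radius for element {exc.args[0]!r}"
        ) from exc
    coords = np.asarray([a.position for a in frame.atoms], dtype=float)
    inflated = radii + probe_radius
    sphere = _fibonacci_sphere(n_sphere_points)
    tree = cKDTree(coords)
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        points = coords[i] + inflated[i] * sphere
        neighbors = [
            j for j in tree.query_ball_point(coords[i], inflated[i] + inflated.max())
            if j != i and np.linalg.norm(coords[j] - coords[i]) < inflated[i] + inflated[j]
        ]
        if neighbors:
            d = np.linalg.norm(
                points[:, None, :] - coords[neighbors][None, :, :], axis=2
            )
            exposed = np.all(d >= inflated[neighbors][None, :] - 1e-12, axis=1)
        else:
            exposed = np.ones(n_sphere_points, dtype=bool)
        areas[i] = exposed.mean() * 4.0 * np.pi * inflated[i] ** 2
    return areas, float(areas.sum())


def sasa_series(
    traj: Trajectory,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    stride: int = 1,
) -> FrameSeries:
    """Total SASA per frame (optionally strided for long trajectories)."""
    labels: list[tuple[int, float]] = []
    vals: list[float] = []
    for f in traj.frames[::stride]:
        _, total = sasa_shrake_rupley(f, probe_radius, n_sphere_points)
        labels.append((f.replica_id, f.time_ns))
        vals.append(total)
    return FrameSeries(frame_labels=labels, values=np.asarray(vals))


def rg_series(traj: Trajectory, weighting: str = "uniform") -> FrameSeries:
    return FrameSeries(
        frame_labels=traj.frame_labels,
        values=np.asarray([radius_of_gyration(f, weighting) for f in traj.frames]),
    )


def series_stats(series: FrameSeries, ddof: int = 1) -> SeriesStats:
    """Overall and per-replica descriptive statistics (sample sd by default)."""
    v = series.values
    if v.size == 0:
        raise DataError("empty series")
    reps = np.asarray([r for r, _ in series.frame_labels])
    rep_ids = sorted(set(reps.tolist()))
    per_means = [float(v[reps == r].mean()) for r in rep_ids]
    per_sds = [
        float(v[reps == r].std(ddof=ddof)) if (reps == r).sum() > ddof else 0.0
        for r in rep_ids
    ]
    sd = float(v.std(ddof=ddof)) if v.size > ddof else 0.0
    return SeriesStats(
        mean=float(v.mean()),
        sd=sd,
        min=float(v.min()),
        max=float(v.max()),
        per_replica_means=per_means,
        per_replica_sds=per_sds,
        replica_ids=[int(r) for r in rep_ids],
    )


def write_profile_csv(profile: ResidueProfile, path: str | Path, name: str = "value") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["residue_index", name])
        for i, val in zip(profile.residue_index, profile.value):
            w.writerow([int(i), repr(float(val))])


def write_series_csv(series: FrameSeries, path: str | Path, name: str = "value") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["replica_id", "time_ns", name])
        for (rep, t), val in zip(series.frame_labels, series.values):
            w.writerow([rep, repr(float(t)), repr(float(val))])


def write_bfactor_pdb(
    reference: Frame, profile: ResidueProfile, path: str | Path
) -> None:
    """Write the reference frame with per-residue values in the B-factor column.

    Lets molecular viewers color the structure by RMSF (or any per-residue
    descriptor).
    """
    lookup = {int(i): float(v) for i, v in zip(profile.residue_index, profile.value)}
    unknown = [a.residue_index for a in reference.atoms if a.residue_index not in lookup]
    if unknown:
        raise EssdynError(f"profile lacks residue {unknown[0]}")
    with open(path, "w") as fh:
        fh.write("MODEL     1\n")
        for serial, a in enumerate(reference.atoms, start=1):
            x, y, z = a.position
            fh.write(
                f"ATOM  {serial:>5} {a.atom_name:^4.4}{a.residue_name:>4.3} A"
                f"{a.residue_index:>4}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.0:6.2f}{lookup[a.residue_index]:6.2f}"
                f"          {a.element:>2.2}\n"
            )
        fh.write("ENDMDL\nEND\n")
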