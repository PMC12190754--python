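"""Synthetic trajectory generator with known ground truth.

Emulates the sampling geometry of a triplicate 100 ns MD study of a
~449-residue chain — three replicas of 101 snapshots at 1 ns — without any
physics: frames are a reference C-alpha trace displaced along a few
orthonormal collective modes with Gaussian amplitudes, plus isotropic
per-atom noise and (optionally) a random rigid-body nuisance motion that
superposition must remove.  Replica-dependent amplitude means create
conformational basins, so clusters in the PC score plane track replicas; a
quadratic energy surface puts free-energy minima at the basin centers; a
Bernoulli tunnel table emulates presence/absence calls in two structure
groups.  A manifest records every latent quantity, so each pipeline stage
can be tested against planted truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .landscape import EnergySeries, write_energy_csv
from .trajectory import Frame, Trajectory, concatenate_replicas, write_multimodel_pdb

__all__ = ["SyntheticSpec", "make_reference_chain", "make_modes", "generate",
           "write_dataset"]


@dataclass
class SyntheticSpec:
    """Study conditions for the generator.

    Defaults mirror the emulated study: 449 residues, 3 replicas x 101
    frames (0-100 ns at 1 ns), three dominant modes of amplitude variance
    9, 4, 1 A^2, the first mode split into two anti-correlated halves,
    replica-specific basin centers well separated in the mode-1/mode-2
    plane, 0.3 A per-coordinate thermal noise, rigid-body nuisance on, an
    energy surface with per-replica depths near 100 kJ/mol, and tunnel
    presence probabilities 23/60 vs 38/60 at 60 sampled frames per group.
    """

    n_residues: int = 449
    n_replicas: int = 3
    frames_per_replica: int = 101
    snapshot_interval_ns: float = 1.0
    mode_variances: tuple[float, ...] = (9.0, 4.0, 1.0)
    #: per-mode optional block structure: list of (start_res, end_res, sign),
    #: 0-based half-open residue ranges; None = unstructured random field
    mode_blocks: tuple | None = None
    #: (n_replicas, n_modes) amplitude means; None = default separated basins
    basin_means: tuple | None = None
    noise_sd: float = 0.3
    rigid_nuisance: bool = True
    basin_depths: tuple[float, ...] = (95.0, 105.0, 100.0)
    curvature_weights: tuple[float, ...] = (0.5, 0.5, 0.0)
    energy_noise_sd: float = 2.0
    tunnel_probs: tuple[float, float] = (23 / 60, 38 / 60)
    tunnel_n: int = 60
    seed: int = 0

    def resolved_blocks(self) -> list[list[tuple[int, int, int]] | None]:
        if self.mode_blocks is not None:
            return list(self.mode_blocks)
        half = self.n_residues // 2
        # first mode: two halves of the chain moving in anti-phase
        blocks: list = [[(0, half, +1), (half, self.n_residues, -1)]]
        blocks += [None] * (len(self.mode_variances) - 1)
        return blocks

    def resolved_basin_means(self) -> np.ndarray:
        n_modes = len(self.mode_variances)
        if self.basin_means is not None:
            means = np.asarray(self.basin_means, dtype=float)
        else:
            # basins >= 10 sd apart in the mode-1/mode-2 plane
            means = np.zeros((self.n_replicas, n_modes))
            anchors = [(0.0, 0.0), (30.0, 0.0), (15.0, 26.0)]
            for r in range(self.n_replicas):
                a = anchors[r % len(anchors)]
                if n_modes >= 1:
                    means[r, 0] = a[0]
                if n_modes >= 2:
                    means[r, 1] = a[1]
        if means.shape != (self.n_replicas, n_modes):
            raise ValueError("basin_means must be (n_replicas, n_modes)")
        return means


def make_reference_chain(n_residues: int, seed: int = 0) -> Frame:
    """Ideal helical C-alpha trace, 3.8 A consecutive spacing, seeded pose.

    A helix with 1.5 A rise and 100 degrees twist per residue is
    self-avoiding and has exactly 3.8 A between consecutive C-alphas; the
    seed only sets a random global orientation.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    rise = 1.5
    twist = np.deg2rad(100.0)
    radius = np.sqrt(3.8**2 - rise**2) / (2.0 * np.sin(twist / 2.0))
    i = np.arange(n_residues)
    coords = np.column_stack(
        [radius * np.cos(twist * i), radius * np.sin(twist * i), rise * i]
    )
    coords -= coords.mean(axis=0)
    rng = np.random.default_rng(seed)
    q = rng.standard_normal(4)
    R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
    return Frame.from_ca_coords(coords @ R.T)


def make_modes(
    reference: Frame,
    variances: tuple[float, ...],
    blocks: list | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Orthonormal displacement fields, one row of length 3N per mode.

    A block-structured mode moves each listed residue range rigidly along a
    common random direction with the requested sign; unstructured modes are
    random Gaussian fields.  Fields are Gram-Schmidt orthonormalized in
    order, block modes first in their given positions.
    """
    n = reference.n_residues
    n_modes = len(variances)
    if n_modes > 3 * n:
        raise ValueError(f"cannot plant {n_modes} modes in a 3N={3 * n} space")
    if blocks is None:
        blocks = [None] * n_modes
    rng = np.random.default_rng(seed)
    fields = np.empty((n_modes, 3 * n))
    for k in range(n_modes):
        if blocks[k] is not None:
            f = np.zeros((n, 3))
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            for start, end, sign in blocks[k]:
                f[start:end] = sign * direction
            fields[k] = f.ravel()
        else:
            fields[k] = rng.standard_normal(3 * n)
    # Gram-Schmidt
    for k in range(n_modes):
        for j in range(k):
            fields[k] -= (fields[k] @ fields[j]) * fields[j]
        norm = np.linalg.norm(fields[k])
        if norm < 1e-12:
            raise ValueError(f"mode {k} degenerate after orthogonalization")
        fields[k] /= norm
    return fields


def generate(
    spec: SyntheticSpec,
) -> tuple[Trajectory, EnergySeries, pd.DataFrame, dict]:
    """Generate (trajectory, energy series, tunnel table, ground-truth manifest).

    Frame t of replica c:  x(t) = R_t [x_ref + sum_k a_k(t) v_k + eps] + s_t
    with a_k ~ Normal(basin mean of c, variance_k), eps isotropic noise, and
    (R_t, s_t) an optional random rigid nuisance.  The energy is quadratic
    about each basin center plus the replica's depth and Gaussian noise;
    tunnel presence is Bernoulli per group.
    """
    rng = np.random.default_rng(spec.seed)
    reference = make_reference_chain(spec.n_residues, seed=spec.seed)
    ref_coords = reference.ca_coords
    blocks = spec.resolved_blocks()
    modes = make_modes(reference, spec.mode_variances, blocks, seed=spec.seed + 1)
    means = spec.resolved_basin_means()
    sds = np.sqrt(np.asarray(spec.mode_variances, dtype=float))
    # curvature weights beyond the mode count are ignored; missing ones are 0
    cw = np.asarray(spec.curvature_weights, dtype=float)
    w = np.zeros(len(sds))
    w[: min(len(cw), len(sds))] = cw[: min(len(cw), len(sds))]

    replicas: list[Trajectory] = []
    amplitudes = np.empty((spec.n_replicas, spec.frames_per_replica, len(sds)))
    dG: list[float] = []
    labels: list[tuple[int, float]] = []
    for c in range(spec.n_replicas):
        frames = []
        for t in range(spec.frames_per_replica):
            a = means[c] + sds * rng.standard_normal(len(sds))
            amplitudes[c, t] = a
            coords = ref_coords + (a @ modes).reshape(-1, 3)
            if spec.noise_sd > 0:
                coords = coords + spec.noise_sd * rng.standard_normal(coords.shape)
            if spec.rigid_nuisance:
                q = rng.standard_normal(4)
                R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
                s = rng.normal(0.0, 20.0, size=3)
                coords = coords @ R.T + s
            time_ns = t * spec.snapshot_interval_ns
            frames.append(Frame.from_ca_coords(coords, time_ns=time_ns, replica_id=c))
            depth = spec.basin_depths[c % len(spec.basin_depths)]
            energy = float(
                np.sum(w * (a - means[c]) ** 2)
                + depth
                + rng.normal(0.0, spec.energy_noise_sd)
            )
            dG.append(energy)
            labels.append((c, time_ns))
        replicas.append(
            Trajectory(
                frames=frames,
                n_residues=spec.n_residues,
                snapshot_interval_ns=spec.snapshot_interval_ns,
            )
        )
    traj = concatenate_replicas(replicas)
    energy_series = EnergySeries(frame_labels=traj.frame_labels, dG=np.asarray(dG))

    p_wt, p_mut = spec.tunnel_probs
    tunnel = pd.DataFrame(
        {
            "frame": list(range(spec.tunnel_n)) * 2,
            "group": ["wt"] * spec.tunnel_n + ["mut"] * spec.tunnel_n,
            "present": np.concatenate(
                [
                    (rng.random(spec.tunnel_n) < p_wt).astype(int),
                    (rng.random(spec.tunnel_n) < p_mut).astype(int),
                ]
            ),
        }
    )

    manifest = {
        "seed": spec.seed,
        "n_residues": spec.n_residues,
        "n_replicas": spec.n_replicas,
        "frames_per_replica": spec.frames_per_replica,
        "mode_variances": list(spec.mode_variances),
        "mode_blocks": [
            [list(b) for b in blk] if blk is not None else None for blk in blocks
        ],
        "modes": modes.tolist(),
        "basin_means": means.tolist(),
        "basin_depths": list(spec.basin_depths),
        "curvature_weights": list(spec.curvature_weights),
        "noise_sd": spec.noise_sd,
        "rigid_nuisance": spec.rigid_nuisance,
        "energy_noise_sd": spec.energy_noise_sd,
        "tunnel_probs": [p_wt, p_mut],
        "tunnel_n": spec.tunnel_n,
        "amplitudes": amplitudes.tolist(),
        "reference_coords": ref_coords.tolist(),
    }
    return traj, energy_series, tunnel, manifest


def write_dataset(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate and write per-replica PDBs, energy CSV, tunnel CSV and manifest.

    One multi-model PDB per replica (`replica_0.pdb`, ...) so the pipeline's
    concatenation step is exercised on read-back; replica identity is not
    encoded inside the PDB format itself.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traj, energy, tunnel, manifest = generate(spec)
    paths: dict[str, Path] = {
        "energy": outdir / "energy.csv",
        "tunnel": outdir / "tunnel.csv",
        "manifest": outdir / "manifest.json",
        "replicas": [],
    }
    for rid in traj.replica_ids:
        sub = Trajectory(
            frames=[f for f in traj.frames if f.replica_id == rid],
            n_residues=traj.n_residues,
            snapshot_interval_ns=traj.snapshot_interval_ns,
        )
        p = outdir / f"replica_{rid}.pdb"
        write_multimodel_pdb(sub, p)
        paths["replicas"].append(p)
    write_energy_csv(energy, paths["energy"])
    tunnel.to_csv(paths["tunnel"], index=False)
    manifest_small = {k: v for k, v in manifest.items() if k not in ("modes", "amplitudes", "reference_coords")}
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest_small, fh, indent=1)
    return paths
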