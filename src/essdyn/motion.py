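"""Coordinated motion: dynamic cross-correlation and porcupine vector fields.

The DCCM entry for residues i, j is the normalized average dot product of
their centered displacement vectors,

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>),  dr_i(t) = r_i(t) - <r_i>,

so C_ij = +1 for perfectly in-phase motion and -1 for anti-phase motion.
Porcupine fields turn a PC eigenvector into one arrow per residue (the
residue's x,y,z loading triplet, scaled), anchored at the reference C-alpha.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError
from .essential_dynamics import EssentialDynamicsResult
from .trajectory import Frame, Trajectory

__all__ = [
    "DCCMatrix",
    "PorcupineField",
    "dccm",
    "dccm_blocks",
    "porcupine_field",
    "export_arrows",
    "read_arrows_csv",
    "arrow_difference_table",
]


@dataclass
class DCCMatrix:
    """Symmetric N x N residue motion correlation in [-1, +1]."""

    values: np.ndarray
    residue_labels: list[int]
    zero_variance_residues: list[int]


@dataclass
class PorcupineField:
    """Per-residue displacement arrows for one principal component."""

    base: np.ndarray       # (N, 3) reference C-alpha positions
    arrows: np.ndarray     # (N, 3) scaled eigenvector triplets
    magnitudes: np.ndarray
    residue_index: np.ndarray
    component: int
    scale: float


def dccm(traj: Trajectory | np.ndarray) -> DCCMatrix:
    """Dynamic cross-correlation matrix over an aligned trajectory.

    Accepts a :class:`Trajectory` or a raw (frames, residues, 3) array.
    A residue with zero displacement variance gets a zeroed row/column
    (diagonal 1) and is flagged rather than dividing by zero.
    """
    if isinstance(traj, Trajectory):
        coords = traj.ca_array()
        labels = list(traj.frames[0].residue_indices)
    else:
        coords = np.asarray(traj, dtype=float)
        labels = list(range(1, coords.shape[1] + 1))
    if coords.shape[0] < 2:
        raise DataError("DCCM requires at least 2 frames")
    dev = coords - coords.mean(axis=0)            # (F, N, 3)
    cross = np.einsum("tia,tja->ij", dev, dev) / coords.shape[0]
    var = np.diag(cross).copy()
    zero = var <= 1e-300
    norm = np.sqrt(np.where(zero, 1.0, var))
    C = cross / np.outer(norm, norm)
    C[zero, :] = 0.0
    C[:, zero] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    return DCCMatrix(
        values=C,
        residue_labels=labels,
        zero_variance_residues=[labels[i] for i in np.flatnonzero(zero)],
    )


def _segments(C: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs of residues whose consecutive correlations exceed threshold."""
    n = C.shape[0]
    segs = []
    start = 0
    for i in range(1, n):
        if C[i - 1, i] < threshold:
            segs.append((start, i - 1))
            start = i
    segs.append((start, n - 1))
    return segs


def dccm_blocks(
    d: DCCMatrix, threshold: float
) -> list[dict]:
    """Summarize a DCCM into coordinated residue-range pairs.

    Residues are first segmented into maximal contiguous runs whose
    consecutive-neighbour correlation stays above ``threshold``; every pair
    of such segments (including a segment with itself) is reported when its
    mean correlation exceeds +threshold (moving together) or falls below
    -threshold (moving oppositely).  Singleton self-pairs are skipped — the
    diagonal is trivially 1.
    """
    if not 0 <= abs(threshold) < 1:
        raise ValueError("|threshold| must be < 1")
    C = d.values
    labels = d.residue_labels
    segs = _segments(C, threshold)
    blocks: list[dict] = []
    for a, (i0, i1) in enumerate(segs):
        for j0, j1 in segs[a:]:
            sub = C[i0 : i1 + 1, j0 : j1 + 1]
            if (i0, i1) == (j0, j1):
                if i1 == i0:
                    continue
                mask = ~np.eye(sub.shape[0], dtype=bool)
                mean_c = float(sub[mask].mean())
            else:
                mean_c = float(sub.mean())
            if mean_c >= threshold:
                sign = +1
            elif mean_c <= -threshold:
                sign = -1
            else:
                continue
            blocks.append(
                {
                    "range_a": (labels[i0], labels[i1]),
                    "range_b": (labels[j0], labels[j1]),
                    "sign": sign,
                    "mean_abs_correlation": abs(mean_c),
                }
            )
    return blocks


def porcupine_field(
    res: EssentialDynamicsResult,
    component: int,
    reference: Frame,
    scale: float | None = None,
) -> PorcupineField:
    """Arrows for PC ``component`` (1-based) anchored at the reference CAs.

    When ``scale`` is omitted it is chosen so the longest arrow is 10 A.
    """
    if component < 1 or component > res.loadings.shape[1]:
        raise ValueError(
            f"component {component} out of range 1..{res.loadings.shape[1]}"
        )
    vec = res.loadings[:, component - 1]
    n_res = reference.n_residues
    if vec.size != 3 * n_res:
        raise DataError(
            f"loading length {vec.size} != 3 x {n_res} residues"
        )
    triplets = vec.reshape(n_res, 3)
    norms = np.linalg.norm(triplets, axis=1)
    if scale is None:
        peak = norms.max()
        scale = 10.0 / peak if peak > 0 else 1.0
    if scale <= 0:
        raise ValueError("scale must be positive")
    arrows = triplets * scale
    return PorcupineField(
        base=reference.ca_coords,
        arrows=arrows,
        magnitudes=np.linalg.norm(arrows, axis=1),
        residue_index=np.asarray(reference.residue_indices),
        component=component,
        scale=float(scale),
    )


def export_arrows(field: PorcupineField, path: str | Path, format: str = "bild") -> None:
    """Write arrows as a Chimera-loadable .bild file or a CSV table."""
    path = Path(path)
    if format == "bild":
        with open(path, "w") as fh:
            fh.write(f".comment porcupine field PC{field.component}\n.color red\n")
            for base, arrow in zip(field.base, field.arrows):
                tip = base + arrow
                fh.write(
                    ".arrow "
                    + " ".join(f"{v:.4f}" for v in base)
                    + " "
                    + " ".join(f"{v:.4f}" for v in tip)
                    + "\n"
                )
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["residue_index", "base_x", "base_y", "base_z",
                 "tip_x", "tip_y", "tip_z", "magnitude"]
            )
            for res, base, arrow, mag in zip(
                field.residue_index, field.base, field.arrows, field.magnitudes
            ):
                tip = base + arrow
                w.writerow(
                    [int(res)]
                    + [repr(float(v)) for v in base]
                    + [repr(float(v)) for v in tip]
                    + [repr(float(mag))]
                )
    else:
        raise ValueError(f"unknown format {format!r}")


def read_arrows_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def arrow_difference_table(
    field_a: PorcupineField, field_b: PorcupineField
) -> pd.DataFrame:
    """Per-residue arrow difference between two variants on a common reference.

    The testable counterpart of superimposing two porcupine plots: for each
    residue the vector difference of the two arrows and its magnitude.
    """
    if not np.array_equal(field_a.residue_index, field_b.residue_index):
        raise DataError("fields cover different residue sets")
    diff = field_b.arrows - field_a.arrows
    return pd.DataFrame(
        {
            "residue_index": field_a.residue_index,
            "dx": diff[:, 0],
            "dy": diff[:, 1],
            "dz": diff[:, 2],
            "difference_magnitude": np.linalg.norm(diff, axis=1),
            "magnitude_a": field_a.magnitudes,
            "magnitude_b": field_b.magnitudes,
        }
    )
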