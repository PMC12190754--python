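"""Free-energy landscape over the PC plane and the tunnel proportion test.

A per-frame Gibbs free-energy series (an external stability estimate, one
value per snapshot) is interpolated linearly over the Delaunay triangulation
of the (PC1, PC2) score points onto a regular grid; nodes outside the convex
hull stay undefined, so the landscape never extrapolates minima.  An
alternative population-based estimator, dG = -kT ln(rho), is available for
comparison but is not the primary construction.  The module also provides
the pooled two-proportion Z-test used to compare tunnel occurrence between
two structure groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError

from .descriptors import FrameSeries, SeriesStats, series_stats
from .exceptions import AlignmentError, DataError, DegeneracyError, DegenerateTestError

__all__ = [
    "EnergySeries",
    "FreeEnergyLandscape",
    "ProportionTest",
    "attach_energy",
    "read_energy_csv",
    "write_energy_csv",
    "build_landscape",
    "build_landscape_boltzmann",
    "landscape_stats",
    "two_proportion_ztest",
    "read_tunnel_csv",
]

#: kJ/mol/K, for the optional Boltzmann-inversion landscape
GAS_CONSTANT_KJ = 0.0083144626


@dataclass
class EnergySeries:
    """Per-frame Gibbs free energy (kJ/mol), labelled like the trajectory."""

    frame_labels: list[tuple[int, float]]
    dG: np.ndarray

    def __post_init__(self) -> None:
        self.dG = np.asarray(self.dG, dtype=float)
        if len(self.frame_labels) != self.dG.shape[0]:
            raise DataError("one energy value per frame required")
        if not np.all(np.isfinite(self.dG)):
            raise DataError("energy series contains non-finite values")

    def as_frame_series(self) -> FrameSeries:
        return FrameSeries(frame_labels=list(self.frame_labels), values=self.dG)


@dataclass
class FreeEnergyLandscape:
    """Gridded dG over the PC1/PC2 plane (NaN outside the data hull)."""

    grid_pc1: np.ndarray
    grid_pc2: np.ndarray
    dG_grid: np.ndarray          # shape (len(grid_pc2), len(grid_pc1))
    interpolator: LinearNDInterpolator
    stats: SeriesStats

    def at(self, points: np.ndarray) -> np.ndarray:
        """Interpolated dG at arbitrary (PC1, PC2) points."""
        return self.interpolator(np.asarray(points, dtype=float))

    def local_minima(self) -> list[tuple[float, float, float]]:
        """Grid nodes strictly below all 8 defined neighbours.

        Returns (pc1, pc2, dG) triples; nodes at the hull edge (with any
        undefined neighbour) are excluded to avoid boundary artefacts.
        """
        Z = self.dG_grid
        minima = []
        for i in range(1, Z.shape[0] - 1):
            for j in range(1, Z.shape[1] - 1):
                patch = Z[i - 1 : i + 2, j - 1 : j + 2]
                if np.any(np.isnan(patch)):
                    continue
                center = Z[i, j]
                rest = np.delete(patch.ravel(), 4)
                if np.all(center < rest):
                    minima.append(
                        (float(self.grid_pc1[j]), float(self.grid_pc2[i]), float(center))
                    )
        return minima


@dataclass
class ProportionTest:
    successes_1: int
    n_1: int
    successes_2: int
    n_2: int
    p1: float
    p2: float
    pooled: float
    se: float
    z: float
    p_two_sided: float


def read_energy_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"replica_id", "time_ns", "dG_kJ_per_mol"}
    if not required.issubset(df.columns):
        raise DataError(f"energy CSV must have columns {sorted(required)}")
    return df


def write_energy_csv(series: EnergySeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "replica_id": [r for r, _ in series.frame_labels],
            "time_ns": [t for _, t in series.frame_labels],
            "dG_kJ_per_mol": series.dG,
        }
    ).to_csv(path, index=False)


def _key(label: tuple[int, float]) -> tuple[int, float]:
    return (int(label[0]), round(float(label[1]), 6))


def attach_energy(
    frame_labels: list[tuple[int, float]],
    energies: pd.DataFrame | str | Path,
) -> EnergySeries:
    """Align an energy table to the trajectory's frame labels.

    Rows may arrive in any order; they are matched on (replica_id, time_ns).
    Missing or extra rows raise an alignment error naming the offenders.
    """
    if not isinstance(energies, pd.DataFrame):
        energies = read_energy_csv(energies)
    table = {
        _key((row.replica_id, row.time_ns)): float(row.dG_kJ_per_mol)
        for row in energies.itertuples()
    }
    if len(table) != len(energies):
        raise AlignmentError("duplicate (replica_id, time_ns) rows in energy table")
    wanted = [_key(lbl) for lbl in frame_labels]
    missing = [k for k in wanted if k not in table]
    extra = sorted(set(table) - set(wanted))
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing frames: {missing[:5]}")
        if extra:
            parts.append(f"extra frames: {extra[:5]}")
        raise AlignmentError("; ".join(parts))
    return EnergySeries(
        frame_labels=list(frame_labels),
        dG=np.asarray([table[k] for k in wanted]),
    )


def build_landscape(
    scores: np.ndarray,
    energy: EnergySeries,
    grid_n: int = 100,
) -> FreeEnergyLandscape:
    """Linear Delaunay interpolation of dG over the (PC1, PC2) score points."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] < 2:
        raise DataError("scores must be (frames, >=2); PC1 and PC2 are used")
    pts = scores[:, :2]
    if pts.shape[0] != energy.dG.shape[0]:
        raise DataError("score and energy lengths differ")
    if pts.shape[0] < 3:
        raise DegeneracyError("need at least 3 score points")
    try:
        interp = LinearNDInterpolator(pts, energy.dG)
    except QhullError as exc:
        raise DegeneracyError(f"degenerate (collinear?) score points: {exc}") from exc
    if interp.tri.npoints < 3 or len(interp.tri.simplices) == 0:
        raise DegeneracyError("score points do not span a 2-D region")
    gx = np.linspace(pts[:, 0].min(), pts[:, 0].max(), grid_n)
    gy = np.linspace(pts[:, 1].min(), pts[:, 1].max(), grid_n)
    X, Y = np.meshgrid(gx, gy)
    Z = interp(X, Y)
    return FreeEnergyLandscape(
        grid_pc1=gx,
        grid_pc2=gy,
        dG_grid=Z,
        interpolator=interp,
        stats=series_stats(energy.as_frame_series()),
    )


def build_landscape_boltzmann(
    scores: np.ndarray,
    grid_n: int = 100,
    temperature: float = 298.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Population-based alternative: dG = -RT ln(rho) from the score density.

    Provided for comparison only; the primary landscape interpolates an
    externally supplied per-frame energy instead.  Returns (grid_pc1,
    grid_pc2, dG_grid) with the minimum shifted to zero.
    """
    pts = np.asarray(scores, dtype=float)[:, :2]
    H, xedges, yedges = np.histogram2d(pts[:, 0], pts[:, 1], bins=grid_n)
    with np.errstate(divide="ignore"):
        dG = -GAS_CONSTANT_KJ * temperature * np.log(H.T / H.sum())
    dG[np.isinf(dG)] = np.nan
    dG -= np.nanmin(dG)
    gx = (xedges[:-1] + xedges[1:]) / 2
    gy = (yedges[:-1] + yedges[1:]) / 2
    return gx, gy, dG


def landscape_stats(
    energy: EnergySeries,
    clusters=None,
) -> pd.DataFrame:
    """One-row summary in the layout of a free-energy statistics table.

    Columns: Average, SD, Minimum, Maximum, one average (and SD) per
    trajectory; per-cluster means appended when a cluster model is given.
    """
    st = series_stats(energy.as_frame_series())
    row: dict[str, float] = {
        "average_kJ_per_mol": st.mean,
        "sd_kJ_per_mol": st.sd,
        "minimum_kJ_per_mol": st.min,
        "maximum_kJ_per_mol": st.max,
    }
    for rid, mean, sd in zip(st.replica_ids, st.per_replica_means, st.per_replica_sds):
        row[f"trajectory_{rid + 1}_average_kJ_per_mol"] = mean
        row[f"trajectory_{rid + 1}_sd_kJ_per_mol"] = sd
    if clusters is not None:
        labels = np.asarray(clusters.labels)
        for c in range(clusters.k):
            row[f"cluster_{c + 1}_average_kJ_per_mol"] = float(
                energy.dG[labels == c].mean()
            )
    return pd.DataFrame([row])


def two_proportion_ztest(s1: int, n1: int, s2: int, n2: int) -> ProportionTest:
    """Pooled-variance two-proportion Z-test, two-sided, no continuity correction.

    z = (p2 - p1) / sqrt(p_hat (1 - p_hat) (1/n1 + 1/n2)) with p_hat the
    pooled proportion; p = 2 (1 - Phi(|z|)).
    """
    for s, n, who in ((s1, n1, "group 1"), (s2, n2, "group 2")):
        if n < 1:
            raise DataError(f"{who}: n must be >= 1")
        if not 0 <= s <= n:
            raise DataError(f"{who}: successes must lie in [0, n]")
    pooled = (s1 + s2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise DegenerateTestError(
            "pooled proportion is 0 or 1; the Z statistic is undefined"
        )
    p1 = s1 / n1
    p2 = s2 / n2
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p2 - p1) / se
    p_two = float(2.0 * stats.norm.sf(abs(z)))
    return ProportionTest(
        successes_1=s1, n_1=n1, successes_2=s2, n_2=n2,
        p1=p1, p2=p2, pooled=pooled, se=se, z=z, p_two_sided=p_two,
    )


def read_tunnel_csv(path: str | Path) -> pd.DataFrame:
    """Tunnel-presence table: columns frame, group, present (0/1)."""
    df = pd.read_csv(path)
    required = {"frame", "group", "present"}
    if not required.issubset(df.columns):
        raise DataError(f"tunnel CSV must have columns {sorted(required)}")
    return df
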