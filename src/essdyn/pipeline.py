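"""End-to-end orchestration: align -> descriptors -> PCA -> clustering ->
DCCM/porcupine -> landscape -> tunnel test, with a resolved-config record,
structured logging and a plain-text report.

Every run writes its resolved configuration and a log of each decision knob
next to the outputs, and is a pure function of (inputs, seeds): re-running
with the same config reproduces the numeric outputs byte for byte.  Stages
fail loudly with their stage name; outputs of completed stages are retained.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering as cl
from . import descriptors as desc
from . import landscape as fel
from . import motion
from . import essential_dynamics as ed
from .exceptions import StageError
from .trajectory import (
    Trajectory,
    build_coordinate_matrix,
    concatenate_replicas,
    read_multimodel_pdb,
    superpose_trajectory,
    write_multimodel_pdb,
)

__all__ = ["RunConfig", "run_pipeline", "analyze", "report"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat, serializable configuration of a full analysis run.

    Defaults follow the emulated study where it states a value (1 ns
    snapshots, |loading| >= 0.7 threshold, top 10% per-cluster selection,
    95th-percentile parallel analysis); everything else is an explicit,
    logged package default.
    """

    replica_paths: list[str] = field(default_factory=list)
    energy_csv: str | None = None
    tunnel_csv: str | None = None
    outdir: str = "essdyn_run"
    snapshot_interval_ns: float = 1.0
    pca_mode: str = "correlation"
    pa_draws: int = 100
    pa_percentile: float = 0.95
    pa_method: str = "permutation"
    k_min: int = 2
    k_max: int = 10
    kmeans_restarts: int = 25
    cluster_dims: int = 2
    loading_cutoff: float = 0.7
    decile_fraction: float = 0.10
    grid_n: int = 100
    dccm_block_threshold: float = 0.5
    sasa_stride: int = 10
    sasa_points: int = 960
    porcupine_components: tuple[int, ...] = (1, 2)
    seed: int = 0
    write_aligned: bool = True
    make_figures: bool = True

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, default=str)


def _fig_scree(table: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(range(1, len(table) + 1), table["eigenvalue"], "o-")
    ax.set_xlabel("component")
    ax.set_ylabel("eigenvalue")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fig_dccm(d: motion.DCCMatrix, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(d.values, cmap="bwr", vmin=-1, vmax=1, origin="lower")
    fig.colorbar(im, ax=ax, label="correlation")
    ax.set_xlabel("residue")
    ax.set_ylabel("residue")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fig_landscape(ls: fel.FreeEnergyLandscape, path2d: Path, path3d: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.6))
    cs = ax.contourf(ls.grid_pc1, ls.grid_pc2, ls.dG_grid, levels=25, cmap="viridis")
    fig.colorbar(cs, ax=ax, label="dG (kJ/mol)")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    fig.tight_layout()
    fig.savefig(path2d, dpi=120)
    plt.close(fig)

    fig = plt.figure(figsize=(5, 4))
    ax = fig.add_subplot(projection="3d")
    X, Y = np.meshgrid(ls.grid_pc1, ls.grid_pc2)
    ax.plot_surface(X, Y, ls.dG_grid, cmap="viridis")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_zlabel("dG")
    fig.savefig(path3d, dpi=120)
    plt.close(fig)


def _fig_porcupine(field_: motion.PorcupineField, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.quiver(
        field_.base[:, 0], field_.base[:, 1],
        field_.arrows[:, 0], field_.arrows[:, 1],
        field_.magnitudes, cmap="plasma", angles="xy",
    )
    ax.set_xlabel("x (A)")
    ax.set_ylabel("y (A)")
    ax.set_title(f"PC{field_.component} porcupine (xy projection)")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def analyze(
    traj: Trajectory,
    cfg: RunConfig,
    energy: fel.EnergySeries | None = None,
    tunnel: pd.DataFrame | None = None,
) -> Path:
    """Run every analysis stage on an in-memory trajectory; returns the run dir."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("essdyn")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    (outdir / "config.json").write_text(cfg.to_json())

    def stage(name):
        logger.info("stage %s", name)
        return name

    try:
        name = stage("align")
        aligned = superpose_trajectory(traj)
        if cfg.write_aligned:
            write_multimodel_pdb(aligned, outdir / "aligned.pdb")

        name = stage("descriptors")
        profile = desc.rmsf(aligned)
        desc.write_profile_csv(profile, outdir / "rmsf.csv", name="rmsf_A")
        desc.write_bfactor_pdb(aligned.frames[0], profile, outdir / "rmsf_bfactor.pdb")
        rg = desc.rg_series(aligned)
        desc.write_series_csv(rg, outdir / "rg.csv", name="rg_A")
        sasa = desc.sasa_series(
            aligned, n_sphere_points=cfg.sasa_points, stride=cfg.sasa_stride
        )
        desc.write_series_csv(sasa, outdir / "sasa.csv", name="sasa_A2")
        stats_rows = []
        for label, series in (("sasa_A2", sasa), ("rg_A", rg)):
            st = desc.series_stats(series)
            stats_rows.append(
                {"series": label, "mean": st.mean, "sd": st.sd,
                 "min": st.min, "max": st.max,
                 **{f"replica_{r}_mean": m
                    for r, m in zip(st.replica_ids, st.per_replica_means)}}
            )
        pd.DataFrame(stats_rows).to_csv(outdir / "descriptor_stats.csv", index=False)

        name = stage("pca")
        matrix = build_coordinate_matrix(aligned)
        if cfg.pca_mode == "correlation":
            std, info = ed.standardize_columns(matrix)
            result = ed.pca(std)
            pa = ed.parallel_analysis(
                std, n_draws=cfg.pa_draws, percentile=cfg.pa_percentile,
                seed=cfg.seed, method=cfg.pa_method,
            )
        else:
            result = ed.pca(matrix, mode="covariance")
            std, _ = ed.standardize_columns(matrix)
            pa = ed.parallel_analysis(
                std, n_draws=cfg.pa_draws, percentile=cfg.pa_percentile,
                seed=cfg.seed, method=cfg.pa_method,
            )
        result.k_retained = max(pa.k_retained, 2)
        logger.info("parallel analysis retains %d components", pa.k_retained)
        scree = ed.scree_data(result, n_show=10)
        scree.to_csv(outdir / "scree.csv", index=False)
        summary = {}
        for i in range(min(3, len(scree))):
            summary[f"PC{i + 1}_eigenvalue"] = float(result.eigenvalues[i])
            summary[f"PC{i + 1}_cumulative_pct"] = float(
                100 * result.cumulative_proportion[i]
            )
        pd.DataFrame([summary]).to_csv(outdir / "pca_summary.csv", index=False)
        n_keep = min(10, result.scores.shape[1])
        scores_df = pd.DataFrame(
            result.scores[:, :n_keep],
            columns=[f"PC{i + 1}" for i in range(n_keep)],
        )
        scores_df.insert(0, "time_ns", [t for _, t in matrix.frame_labels])
        scores_df.insert(0, "replica_id", [r for r, _ in matrix.frame_labels])
        scores_df.to_csv(outdir / "scores.csv", index=False)
        loadings_df = pd.DataFrame(
            result.loadings[:, : min(3, result.loadings.shape[1])],
            columns=[f"PC{i + 1}_loading"
                     for i in range(min(3, result.loadings.shape[1]))],
        )
        loadings_df.insert(0, "axis", [a for _, a in matrix.column_labels])
        loadings_df.insert(0, "residue_index", [r for r, _ in matrix.column_labels])
        loadings_df.to_csv(outdir / "loadings.csv", index=False)
        with open(outdir / "parallel_analysis.json", "w") as fh:
            json.dump(
                {"k_retained": pa.k_retained, "n_draws": pa.n_draws,
                 "percentile": pa.percentile, "method": pa.method, "seed": pa.seed},
                fh, indent=1,
            )
        if cfg.make_figures:
            _fig_scree(scree, outdir / "scree.png")

        name = stage("cluster")
        d = min(cfg.cluster_dims, result.scores.shape[1])
        model = cl.silhouette_scan(
            result.scores[:, :d],
            k_range=range(cfg.k_min, cfg.k_max + 1),
            n_init=cfg.kmeans_restarts,
            seed=cfg.seed,
        )
        model.silhouette_by_k.to_csv(outdir / "silhouette_by_k.csv", index=False)
        assign = pd.DataFrame(
            {
                "frame": range(len(model.labels)),
                "replica_id": [r for r, _ in matrix.frame_labels],
                "time_ns": [t for _, t in matrix.frame_labels],
                "cluster": model.labels,
            }
        )
        assign.to_csv(outdir / "clusters.csv", index=False)
        cluster_map = cl.map_clusters_to_frames(model, matrix.frame_labels)
        with open(outdir / "cluster_map.json", "w") as fh:
            json.dump({str(k): v for k, v in cluster_map.items()}, fh, indent=1,
                      default=str)

        name = stage("loading_selection")
        pair = result.loadings[:, :2]
        thr = cl.select_loadings_threshold(
            pair, matrix.column_labels, cutoff=cfg.loading_cutoff
        )
        thr.variables.to_csv(outdir / "loadings_threshold.csv", index=False)
        dec = cl.select_loadings_top_decile(
            pair, matrix.column_labels, n_clusters=model.k,
            fraction=cfg.decile_fraction, seed=cfg.seed,
            n_init=cfg.kmeans_restarts,
        )
        dec.variables.to_csv(outdir / "loadings_top_decile.csv", index=False)

        name = stage("dccm")
        d_mat = motion.dccm(aligned)
        pd.DataFrame(
            d_mat.values, index=d_mat.residue_labels, columns=d_mat.residue_labels
        ).to_csv(outdir / "dccm.csv")
        blocks = motion.dccm_blocks(d_mat, threshold=cfg.dccm_block_threshold)
        pd.DataFrame(blocks).to_csv(outdir / "dccm_blocks.csv", index=False)
        if cfg.make_figures:
            _fig_dccm(d_mat, outdir / "dccm.png")

        name = stage("porcupine")
        for comp in cfg.porcupine_components:
            if comp > result.loadings.shape[1]:
                continue
            field_ = motion.porcupine_field(result, comp, aligned.frames[0])
            motion.export_arrows(field_, outdir / f"porcupine_pc{comp}.bild", "bild")
            motion.export_arrows(field_, outdir / f"porcupine_pc{comp}.csv", "csv")
            if cfg.make_figures:
                _fig_porcupine(field_, outdir / f"porcupine_pc{comp}.png")

        if energy is not None:
            name = stage("landscape")
            ls = fel.build_landscape(result.scores[:, :2], energy, grid_n=cfg.grid_n)
            grid_df = pd.DataFrame(
                ls.dG_grid, index=ls.grid_pc2, columns=ls.grid_pc1
            )
            grid_df.to_csv(outdir / "landscape_grid.csv")
            fel.landscape_stats(energy, model).to_csv(
                outdir / "landscape_stats.csv", index=False
            )
            minima = ls.local_minima()
            pd.DataFrame(
                minima, columns=["pc1", "pc2", "dG_kJ_per_mol"]
            ).to_csv(outdir / "landscape_minima.csv", index=False)
            if cfg.make_figures:
                _fig_landscape(
                    ls, outdir / "landscape_2d.png", outdir / "landscape_3d.png"
                )
        else:
            logger.warning("no energy series supplied; landscape stage skipped")

        if tunnel is not None:
            name = stage("ztest")
            groups = list(dict.fromkeys(tunnel["group"]))
            if len(groups) != 2:
                raise ValueError(f"tunnel table must have 2 groups, got {groups}")
            g1 = tunnel[tunnel["group"] == groups[0]]
            g2 = tunnel[tunnel["group"] == groups[1]]
            test = fel.two_proportion_ztest(
                int(g1["present"].sum()), len(g1),
                int(g2["present"].sum()), len(g2),
            )
            with open(outdir / "ztest.json", "w") as fh:
                json.dump(
                    {"group_1": groups[0], "group_2": groups[1],
                     "successes_1": test.successes_1, "n_1": test.n_1,
                     "successes_2": test.successes_2, "n_2": test.n_2,
                     "p1": test.p1, "p2": test.p2, "pooled": test.pooled,
                     "se": test.se, "z": test.z,
                     "p_two_sided": test.p_two_sided},
                    fh, indent=1,
                )
        else:
            logger.info("no tunnel table supplied; Z-test stage skipped")
    except Exception as exc:
        raise StageError(name, str(exc)) from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir


def run_pipeline(cfg: RunConfig) -> Path:
    """File-based entry point: read inputs named in the config, then analyze."""
    if not cfg.replica_paths:
        raise ValueError("config names no replica PDB files")
    replicas = [
        read_multimodel_pdb(p, snapshot_interval_ns=cfg.snapshot_interval_ns,
                            replica_id=i)
        for i, p in enumerate(cfg.replica_paths)
    ]
    traj = concatenate_replicas(replicas)
    energy = None
    if cfg.energy_csv is not None:
        if Path(cfg.energy_csv).exists():
            energy = fel.attach_energy(traj.frame_labels, cfg.energy_csv)
        else:
            logger.warning(
                "energy CSV %s not found; landscape stage will be skipped",
                cfg.energy_csv,
            )
    tunnel = None
    if cfg.tunnel_csv is not None:
        if Path(cfg.tunnel_csv).exists():
            tunnel = fel.read_tunnel_csv(cfg.tunnel_csv)
        else:
            logger.warning(
                "tunnel CSV %s not found; Z-test stage will be skipped",
                cfg.tunnel_csv,
            )
    return analyze(traj, cfg, energy=energy, tunnel=tunnel)


def report(run_dir: str | Path) -> str:
    """Assemble a human-readable summary from a run directory.

    Missing stage outputs are flagged as gaps rather than failing, so a
    partial run still yields a partial report.  Regeneration is idempotent.
    """
    run_dir = Path(run_dir)
    lines = [f"# Essential-dynamics run report: {run_dir.name}", ""]

    def section(title: str, filename: str, render) -> None:
        path = run_dir / filename
        lines.append(f"## {title}")
        if not path.exists():
            lines.append(f"(missing: {filename})")
        else:
            lines.extend(render(path))
        lines.append("")

    section("PCA summary", "pca_summary.csv",
            lambda p: [pd.read_csv(p).to_string(index=False)])
    section("Component retention", "parallel_analysis.json",
            lambda p: [p.read_text().strip()])
    section("Conformational clusters", "silhouette_by_k.csv",
            lambda p: [pd.read_csv(p).to_string(index=False)])
    section("Descriptor statistics", "descriptor_stats.csv",
            lambda p: [pd.read_csv(p).to_string(index=False)])
    section("Free-energy statistics", "landscape_stats.csv",
            lambda p: [pd.read_csv(p).to_string(index=False)])
    section("Tunnel two-proportion Z-test", "ztest.json",
            lambda p: [p.read_text().strip()])
    text = "\n".join(lines)
    (run_dir / "report.md").write_text(text)
    return text
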