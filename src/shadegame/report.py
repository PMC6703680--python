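"""Figure generation from saved experiment outputs.

Regenerates the standard diagnostic panels: monomorphic trajectory panels
(mean plant R:FR, total biomass, % petiole biomass against time, one line per
density), monomorphic summaries against the plasticity strategy, discrete and
smoothed pairwise invasibility plot grids, and the cue-reliability boxplots
(absorbed lamina PAR where the petiole perceived a near-control R:FR).
"""

from __future__ import annotations

import os
import warnings

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .game import invasion_exponent, pip_export, smooth_performance
from .simulate import PerformanceMatrix

__all__ = ["trajectory_panels", "monomorphic_summary", "pip_grid",
           "cue_reliability_boxplot", "report"]


def _density_palette(densities):
    cmap = plt.get_cmap("viridis")
    order = sorted(densities)
    return {d: cmap(i / max(len(order) - 1, 1)) for i, d in enumerate(order)}


def trajectory_panels(trajectories: pd.DataFrame, outpath: str) -> str:
    """Three-panel figure (R:FR, biomass, % petiole vs day) by density.

    ``trajectories`` is long-format with columns day, density, mean_rfr,
    total_biomass_mg, pct_petiole (and optionally replicate, averaged out).
    """
    cols = ["mean_rfr", "total_biomass_mg", "pct_petiole"]
    labels = ["mean plant R:FR", "total biomass (mg)", "% biomass in petioles"]
    pal = _density_palette(trajectories["density"].unique())
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6))
    for ax, col, lab in zip(axes, cols, labels):
        for dens, grp in trajectories.groupby("density"):
            daily = grp.groupby("day")[col].agg(["mean", "std"])
            ax.plot(daily.index, daily["mean"], color=pal[dens],
                    label=f"{dens:g} m$^{{-2}}$")
            if daily["std"].notna().any():
                ax.fill_between(daily.index, daily["mean"] - daily["std"],
                                daily["mean"] + daily["std"],
                                color=pal[dens], alpha=0.2, lw=0)
        ax.set_xlabel("day")
        ax.set_ylabel(lab)
    axes[0].legend(fontsize=7, title="density")
    fig.tight_layout()
    fig.savefig(outpath, dpi=120)
    plt.close(fig)
    return outpath


def monomorphic_summary(summary: pd.DataFrame, outpath: str) -> str:
    """Final biomass and allocation against the plasticity strategy.

    ``summary`` columns: density, alpha, biomass_mg, pct_petiole, pct_lamina
    (replicate rows allowed; mean +- SD drawn).
    """
    pal = _density_palette(summary["density"].unique())
    cols = ["biomass_mg", "pct_petiole", "pct_lamina"]
    labels = ["total biomass (mg)", "% in petioles", "% in laminas"]
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6))
    for ax, col, lab in zip(axes, cols, labels):
        for dens, grp in summary.groupby("density"):
            agg = grp.groupby("alpha")[col].agg(["mean", "std"])
            ax.errorbar(agg.index, agg["mean"], yerr=agg["std"],
                        color=pal[dens], marker="o", ms=3, capsize=2,
                        label=f"{dens:g} m$^{{-2}}$")
        ax.set_xlabel("plasticity strategy $\\alpha$")
        ax.set_ylabel(lab)
    axes[0].legend(fontsize=7, title="density")
    fig.tight_layout()
    fig.savefig(outpath, dpi=120)
    plt.close(fig)
    return outpath


def pip_grid(matrices: dict[tuple[float, float], PerformanceMatrix],
             outdir: str, smooth: bool = True) -> list[str]:
    """Discrete + smoothed PIP export per (density, scenario)."""
    paths = []
    for (density, scenario_n), matrix in sorted(matrices.items()):
        inv = invasion_exponent(matrix)
        smoothed = None
        if smooth:
            try:
                smoothed = smooth_performance(matrix)
            except (ValueError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"smoothing failed for density={density:g}, "
                              f"n={scenario_n:g}: {exc}")
        prefix = f"pip_d{density:g}_n{scenario_n:g}"
        out = pip_export(inv, smoothed, outdir, prefix=prefix)
        paths.extend(out.values())
    return paths


def cue_reliability_boxplot(samples: pd.DataFrame, outpath: str) -> str:
    """Boxplots of absorbed lamina PAR per density for leaves whose petiole
    perceived near-control R:FR; ``samples`` columns: density, absorbed_par."""
    densities = sorted(samples["density"].unique())
    data = [samples.loc[samples["density"] == d, "absorbed_par"].dropna()
            for d in densities]
    fig, ax = plt.subplots(figsize=(5, 3.6))
    ax.boxplot(data, tick_labels=[f"{d:g}" for d in densities],
               showmeans=True)
    ax.set_xlabel("planting density (plants m$^{-2}$)")
    ax.set_ylabel("lamina PAR (umol m$^{-2}$ s$^{-1}$)")
    fig.tight_layout()
    fig.savefig(outpath, dpi=120)
    plt.close(fig)
    return outpath


def report(results_dir: str, outdir: str | None = None) -> list[str]:
    """Regenerate every figure the saved CSVs support; list what was made.

    Looks for ``trajectories.csv``, ``monomorphic.csv``, ``performance.csv``
    (the long-format matrix file) and ``cue_samples.csv`` under
    ``results_dir``.  Missing inputs are listed in a warning, not fatal.
    """
    outdir = outdir or results_dir
    os.makedirs(outdir, exist_ok=True)
    made, missing = [], []

    path = os.path.join(results_dir, "trajectories.csv")
    if os.path.exists(path):
        made.append(trajectory_panels(pd.read_csv(path),
                                      os.path.join(outdir, "trajectories.png")))
    else:
        missing.append(path)

    path = os.path.join(results_dir, "monomorphic.csv")
    if os.path.exists(path):
        made.append(monomorphic_summary(pd.read_csv(path),
                                        os.path.join(outdir, "monomorphic.png")))
    else:
        missing.append(path)

    path = os.path.join(results_dir, "performance.csv")
    if os.path.exists(path):
        long = pd.read_csv(path)
        matrices = {}
        for (d, n), grp in long.groupby(["density", "scenario_n"]):
            matrices[(d, n)] = PerformanceMatrix.from_long_frame(grp)
        made.extend(pip_grid(matrices, outdir))
    else:
        missing.append(path)

    path = os.path.join(results_dir, "cue_samples.csv")
    if os.path.exists(path):
        made.append(cue_reliability_boxplot(
            pd.read_csv(path), os.path.join(outdir, "cue_reliability.png")))
    else:
        missing.append(path)

    if missing:
        warnings.warn("report inputs not found: " + ", ".join(missing))
    return made
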