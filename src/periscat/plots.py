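"""Standard figures: distance profiles with CI bands, gradient bars,
strain maps and force-displacement curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_distance_profile(profile: pd.DataFrame, ylabel: str, path) -> None:
    """Mean-vs-distance line with a shaded 95% confidence band."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    d = profile["distance_mm"]
    m = profile["mean"]
    h = profile["ci95_half_width"].fillna(0.0)
    ax.plot(d, m, color="crimson")
    ax.fill_between(d, m - h, m + h, color="crimson", alpha=0.25, lw=0)
    ax.set_xlabel("distance from implant interface (mm)")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_gradient_bars(summary: pd.DataFrame, path) -> None:
    """Bar chart of fitted gradients with 95% CI error bars."""
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.bar(summary["parameter"], summary["slope_per_mm"],
           yerr=summary["slope_ci95_half_width"], capsize=4, color="steelblue")
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_ylabel("gradient (units / mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_strain_map(strain_df: pd.DataFrame, path, force_mn=None) -> None:
    """Image of the relative-strain deviation 1 - epsilon on the scan grid."""
    df = strain_df if force_mn is None else strain_df[
        strain_df["force_mn"] == force_mn]
    grid = df.pivot_table(index="y_um", columns="x_um", values="epsilon",
                          sort=True)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(1.0 - grid.to_numpy(), origin="lower",
                   extent=[grid.columns.min(), grid.columns.max(),
                           grid.index.min(), grid.index.max()])
    fig.colorbar(im, ax=ax, label="1 - epsilon (relative strain deviation)")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    if force_mn is not None:
        ax.set_title(f"{force_mn:g} mN")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_strain_profile(profile: pd.DataFrame, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(profile["tip_distance_um"], profile["mean_deviation"],
                yerr=profile["ci95_half_width"], fmt="o-", ms=3, capsize=3)
    ax.set_xlabel("distance from indenter tip (um)")
    ax.set_ylabel("1 - epsilon")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_force_displacement(fd: pd.DataFrame, path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(fd["displacement_um"], fd["force_mn"], "-o", ms=3)
    ax.set_xlabel("displacement (um)")
    ax.set_ylabel("force (mN)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_radial_profile(q: np.ndarray, intensity: np.ndarray, path,
                        xlabel: str = "q (nm$^{-1}$)") -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(q, intensity, lw=0.8)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("I (counts)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
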