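#!/usr/bin/env python
"""Diagnostic figures: Env vs Env+Bio skill per species and per plot.

Scatter of Spearman rho per species and of Bray-Curtis similarity per
validation plot, Env on the x axis and Env+Bio on the y axis; points above
the identity line mark cases the community information improved.
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

OUT = Path("results/analysis")


def scatter(ax, x, y, label):
    ax.scatter(x, y, s=18, alpha=0.7, edgecolor="k", linewidth=0.3)
    lo = min(x.min(), y.min()) - 0.02
    hi = max(x.max(), y.max()) + 0.02
    ax.plot([lo, hi], [lo, hi], "k--", linewidth=0.8)
    ax.set_xlabel(f"{label} (Env)")
    ax.set_ylabel(f"{label} (Env+Bio)")
    ax.set_title(f"{label}: {int((y > x).sum())}/{len(x)} above the line")


def main() -> None:
    per_sp = pd.read_csv(OUT / "per_species_metrics.csv")
    per_plot = pd.read_csv(OUT / "per_plot_bc.csv")
    fig, axes = plt.subplots(1, 2, figsize=(9, 4.2))
    sp = per_sp.dropna(subset=["rho_env", "rho_env_bio"])
    scatter(axes[0], sp.rho_env, sp.rho_env_bio, "Spearman rho")
    pl = per_plot.dropna(subset=["bc_env", "bc_env_bio"])
    scatter(axes[1], pl.bc_env, pl.bc_env_bio, "Bray-Curtis similarity")
    fig.tight_layout()
    fig.savefig(OUT / "env_vs_envbio.png", dpi=150)
    print(f"wrote {OUT / 'env_vs_envbio.png'}")


if __name__ == "__main__":
    main()
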