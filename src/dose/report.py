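"""Diagnostic plots for a completed study (matplotlib, file output only)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from dose.doe import ParameterSpace
from dose.dstats import PARAMETERS, bin_values, compute_response, interaction_plot_data

__all__ = ["write_report"]


def _scatter_panels(results: pd.DataFrame, path: Path) -> None:
    pairs = [("ridge", "lasso"), ("ridge", "enet"), ("lasso", "enet")]
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, (a, b) in zip(axes, pairs):
        x = results[f"mse_{a}"]
        y = results[f"mse_{b}"]
        ax.scatter(x, y, s=6, alpha=0.5)
        lim = max(x.max(), y.max()) * 1.05
        ax.plot([0, lim], [0, lim], "r-", lw=0.8)
        ax.set_xlabel(f"MSE {a}")
        ax.set_ylabel(f"MSE {b}")
        frac = float(np.mean(x < y))
        ax.set_title(f"{a} wins {100 * frac:.1f}%")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _interaction_plot(y, fx, fz, ax, xname, zname) -> None:
    cells = interaction_plot_data(y, fx, fz)
    for z in range(1, fz.G + 1):
        sub = cells[cells["z"] == z]
        ax.plot(sub["x"], sub["mean"], marker="o", ms=3, label=f"{zname} bin {z}")
    ax.set_xlabel(f"{xname} bin")
    ax.legend(fontsize=6)


def write_report(results, scenarios, out_dir: Path, bins: int = 10, curves: int = 3):
    """Write MSE scatter panels plus per-contrast interaction plots."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    scatter = out_dir / "mse_scatter.png"
    _scatter_panels(results, scatter)
    written.append(scatter)

    merged = results.merge(scenarios[["scenario_id", *PARAMETERS]], on="scenario_id",
                           suffixes=("", "_design"))
    space = ParameterSpace()
    for contrast in ("ridge_vs_lasso", "ridge_vs_enet", "lasso_vs_enet"):
        y = compute_response(merged, contrast).values
        fig, axes = plt.subplots(2, 5, figsize=(18, 7))
        for col, xname in enumerate(PARAMETERS):
            fx = bin_values(merged[xname].to_numpy(float), *space.bounds[xname], bins,
                            parameter=xname)
            zname = PARAMETERS[(col + 1) % len(PARAMETERS)]
            fz = bin_values(merged[zname].to_numpy(float), *space.bounds[zname], curves,
                            parameter=zname)
            # top row: binned response boxplot; bottom: interaction curves
            groups = [y[fx.labels == g] for g in range(1, bins + 1) if (fx.labels == g).any()]
            axes[0, col].boxplot(groups, showfliers=False)
            axes[0, col].set_xlabel(f"{xname} bin")
            _interaction_plot(y, fx, fz, axes[1, col], xname, zname)
        axes[0, 0].set_ylabel(contrast)
        fig.tight_layout()
        p = out_dir / f"{contrast}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)
    return written
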