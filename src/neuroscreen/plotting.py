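"""Plots: plate Z-score heatmaps and Gardner-Altman estimation plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .estim_stats import EstimationResult

__all__ = ["plot_zscore_map", "gardner_altman"]


def plot_zscore_map(zmap: pd.DataFrame, path, rows: int = 8, cols: int = 12):
    """Plate heatmap of within-condition Z-scores.

    ``zmap`` comes from :func:`neuroscreen.plate_stats.zscore_map` (columns
    plate_row, plate_col, z).  Unused wells render as NaN (grey).
    """
    grid = np.full((rows, cols), np.nan)
    for _, r in zmap.iterrows():
        grid[int(r["plate_row"]), int(r["plate_col"])] = r["z"]
    fig, ax = plt.subplots(figsize=(cols * 0.6, rows * 0.6))
    vmax = np.nanmax(np.abs(grid)) or 1.0
    im = ax.imshow(grid, cmap="coolwarm", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(cols), [str(c + 1) for c in range(cols)])
    ax.set_yticks(range(rows), [chr(ord("A") + r) for r in range(rows)])
    ax.set_title("within-condition Z-scores")
    fig.colorbar(im, ax=ax, label="Z")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def gardner_altman(
    test,
    control,
    result: EstimationResult,
    path,
    labels: tuple[str, str] = ("test", "control"),
    bootstrap_sample=None,
):
    """Two-axis estimation plot: raw observations above, the mean-difference
    bootstrap distribution with its BCa CI below."""
    test = np.asarray(test, dtype=float)
    control = np.asarray(control, dtype=float)
    fig, (ax0, ax1) = plt.subplots(
        2, 1, figsize=(4, 6), sharex=False,
        gridspec_kw={"height_ratios": [2, 1]},
    )
    rng = np.random.default_rng(0)  # display jitter only
    for i, (vals, lab) in enumerate(((control, labels[1]), (test, labels[0]))):
        x = np.full(vals.size, i) + rng.uniform(-0.08, 0.08, vals.size)
        ax0.plot(x, vals, "o", alpha=0.7, label=lab)
    ax0.set_xticks([0, 1], [labels[1], labels[0]])
    ax0.set_ylabel("value")
    ax0.legend(frameon=False, fontsize=8)

    if bootstrap_sample is None:
        # re-draw a display-only bootstrap of the mean difference
        it = rng.integers(0, test.size, size=(2000, test.size))
        ic = rng.integers(0, control.size, size=(2000, control.size))
        bootstrap_sample = test[it].mean(axis=1) - control[ic].mean(axis=1)
    ax1.hist(bootstrap_sample, bins=40, color="0.7")
    ax1.axvline(result.delta, color="k")
    ax1.axvline(result.ci_low, color="k", linestyle=":")
    ax1.axvline(result.ci_high, color="k", linestyle=":")
    ax1.set_xlabel(
        f"mean difference = {result.delta:.3g} "
        f"[{result.ci_low:.3g}, {result.ci_high:.3g}], p = {result.p_formatted}"
    )
    ax1.set_ylabel("bootstrap")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
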