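"""Fold-change comparison plots: paired-contrast scatter with marginal histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import pandas as pd

_AXIS_LABELS = {
    "within": ("male ln-fold change (control - perturbed)",
               "female ln-fold change (control - perturbed)"),
    "between": ("perturbed ln-fold change (F - M)",
                "control ln-fold change (F - M)"),
}

_NULL_LABELS = {"null", "unbiased"}


def fold_change_scatter(table: pd.DataFrame, which: str = "within"):
    """Scatter of paired per-region ln-fold changes, coloured by category.

    ``table`` comes from ``ExonDEResults.fold_change_table``: columns
    ``ln_fc_x``, ``ln_fc_y`` and ``label``.  Non-null categories are drawn
    on top of the grey null cloud; marginal histograms show each axis's
    distribution for non-null regions.  Returns the matplotlib Figure.
    """
    xlab, ylab = _AXIS_LABELS.get(which, ("ln-fold change (x)", "ln-fold change (y)"))
    fig, axes = plt.subplots(
        2,
        2,
        figsize=(7, 7),
        gridspec_kw={
            "width_ratios": [4, 1],
            "height_ratios": [4, 1],
            "hspace": 0.08,
            "wspace": 0.08,
        },
    )
    ax, ax_hy = axes[0]
    ax_hx, ax_off = axes[1]
    ax_off.axis("off")

    null_mask = table["label"].isin(_NULL_LABELS)
    ax.scatter(
        table.loc[null_mask, "ln_fc_x"],
        table.loc[null_mask, "ln_fc_y"],
        s=6,
        c="0.8",
        label="NS",
        rasterized=True,
    )
    sig = table[~null_mask]
    for label, sub in sig.groupby("label"):
        ax.scatter(sub["ln_fc_x"], sub["ln_fc_y"], s=8, label=str(label))
    lim = max(1.0, table[["ln_fc_x", "ln_fc_y"]].abs().to_numpy().max()) * 1.05
    ax.plot([-lim, lim], [-lim, lim], color="k", lw=0.8)  # line of equal change
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_ylabel(ylab)
    ax.legend(fontsize=7, markerscale=1.5, loc="upper left")
    ax.tick_params(labelbottom=False)

    ax_hx.hist(sig["ln_fc_x"], bins=40, color="steelblue")
    ax_hx.set_xlim(-lim, lim)
    ax_hx.set_xlabel(xlab)
    ax_hy.hist(sig["ln_fc_y"], bins=40, orientation="horizontal", color="purple")
    ax_hy.set_ylim(-lim, lim)
    ax_hy.tick_params(labelleft=False)
    return fig
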