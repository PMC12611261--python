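"""Matplotlib figures for volcano analyses and melting profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from mmtpp.diffstab import DiffParams, MeltingCurve

CALL_COLORS = {"stabilized": "#d95f02", "destabilized": "#7570b3", "unchanged": "0.7"}


def volcano_plot(results: pd.DataFrame, params: DiffParams = DiffParams(), ax=None):
    """Volcano plot of one temperature's differential results."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for call, sub in results.groupby("call"):
        ax.scatter(
            sub["log2_fc"], sub["neg_log10_p"], s=8,
            c=CALL_COLORS.get(call, "k"), label=f"{call} (n={len(sub)})",
        )
    for x in (-params.fc_cut, params.fc_cut):
        ax.axvline(x, ls="--", lw=0.8, c="0.4")
    ax.axhline(params.logp_cut, ls="--", lw=0.8, c="0.4")
    ax.set_xlabel("log2 fold difference (treatment - control)")
    ax.set_ylabel("-log10 p")
    ax.legend(fontsize=7, frameon=False)
    return ax


def melting_plot(curves: list[MeltingCurve], ax=None):
    """Mean +/- sd melting profiles with their smoothed interpolants."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    colors = {"treatment": "#d95f02", "control": "0.4"}
    for curve in curves:
        c = colors.get(curve.arm, "k")
        ax.errorbar(
            curve.temperatures, curve.mean_log2, yerr=curve.sd_log2,
            fmt="o", ms=4, color=c, label=f"{curve.protein_id} {curve.arm}",
        )
        ax.plot(curve.grid, curve.smoothed, color=c, lw=1)
    ax.set_xlabel("temperature (degC)")
    ax.set_ylabel("log2 intensity")
    ax.legend(fontsize=7, frameon=False)
    return ax
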