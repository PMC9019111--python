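"""Plot helpers for the selection scans (EHH decay and windowed
haplotype homozygosity)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_ehh_decay", "plot_window_homozygosity"]


def plot_ehh_decay(curves: pd.DataFrame, core_position: int, path=None, ax=None):
    """EHH decay per core label on both flanks.

    ``curves`` is the tidy frame written by the pipeline (columns
    label, direction, position, ehh).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    for label, sub in curves.groupby("label"):
        style = dict(color="0.6", lw=0.8) if str(label).startswith("wt") else dict(lw=1.4)
        for _, run in sub.groupby("direction"):
            run = run.sort_values("position")
            ax.plot(run["position"] - core_position, run["ehh"],
                    label=label if run["direction"].iloc[0] == "downstream" else None,
                    **style)
    ax.axvline(0, color="k", lw=0.5, ls=":")
    ax.set_xlabel("distance from core (bp)")
    ax.set_ylabel("EHH")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=7, ncol=2)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_window_homozygosity(frame: pd.DataFrame, gene: tuple[int, int] | None = None,
                             path=None, ax=None):
    """Moving-window haplotype homozygosity per group label."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    for label, sub in frame.groupby("label"):
        style = dict(color="0.6", lw=0.8) if str(label).startswith("wt") else dict(lw=1.4)
        mid = (sub["start"] + sub["end"]) / 2
        ax.plot(mid, sub["homozygosity"], label=label, **style)
    if gene is not None:
        ax.axvspan(gene[0], gene[1], color="0.9", zorder=0)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("haplotype homozygosity")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=7, ncol=2)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
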