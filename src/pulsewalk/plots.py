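"""Flat 2-D channel-layout maps of channel-wise contrast results.

A schematic head-plane scatter (channel midpoints in cm, nose up): marker
color encodes the paired t statistic, a ring marks channels surviving FDR
correction.  This is a channel-space stand-in for cortical-surface
projection, which is out of scope.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .types import Montage

__all__ = ["plot_channel_map"]


def plot_channel_map(
    contrast: pd.DataFrame,
    montage: Montage,
    path: str | Path,
    title: str = "Channel-wise paired t (FDR-ringed)",
) -> Path:
    """Render a contrast table (channel_id, t, q_fdr, significant) to file."""
    path = Path(path)
    xs, ys, ts, sig, labels = [], [], [], [], []
    missing = []
    montage_850 = montage.table[montage.table["wavelength"] == 850].set_index("channel_id")
    for _, row in contrast.iterrows():
        cid = row["channel_id"]
        if cid not in montage_850.index:
            missing.append(cid)
            continue
        m = montage_850.loc[cid]
        xs.append(m["x"])
        ys.append(m["y"])
        ts.append(row["t"])
        sig.append(bool(row.get("significant", False)))
        labels.append(m["label"])
    if missing:
        warnings.warn(f"channels without montage coordinates omitted: {missing}")

    fig, ax = plt.subplots(figsize=(6, 6))
    if ts:
        vmax = max(abs(min(ts)), abs(max(ts)), 1e-9)
        sc = ax.scatter(xs, ys, c=ts, cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                        s=250, edgecolors="k", linewidths=0.5, zorder=3)
        fig.colorbar(sc, ax=ax, label="paired t")
        for x, y, s in zip(xs, ys, sig):
            if s:
                ax.scatter([x], [y], s=550, facecolors="none",
                           edgecolors="limegreen", linewidths=2.5, zorder=4)
        for x, y, lab in zip(xs, ys, labels):
            ax.annotate(lab, (x, y), textcoords="offset points",
                        xytext=(0, 12), ha="center", fontsize=8)
    # schematic head outline, nose up
    theta = np.linspace(0, 2 * np.pi, 200)
    ax.plot(10.5 * np.cos(theta), 10.5 * np.sin(theta), color="gray", lw=1)
    ax.plot([-1.2, 0, 1.2], [10.4, 11.8, 10.4], color="gray", lw=1)
    ax.set_aspect("equal")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
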