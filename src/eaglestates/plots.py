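"""Diagnostic plots: state boxplots and WSS/elbow curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def state_boxplots(points: pd.DataFrame, path) -> None:
    """AGL, speed, and turning-angle boxplots by behavioral state.

    AGL and speed are drawn on a log scale to make the low- and
    high-altitude bands comparable.
    """
    states = sorted(points["state"].dropna().unique())
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.5))
    panels = [("agl_m", "AGL (m)", True), ("speed_kmh", "Speed (km/h)", True),
              ("turn_abs_deg", "Turn angle (deg)", False)]
    for ax, (col, label, logscale) in zip(axes, panels):
        data = [points.loc[points["state"] == s, col].dropna() for s in states]
        if logscale:
            data = [np.log10(np.clip(d, 1e-2, None)) for d in data]
            label = f"log10 {label}"
        ax.boxplot(data, tick_labels=[str(s) for s in states], showfliers=False)
        ax.set_xlabel("state")
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def elbow_plot(wss: np.ndarray, k_selected: int, path) -> None:
    ks = np.arange(1, len(wss) + 1)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(ks, wss, "o-")
    ax.axvline(k_selected, color="grey", ls="--", lw=1)
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("within-cluster sum of squares")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
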