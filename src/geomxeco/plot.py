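"""Plot helpers for the main results (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .survival import KMResult  # noqa: E402


def plot_km(km: KMResult, ax=None, title: str = "Overall survival"):
    """Step plot of the high/low Kaplan-Meier curves."""
    ax = ax or plt.gca()
    for grp, curve in km.curves.items():
        ax.step(curve.index, curve.iloc[:, 0], where="post", label=grp)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(f"{title} (log-rank p = {km.p:.3g})")
    ax.legend()
    return ax


def plot_elbow(wss_per_k: dict[int, float], k_star: int | None = None, ax=None):
    """WSS-vs-k curve with the chosen elbow marked."""
    ax = ax or plt.gca()
    ks = sorted(wss_per_k)
    ax.plot(ks, [wss_per_k[k] for k in ks], marker="o")
    if k_star is not None:
        ax.axvline(k_star, ls="--", color="grey")
    ax.set_xlabel("k")
    ax.set_ylabel("total within-cluster sum of squares")
    return ax


def plot_correlation_heatmap(corr: pd.DataFrame, order: list[str] | None = None,
                             ax=None):
    """Hierarchically ordered Pearson-correlation heatmap of signature scores."""
    ax = ax or plt.gca()
    if order is not None:
        corr = corr.loc[order, order]
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(np.arange(len(corr)), corr.columns, rotation=90, fontsize=7)
    ax.set_yticks(np.arange(len(corr)), corr.index, fontsize=7)
    plt.colorbar(im, ax=ax, label="Pearson r")
    return ax
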