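"""Plot helpers: regional bar profiles, size/composition histograms, shape scatter."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .sizedist import BinSummary, ScatterPoint
from .stereology import BlockSummary, regional_profile

_HORMONE_COLORS = {"beta": "tab:green", "alpha": "tab:red", "delta": "tab:blue"}


def plot_regional_profile(blocks: Sequence[BlockSummary], metric: str = "pct_beta"):
    """Head→tail per-block bars with a trailing average ± SEM bar."""
    prof = regional_profile(blocks, metric=metric)
    n = len(prof.pct_series)
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * n + 2), 3))
    color = _HORMONE_COLORS.get(metric.removeprefix("pct_"), "gray")
    ax.bar(np.arange(1, n + 1), prof.pct_series, color=color)
    ax.bar([n + 2], [prof.mean_pct], yerr=[prof.sem_pct], color="0.4", capsize=3)
    ax.set_xlabel("block (head → tail)")
    ax.set_ylabel(metric.replace("_", " ") + " (% tissue area)")
    ax.annotate(
        f"{prof.mean_pct:.2f} ± {prof.sem_pct:.2f}%",
        xy=(0.98, 0.95), xycoords="axes fraction", ha="right", va="top", fontsize=8,
    )
    fig.tight_layout()
    return fig


def plot_size_composition(bins: Sequence[BinSummary]):
    """Relative frequency bars with per-bin hormone composition lines."""
    ks = [b.bin.k for b in bins]
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(ks, [b.relative_frequency for b in bins], color="0.8", label="frequency")
    ax2 = ax.twinx()
    for name in ("beta", "alpha", "delta"):
        ax2.errorbar(
            ks,
            [getattr(b, f"{name}_frac_mean") for b in bins],
            yerr=[getattr(b, f"{name}_frac_sem") for b in bins],
            color=_HORMONE_COLORS[name],
            label=name,
            capsize=2,
        )
    ax.set_xlabel("size bin k (cell count $[2^{k-1}, 2^k)$)")
    ax.set_ylabel("relative frequency")
    ax2.set_ylabel("hormone area fraction")
    ax2.set_ylim(0, 1)
    ax2.legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_area_share(bins: Sequence[BinSummary]):
    """Size-frequency bars with the per-bin share of total islet area."""
    ks = [b.bin.k for b in bins]
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(ks, [b.relative_frequency for b in bins], color="0.8")
    ax2 = ax.twinx()
    ax2.plot(ks, [b.area_share for b in bins], color="tab:red", marker="o")
    ax.set_xlabel("size bin k")
    ax.set_ylabel("relative frequency")
    ax2.set_ylabel("share of total islet area", color="tab:red")
    fig.tight_layout()
    return fig


def plot_shape_scatter(points: Sequence[ScatterPoint]):
    """3D islet size/shape scatter, color-coded sparse→dense."""
    fig = plt.figure(figsize=(5, 4))
    ax = fig.add_subplot(projection="3d")
    dens = np.array([p.local_density for p in points])
    sc = ax.scatter(
        [p.log_area for p in points],
        [p.circularity for p in points],
        [p.feret_um for p in points],
        c=np.log10(np.maximum(dens, 1e-12)),
        cmap="viridis",
        s=4,
    )
    ax.set_xlabel("log10 cell count")
    ax.set_ylabel("circularity")
    ax.set_zlabel("Feret (µm)")
    fig.colorbar(sc, label="log10 local density", shrink=0.6)
    return fig
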