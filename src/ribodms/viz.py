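"""Figure helpers: pairwise RA heatmap and per-region epsilon violins."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .epistasis import HeatmapMatrix


def plot_heatmap(hm: HeatmapMatrix, path: str | Path, title: str = "") -> None:
    """Render the 3L x 3L pairwise mean-RA matrix; NaN cells stay blank."""
    fig, ax = plt.subplots(figsize=(8, 7))
    masked = np.ma.masked_invalid(hm.values)
    im = ax.imshow(masked, cmap="viridis", vmin=0, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="mean relative activity")
    ax.set_title(title or f"{hm.ref.name}: pairwise relative activity")
    ax.set_xlabel("mutation (position-major, A<C<G<U)")
    ax.set_ylabel("mutation")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_category_violins(
    cats: pd.DataFrame, path: str | Path, title: str = ""
) -> None:
    """Violin plots of epsilon by mismatch category for one region."""
    import seaborn as sns

    order = ["2_mismatch", "1_mismatch", "WC_GU"]
    present = [c for c in order if (cats["category"] == c).any()]
    fig, ax = plt.subplots(figsize=(5, 4))
    if present:
        sns.violinplot(
            data=cats, x="category", y="epsilon", order=present, cut=0, ax=ax
        )
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_title(title)
    ax.set_ylabel("epistasis")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
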