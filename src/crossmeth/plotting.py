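"""Optional plots (requires matplotlib; install the ``plot`` extra)."""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .profile import CpGoeBin


def plot_cpgoe_bins(bins: Sequence[CpGoeBin], path, species: str = "") -> None:
    """Bar plot of mean methylation per CpGo/e bin (island = low methylation)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar([b.label for b in bins], [b.mean_methylation for b in bins], color="0.4")
    ax.set_xlabel("CpGo/e bin (lower bound)")
    ax.set_ylabel("mean methylation")
    if species:
        ax.set_title(species)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_window_profile(profile: pd.DataFrame, path) -> None:
    """Per-window methylation-expression correlation along the promoter."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(profile["window"], profile["rho"], "o-", color="0.2")
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.set_xlabel("promoter window (5' to 3')")
    ax.set_ylabel("Spearman rho (methylation vs expression)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
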