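"""Cosmetic plots: importance bars and the treatment-duration histogram."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_importances", "plot_duration_distribution"]


def plot_importances(importances: pd.DataFrame, path=None, retained_only: bool = True):
    """Horizontal bar chart of signed coefficients, colour-coded by sign.

    Bars extending right (teal) are positively associated with the positive
    class (second treatment period, or fracture); bars extending left (red)
    are negatively associated.
    """
    df = importances[importances["retained"]] if retained_only else importances
    df = df.iloc[::-1]
    colors = ["teal" if c > 0 else "firebrick" for c in df["coefficient"]]
    fig, ax = plt.subplots(figsize=(7, max(2, 0.35 * len(df) + 1)))
    ax.barh(df["feature"], df["coefficient"], color=colors)
    ax.axvline(0, color="black", lw=0.8)
    ax.set_xlabel("linear coefficient (standardized features)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_duration_distribution(cohort: pd.DataFrame, path=None):
    """Histogram of bisphosphonate treatment durations (years)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(cohort["duration_years"], bins=range(1, 16), edgecolor="white")
    ax.set_xlabel("treatment duration (years)")
    ax.set_ylabel("patients")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
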