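"""Bar plots of the behavioral effects and predicted response histograms."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .effects import EFFECT_COLUMNS
from .observers import PredictedResponseDistribution

__all__ = ["plot_effects", "plot_predicted_distribution"]


def plot_effects(summaries: pd.DataFrame, effects=EFFECT_COLUMNS):
    """Group-mean ± SEM bars per effect, individual participants overlaid."""
    groups = list(summaries["group"].unique())
    fig, axes = plt.subplots(2, 3, figsize=(10, 6), sharey="row")
    for ax, eff in zip(axes.ravel(), effects):
        means = summaries.groupby("group")[eff].mean().reindex(groups)
        sems = summaries.groupby("group")[eff].sem().reindex(groups)
        x = np.arange(len(groups))
        ax.bar(x, means, yerr=sems, capsize=3, color="lightsteelblue", edgecolor="k")
        for i, g in enumerate(groups):
            vals = summaries.loc[summaries["group"] == g, eff]
            ax.plot(np.full(len(vals), i) + np.random.default_rng(0).uniform(-0.15, 0.15, len(vals)),
                    vals, "o", ms=3, color="dimgray", alpha=0.6)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xticks(x, groups)
        ax.set_title(eff.replace("_", " "))
        ax.set_ylabel("degrees")
    fig.tight_layout()
    return fig


def plot_predicted_distribution(pred: PredictedResponseDistribution):
    """Side-by-side A and V predicted 12-bin response histograms for one pair."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 3), sharey=True)
    buttons = np.arange(1, len(pred.p_A) + 1)
    for ax, p, label in zip(axes, (pred.p_A, pred.p_V), ("A response", "V response")):
        ax.bar(buttons, p, color="lightsteelblue", edgecolor="k")
        ax.set_xlabel("button")
        ax.set_title(f"{label}  (s_A={pred.pair.s_A:+g}°, s_V={pred.pair.s_V:+g}°)")
    axes[0].set_ylabel("proportion")
    fig.tight_layout()
    return fig
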