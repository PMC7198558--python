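"""Minimal matplotlib views of signature exposures and rank surveys."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_exposures(exposures: pd.DataFrame, path=None, ax=None):
    """Stacked-bar exposures (rows = groups/samples, columns = signatures)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 0.5 * len(exposures)), 4))
    bottom = np.zeros(len(exposures))
    for col in exposures.columns:
        ax.bar(exposures.index, exposures[col], bottom=bottom, label=col)
        bottom += exposures[col].to_numpy()
    ax.set_ylabel("exposure")
    ax.legend(fontsize=7, ncol=2)
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    if path:
        plt.tight_layout()
        plt.savefig(path, dpi=150)
        plt.close()
    return ax


def plot_rank_survey(survey, path=None):
    """Observed vs permuted-null model-selection measures by rank."""
    measures = ["cophenetic", "dispersion", "delta_rss", "silhouette"]
    fig, axes = plt.subplots(1, len(measures), figsize=(4 * len(measures), 3))
    for ax, m in zip(axes, measures):
        ax.plot(survey.ranks, survey.observed[m], "o-", label="observed")
        if m in survey.null_measures[survey.ranks[0]].columns:
            null95 = [survey.null_measures[r][m].quantile(0.95) for r in survey.ranks]
            ax.plot(survey.ranks, null95, "s--", label="null 95%")
        ax.set_xlabel("rank")
        ax.set_title(m)
    axes[0].legend()
    if survey.chosen_rank:
        for ax in axes:
            ax.axvline(survey.chosen_rank, color="red", lw=0.8, alpha=0.6)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
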