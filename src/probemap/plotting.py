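"""Diagnostic plots for QC results (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from scipy.cluster.hierarchy import dendrogram

from .array_qc import ClusterResult, DensityResult


def plot_beta_density(result: DensityResult, ax=None, label: str | None = None):
    """Beta-value density curve with its modes marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(result.grid, result.density, label=label)
    for mode in result.modes[:2]:
        ax.axvline(mode, color="grey", linestyle="--", linewidth=0.8)
    ax.set_xlabel("beta value")
    ax.set_ylabel("density")
    ax.set_xlim(0, 1)
    if label:
        ax.legend(frameon=False)
    return ax


def plot_dendrogram(result: ClusterResult, ax=None):
    """Sample dendrogram from the hierarchical clustering merge table."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    dendrogram(result.merge_table, labels=result.sample_ids, ax=ax)
    ax.set_ylabel("merge height")
    for tick in ax.get_xticklabels():
        tick.set_rotation(90)
    return ax
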