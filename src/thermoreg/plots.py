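"""Basic diagnostic plots (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .traits import PCAResult
from .types import PairedSeries


def plot_series(series: PairedSeries, ax=None):
    """Leaf and air channels over clock time for one plant × treatment."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    hours = series.minutes / 60.0
    ax.plot(hours, series.t_air, label="T_air", lw=1)
    ax.plot(hours, series.t_leaf, label="T_leaf", lw=1)
    ax.set_xlabel("clock time (h)")
    ax.set_ylabel("temperature (°C)")
    ax.set_title(f"{series.plant_id} ({series.treatment.value})")
    ax.legend(frameon=False)
    return ax


def plot_pca(result: PCAResult, ax=None):
    """PC1/PC2 score scatter with axis variance percentages."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(result.scores["PC1"], result.scores["PC2"], s=12)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel(f"PC1 ({result.variance_explained[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({result.variance_explained[1]:.1f}%)")
    return ax
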