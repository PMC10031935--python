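"""Plotting helpers: importance bar charts with the RFE cut-off line."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_importance", "plot_rfe_curve"]


def plot_importance(importance: pd.Series, selected_size: int | None = None,
                    title: str = "", ax=None):
    """Horizontal bar chart of median permutation importance, most important
    on top; a red line marks the RFE-selected cut-off when given."""
    imp = importance.sort_values(ascending=True)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * len(imp) + 1))
    ax.barh(range(len(imp)), imp.to_numpy(), color="#4878a8")
    ax.set_yticks(range(len(imp)))
    ax.set_yticklabels(imp.index)
    ax.set_xlabel("median permutation importance (ΔC)")
    if selected_size is not None and 0 < selected_size <= len(imp):
        ax.axhline(len(imp) - selected_size - 0.5, color="red", lw=1.5)
    if title:
        ax.set_title(title)
    return ax


def plot_rfe_curve(curve: pd.Series, selected_size: int | None = None, ax=None):
    """Median test concordance against the number of retained markers."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.index, curve.to_numpy(), marker="o")
    if selected_size is not None:
        ax.axvline(selected_size, color="red", lw=1.5)
    ax.set_xlabel("number of markers")
    ax.set_ylabel("median test C")
    return ax
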