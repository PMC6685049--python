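"""Plotting helpers (convenience only; not part of the analysis contract)."""

from __future__ import annotations

import pandas as pd


def plot_information_content(information: pd.Series, consensus: str = "", ax=None):
    """Bar plot of per-slot information content with consensus letters."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    slots = list(information.index)
    ax.bar(range(len(slots)), information.values, color="steelblue")
    ax.set_xticks(range(len(slots)))
    ax.set_xticklabels(slots, rotation=90, fontsize=7)
    ax.set_ylabel("information (bits)")
    letters = consensus.replace("↓", "") if consensus else ""
    for i, letter in enumerate(letters[: len(slots)]):
        if letter != ".":
            ax.text(i, information.iloc[i], letter, ha="center", va="bottom", fontsize=8)
    return ax


def plot_logo(probabilities: pd.DataFrame, information: pd.Series, ax=None):
    """Stacked-letter-height logo: residue probability x column information."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    slots = list(probabilities.columns)
    for i, slot in enumerate(slots):
        col = probabilities[slot].dropna().sort_values()
        bottom = 0.0
        for residue, p in col.items():
            height = p * information[slot]
            if height <= 0:
                continue
            if height > 0.05:
                ax.text(
                    i,
                    bottom + height / 2,
                    residue,
                    ha="center",
                    va="center",
                    fontsize=6 + 10 * height,
                )
            bottom += height
    ax.set_xlim(-1, len(slots))
    ax.set_ylim(0, max(information.fillna(0).max(), 1e-6) * 1.1)
    ax.set_xticks(range(len(slots)))
    ax.set_xticklabels(slots, rotation=90, fontsize=7)
    ax.set_ylabel("bits")
    return ax
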