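"""Convenience plots: mean growth patterns and cross-approach mobility."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

PATTERN_COLORS = {"High": "#1b7837", "Middle": "#762a83", "Low": "#d73027"}


def plot_mean_patterns(result, path: str | Path, title: str = "") -> None:
    """Mean trajectory per pattern with the share of children annotated."""
    fig, ax = plt.subplots(figsize=(6, 4))
    names = result.pattern_names or [f"C{c + 1}" for c in range(result.k)]
    counts = pd.Series(list(result.labels.values())).value_counts()
    total = sum(counts)
    for c in range(result.k):
        share = 100.0 * counts.get(c, 0) / total
        ax.plot(
            result.grid, result.mean_patterns[c],
            color=PATTERN_COLORS.get(names[c]),
            label=f"{names[c]} ({share:.1f}%)", lw=2,
        )
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("age (months)")
    ax.set_ylabel("z-score")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_mobility(table: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Stacked-flow view of a pattern-by-pattern contingency table."""
    fig, ax = plt.subplots(figsize=(5, 4))
    bottoms = np.zeros(len(table.columns))
    x = np.arange(len(table.columns))
    for name, row in table.iterrows():
        ax.bar(x, row.to_numpy(), bottom=bottoms,
               color=PATTERN_COLORS.get(str(name)), label=str(name))
        bottoms += row.to_numpy()
    ax.set_xticks(x, [str(c) for c in table.columns])
    ax.set_xlabel("pattern (approach B)")
    ax.set_ylabel("children (colour: pattern in approach A)")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
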