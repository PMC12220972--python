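"""Minimal plotting helpers: radar composition plots and paired pre/post lines."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def radar_composition(mean_comp, phenotypes, condition_col: str, ax=None):
    """Radar plot of mean per-cluster phenotype composition per condition."""
    angles = np.linspace(0, 2 * np.pi, len(phenotypes), endpoint=False)
    angles = np.concatenate([angles, angles[:1]])
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    for _, row in mean_comp.iterrows():
        vals = np.array([row[p] for p in phenotypes])
        vals = np.concatenate([vals, vals[:1]])
        ax.plot(angles, vals, label=str(row[condition_col]))
        ax.fill(angles, vals, alpha=0.1)
    ax.set_xticks(angles[:-1])
    ax.set_xticklabels(phenotypes, fontsize=7)
    ax.legend(fontsize=7, loc="upper right", bbox_to_anchor=(1.3, 1.1))
    return ax


def paired_lines(shift_table, pre: str = "pre", post: str = "post", ax=None):
    """One line per cluster connecting its pre and post values."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3, 4))
    for _, row in shift_table.iterrows():
        ax.plot([0, 1], [row[pre], row[post]], marker="o", color="gray", alpha=0.6)
    ax.set_xticks([0, 1])
    ax.set_xticklabels([pre, post])
    ax.set_ylabel("per-cluster fraction")
    return ax
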