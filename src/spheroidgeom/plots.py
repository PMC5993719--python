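"""Publication-style figures: cohort boxplots and per-cell duration bars."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .timing import PhaseDurations

__all__ = ["boxplot_cohorts", "stacked_duration_bars"]


def boxplot_cohorts(
    groups: Mapping[str, Sequence[float]],
    ylabel: str,
    path=None,
    title: str | None = None,
):
    """Side-by-side Tukey boxplots of named cohorts (e.g. control vs agarose)."""
    fig, ax = plt.subplots(figsize=(1.6 * max(len(groups), 2) + 1, 4))
    ax.boxplot(list(groups.values()), tick_labels=list(groups.keys()), whis=1.5)
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def stacked_duration_bars(
    durations: Sequence[PhaseDurations],
    path=None,
    title: str | None = None,
):
    """Per-cell stacked bars: prometaphase below, metaphase above.

    Cells are aligned on plate formation (prometaphase drawn downward from
    zero, metaphase upward) and sorted by prometaphase duration; stars mark
    lower-bound (censored) prometaphases.
    """
    cells = [d for d in durations if d.prometaphase_min is not None]
    cells.sort(key=lambda d: d.prometaphase_min)
    x = range(len(cells))
    pro = [-d.prometaphase_min for d in cells]
    met = [d.metaphase_min or 0.0 for d in cells]
    fig, ax = plt.subplots(figsize=(max(len(cells) * 0.08, 4), 4))
    ax.bar(x, pro, color="tab:blue", label="prometaphase")
    ax.bar(x, met, color="tab:red", label="metaphase")
    for i, d in enumerate(cells):
        if not d.prometaphase_observed:
            ax.text(i, pro[i] - 2, "*", ha="center", va="top")
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_ylabel("duration (min; plate formation at 0)")
    ax.set_xlabel("mitotic cells")
    ax.legend(loc="upper left", fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
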