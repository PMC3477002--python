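"""Minimal figure helper: score as a function of word length n.

Consumes the long-format results table produced by
:func:`taxosep.scoring.run_grid`.  Matplotlib is imported lazily so the
core library does not require it.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_score_vs_n"]


def plot_score_vs_n(df: pd.DataFrame, level: str = "species", ax=None):
    """One line per (measure, score_measure) of score vs n at ``level``."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    sub = df[(df["level"] == level) & df["defined"]]
    for (measure, mode), grp in sub.groupby(["measure", "score_measure"]):
        grp = grp.sort_values("n")
        ax.plot(grp["n"], grp["score"], marker="o", label=f"s={measure}, {mode}")
    ax.set_xlabel("word length n")
    ax.set_ylabel(f"score at {level}")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    return ax
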