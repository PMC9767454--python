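"""Forest plots of estimator comparisons."""

from __future__ import annotations

import pandas as pd

from .regression import EstimateRecord

__all__ = ["forest_plot"]


def forest_plot(records, ax=None, title: str | None = None):
    """Point estimates with 95% CIs, one row per (estimator, term).

    Accepts EstimateRecords or a tidy estimates frame; returns the axes.
    """
    import matplotlib.pyplot as plt

    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([r.as_row() for r in records])
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.5 * len(df) + 1))
    ypos = range(len(df))[::-1]
    labels = [f"{r.estimator}: {r.term}" for r in df.itertuples()]
    ax.errorbar(df["beta"], list(ypos),
                xerr=[df["beta"] - df["ci_low"], df["ci_high"] - df["beta"]],
                fmt="o", capsize=3)
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(list(ypos), labels)
    ax.set_xlabel("SD outcome per 5 kg/m$^2$ BMI")
    if title:
        ax.set_title(title)
    return ax
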