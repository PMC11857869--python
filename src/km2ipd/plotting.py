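"""Plot helpers: pooled KM curves and the non-inferiority forest plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .survstats import kaplan_meier


def km_plot(ipd: pd.DataFrame, ax=None):
    """One KM step curve per treatment arm of a pooled IPD table."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for arm in sorted(ipd["arm"].unique()):
        km = kaplan_meier(ipd, arm)
        t = np.concatenate([[0.0], km.event_times, [km.max_time]])
        s = np.concatenate([[1.0], km.surv, km.surv[-1:] if len(km.surv) else [1.0]])
        ax.step(t, s, where="post", label=arm)
    ax.set_xlabel("months")
    ax.set_ylabel("event-free survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax


def forest_plot(table: pd.DataFrame, ax=None):
    """Forest plot of RMST losses with 90% CI and the non-inferiority margin."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 1.0 + 0.6 * len(table)))
    y = np.arange(len(table))[::-1]
    ax.errorbar(
        table["loss"], y,
        xerr=[table["loss"] - table["ci90_lower"], table["ci90_upper"] - table["loss"]],
        fmt="s", color="black", capsize=3,
    )
    margin = float(table["margin"].iloc[0])
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.axvline(margin, color="red", ls="--", lw=1.0, label=f"margin = {margin:g} months")
    ax.set_yticks(y)
    ax.set_yticklabels(table["label"])
    ax.set_xlabel("loss in event-free months (90% CI)")
    ax.legend(loc="best")
    return ax
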