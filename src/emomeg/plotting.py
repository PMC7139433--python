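"""Plotting helpers: performance dot-interval charts and rating boxplots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import pandas as pd


def plot_performance(summary: dict, metric: str = "accuracy", ax=None):
    """Dot + interval per feature set with a chance line at 0.5.

    ``summary`` is the evaluate-stage mapping of feature-set name to
    ``{metric: {median, ci_lower, ci_upper}}``.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.35 * max(len(summary), 4) + 1))
    names = sorted(summary)
    for i, name in enumerate(names):
        m = summary[name][metric]
        ax.plot([m["ci_lower"], m["ci_upper"]], [i, i], color="C0", lw=2)
        ax.plot(m["median"], i, "o", color="C0")
    ax.axvline(0.5, ls=":", color="k", lw=1)
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel(metric)
    ax.set_xlim(0, 1)
    ax.figure.tight_layout()
    return ax


def plot_rating_boxes(table: pd.DataFrame, dimension: str = "valence", ax=None):
    """Group-wise boxplots of per-subject median ratings per category."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    per_subject = (
        table.groupby(["category", "group", "subject_id"])[dimension]
        .median()
        .reset_index()
    )
    categories = list(dict.fromkeys(table["category"]))
    data, labels = [], []
    for cat in categories:
        for group, gname in ((1, "controls"), (0, "patients")):
            vals = per_subject[
                (per_subject["category"] == cat) & (per_subject["group"] == group)
            ][dimension]
            data.append(vals.to_numpy())
            labels.append(f"{cat}\n{gname}")
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel(f"median {dimension} (1-7)")
    ax.set_ylim(0.5, 7.5)
    ax.figure.tight_layout()
    return ax
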