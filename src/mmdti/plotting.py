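"""Plots: group-mean tract profiles (mean ± SEM per group) and ROC curves."""

from __future__ import annotations

import numpy as np

GROUP_COLORS = {"NC": "tab:green", "aMCI": "tab:orange", "AD": "tab:red"}


def plot_tract_profiles(profiles, tract: str, metric: str, ax=None):
    """Mean ± 1 SEM node profile per diagnostic group for one tract."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    j = profiles.tract_index(tract)
    arr = profiles.metric_array(metric)
    nodes = np.arange(profiles.n_nodes)
    for g in dict.fromkeys(profiles.group):
        mask = (profiles.group == g) & profiles.tracked[:, j]
        if not mask.any():
            continue
        vals = arr[mask, j, :]
        mean = vals.mean(axis=0)
        sem = vals.std(axis=0, ddof=1) / np.sqrt(mask.sum())
        color = GROUP_COLORS.get(str(g))
        ax.plot(nodes, mean, label=str(g), color=color)
        ax.fill_between(nodes, mean - sem, mean + sem, alpha=0.25, color=color)
    ax.set_xlabel("node along tract")
    ax.set_ylabel(metric + (" (1e-3 mm$^2$/s)" if metric == "MD" else ""))
    ax.set_title(tract)
    ax.legend()
    return ax


def plot_roc(roc, label: str = "", ax=None):
    """One ROC curve with its AUC in the legend."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot(roc.fpr, roc.tpr, label=f"{label} (AUC={roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    return ax
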