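"""Minimal plotting helpers: GA trajectory, ROC curve, accuracy box plot."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

__all__ = ["plot_trajectory", "plot_roc", "plot_accuracy_box"]


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_trajectory(best: Sequence[float], mean: Sequence[float], ax=None):
    """Per-generation best and mean fitness."""
    ax = _get_ax(ax)
    gens = np.arange(len(best))
    ax.plot(gens, best, label="best fitness")
    ax.plot(gens, mean, label="mean fitness", alpha=0.7)
    ax.set_xlabel("generation")
    ax.set_ylabel("fitness (mean CV accuracy)")
    ax.legend()
    return ax


def plot_roc(y_true: Sequence[int], scores: Sequence[float], ax=None, label=None):
    """ROC curve with AUC annotation."""
    from sklearn.metrics import roc_auc_score, roc_curve

    ax = _get_ax(ax)
    fpr, tpr, _ = roc_curve(y_true, scores)
    auc = roc_auc_score(y_true, scores)
    ax.plot(fpr, tpr, label=f"{label or 'model'} (AUC = {auc:.2f})")
    ax.plot([0, 1], [0, 1], linestyle="--", color="grey", linewidth=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    return ax


def plot_accuracy_box(samples: Mapping[str, Sequence[float]], ax=None):
    """Box plot of per-repeat accuracy samples, one box per model."""
    ax = _get_ax(ax)
    names = list(samples)
    ax.boxplot([np.asarray(samples[n], float) for n in names], tick_labels=names)
    ax.set_ylabel("accuracy")
    return ax
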