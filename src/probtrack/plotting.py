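"""Diagnostic figures: posterior-predictive bands and confusion heatmaps."""

from __future__ import annotations

import numpy as np

from .recovery import PosteriorPredictive, RecoveryReport

__all__ = ["plot_predictive_band", "plot_confusion"]


def plot_predictive_band(ppc: PosteriorPredictive, observed=None, ax=None):
    """Posterior-predictive mean with a 68% band, plus observed data.

    Covert: excess-A responses vs trial; overt: 5-trial running-average
    criterion vs trial.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    t = np.arange(1, len(ppc.mean) + 1)
    lo, hi = ppc.band()
    ax.fill_between(t, lo, hi, alpha=0.3, lw=0, label="model 68% band")
    ax.plot(t, ppc.mean, lw=1.2, label="model mean")
    if observed is not None:
        ax.plot(t, observed, color="0.4", lw=0.8, label="observed")
    ax.set_xlabel("trial")
    ax.set_ylabel("excess A responses" if ppc.task == "covert"
                  else "criterion (deg re neutral)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_confusion(report: RecoveryReport, ax=None):
    """Model-recovery confusion matrix as a heatmap with counts."""
    import matplotlib.pyplot as plt

    if report.confusion is None:
        raise ValueError("report has no confusion matrix")
    conf = report.confusion
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(conf.to_numpy(), cmap="Blues")
    ax.set_xticks(range(len(conf.columns)), conf.columns, rotation=45,
                  ha="right")
    ax.set_yticks(range(len(conf.index)), conf.index)
    ax.set_xlabel("best-fitting model")
    ax.set_ylabel("generating model")
    for i in range(conf.shape[0]):
        for j in range(conf.shape[1]):
            ax.text(j, i, str(conf.iat[i, j]), ha="center", va="center",
                    fontsize=9)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax
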