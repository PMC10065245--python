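"""ROC curve plotting."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .stats import RocResult

__all__ = ["plot_roc"]


def plot_roc(roc: RocResult, path=None, title: str = "ROC: median ADC of tDV"):
    """Plot an empirical ROC curve with the Youden point highlighted.

    Returns the matplotlib figure; saves it to ``path`` when given.
    """
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    fpr = 1.0 - roc.specificity[::-1]
    tpr = roc.sensitivity[::-1]
    ax.plot([0, *fpr, 1], [0, *tpr, 1], drawstyle="steps-post", lw=1.5,
            label=f"AUC = {roc.auc:.3f}")
    ax.plot([0, 1], [0, 1], ls=":", c="gray", lw=1)
    ax.plot(1.0 - roc.spec_at_cutoff, roc.sens_at_cutoff, "o", c="crimson",
            label=f"Youden cutoff {roc.youden_cutoff * 1e3:.2f}e-3 mm²/s")
    ax.set_xlabel("1 − specificity")
    ax.set_ylabel("Sensitivity")
    ax.set_title(title)
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(Path(path), dpi=150)
        plt.close(fig)
    return fig
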