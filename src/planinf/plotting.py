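"""Minimal summary-figure helpers (matplotlib imported lazily)."""

from __future__ import annotations

import numpy as np


def plot_learning_curve(kl_by_trial, ax=None):
    """Line plot of KL(true likelihood || learned likelihood) per trial."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(np.arange(len(kl_by_trial)), kl_by_trial)
    ax.set_xlabel("trial")
    ax.set_ylabel("KL(true || learned) [nats]")
    ax.set_title("Likelihood learning")
    return ax


def plot_phenotype(comparison, ax=None):
    """Bar chart of intact vs lesioned phenotype statistics."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    stats = list(comparison.differences)
    x = np.arange(len(stats))
    intact = [getattr(comparison.intact, s) for s in stats]
    lesioned = [getattr(comparison.lesioned, s) for s in stats]
    ax.bar(x - 0.2, intact, width=0.4, label="intact")
    ax.bar(x + 0.2, lesioned, width=0.4, label="lesioned")
    ax.set_xticks(x)
    ax.set_xticklabels(stats, rotation=20)
    ax.legend()
    return ax
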