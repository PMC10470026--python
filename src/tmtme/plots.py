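"""Basic Kaplan-Meier and time-dependent ROC plots for run reports."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .survival import KMCurve, TimeDependentROC  # noqa: E402


def km_plot(curves: dict[str, KMCurve], path, title: str = "Overall survival"):
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for label, curve in curves.items():
        ax.step([0, *curve.event_times], [1.0, *curve.survival], where="post",
                label=f"{label} (n={int(curve.at_risk[0]) if len(curve.at_risk) else 0})")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def roc_plot(rocs: dict[str, TimeDependentROC], path,
             title: str = "Time-dependent ROC"):
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, roc in rocs.items():
        ax.plot(1 - roc.specificities, roc.sensitivities,
                label=f"{label}: AUC={roc.auc:.3f}")
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=8)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
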