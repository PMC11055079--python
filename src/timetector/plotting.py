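"""Plain plotting helpers for run artifacts (requires matplotlib).

Deliberately minimal: loss curves from a feedback log, reconstruction
error against its dynamic threshold, and per-feature ROC curves.  Each
function draws onto a fresh figure and returns it; pass ``path`` to save.
"""

from __future__ import annotations

__all__ = ["plot_loss_curves", "plot_error_vs_threshold", "plot_roc_curves"]


def _plt():
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (install the 'plot' extra)") from exc
    return plt


def plot_loss_curves(feedback, path=None):
    """Train/validation loss per epoch from a FeedbackLog."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4))
    epochs = [e["epoch"] for e in feedback.epochs]
    ax.plot(epochs, [e["train_loss"] for e in feedback.epochs], label="train")
    ax.plot(epochs, [e["val_loss"] for e in feedback.epochs], label="validation")
    ax.set_xlabel("epoch")
    ax.set_ylabel("weighted loss")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
    return fig


def plot_error_vs_threshold(errors, thresholds, mask=None, feature=None, path=None):
    """One feature's error series with its dynamic threshold and flags."""
    plt = _plt()
    names = list(errors.feature_names)
    idx = names.index(feature) if feature else 0
    fig, ax = plt.subplots(figsize=(8, 4))
    e = errors.values[:, idx]
    ax.plot(e, lw=0.8, label="reconstruction error")
    ax.plot(thresholds.threshold[:, idx], lw=0.8, label="dynamic threshold")
    if mask is not None:
        flagged = mask.flags[:, idx]
        ax.plot(
            [i for i, f in enumerate(flagged) if f],
            e[flagged],
            "k.",
            ms=5,
            label="anomaly",
        )
    ax.set_title(names[idx])
    ax.set_xlabel("timestep")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
    return fig


def plot_roc_curves(rocs, path=None):
    """Per-feature ROC curves from :func:`timetector.evaluate.roc_auc`."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, roc in rocs.items():
        if roc is None:
            continue
        ax.plot(roc.fpr, roc.tpr, label=f"{name} (AUC {roc.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="random (AUC 0.5)")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
    return fig
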