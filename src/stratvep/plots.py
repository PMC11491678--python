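"""Optional matplotlib views of an evaluation report.

Box plots of per-class fold-score distributions and a parallel-coordinates
view of mean scores across models, one panel per characteristic. Matplotlib
is imported lazily so the rest of the package works without it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .evaluation import EvaluationReport

__all__ = ["plot_fold_score_boxes", "plot_parallel_coordinates"]


def plot_fold_score_boxes(report: EvaluationReport, path: str | Path | None = None):
    """One panel per characteristic: paired positive/negative score boxes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.scores_frame()
    chars = sorted(df["characteristic"].unique())
    models = sorted(df["model"].unique())
    fig, axes = plt.subplots(1, len(chars), figsize=(4 * len(chars), 4), squeeze=False)
    for ax, char in zip(axes[0], chars):
        data, labels, colors = [], [], []
        for model in models:
            for cls, color in (("positive", "#c44e52"), ("negative", "#4c72b0")):
                sel = df[(df.model == model) & (df.characteristic == char) & (df["class"] == cls)]
                data.append(sel["spearman"].dropna().to_numpy())
                labels.append(f"{model}\n{cls[:3]}")
                colors.append(color)
        boxes = ax.boxplot(data, patch_artist=True, tick_labels=labels)
        for patch, color in zip(boxes["boxes"], colors):
            patch.set_facecolor(color)
            patch.set_alpha(0.6)
        ax.set_title(char)
        ax.set_ylabel("test-fold Spearman")
        ax.tick_params(axis="x", labelsize=7, rotation=45)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_parallel_coordinates(report: EvaluationReport, path: str | Path | None = None):
    """Mean fold score per class connected across models; wide lines mark
    statistically significant class contrasts."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chars = sorted({c for (_m, c, _k) in report.fold_scores})
    models = sorted({m for (m, _c, _k) in report.fold_scores})
    fig, axes = plt.subplots(1, len(chars), figsize=(4 * len(chars), 4), squeeze=False)
    xs = np.arange(len(models))
    for ax, char in zip(axes[0], chars):
        for cls, color in (("positive", "#c44e52"), ("negative", "#4c72b0")):
            ys = [report.mean_score(m, char, cls) for m in models]
            widths = [
                3.0 if report.contrasts[(m, char)].significant else 1.0 for m in models
            ]
            for k in range(len(models) - 1):
                ax.plot(xs[k : k + 2], ys[k : k + 2], color=color,
                        lw=(widths[k] + widths[k + 1]) / 2)
            ax.scatter(xs, ys, s=[20 * w for w in widths], color=color, label=cls)
        ax.set_xticks(xs, models, rotation=45, fontsize=7)
        ax.set_title(char)
        ax.set_ylabel("mean fold Spearman")
        ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
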