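"""Optional figures: similarity heatmap and ROC plot.

Matplotlib is imported lazily so the rest of the package works headless
without it being loaded.
"""

from __future__ import annotations

from .delineation import DEFAULT_THRESHOLD, SimilarityMatrix
from .roc import ROCCurve

__all__ = ["plot_similarity_heatmap", "plot_roc"]


def plot_similarity_heatmap(
    matrix: SimilarityMatrix,
    path=None,
    threshold: float = DEFAULT_THRESHOLD,
):
    """Heatmap with a diverging colormap anchored at the decision threshold,
    so same-species pairs (above threshold) stand out in red."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import TwoSlopeNorm

    fig, ax = plt.subplots(figsize=(7, 6))
    vmin = min(float(matrix.values.min()), threshold - 1)
    norm = TwoSlopeNorm(vmin=vmin, vcenter=threshold, vmax=100)
    im = ax.imshow(matrix.values, cmap="RdBu_r", norm=norm)
    ax.set_xticks(range(len(matrix)), matrix.genome_ids, rotation=90, fontsize=6)
    ax.set_yticks(range(len(matrix)), matrix.genome_ids, fontsize=6)
    fig.colorbar(im, ax=ax, label="similarity (%)")
    ax.set_title(f"subset: {','.join(matrix.subset.members)}; threshold {threshold}%")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_roc(curves: dict[str, ROCCurve], path=None, mark_threshold: float | None = 96.0):
    """Sensitivity vs (100 - specificity), one line per labelled sweep."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for name, curve in curves.items():
        frame = curve.to_frame().dropna(subset=["sensitivity", "specificity"])
        ax.plot(100 - frame["specificity"], frame["sensitivity"], "o-", label=name, ms=3)
        if mark_threshold is not None:
            at = frame[frame["threshold"] == mark_threshold]
            if len(at):
                ax.plot(100 - at["specificity"], at["sensitivity"], "r*", ms=12)
    ax.set_xlabel("100 - specificity (%)")
    ax.set_ylabel("sensitivity (%)")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
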