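"""Presentation helpers: SD scatter, X AI violins and PCA plots.

These are conveniences for inspecting a run; they are not part of the
tested analysis contract.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd


def _get_axes(ax=None):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    return ax


def sd_scatter(calls: pd.DataFrame, threshold: float = 0.15, ax=None, path: Optional[str] = None):
    """Monoclonal vs polyclonal AI standard deviation per gene."""
    ax = _get_axes(ax)
    ax.scatter(calls.sd_mono, calls.sd_poly, s=8, c="0.6", lw=0)
    hit = calls.loc[calls.flagged]
    ax.scatter(hit.sd_mono, hit.sd_poly, s=18, facecolor="none", edgecolor="k")
    ax.axvline(threshold, ls="--", c="k", lw=0.8)
    ax.axhline(threshold, ls="--", c="k", lw=0.8)
    ax.set_xlabel("AI SD, monoclonal samples")
    ax.set_ylabel("AI SD, polyclonal samples")
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
    return ax


def x_ai_violins(ai: pd.DataFrame, x_chrom: str = "chrX", ax=None, path: Optional[str] = None):
    """Per-sample violin plot of X-linked allelic ratios."""
    ax = _get_axes(ax)
    sub = ai.loc[ai.chrom == x_chrom]
    samples = sorted(sub.sample_id.unique())
    data = [sub.loc[sub.sample_id == s, "ai"].to_numpy() for s in samples]
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(samples) + 1), samples, rotation=90, fontsize=7)
    ax.set_ylabel("X-linked AI")
    ax.set_ylim(-0.05, 1.05)
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
    return ax


def pca_plot(scores: pd.DataFrame, metadata: Optional[pd.DataFrame] = None, ax=None, path: Optional[str] = None):
    """Sample projections on the first two AI principal components."""
    ax = _get_axes(ax)
    colors = None
    if metadata is not None:
        clon = metadata.set_index("sample_id")["clonality"]
        palette = {"monoclonal": "tab:red", "polyclonal": "tab:blue", "unmanipulated": "tab:green"}
        colors = [palette.get(clon.get(s), "0.5") for s in scores.index]
    ax.scatter(scores.PC1, scores.PC2, c=colors)
    for s, row in scores.iterrows():
        ax.annotate(str(s), (row.PC1, row.PC2), fontsize=6)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
    return ax
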