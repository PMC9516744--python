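"""Minimal dotplot of homolog anchors and syntenic blocks."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["dotplot"]


def dotplot(anchors, blocks=(), path=None, title=None):
    """Rank-space scatter of anchors for one chromosome pair per panel.

    Anchors are grey dots; anchors belonging to a block are coloured by
    block (forward blocks in blue tones, reverse in green). Returns the
    figure; saves to ``path`` when given.
    """
    chrom_pairs = sorted({(a.chr_a, a.chr_b) for a in anchors})
    n = max(1, len(chrom_pairs))
    ncols = min(3, n)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 4 * nrows),
                             squeeze=False)
    for ax in axes.flat:
        ax.set_visible(False)
    for i, (ca, cb) in enumerate(chrom_pairs):
        ax = axes[i // ncols][i % ncols]
        ax.set_visible(True)
        xs = [a.rank_a for a in anchors if (a.chr_a, a.chr_b) == (ca, cb)]
        ys = [a.rank_b for a in anchors if (a.chr_a, a.chr_b) == (ca, cb)]
        ax.scatter(xs, ys, s=6, c="0.7", label="anchors")
        for b in blocks:
            if (b.chr_a, b.chr_b) != (ca, cb):
                continue
            color = "tab:blue" if b.orientation == "+" else "tab:green"
            ax.plot([a.rank_a for a in b.anchors], [a.rank_b for a in b.anchors],
                    marker=".", ms=4, lw=1, color=color)
        ax.set_xlabel(f"{ca} rank")
        ax.set_ylabel(f"{cb} rank")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
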