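"""Profile figure: normalized k-mer frequencies along the gene and flanks."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

_PANELS = [("flank_5p", "5' flank"), ("gene", "gene"), ("flank_3p", "3' flank")]


def plot_profile(
    rows: pd.DataFrame,
    cn_decimal: float,
    out_path: str,
    title: str = "",
    exons: list[tuple[str, int, int, str]] | None = None,
) -> None:
    """Scatter of per-k-mer normalized frequencies, one panel per region type.

    The horizontal red line in the gene panel marks the estimated copy
    number; flank panels should hover around the ploidy (2). Optional exon
    intervals (0-based half-open) are shaded in the gene panel; steps in the
    gene panel indicate duplication breakpoints inside the gene.
    """
    present = [(t, label) for t, label in _PANELS if (rows["type"] == t).any()]
    widths = [
        max(1, rows.loc[rows["type"] == t, "pos"].nunique()) for t, _ in present
    ]
    fig, axes = plt.subplots(
        1,
        len(present),
        figsize=(10, 3.2),
        sharey=True,
        gridspec_kw={"width_ratios": widths},
    )
    if len(present) == 1:
        axes = [axes]
    ymax = max(rows["normalized"].max() * 1.15, cn_decimal * 1.3, 4.0)
    for ax, (rtype, label) in zip(axes, present):
        sub = rows[rows["type"] == rtype]
        ax.plot(sub["pos"], sub["normalized"], ".", ms=2, alpha=0.5, color="steelblue")
        ax.set_title(label, fontsize=9)
        ax.set_ylim(0, ymax)
        if rtype == "gene":
            ax.axhline(cn_decimal, color="red", lw=1.2)
            if exons:
                for _chrom, start, end, _name in exons:
                    ax.axvspan(start, end, color="0.85", zorder=0)
        else:
            ax.axhline(2.0, color="0.5", lw=0.8, ls="--")
    axes[0].set_ylabel("normalized k-mer frequency")
    if title:
        fig.suptitle(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
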