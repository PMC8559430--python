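"""Figure rendering for locus maps, distance heatmaps and usage tables.

Figures never compute anything: every plotted value is written to a TSV
alongside the image first, and the plots are pure views of those tables.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

_FUNC_COLORS = {"F": "#c0392b", "ORF": "#e67e22", "P": "#95a5a6"}


def locus_ideogram(annotations, length: int, path: str | Path) -> pd.DataFrame:
    """Draw the locus map: oriented glyphs coloured by functionality.

    Functional and ORF genes are red/orange, pseudogenes grey, mirroring the
    conventional locus-map colouring.  Returns the underlying table.
    """
    rows = [
        {
            "name": a.name or "",
            "gene_type": a.gene_type,
            "start": a.start,
            "end": a.end,
            "strand": a.strand,
            "functionality": a.functionality,
        }
        for a in annotations
    ]
    df = pd.DataFrame(rows, columns=["name", "gene_type", "start", "end", "strand",
                                     "functionality"])
    tsv = Path(path).with_suffix(".tsv")
    df.to_csv(tsv, sep="\t", index=False)
    fig, ax = plt.subplots(figsize=(12, 2.5))
    lanes = {"V": 3, "J": 2, "D": 1, "C": 0}
    for _, r in df.iterrows():
        y = lanes.get(r.gene_type, 0)
        color = _FUNC_COLORS.get(r.functionality, "#555555")
        dx = r.end - r.start
        if r.strand == "+":
            ax.arrow(r.start, y, dx, 0, width=0.18, head_width=0.4,
                     head_length=min(dx * 0.3, 120), length_includes_head=True,
                     color=color, lw=0)
        else:
            ax.arrow(r.end, y, -dx, 0, width=0.18, head_width=0.4,
                     head_length=min(dx * 0.3, 120), length_includes_head=True,
                     color=color, lw=0)
    ax.set_yticks(list(lanes.values()), list(lanes.keys()))
    ax.set_xlim(0, length)
    ax.set_xlabel("position (bp)")
    ax.set_title("TRA/TRD locus map (F/ORF red-orange, P grey)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return df


def distance_heatmap(matrix, path: str | Path) -> pd.DataFrame:
    """Heatmap of a pairwise distance matrix (plus its TSV)."""
    df = matrix.to_dataframe()
    df.to_csv(Path(path).with_suffix(".tsv"), sep="\t")
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(df.values, cmap="viridis")
    ax.set_xticks(range(len(df)), df.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(len(df)), df.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="Poisson distance (subst./site)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return df


def usage_heatmap(values: pd.DataFrame, path: str | Path, title: str = "") -> pd.DataFrame:
    """Heatmap of a (normalised) V x J usage matrix (plus its TSV).

    Renders a placeholder panel when the matrix is empty.
    """
    values.to_csv(Path(path).with_suffix(".tsv"), sep="\t")
    fig, ax = plt.subplots(figsize=(8, 6))
    if values.size == 0:
        ax.text(0.5, 0.5, "no data", ha="center", va="center")
        ax.set_axis_off()
    else:
        im = ax.imshow(values.values, aspect="auto", cmap="magma")
        ax.set_xticks(range(values.shape[1]), values.columns, rotation=90, fontsize=5)
        ax.set_yticks(range(values.shape[0]), values.index, fontsize=5)
        fig.colorbar(im, ax=ax, label="log2 normalised count")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return values
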