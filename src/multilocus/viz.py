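"""Multi-panel alignment overview for quality / missing-data assessment.

One panel per locus (rows = canonical individuals, columns = sites), plus an
optional extra panel for the concatenated supermatrix.  Nucleotide data use
a fixed 6-class palette: one colour per base, one for gaps, one for
ambiguity codes; amino acids fall back to a hydrophobicity-grouped palette.
Gap-only padding rows therefore show up as full-width gap-colour bands,
which is the point of the plot.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .core import (
    AMINO_ACID,
    GAP,
    NUCLEOTIDE,
    MultiLocusContainer,
    LocusAlignment,
    concatenate_loci,
)

_NUC_CLASS = {"A": 0, "C": 1, "G": 2, "T": 3, GAP: 4}  # else ambiguous -> 5
_NUC_PALETTE = [
    "#4daf4a",  # A
    "#377eb8",  # C
    "#ff7f00",  # G
    "#e41a1c",  # T
    "#f0f0f0",  # gap
    "#999999",  # ambiguous / missing
]

_AA_GROUPS = {
    **{ch: 0 for ch in "AVLIMFWCP"},  # hydrophobic
    **{ch: 1 for ch in "GSTNQY"},     # polar
    **{ch: 2 for ch in "KRH"},        # basic
    **{ch: 3 for ch in "DE"},         # acidic
    GAP: 4,                            # gap; everything else -> 5
}
_AA_PALETTE = [
    "#984ea3",
    "#377eb8",
    "#4daf4a",
    "#e41a1c",
    "#f0f0f0",
    "#999999",
]


def _class_matrix(a: LocusAlignment) -> np.ndarray:
    table = _NUC_CLASS if a.alphabet == NUCLEOTIDE else _AA_GROUPS
    arr = a.to_array()
    out = np.full(arr.shape, 5, dtype=int)
    for ch, cls in table.items():
        out[arr == ch] = cls
    return out


def _text_char(ch: str, alphabet: str) -> str:
    if alphabet == NUCLEOTIDE:
        return ch if ch in "ACGT-" else "N"
    return ch


def render_text(c: MultiLocusContainer, include_concatenated: bool = False) -> str:
    """Character-grid overview: per panel, one row per individual."""
    panels = list(c.loci)
    if include_concatenated:
        panels.append(concatenate_loci(c))
    width = max(len(l) for l in c.labels)
    blocks = []
    for a in panels:
        lines = [f"## {a.name} ({len(a)} x {a.n_cols})"]
        for label in a.labels:
            row = "".join(_text_char(ch, a.alphabet) for ch in a[label])
            lines.append(f"{label:<{width}}  {row}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


def render_overview(
    c: MultiLocusContainer,
    include_concatenated: bool = False,
    path: str | Path | None = None,
    text: bool = False,
):
    """Render the overview; returns text (``text=True``) or the figure.

    With ``path`` given the figure is saved there (format by extension,
    e.g. ``.png`` / ``.svg``).  Rendering never mutates the container.
    """
    if text:
        return render_text(c, include_concatenated)
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    panels = list(c.loci)
    if include_concatenated:
        panels.append(concatenate_loci(c))
    palette = _NUC_PALETTE if c.alphabet == NUCLEOTIDE else _AA_PALETTE
    cmap = ListedColormap(palette)
    fig, axes = plt.subplots(
        len(panels), 1, figsize=(10, 1.2 + 1.1 * len(panels)), squeeze=False
    )
    for ax, a in zip(axes.ravel(), panels):
        ax.imshow(
            _class_matrix(a),
            aspect="auto",
            interpolation="nearest",
            cmap=cmap,
            vmin=0,
            vmax=len(palette) - 1,
        )
        ax.set_title(a.name, fontsize=9)
        ax.set_yticks(range(len(a.labels)))
        ax.set_yticklabels(a.labels, fontsize=6)
        ax.set_xticks([])
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
        return Path(path)
    return fig
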