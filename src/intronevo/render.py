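"""Exon-intron diagrams as SVG.

One row per gene: numbered exon boxes to scale on the coding axis,
introns as white vertical bars between them.  SVG is plain XML, so the
writer below builds the document directly; no raster dependencies.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence
from xml.sax.saxutils import escape

from .dollo import SpeciesTree
from .gene_models import GeneStructure

_ROW_H = 34
_BOX_H = 18
_LABEL_W = 180
_PLOT_W = 640
_PALETTE = [
    "#4c78a8", "#f58518", "#54a24b", "#e45756", "#72b7b2",
    "#eeca3b", "#b279a2", "#9d755d",
]


def render_structures(
    structures: Sequence[GeneStructure],
    tree: SpeciesTree | None = None,
    title: str = "",
) -> str:
    """Render structures as an SVG document string.

    When a tree is given, rows follow the tree's leaf order (genes whose
    species label matches a leaf first, in tree order, then the rest).
    """
    if not structures:
        raise ValueError("nothing to render")
    structures = list(structures)
    if tree is not None:
        order = [
            tree.label_of(n) for n in tree.tree.leaf_node_iter()
        ]
        rank = {name: i for i, name in enumerate(order)}
        structures.sort(
            key=lambda g: (rank.get(g.species, rank.get(g.gene_id, len(rank))),)
        )
    max_len = max(g.cds_length for g in structures)
    scale = _PLOT_W / max_len
    top = 30 if title else 10
    height = top + _ROW_H * len(structures) + 10
    width = _LABEL_W + _PLOT_W + 20
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" font-family="sans-serif" font-size="11">'
    ]
    if title:
        parts.append(
            f'<text x="10" y="18" font-size="13">{escape(title)}</text>'
        )
    for row, g in enumerate(structures):
        y = top + row * _ROW_H
        cy = y + _ROW_H // 2
        label = f"{g.species or g.gene_id} {g.family}".strip()
        parts.append(
            f'<text x="10" y="{cy + 4}">{escape(label)}</text>'
        )
        x = _LABEL_W
        color = _PALETTE[row % len(_PALETTE)]
        for i, exon in enumerate(g.exons):
            w = max(exon.length * scale, 2.0)
            parts.append(
                f'<rect x="{x:.1f}" y="{cy - _BOX_H // 2}" width="{w:.1f}" '
                f'height="{_BOX_H}" fill="{color}" stroke="black" '
                'stroke-width="0.5"/>'
            )
            parts.append(
                f'<text x="{x + w / 2:.1f}" y="{cy + 4}" fill="white" '
                f'text-anchor="middle">{i + 1}</text>'
            )
            x += w
            if i < len(g.exons) - 1:
                # intron bar: a white gap with a vertical tick
                parts.append(
                    f'<rect x="{x:.1f}" y="{cy - _BOX_H // 2}" width="3" '
                    f'height="{_BOX_H}" fill="white" stroke="black" '
                    'stroke-width="0.5"/>'
                )
                x += 3
    parts.append("</svg>")
    return "\n".join(parts)


def write_svg(svg: str, path: str | Path) -> None:
    Path(path).write_text(svg, encoding="utf-8")
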