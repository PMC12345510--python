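"""Figure-style rendering: RSCU bar charts and linear gene maps."""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Rectangle

from .codons import RSCUTable
from .gene_order import GeneOrder, unsigned
from .nomenclature import CATEGORY

_CATEGORY_COLORS = {"PCG": "white", "tRNA": "#4daf4a", "rRNA": "#bdbdbd", "CR": "#fee08b"}


def plot_rscu(table: RSCUTable, ax=None, title: str | None = None):
    """Stacked-by-family RSCU bar chart (codon-usage figure style)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(12, 4))
    by_family: dict[str, list[tuple[str, float]]] = {}
    for codon, value in table.rscu.items():
        if math.isnan(value):
            continue
        by_family.setdefault(table.family[codon], []).append((codon, value))
    x, ticks = 0.0, []
    for family in sorted(by_family):
        for codon, value in sorted(by_family[family]):
            ax.bar(x, value, width=0.85, edgecolor="black", linewidth=0.3)
            x += 1
        ticks.append((x - (len(by_family[family]) + 1) / 2, family))
        x += 0.8
    ax.set_xticks([t for t, _ in ticks])
    ax.set_xticklabels([f for _, f in ticks], rotation=60, fontsize=8)
    ax.axhline(1.0, color="gray", linestyle=":", linewidth=0.8)
    ax.set_ylabel("RSCU")
    if title:
        ax.set_title(title)
    return ax


def plot_gene_map(
    order: GeneOrder,
    rearranged: set | None = None,
    ax=None,
    path: str | Path | None = None,
):
    """Linear gene map: white PCGs, green tRNAs, red rearranged sites;
    minus-strand genes drawn below the line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(14, 1.8))
    rearranged = rearranged or set()
    for i, token in enumerate(order):
        name = unsigned(token)
        color = "#e41a1c" if name in rearranged else _CATEGORY_COLORS.get(
            CATEGORY.get(name, "CR"), "white"
        )
        y = 0 if not token.startswith("-") else -0.9
        ax.add_patch(Rectangle((i, y), 0.92, 0.8, facecolor=color,
                               edgecolor="black", linewidth=0.5))
        ax.text(i + 0.46, y + 0.4, name, rotation=90, ha="center",
                va="center", fontsize=5)
    ax.set_xlim(-0.5, len(order.order) + 0.5)
    ax.set_ylim(-1.2, 1.2)
    ax.axis("off")
    ax.set_title(order.taxon, fontsize=9)
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
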