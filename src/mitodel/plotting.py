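"""Basic circular arc plot of deletion calls.

Draws the mitochondrial genome as a circle (standard frame, clockwise from
position 1 at the top) with one chord per deletion linking its two
breakpoints — the conventional way recurrent mtDNA deletions are displayed.
Aesthetics are deliberately minimal.
"""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.path import Path as MplPath
import matplotlib.patches as mpatches

from mitodel.calling import DeletionCall


def _angle(pos: float, length: int) -> float:
    # clockwise from 12 o'clock
    return math.pi / 2 - 2 * math.pi * (pos - 1) / length


def plot_arcs(
    calls: list[DeletionCall],
    genome_length: int,
    path: str,
    min_size: int = 2000,
    highlight: tuple[int, int] | None = (8470, 13477),
    highlight_tol: int = 300,
) -> int:
    """Write a circular arc plot of calls larger than ``min_size``.

    Chords use standard-frame breakpoints; calls within ``highlight_tol`` of
    the ``highlight`` interval (default: the human common deletion) are drawn
    in red.  Returns the number of deletions plotted.
    """
    fig, ax = plt.subplots(figsize=(6, 6))
    theta = [i / 400 * 2 * math.pi for i in range(401)]
    ax.plot([math.cos(t) for t in theta], [math.sin(t) for t in theta], color="0.6", lw=1.5)
    n = 0
    for c in calls:
        if c.size <= min_size or c.start_std is None or c.end_std is None:
            continue
        a1 = _angle(c.start_std, genome_length)
        a2 = _angle(c.end_std, genome_length)
        x1, y1 = math.cos(a1), math.sin(a1)
        x2, y2 = math.cos(a2), math.sin(a2)
        color = "steelblue"
        if highlight is not None:
            if (
                abs(c.start_std - highlight[0]) <= highlight_tol
                and abs(c.end_std - highlight[1]) <= highlight_tol
            ):
                color = "red"
        # quadratic Bezier chord pulled toward the center
        verts = [(x1, y1), ((x1 + x2) / 4, (y1 + y2) / 4), (x2, y2)]
        patch = mpatches.PathPatch(
            MplPath(verts, [MplPath.MOVETO, MplPath.CURVE3, MplPath.CURVE3]),
            facecolor="none",
            edgecolor=color,
            alpha=0.4,
            lw=0.8,
        )
        ax.add_patch(patch)
        n += 1
    for frac in (0, 0.25, 0.5, 0.75):
        pos = 1 + frac * genome_length
        a = _angle(pos, genome_length)
        ax.text(1.08 * math.cos(a), 1.08 * math.sin(a), f"{int(pos):,}",
                ha="center", va="center", fontsize=8)
    ax.set_xlim(-1.2, 1.2)
    ax.set_ylim(-1.2, 1.2)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(f"mtDNA deletions > {min_size:,} bp (n={n})", fontsize=10)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return n
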