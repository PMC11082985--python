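"""Matplotlib rendering of the curve families.

The defining visual feature of every plot here is the cut-off annotation:
each curve point carries the concentration that generated it, restoring
the information a traditionally plotted ROC curve discards.  Dense grids
are decimated to at most :data:`MAX_LABELS` labels per curve (every k-th
point, k = ceil(n / MAX_LABELS), first and last always kept).
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .curves import AnnotatedCurve
from .unified import IndexCutoffDiagram, UnifiedResult

__all__ = [
    "MAX_LABELS",
    "plot_cda",
    "plot_index_cutoff",
    "plot_index_roc",
    "plot_reciprocal",
    "plot_roc",
    "render",
]

MAX_LABELS = 25


def _label_indices(n: int) -> list[int]:
    if n <= MAX_LABELS:
        return list(range(n))
    step = -(-n // MAX_LABELS)  # ceil
    idx = list(range(0, n, step))
    if idx[-1] != n - 1:
        idx.append(n - 1)
    return idx


def _annotate(ax, curve: AnnotatedCurve) -> None:
    xs, ys, cs = curve.xs, curve.ys, curve.cutoffs
    for i in _label_indices(len(curve)):
        ax.annotate(
            f"{cs[i]:g}",
            (xs[i], ys[i]),
            textcoords="offset points",
            xytext=(4, 4),
            fontsize=7,
        )


def _plot_curve(ax, curve: AnnotatedCurve, label: str, **kwargs) -> None:
    ax.plot(curve.xs, curve.ys, marker="o", markersize=3, label=label, **kwargs)
    _annotate(ax, curve)


def plot_cda(curves: Sequence[AnnotatedCurve], ax=None):
    """CDA plot: metric values against cut-off, all four metrics."""
    ax = ax or plt.gca()
    for curve in curves:
        _plot_curve(ax, curve, label=curve.axis_labels[1])
    ax.set_xlabel("cut-off (µg/L)")
    ax.set_ylabel("metric value")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    return ax


def plot_roc(curve: AnnotatedCurve, ax=None):
    """SS- or PV-ROC with integrated cut-off annotations; the chance
    diagonal is drawn for SS-ROC context."""
    ax = ax or plt.gca()
    _plot_curve(ax, curve, label=curve.kind.value)
    ax.plot([0, 1], [0, 1], linestyle=":", linewidth=0.8, color="grey")
    ax.set_xlabel(curve.axis_labels[0])
    ax.set_ylabel(curve.axis_labels[1])
    ax.legend(fontsize=8)
    return ax


def plot_index_roc(ssj: AnnotatedCurve, pvpsi: AnnotatedCurve, ax=None):
    ax = ax or plt.gca()
    _plot_curve(ax, ssj, label="SS-J index")
    _plot_curve(ax, pvpsi, label="PV-PSI index")
    ax.axhline(0.0, linestyle=":", linewidth=0.8, color="grey")
    ax.set_xlabel("1 − specificity  /  1 − NPV")
    ax.set_ylabel("index value")
    ax.legend(fontsize=8)
    return ax


def plot_index_cutoff(diagram: IndexCutoffDiagram, unified: UnifiedResult | None = None, ax=None):
    """The index cut-off diagram: J(c) and PSI(c) on a shared cut-off axis,
    unified crossing marked when present."""
    ax = ax or plt.gca()
    _plot_curve(ax, diagram.j_curve, label="SS-J index")
    _plot_curve(ax, diagram.psi_curve, label="PV-PSI index")
    for label, c, y in diagram.overlays:
        ax.scatter([c], [y], marker="x", s=40, zorder=5)
        ax.annotate(label, (c, y), textcoords="offset points", xytext=(4, -8), fontsize=7)
    if unified is not None and unified.cutoff_star is not None and unified.method == "crossing":
        ax.scatter([unified.cutoff_star], [unified.index_star], marker="*", s=90, zorder=6, color="black")
        ax.annotate(
            f"unified {unified.cutoff_star:.1f} µg/L\nindex {unified.index_star:.3f}",
            (unified.cutoff_star, unified.index_star),
            textcoords="offset points",
            xytext=(6, 6),
            fontsize=7,
        )
    ax.set_xlabel("cut-off (µg/L)")
    ax.set_ylabel("index value")
    ax.legend(fontsize=8)
    return ax


def plot_reciprocal(diagram: IndexCutoffDiagram, ax=None):
    ax = ax or plt.gca()
    _plot_curve(ax, diagram.j_curve, label="1/J (persons)")
    _plot_curve(ax, diagram.psi_curve, label="1/PSI (persons)")
    ax.set_xlabel("cut-off (µg/L)")
    ax.set_ylabel("persons to examine")
    ax.legend(fontsize=8)
    return ax


def render(draw: Callable, path: str | Path, title_suffix: str = "") -> Path:
    """Draw onto a fresh figure and save; the config hash rides in the
    title so every artifact is traceable to its run."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(6.5, 5))
    draw(ax)
    if title_suffix:
        ax.set_title(title_suffix, fontsize=7, loc="right", color="grey")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
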