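"""Matplotlib glue: spectra and GHOST diagrams."""

from __future__ import annotations

from .ghost import AXIS_PAIRS, GhostResult, make_diagram
from .spin_model import Spectrum, ValidationError

__all__ = ["plot_spectrum", "plot_ghost_diagram"]

_AXIS_LABELS = {
    "S-tau_c": ("order parameter S", r"$\tau_c$ [ns]"),
    "S-W": ("order parameter S", "W [mT]"),
    "S-pA": ("order parameter S", r"$p_A$"),
}


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt
    _, ax = plt.subplots()
    return ax


def plot_spectrum(spectrum: Spectrum, ax=None, **kw):
    ax = _get_ax(ax)
    ax.plot(spectrum.field, spectrum.intensity, **kw)
    ax.set_xlabel("magnetic field [mT]")
    ax.set_ylabel("dA/dB [arb. u.]")
    return ax


def plot_ghost_diagram(condensed, axis_pair: str = "S-tau_c", ax=None):
    """Scatter of retained solution points, RGB = normalized (tau_c, W, pA);
    group means drawn as red dots with their domain label."""
    if axis_pair not in AXIS_PAIRS:
        raise ValidationError(f"unknown axis pair {axis_pair!r}")
    result: GhostResult = condensed.result if hasattr(condensed, "result") \
        else condensed
    dia = make_diagram(result.points, axis_pair)
    ax = _get_ax(ax)
    ax.scatter(dia.x, dia.y, c=dia.colors, s=12, alpha=0.8, edgecolors="none")
    ycol = axis_pair.split("-")[1]
    for g in result.groups:
        ax.plot(g.mean["S"], g.mean[ycol], "o", color="red", ms=8)
        ax.annotate(f"D{g.label} ({g.proportion_pct:.0f}%)",
                    (g.mean["S"], g.mean[ycol]),
                    textcoords="offset points", xytext=(6, 6), fontsize=8)
    xl, yl = _AXIS_LABELS[axis_pair]
    ax.set_xlabel(xl)
    ax.set_ylabel(yl)
    ax.set_xlim(-0.02, 1.02)
    return ax
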