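"""Matplotlib rendering of the hydrophobic moment plot and helical wheels."""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .classify import EisenbergPlotData, Label
from .io import ChargeClass, WheelPoint

_LABEL_COLORS = {
    Label.D: "tab:red",
    Label.TM: "tab:blue",
    Label.S: "tab:orange",
    Label.GLOBULAR: "0.6",
}

_CHARGE_COLORS = {
    ChargeClass.BASIC: "tab:blue",
    ChargeClass.ACIDIC: "tab:red",
    ChargeClass.POLAR: "tab:green",
    ChargeClass.NONPOLAR: "gold",
}


def _point_color(labels: frozenset[Label]) -> str:
    for lab in (Label.TM, Label.S, Label.D, Label.GLOBULAR):
        if lab in labels:
            return _LABEL_COLORS[lab]
    return "black"  # pragma: no cover


def plot_eisenberg(data: EisenbergPlotData, path: str | Path) -> None:
    """Render <muH> vs <H> with the surface line and TM cutoff overlaid."""
    fig, ax = plt.subplots(figsize=(6, 5))
    for mean_h, mu_h, labels, _near in data.points:
        ax.scatter(mean_h, mu_h, color=_point_color(labels), s=35, zorder=3)
    (x0, y0), (x1, y1) = data.surface_line_endpoints
    ax.plot([x0, x1], [y0, y1], "k--", lw=1,
            label=(f"surface line: muH = {data.rule.surface_line_intercept:g} "
                   f"{data.rule.surface_line_slope:+g}*<H>"))
    ax.axvline(data.tm_cutoff_x, color="k", ls=":", lw=1,
               label=f"TM cutoff <H> = {data.rule.tm_mean_h_cutoff:g}")
    handles = [
        plt.Line2D([], [], marker="o", ls="", color=c, label=str(lab))
        for lab, c in _LABEL_COLORS.items()
    ]
    ax.legend(handles=handles + ax.get_legend_handles_labels()[0],
              fontsize=8, loc="upper right")
    ax.set_xlabel("mean hydrophobicity <H>")
    ax.set_ylabel("hydrophobic moment <muH>")
    ax.set_ylim(bottom=0)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_wheel(points: list[WheelPoint], path: str | Path, title: str = "") -> None:
    """Render a helical-wheel projection, one disc per residue."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for p in points:
        # later turns are drawn slightly further out so overlaps stay legible
        r = p.radius + 0.12 * ((p.position_in_window - 1) * 100 // 360)
        theta = math.radians(p.angle_deg)
        x, y = r * math.cos(theta), r * math.sin(theta)
        ax.scatter(x, y, s=600, color=_CHARGE_COLORS[p.charge_class],
                   edgecolor="black", zorder=3)
        ax.annotate(f"{p.residue}{p.position_in_window}", (x, y),
                    ha="center", va="center", fontsize=8, zorder=4)
    ax.set_aspect("equal")
    lim = 1.6
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
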