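"""Hydrophobic-moment-plot classification of scanned windows.

Three rules, all strict inequalities ("above"):

* lipid-binding (D): discrimination factor D > 0.68
* transmembrane (TM): mean hydrophobicity <H> > 0.75
* surface-seeking (S): <muH> above the line <muH> = 0.645 − 0.324·<H>,
  and not already TM

A window that fires none of the three is labelled globular. Labels are a
set, not a single class — a window can be both D and S, for instance.
Windows within a small band of the TM cutoff or the surface line (but not
over it) get a near-threshold flag, so borderline calls are visible in
reports.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .core import WindowMetrics
from .errors import EmptyDatasetError


class Label(str, enum.Enum):
    """Window classes on the hydrophobic moment plot."""

    D = "D"              # lipid-binding by discrimination factor
    TM = "TM"            # transmembrane by mean hydrophobicity
    S = "S"              # surface-seeking by the Eisenberg-plot line
    GLOBULAR = "globular"

    def __str__(self) -> str:  # for report formatting
        return self.value


class NearFlag(str, enum.Enum):
    """Raised when a value sits within ``near_band`` of an unfired rule."""

    NEAR_TM = "near_TM"
    NEAR_S = "near_S"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class ClassificationRule:
    """Decision thresholds and line coefficients of the three rules."""

    d_cutoff: float = 0.68
    tm_mean_h_cutoff: float = 0.75
    surface_line_intercept: float = 0.645
    surface_line_slope: float = -0.324
    near_band: float = 0.05

    def __post_init__(self) -> None:
        if self.d_cutoff <= 0:
            raise ValueError("d_cutoff must be positive")
        if self.near_band < 0:
            raise ValueError("near_band must be non-negative")


DEFAULT_RULE = ClassificationRule()


@dataclass(frozen=True)
class LabeledRegion:
    """A window plus its label set and near-threshold flags."""

    metrics: WindowMetrics
    labels: frozenset[Label]
    near_flags: frozenset[NearFlag] = field(default_factory=frozenset)
    gated: bool = False  # True when a helicity gate forced GLOBULAR

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("labels must be non-empty")
        if (Label.GLOBULAR in self.labels) != (self.labels == {Label.GLOBULAR}):
            raise ValueError("GLOBULAR must be the sole label when present")

    @property
    def is_positive(self) -> bool:
        """True if any non-globular label fired."""
        return Label.GLOBULAR not in self.labels


def surface_line(mean_h: float, rule: ClassificationRule = DEFAULT_RULE) -> float:
    """The surface-seeking boundary <muH> value at a given <H>."""
    return rule.surface_line_intercept + rule.surface_line_slope * mean_h


def classify(
    metrics: WindowMetrics, rule: ClassificationRule = DEFAULT_RULE
) -> LabeledRegion:
    """Assign the label set of one window.

    All rules use strict ">" (a boundary-equal value does not fire).
    Near flags are raised only when the corresponding label is absent:
    NEAR_TM when |<H> − cutoff| <= near_band, NEAR_S when the vertical
    distance to the surface line is <= near_band.
    """
    labels: set[Label] = set()
    near: set[NearFlag] = set()

    if metrics.d > rule.d_cutoff:
        labels.add(Label.D)
    is_tm = metrics.mean_h > rule.tm_mean_h_cutoff
    if is_tm:
        labels.add(Label.TM)
    line = surface_line(metrics.mean_h, rule)
    if metrics.mu_h > line and not is_tm:
        labels.add(Label.S)

    if Label.TM not in labels and abs(metrics.mean_h - rule.tm_mean_h_cutoff) <= rule.near_band:
        near.add(NearFlag.NEAR_TM)
    if Label.S not in labels and abs(metrics.mu_h - line) <= rule.near_band:
        near.add(NearFlag.NEAR_S)

    if not labels:
        labels.add(Label.GLOBULAR)
    return LabeledRegion(metrics=metrics, labels=frozenset(labels), near_flags=frozenset(near))


@dataclass(frozen=True)
class EisenbergPlotData:
    """Scatter points and overlay geometry for a hydrophobic moment plot.

    ``points`` are (mean_h, mu_h, labels, near_flags) per window;
    ``surface_line_endpoints`` and ``tm_cutoff_x`` describe the two
    decision boundaries so any plotting backend can draw the overlay.
    """

    points: tuple[tuple[float, float, frozenset[Label], frozenset[NearFlag]], ...]
    surface_line_endpoints: tuple[tuple[float, float], tuple[float, float]]
    tm_cutoff_x: float
    rule: ClassificationRule


def eisenberg_plot_points(
    regions: list[WindowMetrics], rule: ClassificationRule = DEFAULT_RULE
) -> EisenbergPlotData:
    """Build the (<H>, <muH>) dataset plus decision-boundary overlays.

    The point labels are recomputed with :func:`classify`, so counts on
    either side of the line always agree with the classifier.
    """
    if not regions:
        raise EmptyDatasetError("no windows to plot")
    points = []
    for m in regions:
        lr = classify(m, rule)
        points.append((m.mean_h, m.mu_h, lr.labels, lr.near_flags))
    xs = [m.mean_h for m in regions]
    lo = min(min(xs), -0.5)
    hi = max(max(xs), 1.2)
    endpoints = ((lo, surface_line(lo, rule)), (hi, surface_line(hi, rule)))
    return EisenbergPlotData(
        points=tuple(points),
        surface_line_endpoints=endpoints,
        tm_cutoff_x=rule.tm_mean_h_cutoff,
        rule=rule,
    )
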