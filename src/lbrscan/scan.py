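"""Sliding-window scanning of full protein sequences.

The study-style workflow picks helical windows by hand; here the scan is
exhaustive (every window position at a configurable step), every window
is classified, and maximal runs of overlapping positive windows are
merged into reported regions. Per-window output remains available for
direct comparison with hand-picked windows.

Windows containing residues outside the scale (B, J, O, U, X, Z) are
skipped with a logged warning, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .classify import (
    DEFAULT_RULE,
    ClassificationRule,
    Label,
    LabeledRegion,
    classify,
)
from .core import (
    ALPHA_HELIX_DELTA,
    DEFAULT_WINDOW_SIZE,
    PeptideWindow,
    window_metrics,
)
from .errors import AnnotationMismatchError, InvalidParameterError, SequenceTooShortError
from .scales import DEFAULT_SCALE, HydrophobicityScale

logger = logging.getLogger(__name__)

HELIX_ALPHABET = frozenset("HEC")  # H = helix, E = strand, C = coil


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters: window geometry, classification rule, helicity gate."""

    window_size: int = DEFAULT_WINDOW_SIZE
    step: int = 1
    delta_deg: float = ALPHA_HELIX_DELTA
    rule: ClassificationRule = DEFAULT_RULE
    #: Minimum helix fraction for a window to keep its labels when a
    #: secondary-structure annotation is supplied (gate is off otherwise).
    helicity_min_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise InvalidParameterError("window_size must be >= 2")
        if self.step < 1:
            raise InvalidParameterError("step must be >= 1")
        if not 0.0 <= self.helicity_min_fraction <= 1.0:
            raise InvalidParameterError("helicity_min_fraction must be in [0, 1]")


@dataclass(frozen=True)
class MergedRegion:
    """A maximal run of overlapping positive windows, reported as one region.

    ``best_window`` is the member window with the highest discrimination
    factor (ties broken toward the smaller start); ``labels`` is the union
    over member windows.
    """

    start: int
    end: int
    best_window: LabeledRegion
    labels: frozenset[Label]


@dataclass(frozen=True)
class ScanResult:
    parent_id: str
    sequence: str
    config: ScanConfig
    windows: tuple[LabeledRegion, ...]
    skipped_starts: tuple[int, ...] = field(default_factory=tuple)

    @property
    def merged_regions(self) -> tuple[MergedRegion, ...]:
        return merge_positive_windows(self.windows)

    @property
    def positive_windows(self) -> tuple[LabeledRegion, ...]:
        return tuple(w for w in self.windows if w.is_positive)


def scan_sequence(
    sequence: str,
    parent_id: str = "",
    config: ScanConfig = ScanConfig(),
    scale: HydrophobicityScale = DEFAULT_SCALE,
) -> ScanResult:
    """Scan one sequence: one classified window per admissible position.

    Positions are 1-based; window starts are 1, 1+step, ... while the
    window fits. Windows with undefined residues are skipped and recorded
    in ``skipped_starts``.
    """
    sequence = sequence.upper()
    n, w = len(sequence), config.window_size
    if n < w:
        raise SequenceTooShortError(
            f"sequence {parent_id!r} has {n} residues, shorter than the "
            f"{w}-residue window"
        )
    windows: list[LabeledRegion] = []
    skipped: list[int] = []
    for start0 in range(0, n - w + 1, config.step):
        fragment = sequence[start0 : start0 + w]
        if not scale.covers(fragment):
            skipped.append(start0 + 1)
            logger.warning(
                "skipping window %s:%d-%d: residue outside scale",
                parent_id, start0 + 1, start0 + w,
            )
            continue
        pw = PeptideWindow(sequence=fragment, parent_id=parent_id, start=start0 + 1)
        windows.append(classify(window_metrics(pw, scale, config.delta_deg), config.rule))
    return ScanResult(
        parent_id=parent_id,
        sequence=sequence,
        config=config,
        windows=tuple(windows),
        skipped_starts=tuple(skipped),
    )


def apply_helicity_gate(
    result: ScanResult,
    annotation: str,
    min_fraction: float | None = None,
) -> ScanResult:
    """Demote windows that are insufficiently helical to GLOBULAR.

    *annotation* is a per-residue string over {H, E, C} of the same length
    as the parent sequence. A window passes when its fraction of H
    residues is >= *min_fraction* (boundary passes); failing windows keep
    their metrics but are relabeled {GLOBULAR} with ``gated=True``.
    """
    if min_fraction is None:
        min_fraction = result.config.helicity_min_fraction
    if len(annotation) != len(result.sequence):
        raise AnnotationMismatchError(
            f"annotation length {len(annotation)} != sequence length "
            f"{len(result.sequence)} for {result.parent_id!r}"
        )
    annotation = annotation.upper()
    bad = set(annotation) - HELIX_ALPHABET
    if bad:
        raise AnnotationMismatchError(
            f"annotation contains characters outside {{H,E,C}}: {sorted(bad)}"
        )
    gated_windows = []
    for w in result.windows:
        s0 = w.metrics.window.start - 1
        span = annotation[s0 : s0 + len(w.metrics.window)]
        frac = span.count("H") / len(span)
        if frac >= min_fraction:
            gated_windows.append(w)
        else:
            gated_windows.append(
                LabeledRegion(
                    metrics=w.metrics,
                    labels=frozenset({Label.GLOBULAR}),
                    near_flags=w.near_flags,
                    gated=True,
                )
            )
    return replace(result, windows=tuple(gated_windows))


def merge_positive_windows(
    windows: tuple[LabeledRegion, ...] | list[LabeledRegion],
) -> tuple[MergedRegion, ...]:
    """Merge maximal runs of overlapping positive windows into regions.

    Two windows belong to the same region when their spans intersect.
    Globular (including gated) windows never join a region. The operation
    is idempotent: merging the output spans again changes nothing.
    """
    positives = sorted(
        (w for w in windows if w.is_positive),
        key=lambda w: (w.metrics.window.start, w.metrics.window.end),
    )
    regions: list[MergedRegion] = []
    run: list[LabeledRegion] = []

    def close_run() -> None:
        if not run:
            return
        best = max(run, key=lambda w: (w.metrics.d, -w.metrics.window.start))
        labels = frozenset().union(*(w.labels for w in run))
        regions.append(
            MergedRegion(
                start=min(w.metrics.window.start for w in run),
                end=max(w.metrics.window.end for w in run),
                best_window=best,
                labels=labels,
            )
        )

    run_end = -1
    for w in positives:
        if run and w.metrics.window.start > run_end:
            close_run()
            run = []
        run.append(w)
        run_end = max(run_end, w.metrics.window.end)
    close_run()
    return tuple(regions)
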