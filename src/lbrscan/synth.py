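"""Synthetic sequences with known ground truth.

Every class the classifier distinguishes can be planted inside a neutral
background, so the full scan-classify-merge pipeline is testable without
any real protein:

* D  — an amphipathic template (hydrophobic face on one side of the
  helical wheel, basic residues opposite) with positive net charge;
* TM — a uniformly hydrophobic stretch drawn from {I, L, V, F, A};
* S  — an uncharged amphipathic template below the TM cutoff;
* GLOBULAR — pure background everywhere.

The background is drawn from small/polar residues with rare isolated
charges. Class membership is *verified* by running the classifier on the
generated material (rejection sampling), never assumed from the
construction; flanks are verified to contain no positive window.

Shuffle nulls are composition-preserving permutations: they conserve
mean hydrophobicity and net charge exactly while destroying the angular
arrangement that produces a high hydrophobic moment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import DEFAULT_RULE, ClassificationRule, Label, classify
from .core import DEFAULT_WINDOW_SIZE, PeptideWindow, window_metrics
from .errors import GenerationError, InvalidParameterError
from .scales import DEFAULT_SCALE, HydrophobicityScale
from .scan import ScanConfig, scan_sequence

#: Rejection-sampling attempt cap; the class templates hit their targets
#: within a handful of draws, so the cap only catches misconfiguration.
MAX_ATTEMPTS = 10_000

HYDROPHOBIC_FACE_RESIDUES = ("L", "I", "F", "V")
TM_RESIDUES = ("I", "L", "V", "F", "A")
POLAR_FILL_RESIDUES = ("Q", "S", "T", "N")
BACKGROUND_RESIDUES = ("G", "S", "T", "N", "Q", "A", "P")

#: Half-width of the hydrophobic arc on the helical wheel, degrees.
FACE_HALF_ARC = 90.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one batch of planted-class sequences."""

    target_class: Label
    window_size: int = DEFAULT_WINDOW_SIZE
    flank_length: int = 50
    seed: int = 0
    n_sequences: int = 1

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise InvalidParameterError("window_size must be >= 2")
        if self.flank_length < 0:
            raise InvalidParameterError("flank_length must be >= 0")
        if self.n_sequences < 1:
            raise InvalidParameterError("n_sequences must be >= 1")


@dataclass(frozen=True)
class PlantedSequence:
    """One synthetic sequence with its ground-truth planted span."""

    id: str
    sequence: str
    start: int  # 1-based inclusive span of the planted window
    end: int
    target_class: Label


def _wheel_face_mask(window_size: int, delta_deg: float = 100.0) -> np.ndarray:
    """True for positions whose wheel angle lies within the hydrophobic arc."""
    angles = (np.arange(window_size) * delta_deg) % 360.0
    dist = np.minimum(angles, 360.0 - angles)  # angular distance from 0
    return dist < FACE_HALF_ARC


def amphipathic_template(
    window_size: int,
    charge_target: int,
    seed: int | np.random.Generator,
    scale: HydrophobicityScale = DEFAULT_SCALE,
) -> str:
    """Build a peptide with a hydrophobic face and an opposite charged face.

    Hydrophobic residues (L/I/F/V) occupy wheel angles within 90 degrees
    of the face axis; the opposite arc carries K/R (or E for a negative
    target) until the net charge equals *charge_target*, with Q/S/T/N
    filling the rest. The resulting hydrophobic moment is high by
    construction but not guaranteed above any cutoff — the classifier
    decides.
    """
    if window_size < 7:
        raise InvalidParameterError("window_size must be >= 7 for a two-faced wheel")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    face = _wheel_face_mask(window_size)
    polar_positions = np.flatnonzero(~face)
    if abs(charge_target) > len(polar_positions):
        raise InvalidParameterError(
            f"charge_target {charge_target:+d} needs more charged positions than "
            f"the polar face offers ({len(polar_positions)})"
        )
    residues = np.empty(window_size, dtype="<U1")
    residues[face] = rng.choice(HYDROPHOBIC_FACE_RESIDUES, size=int(face.sum()))
    residues[~face] = rng.choice(POLAR_FILL_RESIDUES, size=len(polar_positions))
    charged = rng.choice(polar_positions, size=abs(charge_target), replace=False)
    if charge_target >= 0:
        residues[charged] = rng.choice(("K", "R"), size=len(charged))
    else:
        residues[charged] = "E"
    return "".join(residues)


def _background(length: int, rng: np.random.Generator, charge_prob: float = 0.03) -> str:
    """Neutral low-hydrophobicity filler with rare, alternating K/E charges."""
    residues = list(rng.choice(BACKGROUND_RESIDUES, size=length))
    n_charged = rng.binomial(length, charge_prob)
    if n_charged:
        positions = rng.choice(length, size=n_charged, replace=False)
        for j, pos in enumerate(sorted(positions)):
            residues[pos] = "K" if j % 2 == 0 else "E"
    return "".join(residues)


def _planted_window(
    target: Label,
    window_size: int,
    rng: np.random.Generator,
    scale: HydrophobicityScale,
    rule: ClassificationRule,
) -> str:
    """Draw window candidates until the classifier confirms *target*."""
    for _ in range(MAX_ATTEMPTS):
        if target is Label.TM:
            candidate = "".join(
                rng.choice(TM_RESIDUES, size=window_size, p=(0.25, 0.25, 0.2, 0.2, 0.1))
            )
        elif target is Label.D:
            candidate = amphipathic_template(window_size, int(rng.integers(2, 5)), rng, scale)
        elif target is Label.S:
            candidate = amphipathic_template(window_size, 0, rng, scale)
        elif target is Label.GLOBULAR:
            candidate = _background(window_size, rng)
        else:  # pragma: no cover
            raise InvalidParameterError(f"unknown target class {target}")
        metrics = window_metrics(PeptideWindow(candidate), scale)
        if target in classify(metrics, rule).labels:
            return candidate
    raise GenerationError(
        f"no {target.value} window found in {MAX_ATTEMPTS} attempts; "
        "adjust window_size or the rule"
    )


def _flanks_are_globular(
    sequence: str, planted_start0: int, planted_end0: int,
    window_size: int, scale: HydrophobicityScale, rule: ClassificationRule,
) -> bool:
    """True when every window fully outside the planted span is globular."""
    result = scan_sequence(
        sequence, config=ScanConfig(window_size=window_size, rule=rule), scale=scale
    )
    for w in result.windows:
        s0, e0 = w.metrics.window.start - 1, w.metrics.window.end - 1
        outside = e0 < planted_start0 or s0 > planted_end0
        if outside and w.is_positive:
            return False
    return True


def generate_planted(
    spec: SyntheticSpec,
    scale: HydrophobicityScale = DEFAULT_SCALE,
    rule: ClassificationRule = DEFAULT_RULE,
) -> list[PlantedSequence]:
    """Generate ``spec.n_sequences`` sequences, each flank+window+flank.

    The planted window is rejection-sampled until the classifier assigns
    the target class; the flanks are rejection-sampled until no window
    fully outside the planted span is positive. For target GLOBULAR the
    whole sequence must contain no positive window at all.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[PlantedSequence] = []
    for i in range(spec.n_sequences):
        if spec.target_class is Label.GLOBULAR:
            length = spec.window_size + 2 * spec.flank_length
            for _ in range(MAX_ATTEMPTS):
                seq = _background(length, rng)
                if len(seq) >= spec.window_size and not scan_sequence(
                    seq, config=ScanConfig(window_size=spec.window_size, rule=rule),
                    scale=scale,
                ).positive_windows:
                    break
            else:
                raise GenerationError(
                    f"no all-globular background of length {length} found in "
                    f"{MAX_ATTEMPTS} attempts"
                )
            start = spec.flank_length + 1
        else:
            window = _planted_window(
                spec.target_class, spec.window_size, rng, scale, rule
            )
            s0 = spec.flank_length
            e0 = s0 + spec.window_size - 1
            for _ in range(MAX_ATTEMPTS):
                seq = (
                    _background(spec.flank_length, rng)
                    + window
                    + _background(spec.flank_length, rng)
                )
                if _flanks_are_globular(seq, s0, e0, spec.window_size, scale, rule):
                    break
            else:
                raise GenerationError(
                    f"no globular flanks found in {MAX_ATTEMPTS} attempts"
                )
            start = s0 + 1
        out.append(
            PlantedSequence(
                id=f"{spec.target_class.value}_{spec.seed}_{i}",
                sequence=seq,
                start=start,
                end=start + spec.window_size - 1,
                target_class=spec.target_class,
            )
        )
    return out


def shuffle_null(
    sequence: str, n_shuffles: int, seed: int | np.random.Generator
) -> list[str]:
    """Composition-preserving permutations of *sequence*.

    Mean hydrophobicity and net charge are exactly conserved by every
    shuffle; the hydrophobic moment generally is not, which is what makes
    the null useful for judging amphipathicity.
    """
    if n_shuffles < 1:
        raise InvalidParameterError("n_shuffles must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    letters = np.array(list(sequence))
    return ["".join(rng.permutation(letters)) for _ in range(n_shuffles)]
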