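"""Per-window physicochemical quantities.

For an N-residue window the quantities are

* mean hydrophobicity  ``<H> = (1/N) * sum_n H_n``
* hydrophobic moment   ``<muH> = (1/N) * | sum_n H_n * (cos n*delta, sin n*delta) |``
  with n = 0..N-1 and delta = 100 degrees per residue for an alpha-helix
  (the Eisenberg moment, per-residue normalized)
* net charge           ``z = (#K + #R) - (#D + #E)``
* discrimination factor ``D = 0.944*<muH> + 0.33*z`` — the HeliQuest
  linear score for calling potential lipid-binding helices.

All comparisons downstream use full-precision values; rounding happens
only at report time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, ResidueNotInScaleError
from .scales import DEFAULT_SCALE, HydrophobicityScale

#: Coefficients of the HeliQuest discrimination factor D = a*muH + b*z.
D_MU_COEFF = 0.944
D_Z_COEFF = 0.33

#: Angular periodicity of an ideal alpha-helix, degrees per residue.
ALPHA_HELIX_DELTA = 100.0

DEFAULT_WINDOW_SIZE = 18


@dataclass(frozen=True)
class PeptideWindow:
    """A contiguous stretch of a protein sequence.

    Coordinates are 1-based and inclusive, so ``end - start + 1`` equals
    the sequence length (a span written "66–83" is an 18-mer).
    """

    sequence: str
    parent_id: str = ""
    start: int = 1

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise InvalidParameterError(
                f"window must have at least 2 residues, got {len(self.sequence)}"
            )

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class WindowMetrics:
    """All per-window quantities, computed together by :func:`window_metrics`.

    ``d`` is always ``0.944*muH + 0.33*z``; it is stored for convenience
    but never set independently of ``muH`` and ``z``.
    """

    window: PeptideWindow
    mean_h: float
    mu_h: float
    z: int
    d: float
    delta_deg: float = ALPHA_HELIX_DELTA


def _residue_values(sequence: str, scale: HydrophobicityScale) -> np.ndarray:
    try:
        return np.array([scale.values[c] for c in sequence], dtype=float)
    except KeyError:
        for i, c in enumerate(sequence, start=1):
            if c not in scale.values:
                raise ResidueNotInScaleError(c, i) from None
        raise  # pragma: no cover


def mean_hydrophobicity(
    window: PeptideWindow, scale: HydrophobicityScale = DEFAULT_SCALE
) -> float:
    """Arithmetic mean of per-residue hydrophobicities over the window."""
    return float(_residue_values(window.sequence, scale).mean())


def hydrophobic_moment(
    window: PeptideWindow,
    scale: HydrophobicityScale = DEFAULT_SCALE,
    delta_deg: float = ALPHA_HELIX_DELTA,
) -> float:
    """Per-residue-normalized magnitude of the helical hydrophobicity vector sum.

    Residue n (0-based) sits at angle ``n * delta_deg`` around the helix
    axis; the moment is the magnitude of the vector sum of hydrophobicities
    divided by the window length. It is zero for a hydrophobically uniform
    window whose length closes full turns (e.g. any 18-mer homopolymer at
    100 degrees/residue) and large for an amphipathic one.
    """
    if not 0.0 < delta_deg < 360.0:
        raise InvalidParameterError(
            f"delta_deg must be in (0, 360), got {delta_deg}"
        )
    h = _residue_values(window.sequence, scale)
    angles = np.deg2rad(delta_deg) * np.arange(len(h))
    x = float(np.dot(h, np.cos(angles)))
    y = float(np.dot(h, np.sin(angles)))
    return math.hypot(x, y) / len(h)


def net_charge(
    window: PeptideWindow, scale: HydrophobicityScale = DEFAULT_SCALE
) -> int:
    """Formal net charge: (#K + #R) − (#D + #E); His and termini contribute 0."""
    return sum(scale.charge(c, i) for i, c in enumerate(window.sequence, start=1))


def discrimination_factor(mu_h: float, z: int) -> float:
    """HeliQuest lipid-binding discrimination factor D = 0.944·μH + 0.33·z.

    A window with D above 0.68 is called a potential lipid-binding helix.
    """
    if mu_h < 0:
        raise InvalidParameterError(f"mu_h must be non-negative, got {mu_h}")
    return D_MU_COEFF * mu_h + D_Z_COEFF * z


def window_metrics(
    window: PeptideWindow,
    scale: HydrophobicityScale = DEFAULT_SCALE,
    delta_deg: float = ALPHA_HELIX_DELTA,
) -> WindowMetrics:
    """Compute all four quantities for one window."""
    mu_h = hydrophobic_moment(window, scale, delta_deg)
    z = net_charge(window, scale)
    return WindowMetrics(
        window=window,
        mean_h=mean_hydrophobicity(window, scale),
        mu_h=mu_h,
        z=z,
        d=discrimination_factor(mu_h, z),
        delta_deg=delta_deg,
    )


def neutralized_discrimination_factor(
    window: PeptideWindow,
    scale: HydrophobicityScale = DEFAULT_SCALE,
    n_acidic_neutralized: int = 1,
    delta_deg: float = ALPHA_HELIX_DELTA,
) -> float:
    """D recomputed as if *n* acidic residues lost their negative charge.

    Models charge neutralization of D/E side chains upon binding to
    negatively charged phospholipids: each neutralized acidic residue
    raises z by one while muH is unchanged, so the result exceeds the
    plain D by exactly ``0.33 * n_acidic_neutralized``.
    """
    n_acidic = sum(1 for c in window.sequence if scale.charges.get(c, 0) < 0)
    if not 0 <= n_acidic_neutralized <= n_acidic:
        raise InvalidParameterError(
            f"cannot neutralize {n_acidic_neutralized} acidic residues in a "
            f"window containing {n_acidic}"
        )
    mu_h = hydrophobic_moment(window, scale, delta_deg)
    z = net_charge(window, scale) + n_acidic_neutralized
    return discrimination_factor(mu_h, z)
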