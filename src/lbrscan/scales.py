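"""Hydrophobicity scales and residue formal charges.

The default scale is the Fauchère–Pliška (1983) octanol/water partition
scale as used by the HeliQuest server, with formal charges K/R = +1 and
D/E = −1 (histidine and the termini are taken as neutral; no pH model).
These are the numbers every downstream quantity — mean hydrophobicity,
hydrophobic moment, net charge and the discrimination factor — is
computed from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import FastaParseError, ResidueNotInScaleError

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Residues with no defined scale value; windows containing them are
#: rejected rather than imputed (imputation would silently corrupt D).
NON_CANONICAL = frozenset("BJOUXZ")

_FAUCHERE_PLISKA = {
    "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
    "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
    "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
    "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
}

_FORMAL_CHARGES = {"K": 1, "R": 1, "D": -1, "E": -1}


@dataclass(frozen=True)
class HydrophobicityScale:
    """Per-residue hydrophobicity values plus per-residue formal charges.

    Parameters
    ----------
    name
        Identifier recorded in report headers for provenance.
    values
        One-letter residue code -> hydrophobicity (dimensionless).
        Must cover all 20 canonical residues.
    charges
        One-letter code -> integer formal charge; residues absent from
        this map are neutral.
    """

    name: str
    values: dict[str, float]
    charges: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = CANONICAL_RESIDUES - set(self.values)
        if missing:
            raise ValueError(
                f"scale {self.name!r} lacks values for: {''.join(sorted(missing))}"
            )

    def hydrophobicity(self, residue: str, position: int = 0) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise ResidueNotInScaleError(residue, position) from None

    def charge(self, residue: str, position: int = 0) -> int:
        if residue not in self.values:
            raise ResidueNotInScaleError(residue, position)
        return self.charges.get(residue, 0)

    def covers(self, sequence: str) -> bool:
        """True if every residue of *sequence* has a scale value."""
        return all(c in self.values for c in sequence)

    def shifted(self, constant: float, name: str | None = None) -> "HydrophobicityScale":
        """Return a copy with *constant* added to every hydrophobicity value."""
        return HydrophobicityScale(
            name=name or f"{self.name}+{constant:g}",
            values={k: v + constant for k, v in self.values.items()},
            charges=dict(self.charges),
        )


#: The bundled default: Fauchère–Pliška values as used by HeliQuest.
FAUCHERE_PLISKA = HydrophobicityScale(
    name="fauchere-pliska",
    values=dict(_FAUCHERE_PLISKA),
    charges=dict(_FORMAL_CHARGES),
)

DEFAULT_SCALE = FAUCHERE_PLISKA


def load_scale(path: str | Path, name: str | None = None) -> HydrophobicityScale:
    """Read a scale from a two-column text file.

    Format: one ``RESIDUE VALUE`` pair per line; a line ``[charges]``
    switches to the charge section (``RESIDUE INTEGER`` pairs). Blank
    lines and ``#`` comments are ignored.
    """
    path = Path(path)
    values: dict[str, float] = {}
    charges: dict[str, int] = {}
    section = values
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower() == "[charges]":
            section = charges
            continue
        parts = line.split()
        if len(parts) != 2 or len(parts[0]) != 1:
            raise FastaParseError(f"malformed scale line {raw!r}", line=lineno)
        residue, value = parts[0].upper(), parts[1]
        section[residue] = int(value) if section is charges else float(value)
    return HydrophobicityScale(name=name or path.stem, values=values, charges=charges)


def save_scale(scale: HydrophobicityScale, path: str | Path) -> None:
    """Write *scale* in the format read by :func:`load_scale`."""
    lines = [f"# hydrophobicity scale: {scale.name}"]
    lines += [f"{r} {scale.values[r]}" for r in sorted(scale.values)]
    lines.append("[charges]")
    lines += [f"{r} {c:+d}" for r, c in sorted(scale.charges.items())]
    Path(path).write_text("\n".join(lines) + "\n")
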