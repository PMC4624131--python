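"""Exception hierarchy for lbrscan.

All errors derive from :class:`LbrscanError` so callers can catch the
package's failures with a single except clause; the concrete subclasses
carry enough context (offending residue, position, file line) to be
actionable.
"""

from __future__ import annotations


class LbrscanError(Exception):
    """Base class for all lbrscan errors."""


class ResidueNotInScaleError(LbrscanError, KeyError):
    """A sequence contains a residue with no value in the hydrophobicity scale."""

    def __init__(self, residue: str, position: int) -> None:
        self.residue = residue
        self.position = position  # 1-based within the offending sequence/window
        super().__init__(
            f"residue {residue!r} at position {position} has no value in the scale"
        )


class InvalidParameterError(LbrscanError, ValueError):
    """A numeric parameter is outside its admissible range."""


class SequenceTooShortError(LbrscanError, ValueError):
    """A sequence is shorter than the scanning window."""


class AnnotationMismatchError(LbrscanError, ValueError):
    """A secondary-structure annotation does not match its sequence."""


class EmptyDatasetError(LbrscanError, ValueError):
    """An operation that needs at least one window received none."""


class FastaParseError(LbrscanError, ValueError):
    """A FASTA file is malformed."""

    def __init__(self, message: str, line: int | None = None) -> None:
        self.line = line
        loc = f" (line {line})" if line is not None else ""
        super().__init__(f"{message}{loc}")


class GenerationError(LbrscanError, RuntimeError):
    """Rejection sampling failed to produce a sequence of the requested class."""
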