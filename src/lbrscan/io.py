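"""File I/O: FASTA input, annotation files, TSV reports, wheel coordinates.

Reports are TSV with a commented header block recording the scale, the
helical periodicity, the thresholds and the package version, so every
report is self-describing. Numeric formatting matches the published
precision: <H> and <muH> at 3 decimals, D at 2, z as an integer.
"""

from __future__ import annotations

import enum
import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO

import pandas as pd
from Bio import SeqIO

from . import __version__
from .classify import ClassificationRule, DEFAULT_RULE
from .core import ALPHA_HELIX_DELTA, PeptideWindow
from .errors import FastaParseError
from .scales import DEFAULT_SCALE, HydrophobicityScale
from .scan import MergedRegion, ScanResult

REPORT_COLUMNS = (
    "id", "start", "end", "sequence", "meanH", "muH", "z", "D",
    "labels", "near_flags", "gated",
)


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA; sequences are uppercased, ids verbatim.

    Raises :class:`FastaParseError` (with a line number where it can be
    determined) for files that do not start with a header, contain empty
    records, or duplicate ids.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if not stripped:
        raise FastaParseError("empty FASTA file", line=1)
    if not stripped.startswith(">"):
        first_bad = next(
            i for i, ln in enumerate(text.splitlines(), start=1) if ln.strip()
        )
        raise FastaParseError("expected '>' header before sequence data", line=first_bad)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaParseError(f"record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise FastaParseError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    if not records:
        raise FastaParseError("no records found", line=1)
    return records


def read_annotations(path: str | Path) -> dict[str, str]:
    """Read per-residue {H,E,C} annotation strings keyed by record id.

    Accepts either FASTA-like files (``>id`` then the annotation string)
    or two-column ``id<TAB>annotation`` lines.
    """
    path = Path(path)
    text = path.read_text()
    out: dict[str, str] = {}
    if text.lstrip().startswith(">"):
        for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
            out[rec.id] = str(rec.seq).upper()
    else:
        for lineno, raw in enumerate(text.splitlines(), start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            parts = raw.split()
            if len(parts) != 2:
                raise FastaParseError("expected 'id annotation' pairs", line=lineno)
            out[parts[0]] = parts[1].upper()
    return out


def _fmt_set(values: Iterable[enum.Enum]) -> str:
    items = sorted(str(v) for v in values)
    return ",".join(items) if items else "-"


def _provenance_header(
    scale: HydrophobicityScale, rule: ClassificationRule, delta_deg: float
) -> list[str]:
    return [
        f"# lbrscan {__version__}",
        f"# scale: {scale.name}",
        f"# delta_deg: {delta_deg:g}",
        f"# d_cutoff: {rule.d_cutoff:g}",
        f"# tm_meanH_cutoff: {rule.tm_mean_h_cutoff:g}",
        f"# surface_line: muH = {rule.surface_line_intercept:g} "
        f"{rule.surface_line_slope:+g}*meanH",
        f"# near_band: {rule.near_band:g}",
    ]


def report_rows(
    results: Iterable[ScanResult], merged: bool = False
) -> pd.DataFrame:
    """Tabulate scan results, one row per window (or per merged region)."""
    rows = []
    for res in results:
        if merged:
            for region in res.merged_regions:
                b = region.best_window
                rows.append(_row(res.parent_id, region.start, region.end,
                                 res.sequence[region.start - 1 : region.end],
                                 b.metrics, region.labels, b.near_flags, b.gated))
        else:
            for w in res.windows:
                pw = w.metrics.window
                rows.append(_row(res.parent_id, pw.start, pw.end, pw.sequence,
                                 w.metrics, w.labels, w.near_flags, w.gated))
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def _row(parent_id, start, end, seq, metrics, labels, near, gated):
    return {
        "id": parent_id,
        "start": start,
        "end": end,
        "sequence": seq,
        "meanH": f"{metrics.mean_h:.3f}",
        "muH": f"{metrics.mu_h:.3f}",
        "z": metrics.z,
        "D": f"{metrics.d:.2f}",
        "labels": _fmt_set(labels),
        "near_flags": _fmt_set(near),
        "gated": int(gated),
    }


def write_report(
    df: pd.DataFrame,
    path_or_handle: str | Path | TextIO,
    scale: HydrophobicityScale = DEFAULT_SCALE,
    rule: ClassificationRule = DEFAULT_RULE,
    delta_deg: float = ALPHA_HELIX_DELTA,
) -> None:
    """Write a report DataFrame as TSV with a provenance header block."""
    header = "\n".join(_provenance_header(scale, rule, delta_deg)) + "\n"
    body = df.to_csv(sep="\t", index=False)
    if isinstance(path_or_handle, (str, Path)):
        Path(path_or_handle).write_text(header + body)
    else:
        path_or_handle.write(header + body)


def read_report(path: str | Path) -> pd.DataFrame:
    """Read a TSV report back; numeric columns keep their printed strings
    for meanH/muH/D so that a write/read round trip is exact."""
    return pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"meanH": str, "muH": str, "D": str, "sequence": str,
               "labels": str, "near_flags": str},
    )


# ---------------------------------------------------------------------------
# Helical wheel coordinates

#: Presentation classes for wheel plots; basic/acidic come from the charge
#: map, the polar/nonpolar split is a fixed partition of the neutral rest.
POLAR_RESIDUES = frozenset("STNQCYH")


class ChargeClass(str, enum.Enum):
    BASIC = "basic"
    ACIDIC = "acidic"
    POLAR = "polar"
    NONPOLAR = "nonpolar"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class WheelPoint:
    """One residue on the helical-wheel projection (unit circle)."""

    residue: str
    position_in_window: int  # 1-based
    angle_deg: float         # n*delta mod 360, residue 1 at 0 degrees
    radius: float
    charge_class: ChargeClass


def wheel_coordinates(
    window: PeptideWindow,
    scale: HydrophobicityScale = DEFAULT_SCALE,
    delta_deg: float = ALPHA_HELIX_DELTA,
) -> list[WheelPoint]:
    """Project a window onto the helical wheel: residue n at n*delta degrees.

    Angles increase counter-clockwise with residue 1 at 0 degrees. Windows
    longer than one full revolution (36 residues at 100 degrees) are
    permitted; later residues simply overlap earlier wheel positions.
    """
    points = []
    for n, residue in enumerate(window.sequence):
        charge = scale.charges.get(residue, 0)
        if charge > 0:
            cls = ChargeClass.BASIC
        elif charge < 0:
            cls = ChargeClass.ACIDIC
        elif residue in POLAR_RESIDUES:
            cls = ChargeClass.POLAR
        else:
            cls = ChargeClass.NONPOLAR
        points.append(
            WheelPoint(
                residue=residue,
                position_in_window=n + 1,
                angle_deg=(n * delta_deg) % 360.0,
                radius=1.0,
                charge_class=cls,
            )
        )
    return points


def write_wheel_tsv(points: list[WheelPoint], path_or_handle: str | Path | TextIO) -> None:
    df = pd.DataFrame(
        {
            "position": [p.position_in_window for p in points],
            "residue": [p.residue for p in points],
            "angle_deg": [f"{p.angle_deg:.1f}" for p in points],
            "radius": [f"{p.radius:.2f}" for p in points],
            "charge_class": [str(p.charge_class) for p in points],
        }
    )
    text = df.to_csv(sep="\t", index=False)
    if isinstance(path_or_handle, (str, Path)):
        Path(path_or_handle).write_text(text)
    else:
        path_or_handle.write(text)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    lines = []
    for rec in records:
        lines.append(f">{rec.id}")
        lines.append(rec.sequence)
    Path(path).write_text("\n".join(lines) + "\n")
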