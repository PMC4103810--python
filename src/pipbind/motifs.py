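"""PIP-Box motif scanning over protein sequences.

The PIP Box is the eight-residue PCNA-interaction motif QxxφxxΩΩ (φ any
hydrophobic residue, Ω any aromatic residue, x anything).  Some partners
carry the motif in *reverse* orientation — the reversed eight-residue
window matches the forward pattern (e.g. the Akt kinase) — so the scanner
matches both directions.  Residue classes are configuration, not constants:
published screens differ on whether histidine counts as aromatic and which
residues count as hydrophobic.

Coordinates are 0-based half-open in the API; rendered reports use 1-based
inclusive positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import ParseError, SeriesValidationError

__all__ = [
    "AMINO_ACIDS",
    "HYDROPHOBIC",
    "AROMATIC",
    "MotifPattern",
    "MotifHit",
    "compile_pattern",
    "scan_sequence",
    "scan_fasta",
    "hits_to_frame",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: default hydrophobic class for the φ position (A and C excluded)
HYDROPHOBIC = frozenset("LIMVF")
#: default aromatic class for Ω positions (H excluded)
AROMATIC = frozenset("FYW")

MOTIF_LENGTH = 8


@dataclass(frozen=True)
class MotifPattern:
    """Position-wise allowed-residue pattern of length 8."""

    name: str
    positions: tuple[frozenset, ...]
    orientation: str = "both"  # forward | reverse | both

    def __post_init__(self) -> None:
        if len(self.positions) != MOTIF_LENGTH:
            raise SeriesValidationError(
                f"pattern must have exactly {MOTIF_LENGTH} positions, "
                f"got {len(self.positions)}"
            )
        norm = []
        for i, allowed in enumerate(self.positions):
            allowed = frozenset(str(a).upper() for a in allowed)
            if not allowed:
                raise SeriesValidationError(f"position {i} allows no residues")
            if not allowed <= AMINO_ACIDS:
                raise SeriesValidationError(
                    f"position {i} contains non-amino-acid codes: "
                    f"{sorted(allowed - AMINO_ACIDS)}"
                )
            norm.append(allowed)
        object.__setattr__(self, "positions", tuple(norm))
        if self.orientation not in ("forward", "reverse", "both"):
            raise SeriesValidationError(f"bad orientation {self.orientation!r}")

    def matches(self, window: str) -> bool:
        """Forward match of an 8-residue window against the pattern."""
        if len(window) != MOTIF_LENGTH:
            return False
        return all(c in allowed for c, allowed in zip(window.upper(), self.positions))


@dataclass(frozen=True)
class MotifHit:
    """A single motif match on a sequence.

    ``start`` is a 0-based offset; the hit spans [start, start+8).  For
    reverse hits, the *reversed* window matches the forward pattern;
    ``matched`` is always the substring as it appears in the sequence."""

    sequence_id: str
    start: int
    orientation: str
    matched: str
    pattern_name: str

    @property
    def end(self) -> int:
        return self.start + MOTIF_LENGTH


def compile_pattern(
    preset: str | None = None,
    custom_classes: Sequence[Iterable[str]] | None = None,
    hydrophobic: Iterable[str] = HYDROPHOBIC,
    aromatic: Iterable[str] = AROMATIC,
    orientation: str = "both",
    name: str | None = None,
) -> MotifPattern:
    """Build a PIP-Box pattern.

    ``preset='strict'`` is the canonical QxxφxxΩΩ; ``preset='relaxed'``
    requires only the final aromatic (QxxφxxxΩ), accommodating predicted
    partners such as NEK11 (QLLLGVDY, aspartate at position 7).  Pass
    ``custom_classes`` (8 residue sets) for anything else.
    """
    phi = frozenset(str(a).upper() for a in hydrophobic)
    omega = frozenset(str(a).upper() for a in aromatic)
    any_res = AMINO_ACIDS
    if custom_classes is not None:
        return MotifPattern(name or "custom", tuple(frozenset(c) for c in custom_classes),
                            orientation)
    if preset == "strict":
        positions = (frozenset("Q"), any_res, any_res, phi, any_res, any_res,
                     omega, omega)
    elif preset == "relaxed":
        positions = (frozenset("Q"), any_res, any_res, phi, any_res, any_res,
                     any_res, omega)
    else:
        raise SeriesValidationError(f"unknown preset {preset!r}")
    return MotifPattern(name or preset, positions, orientation)


def scan_sequence(seq: str, pattern: MotifPattern, sequence_id: str = "") -> list[MotifHit]:
    """Report every overlapping window of ``seq`` matching ``pattern``.

    Unknown characters (X, gaps, ...) never match.  Reverse-orientation
    hits are windows whose reversal matches the forward pattern.  Hits are
    sorted by start, forward before reverse at the same offset.
    """
    seq = seq.upper()
    hits: list[MotifHit] = []
    for start in range(len(seq) - MOTIF_LENGTH + 1):
        window = seq[start : start + MOTIF_LENGTH]
        if pattern.orientation in ("forward", "both") and pattern.matches(window):
            hits.append(MotifHit(sequence_id, start, "forward", window, pattern.name))
        if pattern.orientation in ("reverse", "both") and pattern.matches(window[::-1]):
            hits.append(MotifHit(sequence_id, start, "reverse", window, pattern.name))
    hits.sort(key=lambda h: (h.start, h.orientation))
    return hits


def scan_fasta(path, patterns: MotifPattern | Sequence[MotifPattern]) -> list[MotifHit]:
    """Scan every record of a FASTA file with one or more patterns."""
    if isinstance(patterns, MotifPattern):
        patterns = [patterns]
    path = Path(path)
    hits: list[MotifHit] = []
    def _first_bad_line():
        bad = None
        for i, line in enumerate(path.read_text().splitlines()):
            if line.startswith(">"):
                break
            if line.strip():
                bad = i + 1
                break
        return bad

    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except FileNotFoundError as exc:
        raise ParseError(f"cannot read FASTA {path}: {exc}") from exc
    except ValueError as exc:
        bad = _first_bad_line()
        where = f"line {bad}: " if bad is not None else ""
        raise ParseError(f"{path}: {where}malformed FASTA ({exc})") from exc
    if not records:
        bad = _first_bad_line()
        if bad is not None:
            raise ParseError(f"{path}: line {bad}: sequence data before any '>' header")
    for rec in records:
        for pat in patterns:
            hits.extend(scan_sequence(str(rec.seq), pat, sequence_id=rec.id))
    return hits


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    """Tabulate hits (0-based half-open plus 1-based inclusive columns)."""
    return pd.DataFrame(
        [
            {
                "seq_id": h.sequence_id,
                "start0": h.start,
                "end0": h.end,
                "start1": h.start + 1,
                "end1": h.end,
                "orientation": h.orientation,
                "matched": h.matched,
                "pattern": h.pattern_name,
            }
            for h in hits
        ],
        columns=["seq_id", "start0", "end0", "start1", "end1",
                 "orientation", "matched", "pattern"],
    )
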