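"""Reading, sanitizing and windowing protein sequences.

Input handling mirrors a single-sequence submission form: FASTA (one or
more records) or header-less plain text is accepted, invalid characters
(digits, whitespace, ``*``, ``>`` end markers, gaps and any other
symbols) are stripped automatically, and prediction operates on the
C-terminal 14 residues of each sanitized sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AMBIGUITY_CODES, AMINO_ACIDS, WINDOW_WIDTH

__all__ = [
    "ProteinSequence",
    "CTerminalWindow",
    "sanitize_sequence",
    "parse_fasta",
    "write_fasta",
    "extract_cterminal_window",
]

_NON_LETTER = re.compile(r"[^A-Za-z]+")

_VALID_RESIDUES = frozenset(AMINO_ACIDS) | AMBIGUITY_CODES


@dataclass(frozen=True)
class ProteinSequence:
    """A sanitized protein sequence.

    ``residues`` contains only uppercase letters: the 20 canonical
    amino acids plus the ambiguity codes X, B, Z, U, O, J.
    """

    identifier: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(
                f"record {self.identifier!r}: empty sequence after sanitization"
            )
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.identifier!r}: invalid residue letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CTerminalWindow:
    """The final residues of a protein, position -width .. -1.

    Position -1 is the C-terminal residue of the source sequence.
    """

    residues: str
    width: int = field(default=WINDOW_WIDTH)

    def __post_init__(self) -> None:
        if len(self.residues) != self.width:
            raise ValueError(
                f"window must have exactly {self.width} residues, "
                f"got {len(self.residues)}"
            )

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(range(-self.width, 0))

    @property
    def tripeptide(self) -> str:
        """The C-terminal tripeptide (positions -3..-1)."""
        return self.residues[-3:]

    def residue_at(self, position: int) -> str:
        if not -self.width <= position <= -1:
            raise KeyError(position)
        return self.residues[position]

    def __len__(self) -> int:
        return self.width

    def __str__(self) -> str:
        return self.residues


def sanitize_sequence(raw: str) -> str:
    """Strip everything that is not a letter and uppercase the rest.

    Removes digits, whitespace, ``*`` (stop codons), ``>`` C-terminal
    markers, ``-`` gaps and all other symbols.  Idempotent; may return
    an empty string, which callers must handle.
    """
    return _NON_LETTER.sub("", raw).upper()


def parse_fasta(text: str) -> list[ProteinSequence]:
    """Parse FASTA or header-less plain text into sanitized records.

    A text without a ``>`` header is treated as a single sequence with
    the generated identifier ``"query"``.  Record order is preserved.

    Raises :class:`ValueError` on empty input or when a record's body
    is empty after sanitization.
    """
    if not text or not text.strip():
        raise ValueError("no sequence provided")
    if text.lstrip().startswith(">"):
        records = []
        for rec in SeqIO.parse(StringIO(text), "fasta"):
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            records.append(
                ProteinSequence(
                    identifier=rec.id,
                    residues=sanitize_sequence(str(rec.seq)),
                    description=desc,
                )
            )
        if not records:
            raise ValueError("no sequence provided")
        return records
    return [ProteinSequence(identifier="query", residues=sanitize_sequence(text))]


def write_fasta(records: Iterable[ProteinSequence]) -> str:
    """Render records as FASTA text (inverse of :func:`parse_fasta`)."""
    out = StringIO()
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.identifier, description=r.description)
        for r in records
    ]
    SeqIO.write(seq_records, out, "fasta")
    return out.getvalue()


def extract_cterminal_window(
    seq: ProteinSequence | str, width: int = WINDOW_WIDTH
) -> CTerminalWindow:
    """Return the final ``width`` residues as a scoring window.

    Raises :class:`ValueError` (naming the offending length) for
    sequences shorter than ``width``; short sequences are rejected
    rather than padded because the scoring model is defined on exactly
    ``width`` positions.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    name = seq.identifier if isinstance(seq, ProteinSequence) else "sequence"
    if len(residues) < width:
        raise ValueError(
            f"{name}: sequence too short ({len(residues)} residues; "
            f"at least {width} required)"
        )
    return CTerminalWindow(residues[-width:], width=width)
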