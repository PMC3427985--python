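"""Registry of experimentally validated plant PTS1 tripeptides.

A prediction for a sequence ending in a tripeptide that has already
been shown to direct a reporter protein to plant peroxisomes deserves
more trust than one resting on a never-tested tripeptide — especially
when a predicted tripeptide residue is itself novel.  The registry
answers exactly that question for the C-terminal tripeptide of a
query.

The bundled registry (``data/pts1_tripeptides.synthetic.tsv``) is a
synthetic reconstruction assembled from tripeptides individually
reported as validated in the plant PTS1 literature; it is not the
(frequently updated) list distributed by the original web server.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files
from typing import Iterable, Mapping, TextIO

import pandas as pd

from .alphabet import AMINO_ACIDS
from .sequence_io import CTerminalWindow

__all__ = [
    "TripeptideRecord",
    "load_registry",
    "save_registry",
    "default_registry",
    "lookup_tripeptide",
]

_COLUMNS = ("tripeptide", "validated", "canonical", "evidence", "species")

_CANONICAL_LETTERS = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class TripeptideRecord:
    """Validation evidence for one C-terminal tripeptide."""

    tripeptide: str
    validated: bool
    canonical: bool
    evidence: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if len(self.tripeptide) != 3:
            raise ValueError(
                f"tripeptide must have exactly 3 residues, got {self.tripeptide!r}"
            )
        bad = set(self.tripeptide) - _CANONICAL_LETTERS
        if bad:
            raise ValueError(
                f"tripeptide {self.tripeptide!r} has invalid residue letters {sorted(bad)}"
            )
        if self.canonical and not self.validated:
            raise ValueError(
                f"{self.tripeptide}: a canonical tripeptide must be validated"
            )


def _parse_flag(value) -> bool:
    text = str(value).strip().lower()
    if text in ("true", "yes", "1"):
        return True
    if text in ("false", "no", "0"):
        return False
    raise ValueError(f"flag column must be true/false, got {value!r}")


def load_registry(source: str | TextIO) -> dict[str, TripeptideRecord]:
    """Load a tripeptide registry from TSV.

    Expected columns: tripeptide, validated, canonical, evidence,
    species.  ``#`` comment lines are permitted.  Malformed rows,
    invalid residue letters and duplicate tripeptides are rejected.
    """
    frame = pd.read_csv(source, sep="\t", comment="#", dtype=str).fillna("")
    missing = set(_COLUMNS[:3]) - set(frame.columns)
    if missing:
        raise ValueError(f"registry is missing required columns {sorted(missing)}")
    registry: dict[str, TripeptideRecord] = {}
    for _, row in frame.iterrows():
        record = TripeptideRecord(
            tripeptide=str(row["tripeptide"]).strip().upper(),
            validated=_parse_flag(row["validated"]),
            canonical=_parse_flag(row["canonical"]),
            evidence=str(row.get("evidence", "")).strip(),
            species=str(row.get("species", "")).strip(),
        )
        if record.tripeptide in registry:
            raise ValueError(f"duplicate tripeptide {record.tripeptide!r} in registry")
        registry[record.tripeptide] = record
    return registry


def save_registry(
    registry: Mapping[str, TripeptideRecord] | Iterable[TripeptideRecord],
    handle: TextIO,
) -> None:
    """Write a registry as TSV (inverse of :func:`load_registry`)."""
    records = (
        list(registry.values()) if isinstance(registry, Mapping) else list(registry)
    )
    frame = pd.DataFrame(
        [
            {
                "tripeptide": r.tripeptide,
                "validated": str(r.validated).lower(),
                "canonical": str(r.canonical).lower(),
                "evidence": r.evidence,
                "species": r.species,
            }
            for r in records
        ],
        columns=list(_COLUMNS),
    )
    handle.write("# plant PTS1 tripeptide registry\n")
    frame.to_csv(handle, sep="\t", index=False)


def default_registry() -> dict[str, TripeptideRecord]:
    """The bundled (synthetic, reconstructed) validated-tripeptide registry."""
    resource = files("plantpts1").joinpath("data/pts1_tripeptides.synthetic.tsv")
    with resource.open("r") as handle:
        return load_registry(handle)


def lookup_tripeptide(
    registry: Mapping[str, TripeptideRecord], window: CTerminalWindow | str
) -> TripeptideRecord | None:
    """Exact-match lookup of a window's C-terminal tripeptide.

    Returns ``None`` when the tripeptide is not in the registry
    ("unknown": never experimentally tested, as far as the registry
    knows).  A pure function of the last three residues.
    """
    residues = window.residues if isinstance(window, CTerminalWindow) else str(window)
    if len(residues) < 3:
        raise ValueError("window must have at least three residues")
    return registry.get(residues[-3:].upper())
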