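"""Amino-acid alphabet and C-terminal window coordinates.

Window positions are labelled -14 (most upstream) through -1 (the
C-terminal residue).  The PTS1 tripeptide occupies positions -3..-1;
the remaining 11 residues form the upstream region.
"""

from __future__ import annotations

#: The 20 canonical amino-acid one-letter codes, alphabetical.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity / non-standard letters retained through sanitization but
#: resolved (scored neutrally) at scoring time.
AMBIGUITY_CODES: frozenset[str] = frozenset("XBZUOJ")

#: Width of the scored C-terminal window.
WINDOW_WIDTH: int = 14

#: Position labels, upstream to C-terminus.
POSITIONS: tuple[int, ...] = tuple(range(-WINDOW_WIDTH, 0))

#: Positions of the C-terminal tripeptide region.
TRIPEPTIDE_POSITIONS: tuple[int, ...] = (-3, -2, -1)

#: Positions of the upstream region.
UPSTREAM_POSITIONS: tuple[int, ...] = tuple(range(-WINDOW_WIDTH, -3))

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
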