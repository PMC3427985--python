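"""Position weight matrix training, scoring and score interpretation.

The model is a 14-position x 20-residue table of log-odds scores.  A
window's total prediction score is the sum of the 14 entries its
residues select; totals at or above a decision threshold predict a
functional PTS1 (peroxisomal targeting) domain.

The published plant PTS1 server operates a matrix trained on >2,500
spermatophyte PTS1 proteins whose weights were never printed; its
operating constants (threshold 0.412, Arabidopsis proteome score range
1.188 / -1.966, display statistics) are shipped here as
:data:`PUBLISHED`, while :func:`train_pwm` fits fresh matrices from
user-supplied positive examples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

from .alphabet import AMBIGUITY_CODES, AMINO_ACIDS, POSITIONS, WINDOW_WIDTH
from .sequence_io import CTerminalWindow, ProteinSequence, extract_cterminal_window

__all__ = [
    "PWM",
    "ScoreProfile",
    "PublishedConstants",
    "PUBLISHED",
    "PEROXISOMAL",
    "NON_PEROXISOMAL",
    "uniform_background",
    "background_from_windows",
    "train_pwm",
    "score_window",
    "classify_score",
    "pwm_score_bounds",
    "proteome_score_range",
]

#: Decision labels.
PEROXISOMAL = "peroxisomal"
NON_PEROXISOMAL = "non-peroxisomal"


def uniform_background() -> pd.Series:
    """Uniform 1/20 residue background."""
    return pd.Series(1.0 / 20.0, index=list(AMINO_ACIDS), name="background")


def background_from_windows(windows: Iterable[CTerminalWindow | str]) -> pd.Series:
    """Residue background estimated from the pooled composition of windows."""
    counts = pd.Series(0.0, index=list(AMINO_ACIDS))
    total = 0
    for w in windows:
        for aa in str(w):
            if aa in counts.index:
                counts[aa] += 1
                total += 1
    if total == 0:
        raise ValueError("no canonical residues in background windows")
    if (counts == 0).any():
        raise ValueError(
            "background has zero frequency for "
            f"{sorted(counts.index[counts == 0])}; supply more data or use "
            "the uniform background"
        )
    return (counts / total).rename("background")


def _as_background(background: Mapping[str, float] | pd.Series | None) -> pd.Series:
    if background is None:
        return uniform_background()
    bg = pd.Series(background, dtype=float).reindex(list(AMINO_ACIDS))
    if bg.isna().any() or (bg <= 0).any():
        raise ValueError("background must assign a positive frequency to all 20 residues")
    if abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError(f"background frequencies must sum to 1 (got {bg.sum():.12f})")
    return bg.rename("background")


@dataclass(frozen=True)
class PWM:
    """A position weight matrix of log-odds scores.

    ``scores`` is indexed by window position (-14..-1) with one column
    per canonical residue.  ``log_base`` records the logarithm base of
    the entries; ``pseudocount`` and ``n_positive`` record how the
    matrix was estimated (``n_positive`` is 0 for analytic matrices).
    """

    scores: pd.DataFrame
    background: pd.Series
    log_base: float = 10.0
    pseudocount: float = 1.0
    n_positive: int = 0

    def __post_init__(self) -> None:
        expected_index = list(POSITIONS)
        if list(self.scores.index) != expected_index:
            raise ValueError(f"score rows must be positions {expected_index[0]}..-1")
        if list(self.scores.columns) != list(AMINO_ACIDS):
            raise ValueError("score columns must be the 20 canonical residues")
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("all matrix entries must be finite")
        if self.log_base <= 1:
            raise ValueError("log_base must exceed 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        _as_background(self.background)

    @property
    def width(self) -> int:
        return len(self.scores.index)

    def entry(self, position: int, residue: str) -> float:
        """Score of ``residue`` at window ``position`` (-14..-1)."""
        return float(self.scores.at[position, residue])

    # ---- persistence ------------------------------------------------

    def to_tsv(self, handle: TextIO) -> None:
        """Write the matrix as TSV with header comments.

        Layout: '#' metadata lines (log_base, pseudocount, n_positive,
        background), a header row of residue letters, then 14 data rows
        (positions -14..-1).
        """
        handle.write("# plantpts1 position weight matrix (log-odds scores)\n")
        handle.write(
            f"# log_base={self.log_base!r} pseudocount={self.pseudocount!r} "
            f"n_positive={self.n_positive}\n"
        )
        bg = ",".join(repr(float(self.background[a])) for a in AMINO_ACIDS)
        handle.write(f"# background={bg}\n")
        out = self.scores.copy()
        out.index.name = "position"
        out.to_csv(handle, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, handle: TextIO) -> "PWM":
        meta: dict[str, str] = {}
        body: list[str] = []
        for line in handle:
            if line.startswith("#"):
                for token in line[1:].strip().split(" "):
                    if "=" in token:
                        k, v = token.split("=", 1)
                        meta[k] = v
            else:
                body.append(line)
        from io import StringIO

        frame = pd.read_csv(StringIO("".join(body)), sep="\t", index_col="position")
        bg_values = [float(x) for x in meta.get("background", "").split(",")] if meta.get(
            "background"
        ) else [1.0 / 20.0] * 20
        return cls(
            scores=frame[list(AMINO_ACIDS)].astype(float),
            background=pd.Series(bg_values, index=list(AMINO_ACIDS)),
            log_base=float(meta.get("log_base", 10.0)),
            pseudocount=float(meta.get("pseudocount", 1.0)),
            n_positive=int(meta.get("n_positive", 0)),
        )


@dataclass(frozen=True)
class ScoreProfile:
    """Per-position scores of one window and their additive total."""

    window: CTerminalWindow
    per_position: tuple[float, ...]
    total: float
    ambiguous_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.per_position) != self.window.width:
            raise ValueError("one score per window position required")
        if abs(self.total - sum(self.per_position)) > 1e-9:
            raise ValueError("total must equal the sum of per-position scores")


@dataclass(frozen=True)
class PublishedConstants:
    """Operating constants of the published plant PTS1 model.

    The decision threshold was deduced from >2,500 spermatophyte PTS1
    example sequences; the score range is the observed extreme of the
    Arabidopsis proteome; the display statistics drive residue
    highlighting (mean with region-specific standard deviations for the
    tripeptide and the 11 upstream positions).
    """

    decision_threshold: float = 0.412
    arabidopsis_max: float = 1.188
    arabidopsis_min: float = -1.966
    display_mean: float = -0.069
    sd_tripeptide: float = 0.112
    sd_upstream: float = 0.057

    def __post_init__(self) -> None:
        if not self.arabidopsis_min < self.decision_threshold < self.arabidopsis_max:
            raise ValueError("threshold must lie inside the proteome score range")
        if self.sd_tripeptide <= 0 or self.sd_upstream <= 0:
            raise ValueError("standard deviations must be positive")

    @property
    def score_range(self) -> tuple[float, float]:
        return (self.arabidopsis_min, self.arabidopsis_max)


#: Constants printed for the published spermatophyte model.
PUBLISHED = PublishedConstants()


def _coerce_window(w: CTerminalWindow | str) -> CTerminalWindow:
    return w if isinstance(w, CTerminalWindow) else CTerminalWindow(str(w))


def train_pwm(
    positives: Sequence[CTerminalWindow | str],
    background: Mapping[str, float] | pd.Series | None = None,
    pseudocount: float = 1.0,
    log_base: float = 10.0,
) -> PWM:
    """Estimate a log-odds PWM from positive example windows.

    The entry for residue ``a`` at position ``p`` is::

        log_base[ (count(a at p) + pseudocount * bg(a))
                  / (n + pseudocount) / bg(a) ]

    i.e. an additive-pseudocount frequency estimate divided by the
    background frequency.  Deterministic given its inputs.

    Raises :class:`ValueError` for an empty training set, windows that
    are not exactly 14 canonical residues, or a background with a
    non-positive frequency.
    """
    if len(positives) == 0:
        raise ValueError("at least one positive training window is required")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if log_base <= 1:
        raise ValueError("log_base must exceed 1")
    bg = _as_background(background)

    counts = np.zeros((WINDOW_WIDTH, len(AMINO_ACIDS)), dtype=float)
    col = {aa: j for j, aa in enumerate(AMINO_ACIDS)}
    for w in positives:
        window = _coerce_window(w)
        if window.width != WINDOW_WIDTH:
            raise ValueError("training windows must have exactly 14 residues")
        for i, aa in enumerate(window.residues):
            if aa not in col:
                raise ValueError(
                    f"training window {window.residues!r} contains "
                    f"non-canonical residue {aa!r}"
                )
            counts[i, col[aa]] += 1

    n = len(positives)
    bg_row = bg.to_numpy()
    freq = (counts + pseudocount * bg_row) / (n + pseudocount)
    scores = np.log(freq / bg_row) / math.log(log_base)
    frame = pd.DataFrame(scores, index=list(POSITIONS), columns=list(AMINO_ACIDS))
    return PWM(
        scores=frame,
        background=bg,
        log_base=log_base,
        pseudocount=pseudocount,
        n_positive=n,
    )


def score_window(pwm: PWM, window: CTerminalWindow | str) -> ScoreProfile:
    """Score one 14-residue window against a PWM.

    Ambiguity-code residues (X, B, Z, U, O, J) contribute a neutral
    score of 0 at their position and are flagged in
    ``ambiguous_positions`` so a single unknown residue does not void
    the prediction.
    """
    window = _coerce_window(window)
    if window.width != pwm.width:
        raise ValueError(
            f"window width {window.width} does not match matrix width {pwm.width}"
        )
    per: list[float] = []
    ambiguous: list[int] = []
    for pos, aa in zip(window.positions, window.residues):
        if aa in AMBIGUITY_CODES:
            per.append(0.0)
            ambiguous.append(pos)
        else:
            per.append(float(pwm.scores.at[pos, aa]))
    return ScoreProfile(
        window=window,
        per_position=tuple(per),
        total=float(sum(per)),
        ambiguous_positions=tuple(ambiguous),
    )


def classify_score(total: float, threshold: float = PUBLISHED.decision_threshold) -> str:
    """Decision rule: peroxisomal iff ``total >= threshold`` (inclusive)."""
    if not math.isfinite(total):
        raise ValueError(f"total score must be finite, got {total!r}")
    return PEROXISOMAL if total >= threshold else NON_PEROXISOMAL


def pwm_score_bounds(pwm: PWM) -> tuple[float, float]:
    """Attainable (min_total, max_total) over all possible windows."""
    mat = pwm.scores.to_numpy()
    return float(mat.min(axis=1).sum()), float(mat.max(axis=1).sum())


def proteome_score_range(
    pwm: PWM, sequences: Sequence[ProteinSequence | str]
) -> tuple[float, float]:
    """Observed (min, max) total score over a sequence collection.

    The published server displays the analogous Arabidopsis-proteome
    extremes (1.188 / -1.966) as context for a query's total score.
    """
    if len(sequences) == 0:
        raise ValueError("at least one sequence is required")
    totals = [
        score_window(pwm, extract_cterminal_window(s, pwm.width)).total
        for s in sequences
    ]
    return (min(totals), max(totals))
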