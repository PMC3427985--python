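"""Synthetic C-terminal windows with known statistical structure.

The >2,500-sequence spermatophyte training set behind the published
model is not available, so training, calibration and parameter-recovery
tests run on synthetic windows drawn from an explicit generative model:

* the C-terminal tripeptide (positions -3..-1) is drawn from a weight
  table over tripeptides, optionally mixed with a background component
  in which the three residues are drawn independently from the
  background distribution (giving every tripeptide positive
  probability, hence finite analytic log-odds);
* the 11 upstream residues are drawn per position from per-position
  composition tables.

Two sampling modes are provided.  ``balanced`` (default) allocates
per-category counts by largest-remainder stratification — randomized
remainders, independently shuffled columns — so a size-n sample
realizes the nominal composition with O(1/n) discrepancy; this keeps
parameter-recovery diagnostics sharp at moderate n.  ``iid`` draws
plain multinomial samples.  Both are deterministic under a seed.

:func:`true_logodds` returns the analytic log-odds of the generator
against a background — the ground truth that a trained matrix must
recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS, UPSTREAM_POSITIONS, WINDOW_WIDTH
from .pwm import PWM, _as_background
from .sequence_io import CTerminalWindow

__all__ = [
    "GeneratorParams",
    "default_params",
    "generate_positive_windows",
    "generate_negative_windows",
    "marginal_distributions",
    "true_logodds",
]

_N_UPSTREAM = len(UPSTREAM_POSITIONS)


def _uniform_upstream() -> pd.DataFrame:
    return pd.DataFrame(
        1.0 / 20.0, index=list(UPSTREAM_POSITIONS), columns=list(AMINO_ACIDS)
    )


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the positive-window generator.

    ``tripeptide_weights`` is a probability table over tripeptides
    summing to 1; a fraction ``tripeptide_background_weight`` of
    windows instead receives three independent background residues.
    ``upstream_composition`` holds one residue distribution per
    upstream position (-14..-4).
    """

    n: int
    seed: int
    tripeptide_weights: Mapping[str, float]
    upstream_composition: pd.DataFrame = field(default_factory=_uniform_upstream)
    background: pd.Series | None = None
    tripeptide_background_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if not 0.0 <= self.tripeptide_background_weight < 1.0:
            raise ValueError("tripeptide_background_weight must lie in [0, 1)")
        w = np.asarray(list(self.tripeptide_weights.values()), dtype=float)
        if w.size == 0 or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("tripeptide weights must be non-negative and sum to 1")
        for t in self.tripeptide_weights:
            if len(t) != 3 or any(a not in AMINO_ACIDS for a in t):
                raise ValueError(f"invalid tripeptide {t!r} in weight table")
        comp = self.upstream_composition
        if list(comp.index) != list(UPSTREAM_POSITIONS) or list(comp.columns) != list(
            AMINO_ACIDS
        ):
            raise ValueError(
                "upstream_composition must be indexed by positions -14..-4 "
                "with one column per canonical residue"
            )
        rows = comp.to_numpy()
        if (rows < 0).any() or np.abs(rows.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("each upstream position's frequencies must sum to 1")

    @property
    def effective_background(self) -> pd.Series:
        return _as_background(self.background)


def default_params(n: int = 10_000, seed: int = 20120827) -> GeneratorParams:
    """Study-condition defaults for the positive generator.

    The tripeptide positions are heavily enriched for canonical and
    validated non-canonical plant PTS1 tripeptides (SKL-type motifs
    dominate, as in real PTS1 training collections), with 10% of
    windows carrying background tripeptides so every residue remains
    possible at every position.  Upstream positions are near-background
    except -6 and -11, which carry moderate enrichment of basic/small
    residues — the two upstream positions with the widest score range
    in the published model.  Illustrative of PTS1-like structure, not a
    reconstruction of the original training distribution.
    """
    weights = {
        "SKL": 0.30,
        "SRL": 0.10,
        "SRM": 0.08,
        "SKI": 0.08,
        "AKL": 0.08,
        "PKL": 0.06,
        "SKV": 0.05,
        "ARL": 0.05,
        "SSL": 0.04,
        "VKL": 0.04,
        "IKL": 0.04,
        "SEL": 0.03,
        "QRL": 0.03,
        "SYM": 0.02,
    }
    comp = _uniform_upstream()

    def _enrich(position: int, residues: str, mass: float) -> None:
        row = np.full(20, (1.0 - mass) / 20.0)
        for aa in residues:
            row[AMINO_ACIDS.index(aa)] += mass / len(residues)
        comp.loc[position] = row

    _enrich(-6, "RKS", 0.25)
    _enrich(-11, "RK", 0.15)
    return GeneratorParams(
        n=n,
        seed=seed,
        tripeptide_weights=weights,
        upstream_composition=comp,
        tripeptide_background_weight=0.10,
    )


def _stratified_counts(weights: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder allocation of n draws to categories.

    Each category receives floor(n*w) deterministic draws; the
    remaining draws are assigned without replacement with probability
    proportional to the fractional parts.  |count - n*w| < 1 for every
    category.
    """
    exact = weights * n
    base = np.floor(exact).astype(int)
    short = n - int(base.sum())
    if short > 0:
        frac = exact - base
        total = frac.sum()
        if total <= 0:
            extra = rng.choice(len(weights), size=short, replace=False)
        else:
            extra = rng.choice(len(weights), size=short, replace=False, p=frac / total)
        base[extra] += 1
    return base


def _column(
    dist: np.ndarray, n: int, rng: np.random.Generator, method: str
) -> np.ndarray:
    """n residue indices drawn from one per-position distribution."""
    if method == "iid":
        return rng.choice(len(dist), size=n, p=dist)
    counts = _stratified_counts(dist, n, rng)
    col = np.repeat(np.arange(len(dist)), counts)
    rng.shuffle(col)
    return col


def _check_method(method: str) -> None:
    if method not in ("balanced", "iid"):
        raise ValueError(f"sampling method must be 'balanced' or 'iid', got {method!r}")


def generate_positive_windows(
    params: GeneratorParams, method: str = "balanced"
) -> list[CTerminalWindow]:
    """Draw n PTS1-like windows from the generator; seeded, reproducible."""
    _check_method(method)
    rng = np.random.default_rng(params.seed)
    n = params.n
    bg = params.effective_background.to_numpy()
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")

    # Upstream block: one column per position, independently shuffled.
    upstream = np.empty((n, _N_UPSTREAM), dtype="U1")
    for j, pos in enumerate(UPSTREAM_POSITIONS):
        dist = params.upstream_composition.loc[pos].to_numpy()
        upstream[:, j] = aa[_column(dist, n, rng, method)]

    # Tripeptide block: named motifs (joint draw) + background component.
    names = list(params.tripeptide_weights)
    w_bg = params.tripeptide_background_weight
    named_w = np.asarray([params.tripeptide_weights[t] for t in names]) * (1.0 - w_bg)
    full_w = np.append(named_w, w_bg)
    if method == "iid":
        pick = rng.choice(len(full_w), size=n, p=full_w)
        counts = np.bincount(pick, minlength=len(full_w))
    else:
        counts = _stratified_counts(full_w, n, rng)
    n_bg = int(counts[-1])
    tripeptides = [t for t, c in zip(names, counts[:-1]) for _ in range(c)]
    if n_bg:
        block = np.empty((n_bg, 3), dtype="U1")
        for j in range(3):
            block[:, j] = aa[_column(bg, n_bg, rng, method)]
        tripeptides.extend("".join(row) for row in block)
    order = rng.permutation(n)
    tri = np.asarray(tripeptides, dtype="U3")[order]

    return [
        CTerminalWindow("".join(upstream[i]) + tri[i]) for i in range(n)
    ]


def generate_negative_windows(
    n: int,
    seed: int,
    background: Mapping[str, float] | pd.Series | None = None,
    method: str = "balanced",
) -> list[CTerminalWindow]:
    """n windows of 14 residues drawn from the background distribution."""
    if n < 1:
        raise ValueError("n must be at least 1")
    _check_method(method)
    bg = _as_background(background).to_numpy()
    rng = np.random.default_rng(seed)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    block = np.empty((n, WINDOW_WIDTH), dtype="U1")
    for j in range(WINDOW_WIDTH):
        block[:, j] = aa[_column(bg, n, rng, method)]
    return [CTerminalWindow("".join(row)) for row in block]


def marginal_distributions(params: GeneratorParams) -> pd.DataFrame:
    """Per-position residue probabilities implied by the generator."""
    bg = params.effective_background
    w_bg = params.tripeptide_background_weight
    rows: dict[int, pd.Series] = {}
    for pos in UPSTREAM_POSITIONS:
        rows[pos] = params.upstream_composition.loc[pos]
    for offset, pos in enumerate((-3, -2, -1)):
        marg = pd.Series(0.0, index=list(AMINO_ACIDS))
        for tri, w in params.tripeptide_weights.items():
            marg[tri[offset]] += w * (1.0 - w_bg)
        rows[pos] = marg + w_bg * bg
    return pd.DataFrame(rows).T.reindex(range(-WINDOW_WIDTH, 0))


def true_logodds(
    params: GeneratorParams,
    background: Mapping[str, float] | pd.Series | None = None,
    log_base: float = 10.0,
) -> PWM:
    """Analytic log-odds of the generating distribution vs a background.

    Ground truth for parameter-recovery tests: entries are
    ``log_base(p(a at pos) / bg(a))``.  Raises if any residue has zero
    probability at some position (the log-odds would be infinite);
    supply a positive ``tripeptide_background_weight`` to avoid this.
    """
    bg = _as_background(background if background is not None else params.background)
    marg = marginal_distributions(params)
    if (marg.to_numpy() <= 0).any():
        raise ValueError(
            "generator assigns zero probability to some residue/position; "
            "analytic log-odds would be infinite"
        )
    scores = np.log(marg.to_numpy() / bg.to_numpy()) / np.log(log_base)
    return PWM(
        scores=pd.DataFrame(
            scores, index=list(range(-WINDOW_WIDTH, 0)), columns=list(AMINO_ACIDS)
        ),
        background=bg,
        log_base=log_base,
        pseudocount=1.0,
        n_positive=0,
    )
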