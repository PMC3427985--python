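"""Published worked examples shipped as fixtures.

The server publication prints, for ten experimentally validated
Arabidopsis proteins with non-canonical PTS1 tripeptides, the
C-terminal 14-mer, the total prediction score and the targeting
probability assigned by the published model, together with the
resulting decision.  Because the trained matrix behind those numbers
was never published, the records are fixture *inputs*: they anchor the
decision rule (6/10 peroxisomal at threshold 0.412), the coherence of
printed probabilities with the threshold, and the empirical
score-to-probability curve.

Also bundled: the published worked-example splice variants of the
At1g18700 DNAJ-domain protein, whose alternative C-termini receive
totals of -1.298 (At1g18700.1/3/4, ...DSD) and 0.440 (At1g18700.2,
...QRL) from the published matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files

import pandas as pd

__all__ = [
    "BenchmarkRecord",
    "load_benchmark",
    "benchmark_dataframe",
    "benchmark_pairs",
    "WORKED_EXAMPLE",
]

#: Published worked example: the At1g18700 splice variants.  Keys are
#: variant labels; values are (C-terminal 14-mer, published total score).
WORKED_EXAMPLE: dict[str, tuple[str, float]] = {
    "At1g18700.1/3/4": ("KDAVQILSSGSDSD", -1.298),
    "At1g18700.2": ("ILSSVRSMKGFQRL", 0.440),
}


@dataclass(frozen=True)
class BenchmarkRecord:
    """One published benchmark row."""

    agi: str
    acronym: str
    cterm14: str
    experimental: str
    score: float
    probability: float
    decision: str

    def __post_init__(self) -> None:
        if len(self.cterm14) != 14:
            raise ValueError(
                f"{self.agi}: C-terminal window must have 14 residues, "
                f"got {len(self.cterm14)}"
            )


def benchmark_dataframe() -> pd.DataFrame:
    """The benchmark table as a DataFrame."""
    resource = files("plantpts1").joinpath("data/arabidopsis_noncanonical_benchmark.tsv")
    with resource.open("r") as handle:
        return pd.read_csv(handle, sep="\t", comment="#")


def load_benchmark() -> list[BenchmarkRecord]:
    """The ten published benchmark records, transcribed verbatim."""
    return [
        BenchmarkRecord(
            agi=row.agi,
            acronym=row.acronym,
            cterm14=row.cterm14,
            experimental=row.experimental,
            score=float(row.score),
            probability=float(row.probability),
            decision=row.decision,
        )
        for row in benchmark_dataframe().itertuples(index=False)
    ]


def benchmark_pairs() -> list[tuple[float, float]]:
    """(score, probability) pairs for empirical curve fitting."""
    return [(r.score, r.probability) for r in load_benchmark()]
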