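"""Per-sequence prediction reports and ortholog-consensus summaries.

:func:`predict_report` assembles everything the original server's
result page displays for one sequence: the C-terminal 14-mer with
per-position scores and enhancing/inhibiting flags, the total score
against the decision threshold and a context score range, the decision,
both posterior probabilities, and the validation status of the
C-terminal tripeptide.

:func:`consensus_summary` operationalizes the ortholog plausibility
check: peroxisome targeting by the PTS1 pathway is generally conserved
among orthologs, so an ambiguous prediction is strengthened when most
members of a user-supplied putative-ortholog set are predicted
peroxisomal, and weakened when few are.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

from .calibration import CalibrationModel, format_percent, posterior_probability
from .highlighting import FLAG_SYMBOLS, RegionStats, highlight_profile
from .pwm import (
    PEROXISOMAL,
    PWM,
    PublishedConstants,
    classify_score,
    score_window,
)
from .registry import TripeptideRecord, lookup_tripeptide
from .sequence_io import CTerminalWindow, ProteinSequence, extract_cterminal_window

__all__ = [
    "PredictionReport",
    "ConsensusSummary",
    "predict_report",
    "consensus_summary",
    "render_report",
    "report_from_json",
]

SUPPORTED = "supported"
AMBIGUOUS = "ambiguous"
CONTRADICTED = "contradicted"


@dataclass(frozen=True)
class PredictionReport:
    """Complete prediction output for one sequence."""

    identifier: str
    window: str
    per_position: tuple[float, ...]
    flags: tuple[str, ...]
    total: float
    threshold: float
    decision: str
    score_range: tuple[float, float] | None = None
    probability_original: float | None = None
    probability_balanced: float | None = None
    tripeptide: str = ""
    tripeptide_record: TripeptideRecord | None = None
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.decision != classify_score(self.total, self.threshold):
            raise ValueError("decision is inconsistent with total vs threshold")
        for p in (self.probability_original, self.probability_balanced):
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def tripeptide_status(self) -> str:
        if self.tripeptide_record is None:
            return "not experimentally verified"
        kind = "canonical" if self.tripeptide_record.canonical else "non-canonical"
        return f"experimentally verified ({kind})"


@dataclass(frozen=True)
class ConsensusSummary:
    """Vote over predictions for a set of putative orthologs."""

    n_sequences: int
    n_predicted_peroxisomal: int
    n_validated_tripeptides: int
    fraction_predicted: float
    verdict: str

    def __post_init__(self) -> None:
        if not 0 <= self.n_predicted_peroxisomal <= self.n_sequences:
            raise ValueError("peroxisomal count out of range")
        expected = self.n_predicted_peroxisomal / self.n_sequences
        if abs(self.fraction_predicted - expected) > 1e-12:
            raise ValueError("fraction inconsistent with counts")


def predict_report(
    seq: ProteinSequence,
    pwm: PWM,
    calibrations: Mapping[str, CalibrationModel] | None = None,
    stats: tuple[RegionStats, RegionStats] | None = None,
    registry: Mapping[str, TripeptideRecord] | None = None,
    threshold: float | None = None,
    score_range: tuple[float, float] | None = None,
    constants: PublishedConstants | None = None,
) -> PredictionReport:
    """Assemble the full prediction report for one sequence.

    ``constants`` switches on published-constants mode: the decision
    threshold, context score range and highlighting statistics default
    to the published model's values (explicit arguments still win).
    ``calibrations`` maps scheme name ('original'/'balanced') to a
    fitted :class:`CalibrationModel`.  Component errors propagate with
    the sequence identifier attached.
    """
    if constants is not None:
        if threshold is None:
            threshold = constants.decision_threshold
        if score_range is None:
            score_range = constants.score_range
        if stats is None:
            from .highlighting import published_region_stats

            stats = published_region_stats(constants)
    if threshold is None:
        threshold = PublishedConstants().decision_threshold

    try:
        window = extract_cterminal_window(seq, pwm.width)
        profile = score_window(pwm, window)
        if stats is None:
            from .highlighting import compute_region_stats

            stats = compute_region_stats(pwm)
        flags = highlight_profile(profile, stats)
        warnings: list[str] = []
        if profile.ambiguous_positions:
            warnings.append(
                "ambiguity codes scored neutrally at positions "
                + ", ".join(str(p) for p in profile.ambiguous_positions)
            )
        probs: dict[str, float | None] = {"original": None, "balanced": None}
        if calibrations:
            for scheme, model in calibrations.items():
                probs[scheme] = float(posterior_probability(model, profile.total))
        record = lookup_tripeptide(registry, window) if registry is not None else None
        return PredictionReport(
            identifier=seq.identifier,
            window=window.residues,
            per_position=profile.per_position,
            flags=tuple(flags),
            total=profile.total,
            threshold=threshold,
            decision=classify_score(profile.total, threshold),
            score_range=score_range,
            probability_original=probs["original"],
            probability_balanced=probs["balanced"],
            tripeptide=window.tripeptide,
            tripeptide_record=record,
            warnings=tuple(warnings),
        )
    except ValueError as exc:
        raise ValueError(f"{seq.identifier}: {exc}") from exc


def consensus_summary(
    reports: Sequence[PredictionReport], support_fraction: float = 0.5
) -> ConsensusSummary:
    """Majority vote over a putative-ortholog set.

    supported iff fraction predicted peroxisomal > ``support_fraction``;
    contradicted iff fraction < 1 - ``support_fraction``; otherwise
    ambiguous (ties land here).
    """
    if len(reports) == 0:
        raise ValueError("at least one report is required")
    n = len(reports)
    n_pos = sum(1 for r in reports if r.decision == PEROXISOMAL)
    n_val = sum(
        1
        for r in reports
        if r.tripeptide_record is not None and r.tripeptide_record.validated
    )
    fraction = n_pos / n
    if fraction > support_fraction:
        verdict = SUPPORTED
    elif fraction < 1.0 - support_fraction:
        verdict = CONTRADICTED
    else:
        verdict = AMBIGUOUS
    return ConsensusSummary(
        n_sequences=n,
        n_predicted_peroxisomal=n_pos,
        n_validated_tripeptides=n_val,
        fraction_predicted=fraction,
        verdict=verdict,
    )


def _report_to_dict(report: PredictionReport) -> dict:
    data = asdict(report)
    data["tripeptide_status"] = report.tripeptide_status
    return data


def report_from_json(text: str) -> PredictionReport:
    """Rebuild a report from its JSON rendering (lossless round trip)."""
    data = json.loads(text)
    data.pop("tripeptide_status", None)
    record = data.pop("tripeptide_record", None)
    return PredictionReport(
        **{
            **data,
            "per_position": tuple(data["per_position"]),
            "flags": tuple(data["flags"]),
            "warnings": tuple(data["warnings"]),
            "score_range": tuple(data["score_range"]) if data["score_range"] else None,
            "tripeptide_record": TripeptideRecord(**record) if record else None,
        }
    )


def _render_text(report: PredictionReport) -> str:
    lines = [f"Prediction report for {report.identifier}", ""]
    lines.append(f"C-terminal 14 aa:       {report.window}")
    lines.append("")
    lines.append("pos  aa  score    flag")
    positions = range(-len(report.window), 0)
    for pos, aa, score, flag in zip(
        positions, report.window, report.per_position, report.flags
    ):
        symbol = FLAG_SYMBOLS.get(flag, "?")
        lines.append(f"{pos:>3}  {aa}   {score:>7.3f}  {symbol} {flag}")
    lines.append("")
    lines.append(f"total prediction score: {report.total:.3f}")
    context = (
        f" (range {report.score_range[0]:.3f} .. {report.score_range[1]:.3f})"
        if report.score_range
        else ""
    )
    lines.append(f"decision threshold:     {report.threshold:.3f}{context}")
    lines.append(f"prediction:             {report.decision}")
    if report.probability_original is not None:
        lines.append(
            f"targeting probability:  {format_percent(report.probability_original)}"
            + (
                f" (balanced: {format_percent(report.probability_balanced)})"
                if report.probability_balanced is not None
                else ""
            )
        )
    elif report.probability_balanced is not None:
        lines.append(
            f"targeting probability (balanced): "
            f"{format_percent(report.probability_balanced)}"
        )
    lines.append(f"C-terminal tripeptide:  {report.tripeptide} — {report.tripeptide_status}")
    for w in report.warnings:
        lines.append(f"warning: {w}")
    return "\n".join(lines) + "\n"


_TSV_FIELDS = (
    "identifier",
    "window",
    "tripeptide",
    "total",
    "threshold",
    "decision",
    "probability_original",
    "probability_balanced",
    "tripeptide_status",
)


def _render_tsv(report: PredictionReport, header: bool = True) -> str:
    row = {f: getattr(report, f, None) for f in _TSV_FIELDS}
    row["tripeptide_status"] = report.tripeptide_status
    values = ["" if row[f] is None else str(row[f]) for f in _TSV_FIELDS]
    out = ("\t".join(_TSV_FIELDS) + "\n") if header else ""
    return out + "\t".join(values) + "\n"


def render_report(report: PredictionReport, format: str = "text") -> str:
    """Render a report as 'text', 'json' (lossless) or 'tsv'."""
    if format == "text":
        return _render_text(report)
    if format == "json":
        return json.dumps(_report_to_dict(report))
    if format == "tsv":
        return _render_tsv(report)
    raise ValueError(f"unknown report format {format!r}")
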