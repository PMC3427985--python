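"""Prediction reports, rendering and ortholog consensus."""

import json

import pytest

from plantpts1.calibration import fit_gaussian_calibration
from plantpts1.pwm import NON_PEROXISOMAL, PEROXISOMAL, PUBLISHED, classify_score
from plantpts1.registry import default_registry
from plantpts1.report import (
    AMBIGUOUS,
    CONTRADICTED,
    SUPPORTED,
    PredictionReport,
    consensus_summary,
    predict_report,
    render_report,
    report_from_json,
)
from plantpts1.sequence_io import ProteinSequence
from tests.conftest import make_random_pwm


@pytest.fixture
def calibrations(rng):
    pos = rng.normal(1.2, 0.4, size=500)
    neg = rng.normal(-1.0, 0.7, size=500)
    return {
        "original": fit_gaussian_calibration(pos, neg, "original"),
        "balanced": fit_gaussian_calibration(pos, neg, "balanced"),
    }


@pytest.fixture
def report(rng, calibrations):
    pwm = make_random_pwm(rng)
    seq = ProteinSequence("At1g18700.2", "MKTAYVQQQILSSVRSMKGFQRL")
    return predict_report(
        seq,
        pwm,
        calibrations=calibrations,
        registry=default_registry(),
        threshold=0.0,
    )


class TestPredictReport:
    def test_decision_matches_threshold_rule(self, report):
        assert report.decision == classify_score(report.total, report.threshold)

    def test_both_probabilities_present_and_bounded(self, report):
        assert 0.0 <= report.probability_original <= 1.0
        assert 0.0 <= report.probability_balanced <= 1.0

    def test_validated_tripeptide_evidence_attached(self, report):
        assert report.tripeptide == "QRL"
        assert report.tripeptide_record is not None
        assert report.tripeptide_status.startswith("experimentally verified")

    def test_unknown_tripeptide_reported_as_unverified(self, rng):
        pwm = make_random_pwm(rng)
        seq = ProteinSequence("At1g18700.1", "MKTAYVKDAVQILSSGSDSD")
        rep = predict_report(pwm=pwm, seq=seq, registry=default_registry())
        assert rep.tripeptide == "DSD"
        assert rep.tripeptide_record is None
        assert rep.tripeptide_status == "not experimentally verified"

    def test_fourteen_residue_input_is_its_own_window(self, rng):
        pwm = make_random_pwm(rng)
        seq = ProteinSequence("w", "ILSSVRSMKGFQRL")
        rep = predict_report(seq, pwm, threshold=0.0)
        assert rep.window == seq.residues

    def test_published_constants_mode_sets_threshold_and_range(self, rng):
        pwm = make_random_pwm(rng)
        seq = ProteinSequence("q", "A" * 20)
        rep = predict_report(seq, pwm, constants=PUBLISHED)
        assert rep.threshold == PUBLISHED.decision_threshold
        assert rep.score_range == (PUBLISHED.arabidopsis_min, PUBLISHED.arabidopsis_max)

    def test_ambiguity_codes_produce_warning(self, rng):
        pwm = make_random_pwm(rng)
        seq = ProteinSequence("amb", "MKTAYVQQQILSXVRSMKGFQRL")
        rep = predict_report(seq, pwm, threshold=0.0)
        assert any("ambiguity" in w for w in rep.warnings)

    def test_short_sequence_error_names_the_sequence(self, rng):
        pwm = make_random_pwm(rng)
        with pytest.raises(ValueError, match="tiny.*too short"):
            predict_report(ProteinSequence("tiny", "MSKL"), pwm, threshold=0.0)

    def test_inconsistent_decision_rejected_at_construction(self, report):
        with pytest.raises(ValueError, match="inconsistent"):
            PredictionReport(
                identifier="x",
                window=report.window,
                per_position=report.per_position,
                flags=report.flags,
                total=report.total,
                threshold=report.threshold,
                decision=(
                    NON_PEROXISOMAL if report.decision == PEROXISOMAL else PEROXISOMAL
                ),
            )


class TestRendering:
    def test_text_mode_lists_exactly_14_position_lines(self, report):
        text = render_report(report, "text")
        position_lines = [
            line for line in text.splitlines() if line.strip().startswith("-")
        ]
        assert len(position_lines) == 14

    def test_text_mode_formats_probabilities_as_one_decimal_percent(self, report):
        object.__setattr__(report, "probability_original", 0.666)
        object.__setattr__(report, "probability_balanced", 0.945)
        text = render_report(report, "text")
        assert "66.6%" in text and "94.5%" in text

    def test_json_round_trip_is_lossless(self, report):
        assert report_from_json(render_report(report, "json")) == report

    def test_json_is_deterministic_for_identical_inputs(self, rng, calibrations):
        pwm = make_random_pwm(rng)
        seq = ProteinSequence("s", "MKTAYVQQQILSSVRSMKGFQRL")
        kwargs = dict(
            calibrations=calibrations, registry=default_registry(), threshold=0.1
        )
        first = render_report(predict_report(seq, pwm, **kwargs), "json")
        second = render_report(predict_report(seq, pwm, **kwargs), "json")
        assert first == second

    def test_tsv_mode_has_header_and_one_row(self, report):
        lines = render_report(report, "tsv").strip().splitlines()
        assert len(lines) == 2
        header = lines[0].split("\t")
        row = dict(zip(header, lines[1].split("\t")))
        assert row["identifier"] == report.identifier
        assert float(row["total"]) == pytest.approx(report.total)
        assert row["decision"] == report.decision

    def test_unknown_format_rejected(self, report):
        with pytest.raises(ValueError, match="unknown report format"):
            render_report(report, "xml")

    def test_json_probabilities_parse_back_to_unit_interval(self, report):
        data = json.loads(render_report(report, "json"))
        assert 0.0 <= data["probability_original"] <= 1.0
        assert 0.0 <= data["probability_balanced"] <= 1.0


def _vote_report(identifier, total, threshold=0.0, tripeptide="AAA"):
    return PredictionReport(
        identifier=identifier,
        window="A" * 11 + tripeptide,
        per_position=(total / 14.0,) * 14,
        flags=("neutral",) * 14,
        total=total,
        threshold=threshold,
        decision=classify_score(total, threshold),
        tripeptide=tripeptide,
    )


class TestConsensusSummary:
    def test_four_of_five_supported(self):
        reports = [_vote_report(f"s{i}", 1.0) for i in range(4)]
        reports.append(_vote_report("s4", -1.0))
        summary = consensus_summary(reports)
        assert summary.fraction_predicted == pytest.approx(0.8)
        assert summary.verdict == SUPPORTED

    def test_none_of_five_contradicted(self):
        reports = [_vote_report(f"s{i}", -1.0) for i in range(5)]
        summary = consensus_summary(reports)
        assert summary.n_predicted_peroxisomal == 0
        assert summary.verdict == CONTRADICTED

    def test_tie_is_ambiguous(self):
        reports = [_vote_report(f"s{i}", 1.0 if i < 2 else -1.0) for i in range(4)]
        assert consensus_summary(reports, support_fraction=0.5).verdict == AMBIGUOUS

    def test_validated_tripeptides_counted(self, rng):
        from plantpts1.registry import lookup_tripeptide

        registry = default_registry()
        reports = []
        for i, tri in enumerate(["SKL", "QRL", "DSD"]):
            rep = _vote_report(f"s{i}", 1.0, tripeptide=tri)
            object.__setattr__(rep, "tripeptide_record", lookup_tripeptide(registry, rep.window))
            reports.append(rep)
        assert consensus_summary(reports).n_validated_tripeptides == 2

    def test_empty_report_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            consensus_summary([])
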