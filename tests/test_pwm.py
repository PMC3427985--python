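"""PWM training, scoring, classification and score ranges."""

import io
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plantpts1 import synthetic
from plantpts1.alphabet import AMINO_ACIDS, POSITIONS
from plantpts1.pwm import (
    NON_PEROXISOMAL,
    PEROXISOMAL,
    PUBLISHED,
    PWM,
    classify_score,
    proteome_score_range,
    pwm_score_bounds,
    score_window,
    train_pwm,
    uniform_background,
)
from tests.conftest import make_random_pwm, make_random_window


class TestTrainPwm:
    def test_single_homopolymer_window_enriches_that_residue_everywhere(self):
        pwm = train_pwm(["A" * 14], pseudocount=1.0)
        assert (pwm.scores["A"] > 0).all()
        assert (pwm.scores["C"] < 0).all()

    def test_background_composition_training_set_gives_near_zero_scores(self):
        # 20 windows realizing the uniform background exactly at every position
        windows = ["".join(AMINO_ACIDS[(i + k) % 20] for i in range(14)) for k in range(20)]
        pwm = train_pwm(windows, pseudocount=1.0)
        assert np.abs(pwm.scores.to_numpy()).max() < 1e-12

    def test_matches_estimator_formula_by_hand(self):
        # 4 windows, position -14: A,A,A,C. bg uniform, pseudocount 2.
        windows = ["A" * 14, "A" * 14, "A" * 14, "C" + "A" * 13]
        pwm = train_pwm(windows, pseudocount=2.0, log_base=10.0)
        expected_a = math.log10((3 + 2 * 0.05) / (4 + 2) / 0.05)
        expected_g = math.log10((0 + 2 * 0.05) / (4 + 2) / 0.05)
        assert pwm.entry(-14, "A") == pytest.approx(expected_a, abs=1e-12)
        assert pwm.entry(-14, "G") == pytest.approx(expected_g, abs=1e-12)

    def test_recovers_generator_logodds_at_large_n(self):
        params = synthetic.default_params(n=10_000, seed=91)
        truth = synthetic.true_logodds(params)
        trained = train_pwm(synthetic.generate_positive_windows(params))
        err = np.abs(trained.scores.to_numpy() - truth.scores.to_numpy()).max()
        assert err < 0.05

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            train_pwm([])

    def test_zero_background_frequency_rejected(self):
        bg = uniform_background()
        bg["A"] = 0.0
        bg["C"] = 0.1
        with pytest.raises(ValueError, match="positive frequency"):
            train_pwm(["A" * 14], background=bg)

    def test_ambiguity_codes_rejected_in_training(self):
        with pytest.raises(ValueError, match="non-canonical"):
            train_pwm(["X" + "A" * 13])


class TestScoreWindow:
    def test_single_entry_pwm_sums_that_entry(self, random_pwm):
        scores = random_pwm.scores * 0.0
        scores.at[-1, "L"] = 0.3
        pwm = PWM(scores=scores, background=random_pwm.background)
        profile = score_window(pwm, "A" * 13 + "L")
        assert profile.total == pytest.approx(0.3)
        assert profile.per_position[-1] == pytest.approx(0.3)

    def test_totals_match_loop_oracle_exactly(self, rng):
        for _ in range(100):
            pwm = make_random_pwm(rng)
            window = make_random_window(rng)
            profile = score_window(pwm, window)
            oracle = 0.0
            for pos, aa in zip(POSITIONS, window):
                oracle += pwm.scores.at[pos, aa]
            assert profile.total == oracle

    def test_ambiguity_codes_score_zero_and_are_flagged(self, random_pwm):
        window = "AX" + "A" * 11 + "L"
        profile = score_window(random_pwm, window)
        assert profile.per_position[1] == 0.0
        assert profile.ambiguous_positions == (-13,)

    def test_monotone_response_to_a_single_entry(self, random_pwm):
        window = make_random_window(np.random.default_rng(5))
        before = score_window(random_pwm, window).total
        scores = random_pwm.scores.copy()
        scores.at[-1, window[-1]] += 0.5
        bumped = PWM(scores=scores, background=random_pwm.background)
        assert score_window(bumped, window).total > before


class TestClassifyScore:
    @pytest.mark.parametrize(
        "total, expected",
        [
            (0.440, PEROXISOMAL),
            (-1.298, NON_PEROXISOMAL),
            (0.412, PEROXISOMAL),  # boundary is inclusive
            (0.41199999, NON_PEROXISOMAL),
        ],
    )
    def test_published_threshold_decisions(self, total, expected):
        assert classify_score(total) == expected

    def test_non_finite_total_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            classify_score(float("nan"))

    @given(st.floats(-5, 5), st.floats(-2, 2))
    def test_decision_rule_is_inclusive_threshold(self, total, threshold):
        decision = classify_score(total, threshold)
        assert (decision == PEROXISOMAL) == (total >= threshold)


class TestScoreBounds:
    def test_all_zero_matrix_has_zero_bounds(self, random_pwm):
        pwm = PWM(scores=random_pwm.scores * 0.0, background=random_pwm.background)
        assert pwm_score_bounds(pwm) == (0.0, 0.0)

    def test_constant_per_position_extremes(self, random_pwm):
        scores = random_pwm.scores * 0.0
        scores["A"] = 0.2
        scores["C"] = -0.1
        pwm = PWM(scores=scores, background=random_pwm.background)
        assert pwm_score_bounds(pwm) == (pytest.approx(-1.4), pytest.approx(2.8))

    def test_bounds_match_brute_force_and_contain_all_windows(self, rng):
        pwm = make_random_pwm(rng)
        lo = sum(min(pwm.entry(p, a) for a in AMINO_ACIDS) for p in POSITIONS)
        hi = sum(max(pwm.entry(p, a) for a in AMINO_ACIDS) for p in POSITIONS)
        bounds = pwm_score_bounds(pwm)
        assert bounds == (pytest.approx(lo), pytest.approx(hi))
        for _ in range(50):
            total = score_window(pwm, make_random_window(rng)).total
            assert bounds[0] - 1e-9 <= total <= bounds[1] + 1e-9


class TestProteomeScoreRange:
    def test_single_sequence_range_is_degenerate(self, random_pwm, rng):
        seq = make_random_window(rng)
        t = score_window(random_pwm, seq).total
        assert proteome_score_range(random_pwm, [seq]) == (t, t)

    def test_matches_sorted_totals(self, random_pwm, rng):
        seqs = [make_random_window(rng) for _ in range(50)]
        totals = sorted(score_window(random_pwm, s).total for s in seqs)
        assert proteome_score_range(random_pwm, seqs) == (totals[0], totals[-1])

    def test_empty_collection_rejected(self, random_pwm):
        with pytest.raises(ValueError, match="at least one"):
            proteome_score_range(random_pwm, [])


class TestPublishedConstants:
    def test_threshold_sits_inside_arabidopsis_range(self):
        assert PUBLISHED.arabidopsis_min < PUBLISHED.decision_threshold
        assert PUBLISHED.decision_threshold < PUBLISHED.arabidopsis_max

    def test_region_sds_positive(self):
        assert PUBLISHED.sd_tripeptide > 0 and PUBLISHED.sd_upstream > 0


def test_pwm_tsv_round_trip(rng):
    pwm = make_random_pwm(rng)
    buffer = io.StringIO()
    pwm.to_tsv(buffer)
    buffer.seek(0)
    again = PWM.from_tsv(buffer)
    np.testing.assert_allclose(
        again.scores.to_numpy(), pwm.scores.to_numpy(), atol=1e-9
    )
    assert again.log_base == pwm.log_base
    assert again.pseudocount == pwm.pseudocount
    assert again.n_positive == pwm.n_positive
    np.testing.assert_allclose(again.background, pwm.background, atol=1e-12)
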