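"""Model/results facade over the full prediction pipeline.

`PlantPTS1Model` bundles the training inputs (positive PTS1 windows,
optional negative windows, background, estimator settings); `fit()`
trains the position weight matrix, fits both posterior calibrations
when negatives are available, derives the decision threshold and
highlighting statistics, and returns a `PlantPTS1Results` that predicts
and summarizes — in the spirit of the model/results split used by
statistical modelling packages.

>>> from plantpts1 import synthetic
>>> from plantpts1.model import PlantPTS1Model
>>> params = synthetic.default_params(n=500, seed=7)
>>> pos = synthetic.generate_positive_windows(params)
>>> neg = synthetic.generate_negative_windows(500, 8)
>>> results = PlantPTS1Model(pos, neg).fit()
>>> print(results.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .calibration import (
    CalibrationModel,
    balanced_logistic,
    fit_gaussian_calibration,
)
from .highlighting import RegionStats, compute_region_stats
from .pwm import (
    PWM,
    pwm_score_bounds,
    score_window,
    train_pwm,
)
from .registry import TripeptideRecord, default_registry
from .report import PredictionReport, predict_report
from .sequence_io import CTerminalWindow, ProteinSequence, parse_fasta

__all__ = ["PlantPTS1Model", "PlantPTS1Results"]


class PlantPTS1Model:
    """Specification of a trainable plant PTS1 prediction model.

    Parameters
    ----------
    positive_windows
        C-terminal 14-mers of known PTS1 proteins (training set).
    negative_windows
        Optional 14-mers of non-PTS1 proteins; required for posterior
        calibration and for a data-driven decision threshold.
    background
        Residue background frequencies (default uniform 1/20).
    pseudocount, log_base
        Estimator settings of the log-odds trainer.
    prior_pos
        Class prior used by the posterior calibrations.
    threshold
        Decision threshold override.  When omitted it is derived from
        the balanced calibration (the score at posterior 0.5) if
        negatives are available, else the published constant 0.412.
    """

    def __init__(
        self,
        positive_windows: Sequence[CTerminalWindow | str],
        negative_windows: Sequence[CTerminalWindow | str] | None = None,
        *,
        background: Mapping[str, float] | pd.Series | None = None,
        pseudocount: float = 1.0,
        log_base: float = 10.0,
        prior_pos: float = 0.5,
        threshold: float | None = None,
    ) -> None:
        self.positive_windows = list(positive_windows)
        self.negative_windows = (
            list(negative_windows) if negative_windows is not None else None
        )
        self.background = background
        self.pseudocount = pseudocount
        self.log_base = log_base
        self.prior_pos = prior_pos
        self.threshold = threshold

    @classmethod
    def from_fasta(
        cls,
        positives_text: str,
        negatives_text: str | None = None,
        **kwargs,
    ) -> "PlantPTS1Model":
        """Build from FASTA text; windows are the final 14 residues."""
        from .sequence_io import extract_cterminal_window

        pos = [extract_cterminal_window(s) for s in parse_fasta(positives_text)]
        neg = (
            [extract_cterminal_window(s) for s in parse_fasta(negatives_text)]
            if negatives_text is not None
            else None
        )
        return cls(pos, neg, **kwargs)

    def fit(self) -> "PlantPTS1Results":
        pwm = train_pwm(
            self.positive_windows,
            background=self.background,
            pseudocount=self.pseudocount,
            log_base=self.log_base,
        )
        calibrations: dict[str, CalibrationModel] = {}
        if self.negative_windows:
            pos_scores = [score_window(pwm, w).total for w in self.positive_windows]
            neg_scores = [score_window(pwm, w).total for w in self.negative_windows]
            for scheme in ("original", "balanced"):
                calibrations[scheme] = fit_gaussian_calibration(
                    pos_scores, neg_scores, scheme, self.prior_pos
                )
        if self.threshold is not None:
            threshold = self.threshold
        elif "balanced" in calibrations:
            curve = balanced_logistic(calibrations["balanced"])
            threshold = -curve.intercept / curve.slope  # posterior = 0.5
        else:
            from .pwm import PUBLISHED

            threshold = PUBLISHED.decision_threshold
        return PlantPTS1Results(
            model=self,
            pwm=pwm,
            calibrations=calibrations,
            threshold=threshold,
            region_stats=compute_region_stats(pwm),
            score_bounds=pwm_score_bounds(pwm),
        )


@dataclass(frozen=True)
class PlantPTS1Results:
    """Fitted matrix, calibrations and derived operating constants."""

    model: PlantPTS1Model
    pwm: PWM
    calibrations: dict[str, CalibrationModel]
    threshold: float
    region_stats: tuple[RegionStats, RegionStats]
    score_bounds: tuple[float, float]
    registry: Mapping[str, TripeptideRecord] | None = field(default=None)

    def predict(
        self,
        sequences: str | Sequence[ProteinSequence],
        registry: Mapping[str, TripeptideRecord] | None = None,
    ) -> list[PredictionReport]:
        """Prediction reports for FASTA text or parsed sequences."""
        if isinstance(sequences, str):
            sequences = parse_fasta(sequences)
        if registry is None:
            registry = self.registry if self.registry is not None else default_registry()
        return [
            predict_report(
                seq,
                self.pwm,
                calibrations=self.calibrations or None,
                stats=self.region_stats,
                registry=registry,
                threshold=self.threshold,
            )
            for seq in sequences
        ]

    def summary(self) -> str:
        """Human-readable account of the fitted model."""
        tri, up = self.region_stats
        lines = [
            "Plant PTS1 prediction model (position weight matrix)",
            "====================================================",
            f"positive training windows: {self.pwm.n_positive}",
            f"log base / pseudocount:    {self.pwm.log_base:g} / {self.pwm.pseudocount:g}",
            f"decision threshold:        {self.threshold:.3f}",
            f"attainable score bounds:   {self.score_bounds[0]:.3f} .. {self.score_bounds[1]:.3f}",
            f"tripeptide region stats:   mean {tri.mean:.3f}, SD {tri.sd:.3f}",
            f"upstream region stats:     mean {up.mean:.3f}, SD {up.sd:.3f}",
        ]
        for scheme in ("original", "balanced"):
            cal = self.calibrations.get(scheme)
            if cal is not None:
                lines.append(
                    f"{scheme:>8} calibration:      "
                    f"mu+ {cal.mu_pos:.3f} (sd {cal.sigma_pos:.3f}), "
                    f"mu- {cal.mu_neg:.3f} (sd {cal.sigma_neg:.3f}), "
                    f"prior {cal.prior_pos:g}"
                )
        if not self.calibrations:
            lines.append("calibrations:              none (no negative windows supplied)")
        return "\n".join(lines)
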