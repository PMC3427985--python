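"""Posterior-probability calibration of total prediction scores.

Two class-conditional Gaussian schemes map a total score to the
probability that the sequence is a PTS1 (peroxisome-targeted) protein:

``original``
    class means and class-specific variances estimated by maximum
    likelihood — the log-odds is quadratic in the score when the
    variances differ;
``balanced``
    the same means with one pooled variance shared by both classes,
    which reduces analytically to a logistic function of the score.

Pooling the variances broadens the intermediate probability range and
raises the probability of positives that sit far from the bulk of the
positive class (non-canonical, low-abundance PTS1 proteins), at the
price of more false positives above 50%.

A third, purely empirical device — :class:`CalibrationCurve` — fits a
monotone logistic to published (score, probability) pairs so printed
server outputs can be interpolated without the unpublished matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, TextIO

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit, logit
from scipy.stats import norm

__all__ = [
    "CalibrationModel",
    "CalibrationCurve",
    "fit_gaussian_calibration",
    "posterior_probability",
    "balanced_logistic",
    "fit_curve_to_pairs",
    "scheme_contrast",
    "format_percent",
]

SCHEMES = ("original", "balanced")


@dataclass(frozen=True)
class CalibrationModel:
    """Class-conditional Gaussian score model for one calibration scheme."""

    scheme: str
    mu_pos: float
    mu_neg: float
    sigma_pos: float
    sigma_neg: float
    prior_pos: float = 0.5

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if self.sigma_pos <= 0 or self.sigma_neg <= 0:
            raise ValueError("class standard deviations must be positive")
        if self.mu_pos <= self.mu_neg:
            raise ValueError(
                "positive-class mean must exceed negative-class mean "
                f"(got mu_pos={self.mu_pos!r}, mu_neg={self.mu_neg!r})"
            )
        if self.scheme == "balanced" and self.sigma_pos != self.sigma_neg:
            raise ValueError("balanced scheme requires equal class variances")
        if not 0.0 < self.prior_pos < 1.0:
            raise ValueError("prior_pos must lie strictly between 0 and 1")

    # ---- persistence (flat key-value text) ---------------------------

    def to_text(self, handle: TextIO) -> None:
        for key in ("scheme", "mu_pos", "mu_neg", "sigma_pos", "sigma_neg", "prior_pos"):
            handle.write(f"{key}={getattr(self, key)!r}\n")

    @classmethod
    def from_text(cls, handle: TextIO) -> "CalibrationModel":
        fields: dict[str, str] = {}
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                k, v = line.split("=", 1)
                fields[k] = v
        return cls(
            scheme=fields["scheme"].strip("'\""),
            mu_pos=float(fields["mu_pos"]),
            mu_neg=float(fields["mu_neg"]),
            sigma_pos=float(fields["sigma_pos"]),
            sigma_neg=float(fields["sigma_neg"]),
            prior_pos=float(fields.get("prior_pos", 0.5)),
        )


@dataclass(frozen=True)
class CalibrationCurve:
    """Strictly increasing logistic curve p(s) = expit(intercept + slope*s)."""

    intercept: float
    slope: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive (curve must be increasing)")

    def predict(self, score):
        return expit(self.intercept + self.slope * np.asarray(score, dtype=float))

    def __call__(self, score):
        return self.predict(score)


def fit_gaussian_calibration(
    pos_scores: Sequence[float],
    neg_scores: Sequence[float],
    scheme: str = "balanced",
    prior_pos: float = 0.5,
) -> CalibrationModel:
    """Fit a class-conditional Gaussian calibration by maximum likelihood.

    ``original`` keeps class-specific variances; ``balanced`` replaces
    both with the pooled (sample-size weighted) ML variance.  Requires
    at least two scores per class, positive sample variances, and a
    positive class that scores higher on average than the negatives.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("at least two scores per class are required")
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    mu_pos, mu_neg = float(pos.mean()), float(neg.mean())
    var_pos = float(pos.var(ddof=0))
    var_neg = float(neg.var(ddof=0))
    if var_pos <= 0 or var_neg <= 0:
        raise ValueError("degenerate (zero-variance) class scores")
    if mu_pos <= mu_neg:
        raise ValueError(
            "positive scores do not exceed negative scores on average; "
            "calibration is undefined"
        )
    if scheme == "balanced":
        pooled = (pos.size * var_pos + neg.size * var_neg) / (pos.size + neg.size)
        sigma = math.sqrt(pooled)
        return CalibrationModel("balanced", mu_pos, mu_neg, sigma, sigma, prior_pos)
    return CalibrationModel(
        "original", mu_pos, mu_neg, math.sqrt(var_pos), math.sqrt(var_neg), prior_pos
    )


def posterior_probability(model: CalibrationModel, score) -> float | np.ndarray:
    """P(PTS1 | score) under the class-conditional Gaussian model.

    Computed on the log scale, ``expit(logit(prior) + log g_pos - log
    g_neg)``, which is algebraically the prior-weighted density ratio
    but stable far into the tails.
    """
    s = np.asarray(score, dtype=float)
    log_odds = (
        logit(model.prior_pos)
        + norm.logpdf(s, model.mu_pos, model.sigma_pos)
        - norm.logpdf(s, model.mu_neg, model.sigma_neg)
    )
    p = expit(log_odds)
    return float(p) if np.isscalar(score) else p


def balanced_logistic(model: CalibrationModel) -> CalibrationCurve:
    """Closed-form logistic equivalent of a balanced calibration.

    With a shared variance sigma^2 the posterior is
    ``expit(a + b*s)`` with ``b = (mu_pos - mu_neg)/sigma^2`` and
    ``a = logit(prior) + (mu_neg^2 - mu_pos^2)/(2 sigma^2)``.
    """
    if model.scheme != "balanced":
        raise ValueError("closed form applies to the balanced scheme only")
    var = model.sigma_pos**2
    slope = (model.mu_pos - model.mu_neg) / var
    intercept = float(logit(model.prior_pos)) + (model.mu_neg**2 - model.mu_pos**2) / (
        2 * var
    )
    return CalibrationCurve(intercept=intercept, slope=slope)


def fit_curve_to_pairs(
    pairs: Sequence[tuple[float, float]],
) -> CalibrationCurve:
    """Least-squares logistic fit to (score, probability) pairs.

    Fitting is done on the probabilities themselves (not log-odds) so
    exact 0.0 / near-1.0 endpoints are tolerated; the slope is
    constrained positive so the curve is strictly increasing.  Two
    pairs exactly identify the curve.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("at least two (score, probability) pairs are required")
    s, p = arr[:, 0], arr[:, 1]
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if np.allclose(s, s[0]):
        raise ValueError("scores must not all be equal")
    if np.allclose(p, p[0]):
        raise ValueError("degenerate input: all probabilities identical")

    # Initial guess from a linear fit on clipped log-odds.
    z = logit(np.clip(p, 1e-3, 1 - 1e-3))
    b0, a0 = np.polyfit(s, z, 1)
    if b0 <= 0:
        b0 = 1.0

    def model(x, a, b):
        return expit(a + b * x)

    import warnings

    from scipy.optimize import OptimizeWarning

    with warnings.catch_warnings():
        # exactly identified two-point fits cannot estimate a covariance
        warnings.simplefilter("ignore", OptimizeWarning)
        params, _ = _bounded_curve_fit(model, s, p, a0, b0)
    return CalibrationCurve(intercept=float(params[0]), slope=float(params[1]))


def _bounded_curve_fit(model, s, p, a0, b0):
    return curve_fit(
        model,
        s,
        p,
        p0=(a0, b0),
        bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
        maxfev=20000,
    )


def scheme_contrast(
    pos_scores: Sequence[float],
    neg_scores: Sequence[float],
    score: float,
    prior_pos: float = 0.5,
) -> tuple[float, float]:
    """(original, balanced) posteriors at one score, same training data.

    When the negative class is broader than the positive class the
    balanced posterior exceeds the original one for positives lying
    below the bulk of the positive class — the behaviour that rescues
    non-canonical PTS1 proteins at the price of extra false positives.
    """
    original = fit_gaussian_calibration(pos_scores, neg_scores, "original", prior_pos)
    balanced = fit_gaussian_calibration(pos_scores, neg_scores, "balanced", prior_pos)
    return (
        float(posterior_probability(original, score)),
        float(posterior_probability(balanced, score)),
    )


def format_percent(probability: float) -> str:
    """Render a probability as a one-decimal percentage, e.g. '66.6%'."""
    return f"{probability * 100:.1f}%"
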