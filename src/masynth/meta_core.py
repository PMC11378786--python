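"""Random-effects meta-analysis primitives.

This module implements the standard random-effects model for a collection of
independent effect-size estimates ``y_i`` with known within-study standard
errors.  The between-study heterogeneity variance ``tau^2`` is estimated by
the DerSimonian–Laird method of moments; pooled means use inverse-variance
weights ``w_i = 1 / (tau^2 + v_i)`` and 95% confidence intervals use the
normal quantile 1.96.  The same algebra is applied at two levels elsewhere in
the package: to primary studies within one meta-analysis, and to the mean
effect sizes of several meta-analyses (a second-order meta-analysis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Hashable, Iterable, Sequence

import numpy as np

__all__ = [
    "Z95",
    "Category",
    "Study",
    "MAResult",
    "estimate_tau2",
    "fit_arrays",
    "fit_random_effects",
    "classify_interval",
]

#: Normal quantile used for all 95% confidence intervals.
Z95 = 1.96


class Category(str, Enum):
    """Three-way verdict attached to a confidence interval or a true mean."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    NO_EFFECT = "no_effect"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def opposite(self) -> "Category":
        """Mirror image under a sign flip of all effects."""
        if self is Category.POSITIVE:
            return Category.NEGATIVE
        if self is Category.NEGATIVE:
            return Category.POSITIVE
        return Category.NO_EFFECT


@dataclass(frozen=True)
class Study:
    """One primary observation: a log-response-ratio effect and its SE.

    ``study_id`` is an opaque identifier used only for duplicate removal when
    several meta-analyses share primary studies.
    """

    effect: float
    within_se: float
    study_id: Hashable

    def __post_init__(self) -> None:
        if not self.within_se > 0:
            raise ValueError(f"within_se must be positive, got {self.within_se}")


@dataclass(frozen=True)
class MAResult:
    """Output of one random-effects fit.

    ``cv`` is the coefficient of variation ``se / |mean|`` used by the
    most-accurate-MA selection rule; it is ``+inf`` when the mean is exactly
    zero, so a zero-mean meta-analysis is never selected.
    """

    mean: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    n_studies: int
    cv: float

    @classmethod
    def from_estimate(cls, mean: float, se: float, tau2: float, n_studies: int) -> "MAResult":
        """Build a result from a pooled mean and SE, deriving CI and CV."""
        if not se > 0:
            raise ValueError(f"se must be positive, got {se}")
        if tau2 < 0:
            raise ValueError(f"tau2 must be non-negative, got {tau2}")
        cv = se / abs(mean) if mean != 0 else math.inf
        return cls(
            mean=mean,
            se=se,
            ci_low=mean - Z95 * se,
            ci_high=mean + Z95 * se,
            tau2=tau2,
            n_studies=n_studies,
            cv=cv,
        )

    @classmethod
    def from_summary(cls, mean: float, se: float, n_studies: int = 1) -> "MAResult":
        """Build a result from a published (mean, se) summary row.

        Published summaries carry no heterogeneity information, so ``tau2``
        is recorded as 0; it plays no role in the synthesis methods, which
        only consume the mean, SE and CI.
        """
        return cls.from_estimate(mean, se, tau2=0.0, n_studies=n_studies)

    @property
    def category(self) -> Category:
        return classify_interval(self.ci_low, self.ci_high)


def _validate_arrays(effects: np.ndarray, variances: np.ndarray) -> None:
    if effects.ndim != 1 or variances.ndim != 1:
        raise ValueError("effects and variances must be one-dimensional")
    if effects.size == 0:
        raise ValueError("at least one study is required")
    if effects.size != variances.size:
        raise ValueError(
            f"length mismatch: {effects.size} effects vs {variances.size} variances"
        )
    if not np.all(variances > 0):
        raise ValueError("all within-study variances must be positive")


def estimate_tau2(effects: Sequence[float], variances: Sequence[float]) -> float:
    """DerSimonian–Laird moment estimate of the between-study variance.

    With fixed-effect weights ``w_i = 1/v_i``, the heterogeneity statistic is
    ``Q = sum w_i (y_i - ybar)^2`` around the fixed-effect mean ``ybar``, and

        tau2 = max(0, (Q - (k - 1)) / C),   C = sum w - sum w^2 / sum w.

    A single study carries no between-study information and returns 0.
    """
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    _validate_arrays(y, v)
    k = y.size
    if k == 1:
        return 0.0
    w = 1.0 / v
    sw = w.sum()
    ybar = (w * y).sum() / sw
    q = (w * (y - ybar) ** 2).sum()
    c = sw - (w * w).sum() / sw
    return float(max(0.0, (q - (k - 1)) / c))


def fit_arrays(effects: Sequence[float], within_ses: Sequence[float]) -> MAResult:
    """Random-effects fit on parallel arrays of effects and within-study SEs.

    This is the array fast path used by the simulation engine;
    :func:`fit_random_effects` is the same fit on :class:`Study` records.
    """
    y = np.asarray(effects, dtype=float)
    se = np.asarray(within_ses, dtype=float)
    v = se * se
    _validate_arrays(y, v)
    tau2 = estimate_tau2(y, v)
    w = 1.0 / (tau2 + v)
    sw = w.sum()
    mean = float((w * y).sum() / sw)
    pooled_se = float(1.0 / math.sqrt(sw))
    return MAResult.from_estimate(mean, pooled_se, tau2=tau2, n_studies=y.size)


def fit_random_effects(studies: Iterable[Study]) -> MAResult:
    """Fit a random-effects meta-analysis to a collection of studies."""
    studies = list(studies)
    if not studies:
        raise ValueError("at least one study is required")
    effects = np.array([s.effect for s in studies], dtype=float)
    ses = np.array([s.within_se for s in studies], dtype=float)
    return fit_arrays(effects, ses)


def classify_interval(ci_low: float, ci_high: float) -> Category:
    """Three-way classification of a 95% confidence interval.

    Significantly positive iff the lower bound exceeds 0, significantly
    negative iff the upper bound is below 0, otherwise no effect.  An
    endpoint exactly at 0 counts as no effect (conservative; probability
    zero under the continuous model).
    """
    if ci_low > ci_high:
        raise ValueError(f"invalid interval: [{ci_low}, {ci_high}]")
    if ci_low > 0:
        return Category.POSITIVE
    if ci_high < 0:
        return Category.NEGATIVE
    return Category.NO_EFFECT
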