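"""Synthetic first-order meta-analysis datasets.

Effect sizes follow the hierarchical Gaussian model standard in
meta-analysis: the true effect of study *i* is ``theta_i ~ N(mu, sigma_theta^2)``
and the observed effect is ``y_i = theta_i + eps_i`` with
``eps_i ~ N(0, sigma_eps_i^2)`` (the sampling error has mean zero), so that
marginally ``y_i ~ N(mu, sigma_theta^2 + sigma_eps_i^2)``.  Within-study
standard errors ``sigma_eps_i`` are drawn uniformly from a range set by a
precision level (low / medium / high).

A scenario produces K first-order datasets of N studies each.  A proportion
P of the studies is common to all K datasets: m = round(P*N) studies are
drawn once into a shared pool and inserted into every dataset, which is then
completed with N - m independent draws.  The pooled dataset is the union
with the shared studies counted once, hence K*(N - m) + m studies.

Three selective-publication regimes truncate the marginal distribution of
``y_i`` conditional on its within-study SE:

* ``sig_both``      — only studies significant at the 5% level in either
  direction are published: ``|y| > 1.96 * sigma_eps``;
* ``sig_negative``  — only significantly negative studies:
  ``y + 1.96 * sigma_eps < 0``;
* ``sig_positive``  — only significantly positive studies:
  ``y - 1.96 * sigma_eps > 0``.

Constrained draws use exact inverse-CDF sampling from the truncated normal
(conditional on the drawn SE), not rejection: under ``sig_positive`` with a
strongly negative mu the acceptance region can have probability ~1e-5 or
far less, where rejection sampling is infeasible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Mapping

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .meta_core import Study, Z95

__all__ = [
    "PRECISION_LEVELS",
    "BIAS_TYPES",
    "DEFAULT_SE_RANGES",
    "DEFAULT_SIGMA_THETA",
    "DegenerateRegionError",
    "Scenario",
    "DatasetBundle",
    "normalize_bias",
    "round_half_up",
    "draw_within_se",
    "draw_study",
    "build_scenario_data",
]

PRECISION_LEVELS = ("low", "medium", "high")
BIAS_TYPES = ("none", "sig_both", "sig_negative", "sig_positive")

#: Uniform ranges for the within-study SE at each precision level.  The
#: three levels are disjoint and strictly ordered (high precision = small
#: SE), spanning values typical for log response ratios in field studies.
DEFAULT_SE_RANGES: Mapping[str, tuple[float, float]] = {
    "high": (0.05, 0.15),
    "medium": (0.15, 0.35),
    "low": (0.35, 0.70),
}

#: Between-study SD of the true effects; moderate heterogeneity relative to
#: the benchmark's true means (|mu| up to 0.69).
DEFAULT_SIGMA_THETA = 0.15

#: Truncation regions with conditional probability below this floor are
#: treated as numerically degenerate.
MIN_REGION_PROB = 1e-300

# Numbered aliases accepted on the command line and in configs: 1 = any
# significant study published, 2 = significantly negative only, 3 =
# significantly positive only.
_BIAS_ALIASES = {
    "none": "none",
    "0": "none",
    "1": "sig_both",
    "2": "sig_negative",
    "3": "sig_positive",
    "sig_both": "sig_both",
    "sig_negative": "sig_negative",
    "sig_positive": "sig_positive",
}


class DegenerateRegionError(ValueError):
    """Raised when a truncation region is numerically impossible to sample."""


def normalize_bias(bias: str | int) -> str:
    """Map a bias label or its conventional number (1/2/3) to the canonical name."""
    key = str(bias).strip().lower()
    try:
        return _BIAS_ALIASES[key]
    except KeyError:
        raise ValueError(f"unknown bias type: {bias!r}; expected one of {BIAS_TYPES}") from None


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves away from zero (0.25*10 -> 3)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class Scenario:
    """One cell of the factorial design.

    Parameters
    ----------
    mu : true mean effect (log response ratio).
    n_ma : number of first-order meta-analyses K.
    n_per_ma : number of primary studies N in each meta-analysis.
    overlap : proportion P of studies common to all K datasets.
    precision : within-study SE level, one of ``low`` / ``medium`` / ``high``.
    bias_type : publication-bias regime; biased regimes require overlap 0,
        matching the benchmark's biased design.
    n_iter : Monte-Carlo iterations when the scenario is run.
    """

    mu: float
    n_ma: int
    n_per_ma: int
    overlap: float = 0.0
    precision: str = "medium"
    bias_type: str = "none"
    n_iter: int = 100

    def __post_init__(self) -> None:
        object.__setattr__(self, "bias_type", normalize_bias(self.bias_type))
        if self.n_ma < 1 or self.n_per_ma < 1 or self.n_iter < 1:
            raise ValueError("n_ma, n_per_ma and n_iter must be positive")
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError(f"overlap must lie in [0, 1], got {self.overlap}")
        if self.precision not in PRECISION_LEVELS:
            raise ValueError(f"unknown precision level: {self.precision!r}")
        if self.bias_type != "none" and self.overlap != 0.0:
            raise ValueError("biased scenarios require overlap = 0")

    @property
    def n_common(self) -> int:
        """Number of shared studies m = round(P*N)."""
        return round_half_up(self.overlap * self.n_per_ma)

    @property
    def pooled_size(self) -> int:
        """Size of the deduplicated pooled dataset, K*(N - m) + m."""
        m = self.n_common
        return self.n_ma * (self.n_per_ma - m) + m


@dataclass(frozen=True)
class DatasetBundle:
    """K first-order study lists plus their deduplicated union."""

    first_order: tuple[tuple[Study, ...], ...]
    pooled: tuple[Study, ...]

    def to_frame(self) -> pd.DataFrame:
        """Audit table with one row per (dataset, study) pair.

        ``ma_index`` is the 0-based dataset index; shared studies appear in
        every dataset under the same ``study_id``.
        """
        rows = [
            (k, str(s.study_id), s.effect, s.within_se)
            for k, ds in enumerate(self.first_order)
            for s in ds
        ]
        return pd.DataFrame(rows, columns=["ma_index", "study_id", "effect", "within_se"])


def _se_range(precision: str, se_ranges: Mapping[str, tuple[float, float]] | None) -> tuple[float, float]:
    ranges = DEFAULT_SE_RANGES if se_ranges is None else se_ranges
    try:
        lo, hi = ranges[precision]
    except KeyError:
        raise ValueError(f"unknown precision level: {precision!r}") from None
    if not (0 < lo <= hi):
        raise ValueError(f"invalid SE range for {precision!r}: ({lo}, {hi})")
    return lo, hi


def _draw_within_ses(
    n: int,
    precision: str,
    rng: np.random.Generator,
    se_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> np.ndarray:
    lo, hi = _se_range(precision, se_ranges)
    if lo == hi:  # degenerate point-mass configuration
        return np.full(n, lo)
    return rng.uniform(lo, hi, size=n)


def draw_within_se(
    precision: str,
    rng: np.random.Generator,
    se_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> float:
    """Draw one within-study SE uniformly from the range of a precision level."""
    return float(_draw_within_ses(1, precision, rng, se_ranges)[0])


def _draw_effects(
    mu: float,
    sigma_theta: float,
    within_ses: np.ndarray,
    bias_type: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample observed effects conditional on their within-study SEs.

    Marginally y ~ N(mu, sigma_theta^2 + se^2); biased regimes condition on
    the significance region via the inverse CDF.  The uniforms are clipped
    into the open interval so sampled effects satisfy the truncation
    condition strictly.
    """
    sd = np.sqrt(sigma_theta**2 + within_ses**2)
    if bias_type == "none":
        return mu + sd * rng.standard_normal(within_ses.size)

    thr = Z95 * within_ses  # significance threshold per study
    u = np.clip(rng.random(within_ses.size), 1e-16, 1.0 - 1e-16)
    if bias_type == "sig_negative":
        p = ndtr((-thr - mu) / sd)  # mass of {y < -thr}
        _check_region(p)
        return mu + sd * ndtri(u * p)
    if bias_type == "sig_positive":
        p = ndtr(-(thr - mu) / sd)  # mass of {y > thr}
        _check_region(p)
        return mu - sd * ndtri(u * p)
    if bias_type == "sig_both":
        p_left = ndtr((-thr - mu) / sd)
        p_right = ndtr(-(thr - mu) / sd)
        p = p_left + p_right
        _check_region(p)
        q = u * p
        left = q < p_left
        y = np.empty_like(sd)
        y[left] = mu + sd[left] * ndtri(q[left])
        w = q[~left] - p_left[~left]
        pr = p_right[~left]
        w = np.clip(w, pr * 1e-16, pr * (1.0 - 1e-16))
        y[~left] = mu - sd[~left] * ndtri(w)
        return y
    raise ValueError(f"unknown bias type: {bias_type!r}")


def _check_region(p: np.ndarray) -> None:
    if np.any(p < MIN_REGION_PROB):
        raise DegenerateRegionError(
            f"truncation region probability below {MIN_REGION_PROB:g}; "
            "the selective-publication condition is numerically unsatisfiable"
        )


def draw_study(
    mu: float,
    sigma_theta: float,
    precision: str,
    bias_type: str,
    rng: np.random.Generator,
    se_ranges: Mapping[str, tuple[float, float]] | None = None,
    study_id: Hashable = None,
) -> Study:
    """Draw one primary study, optionally under a publication-bias regime."""
    if sigma_theta < 0:
        raise ValueError(f"sigma_theta must be non-negative, got {sigma_theta}")
    bias = normalize_bias(bias_type)
    se = _draw_within_ses(1, precision, rng, se_ranges)
    y = _draw_effects(mu, sigma_theta, se, bias, rng)
    return Study(effect=float(y[0]), within_se=float(se[0]), study_id=study_id)


def _bundle_arrays(
    scenario: Scenario,
    rng: np.random.Generator,
    sigma_theta: float = DEFAULT_SIGMA_THETA,
    se_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], tuple[np.ndarray, np.ndarray]]:
    """Array-level generation shared by :func:`build_scenario_data` and the
    benchmark engine: returns per-dataset (effects, ses) pairs and the pooled
    deduplicated (effects, ses).

    Draw order is fixed (shared pool first, then each dataset's unique
    studies) so a given (scenario, generator state) is bit-reproducible.
    """
    m = scenario.n_common
    n_unique = scenario.n_per_ma - m
    common_se = _draw_within_ses(m, scenario.precision, rng, se_ranges)
    common_y = _draw_effects(scenario.mu, sigma_theta, common_se, scenario.bias_type, rng)
    per_ma: list[tuple[np.ndarray, np.ndarray]] = []
    uniq_y: list[np.ndarray] = []
    uniq_se: list[np.ndarray] = []
    for _ in range(scenario.n_ma):
        se_k = _draw_within_ses(n_unique, scenario.precision, rng, se_ranges)
        y_k = _draw_effects(scenario.mu, sigma_theta, se_k, scenario.bias_type, rng)
        per_ma.append((np.concatenate([common_y, y_k]), np.concatenate([common_se, se_k])))
        uniq_y.append(y_k)
        uniq_se.append(se_k)
    pooled_y = np.concatenate([common_y, *uniq_y])
    pooled_se = np.concatenate([common_se, *uniq_se])
    return per_ma, (pooled_y, pooled_se)


def build_scenario_data(
    scenario: Scenario,
    rng: np.random.Generator,
    sigma_theta: float = DEFAULT_SIGMA_THETA,
    se_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> DatasetBundle:
    """Generate the K first-order datasets and their deduplicated union.

    The m shared studies are drawn once into a global pool common to all K
    datasets and carry identifiers ``common<j>``; unique studies carry
    ``ma<k>_u<j>``.
    """
    m = scenario.n_common
    per_ma, _ = _bundle_arrays(scenario, rng, sigma_theta, se_ranges)
    common_ids = [f"common{j}" for j in range(m)]
    first_order: list[tuple[Study, ...]] = []
    pooled: list[Study] = []
    for k, (y, se) in enumerate(per_ma):
        ids = common_ids + [f"ma{k}_u{j}" for j in range(scenario.n_per_ma - m)]
        ds = tuple(Study(float(yi), float(si), sid) for yi, si, sid in zip(y, se, ids))
        first_order.append(ds)
        pooled.extend(ds[m:])
    pooled = list(first_order[0][:m]) + pooled
    return DatasetBundle(first_order=tuple(first_order), pooled=tuple(pooled))
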