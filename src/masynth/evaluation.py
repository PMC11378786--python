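"""Comparison criteria for synthesis methods.

Each method is judged per scenario over its Monte-Carlo iterations on four
criteria:

* **PCC** — probability of correct conclusion: the fraction of iterations
  whose three-way verdict matches the sign of the true mean effect.
* **BES** — bias of the estimated mean effect size, mean(estimates) - mu
  (estimated minus true, so a positive value is overestimation).
* **RMSE** — root mean square error of the estimates around mu.
* **CCI** — coverage: the fraction of 95% confidence intervals containing mu.

BES, RMSE and CCI require a quantitative estimate and are therefore absent
for vote counting (COMA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .meta_core import Category
from .simulator import Scenario
from .synthesis import SynthesisOutcome

__all__ = ["CriteriaRow", "true_category", "compute_criteria"]


def true_category(mu: float) -> Category:
    """True three-way category of a mean effect: its sign."""
    if mu > 0:
        return Category.POSITIVE
    if mu < 0:
        return Category.NEGATIVE
    return Category.NO_EFFECT


@dataclass(frozen=True)
class CriteriaRow:
    """Per-(scenario, method) evaluation; bes/rmse/cci are None for COMA."""

    method: str
    pcc: float
    bes: float | None
    rmse: float | None
    cci: float | None
    n_iter: int
    scenario: Scenario | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pcc <= 1.0:
            raise ValueError(f"pcc must lie in [0, 1], got {self.pcc}")
        if self.cci is not None and not 0.0 <= self.cci <= 1.0:
            raise ValueError(f"cci must lie in [0, 1], got {self.cci}")
        if self.rmse is not None and self.bes is not None:
            # RMSE^2 = bias^2 + variance, so RMSE can never fall below |bias|
            if self.rmse < abs(self.bes) - 1e-12:
                raise ValueError("rmse smaller than |bes|: inconsistent criteria")


def compute_criteria(
    outcomes: Sequence[SynthesisOutcome],
    mu: float,
    scenario: Scenario | None = None,
) -> CriteriaRow:
    """Aggregate one method's per-iteration outcomes into a criteria row."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("at least one outcome is required")
    methods = {o.method for o in outcomes}
    if len(methods) > 1:
        raise ValueError(f"outcomes mix methods: {sorted(methods)}")
    method = outcomes[0].method

    target = true_category(mu)
    n = len(outcomes)
    pcc = sum(o.category is target for o in outcomes) / n

    if all(o.is_quantitative for o in outcomes):
        est = np.array([o.mean for o in outcomes], dtype=float)
        lo = np.array([o.ci_low for o in outcomes], dtype=float)
        hi = np.array([o.ci_high for o in outcomes], dtype=float)
        bes = float(est.mean() - mu)
        rmse = float(np.sqrt(np.mean((est - mu) ** 2)))
        cci = float(np.mean((lo <= mu) & (mu <= hi)))
    else:
        bes = rmse = cci = None
    return CriteriaRow(
        method=method, pcc=pcc, bes=bes, rmse=rmse, cci=cci, n_iter=n, scenario=scenario
    )
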