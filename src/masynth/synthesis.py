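"""The four synthesis methods.

Given the results of K first-order meta-analyses (each a mean effect size
``Delta_k`` with standard error ``sigma_k``), a synthesis method produces a
single verdict on the intervention:

* **SOMA** — second-order meta-analysis: a random-effects weighted average
  of the K means, with weights ``1 / (tau^2 + sigma_k^2)`` where ``tau^2``
  is the between-MA heterogeneity, and a 95% CI from the pooled SE.  The
  weights assume the K meta-analyses are independent, which is violated
  when they share primary studies.
* **MAMA** — most-accurate meta-analysis: selects the single MA with the
  lowest coefficient of variation ``sigma_k / |Delta_k|`` and passes its
  estimate through unchanged.
* **COMA** — vote counting: classifies each MA's CI as significantly
  positive / negative / not significant and returns the plurality category;
  it yields no quantitative estimate.
* **REMA** — reference method: a single random-effects meta-analysis of the
  union of all primary studies, redundant studies counted once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

from .meta_core import Category, MAResult, Study, fit_arrays, fit_random_effects

__all__ = ["METHODS", "SynthesisOutcome", "soma", "mama", "coma", "rema"]

METHODS = ("SOMA", "MAMA", "COMA", "REMA")


@dataclass(frozen=True)
class SynthesisOutcome:
    """A synthesis method's answer.

    Quantitative methods carry a point estimate with SE and 95% CI; COMA
    carries only the three-way category.  ``detail`` records method
    internals (selected index for MAMA, vote counts for COMA, heterogeneity
    for SOMA/REMA).
    """

    method: str
    category: Category
    mean: float | None = None
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    detail: Mapping[str, Any] = field(default_factory=dict)

    @property
    def is_quantitative(self) -> bool:
        return self.mean is not None


def _outcome_from_result(method: str, r: MAResult, detail: Mapping[str, Any]) -> SynthesisOutcome:
    return SynthesisOutcome(
        method=method,
        category=r.category,
        mean=r.mean,
        se=r.se,
        ci_low=r.ci_low,
        ci_high=r.ci_high,
        detail=detail,
    )


def _require(results: Sequence[MAResult]) -> list[MAResult]:
    results = list(results)
    if not results:
        raise ValueError("at least one meta-analysis result is required")
    return results


def soma(results: Iterable[MAResult]) -> SynthesisOutcome:
    """Second-order meta-analysis of the K first-order means.

    The first-order (mean, se) pairs are treated exactly like study-level
    data in a random-effects fit: heterogeneity across meta-analyses is
    estimated by DerSimonian–Laird and enters the weights.
    """
    results = _require(results)
    means = np.array([r.mean for r in results])
    ses = np.array([r.se for r in results])
    fit = fit_arrays(means, ses)
    return _outcome_from_result("SOMA", fit, {"tau2": fit.tau2, "k": len(results)})


def mama(results: Iterable[MAResult]) -> SynthesisOutcome:
    """Select the most accurate meta-analysis by coefficient of variation.

    CV ties are broken by the lowest index (deterministic; a tie is a
    probability-zero event under the continuous model).
    """
    results = _require(results)
    idx = int(np.argmin([r.cv for r in results]))
    chosen = results[idx]
    return _outcome_from_result("MAMA", chosen, {"selected": idx, "cv": chosen.cv})


def coma(results: Iterable[MAResult]) -> SynthesisOutcome:
    """Vote counting over the three significance categories.

    Each MA votes with its CI classification; the plurality category wins.
    Any tie for the most votes returns ``no_effect``: a split verdict is not
    evidence for a direction, and the rule is symmetric in positive and
    negative.
    """
    results = _require(results)
    votes = {cat: 0 for cat in Category}
    for r in results:
        votes[r.category] += 1
    top = max(votes.values())
    winners = [cat for cat, n in votes.items() if n == top]
    category = winners[0] if len(winners) == 1 else Category.NO_EFFECT
    detail = {"votes": {cat.value: n for cat, n in votes.items()}}
    return SynthesisOutcome(method="COMA", category=category, detail=detail)


def rema(pooled: Sequence[Study]) -> SynthesisOutcome:
    """Reference synthesis: one random-effects fit of all primary studies.

    ``pooled`` must already be deduplicated (shared studies counted once);
    duplicate identifiers raise.
    """
    pooled = list(pooled)
    if not pooled:
        raise ValueError("at least one study is required")
    ids = [s.study_id for s in pooled]
    if len(set(ids)) != len(ids):
        raise ValueError("pooled dataset contains duplicate study_ids")
    fit = fit_random_effects(pooled)
    return _outcome_from_result("REMA", fit, {"tau2": fit.tau2, "n_studies": fit.n_studies})


def rema_from_fit(fit: MAResult) -> SynthesisOutcome:
    """Wrap an already-computed pooled fit as a REMA outcome (engine fast path)."""
    return _outcome_from_result("REMA", fit, {"tau2": fit.tau2, "n_studies": fit.n_studies})
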