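"""Factorial scenario grids and the Monte-Carlo benchmark engine.

The benchmark runs every scenario of a factorial grid for ``n_iter``
iterations.  Each iteration generates K first-order datasets, fits a
random-effects meta-analysis to each, applies SOMA / MAMA / COMA to the K
results and REMA to the deduplicated pooled dataset, and classifies every
answer.  Per (scenario, method), the iterations are aggregated into the
four criteria (PCC, BES, RMSE, CCI).

Randomness is controlled by a counter-based substream scheme: the master
seed and the pair (scenario index, iteration index) key an independent
``numpy`` ``SeedSequence``, so results are bit-identical regardless of
execution order or parallelism.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import asdict, dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .evaluation import CriteriaRow, compute_criteria
from .meta_core import fit_arrays
from .simulator import (
    DEFAULT_SIGMA_THETA,
    PRECISION_LEVELS,
    Scenario,
    _bundle_arrays,
    normalize_bias,
)
from .synthesis import coma, mama, rema_from_fit, soma

__all__ = [
    "GridConfig",
    "default_unbiased_config",
    "default_bias_config",
    "build_grid",
    "run_scenario",
    "run_experiment",
    "summarize",
]

logger = logging.getLogger(__name__)

#: Column order of the benchmark output table.
RESULT_COLUMNS = [
    "mu", "K", "N", "P", "precision", "bias_type", "method",
    "pcc", "bes", "rmse", "cci", "n_iter",
]


@dataclass(frozen=True)
class GridConfig:
    """Factor levels of a factorial scenario grid.

    The grid is the Cartesian product of the level lists; scenarios are
    ordered lexicographically in (mu, K, N, P, precision, bias), each factor
    in the order its levels are listed here.
    """

    mu_levels: tuple[float, ...]
    k_levels: tuple[int, ...]
    n_levels: tuple[int, ...]
    p_levels: tuple[float, ...]
    precision_levels: tuple[str, ...]
    bias_levels: tuple[str, ...]
    n_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mu_levels", "k_levels", "n_levels", "p_levels",
                     "precision_levels", "bias_levels"):
            levels = getattr(self, name)
            object.__setattr__(self, name, tuple(levels))
            if not getattr(self, name):
                raise ValueError(f"{name} must not be empty")
        object.__setattr__(
            self, "bias_levels", tuple(normalize_bias(b) for b in self.bias_levels)
        )
        for p in self.precision_levels:
            if p not in PRECISION_LEVELS:
                raise ValueError(f"unknown precision level: {p!r}")
        if self.n_iter < 1:
            raise ValueError("n_iter must be positive")

    @property
    def size(self) -> int:
        return (
            len(self.mu_levels) * len(self.k_levels) * len(self.n_levels)
            * len(self.p_levels) * len(self.precision_levels) * len(self.bias_levels)
        )

    @classmethod
    def from_yaml(cls, path: str) -> "GridConfig":
        """Load a grid from a plain-text key/value config (YAML)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"config {path!r} must be a mapping of factor levels")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: list(v) if isinstance(v, tuple) else v
                            for k, v in asdict(self).items()}, fh, sort_keys=False)


def default_unbiased_config(n_iter: int = 100, seed: int = 0) -> GridConfig:
    """The 720-scenario unbiased benchmark grid.

    5 true means x 3 numbers of MAs x 4 MA sizes x 4 overlap proportions
    x 3 precision levels.  The true means are log ratios corresponding to
    relative changes of -50%, -25%, 0%, +25% and +50%.
    """
    return GridConfig(
        mu_levels=(-0.69, -0.29, 0.0, 0.22, 0.41),
        k_levels=(3, 5, 10),
        n_levels=(10, 15, 25, 50),
        p_levels=(0.0, 0.10, 0.25, 0.50),
        precision_levels=("low", "medium", "high"),
        bias_levels=("none",),
        n_iter=n_iter,
        seed=seed,
    )


def default_bias_config(n_iter: int = 100, seed: int = 0) -> GridConfig:
    """The 27-scenario publication-bias grid.

    3 non-positive true means x 3 numbers of MAs x 3 bias regimes, with
    N = 50 studies per MA, no overlap, medium precision.  Positive means are
    omitted: results would be symmetric.
    """
    return GridConfig(
        mu_levels=(-0.69, -0.29, 0.0),
        k_levels=(3, 5, 10),
        n_levels=(50,),
        p_levels=(0.0,),
        precision_levels=("medium",),
        bias_levels=("sig_both", "sig_negative", "sig_positive"),
        n_iter=n_iter,
        seed=seed,
    )


def build_grid(config: GridConfig) -> list[Scenario]:
    """Expand a grid config into its ordered list of scenarios."""
    return [
        Scenario(mu=mu, n_ma=k, n_per_ma=n, overlap=p, precision=prec,
                 bias_type=bias, n_iter=config.n_iter)
        for mu, k, n, p, prec, bias in itertools.product(
            config.mu_levels, config.k_levels, config.n_levels,
            config.p_levels, config.precision_levels, config.bias_levels,
        )
    ]


def run_scenario(
    scenario: Scenario,
    scenario_index: int,
    seed: int,
    sigma_theta: float = DEFAULT_SIGMA_THETA,
    se_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> list[CriteriaRow]:
    """Run one scenario's Monte-Carlo loop; returns one row per method."""
    per_method: dict[str, list] = {"SOMA": [], "MAMA": [], "COMA": [], "REMA": []}
    for it in range(scenario.n_iter):
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(scenario_index, it))
        )
        per_ma, (pool_y, pool_se) = _bundle_arrays(scenario, rng, sigma_theta, se_ranges)
        results = [fit_arrays(y, se) for y, se in per_ma]
        per_method["SOMA"].append(soma(results))
        per_method["MAMA"].append(mama(results))
        per_method["COMA"].append(coma(results))
        per_method["REMA"].append(rema_from_fit(fit_arrays(pool_y, pool_se)))
    return [
        compute_criteria(outs, scenario.mu, scenario=scenario)
        for outs in per_method.values()
    ]


def _rows_to_frame(rows: Iterable[CriteriaRow]) -> pd.DataFrame:
    records = []
    for r in rows:
        s = r.scenario
        records.append({
            "mu": s.mu, "K": s.n_ma, "N": s.n_per_ma, "P": s.overlap,
            "precision": s.precision, "bias_type": s.bias_type,
            "method": r.method, "pcc": r.pcc, "bes": r.bes,
            "rmse": r.rmse, "cci": r.cci, "n_iter": r.n_iter,
        })
    return pd.DataFrame(records, columns=RESULT_COLUMNS)


def run_experiment(
    scenarios: Sequence[Scenario],
    seed: int,
    sigma_theta: float = DEFAULT_SIGMA_THETA,
    se_ranges: Mapping[str, tuple[float, float]] | None = None,
    n_jobs: int = 1,
    log_every: int = 100,
) -> pd.DataFrame:
    """Run all scenarios; one output row per (scenario, method).

    ``n_jobs > 1`` distributes scenarios over processes; the substream
    seeding guarantees serial and parallel runs produce identical tables.
    """
    scenarios = list(scenarios)
    if not scenarios:
        raise ValueError("at least one scenario is required")

    if n_jobs > 1:
        from concurrent.futures import ProcessPoolExecutor

        with ProcessPoolExecutor(max_workers=n_jobs) as pool:
            chunks = pool.map(
                run_scenario, scenarios, range(len(scenarios)),
                itertools.repeat(seed), itertools.repeat(sigma_theta),
                itertools.repeat(se_ranges), chunksize=8,
            )
            rows = [r for chunk in chunks for r in chunk]
    else:
        rows = []
        for i, sc in enumerate(scenarios):
            try:
                rows.extend(run_scenario(sc, i, seed, sigma_theta, se_ranges))
            except Exception as exc:
                raise RuntimeError(f"scenario {i} ({sc}) failed") from exc
            if log_every and (i + 1) % log_every == 0:
                logger.info("completed %d/%d scenarios", i + 1, len(scenarios))
    return _rows_to_frame(rows)


def summarize(
    rows: pd.DataFrame,
    thresholds: Sequence[float] = (0.9, 0.75),
    by: str | Sequence[str] | None = None,
) -> pd.DataFrame:
    """Headline summary per method (optionally stratified by a factor).

    Reports, per group: the percentage of scenarios whose PCC falls below
    each threshold, mean and median PCC, the mean of BES / RMSE / CCI over
    the quantitative methods, and the mean proportion of wrong conclusions
    (1 - PCC).
    """
    if rows.empty:
        raise ValueError("no rows to summarize")
    keys = ["method"]
    if by is not None:
        extra = [by] if isinstance(by, str) else list(by)
        for col in extra:
            if col not in rows.columns:
                raise ValueError(f"unknown stratification column: {col!r}")
        keys += extra

    def _agg(g: pd.DataFrame) -> pd.Series:
        out = {"n_scenarios": len(g)}
        for t in thresholds:
            out[f"pct_pcc_below_{t:g}"] = 100.0 * float((g["pcc"] < t).mean())
        out["mean_pcc"] = float(g["pcc"].mean())
        out["median_pcc"] = float(g["pcc"].median())
        out["mean_wrong"] = float((1.0 - g["pcc"]).mean())
        for col in ("bes", "rmse", "cci"):
            out[f"mean_{col}"] = float(g[col].mean()) if g[col].notna().any() else float("nan")
        return pd.Series(out)

    grouped = rows.groupby(keys, sort=True).apply(_agg, include_groups=False)
    return grouped.reset_index()
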