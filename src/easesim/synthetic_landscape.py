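"""Synthetic parcel portfolios and reserve-network selection.

Generates parcel tables with the statistical structure of an expensive
coastal real-estate market (lognormal areas and prices per acre, a
configurable negative rank correlation between price per acre and
biodiversity score) and selects ensembles of reserve networks that protect
a target fraction of the portfolio's total beta-diversity score.

Selection is a stand-in for a full systematic reserve-design run: a greedy
benefit/cost heuristic (default) and an optional simulated-annealing
minimum-set solver, with ensemble variability produced by jittering parcel
costs per solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError

__all__ = [
    "Parcel",
    "PortfolioParams",
    "Portfolio",
    "ReserveNetwork",
    "AnnealSchedule",
    "generate_portfolio",
    "select_network_greedy",
    "select_network_annealed",
    "generate_solution_set",
]

PARCEL_COLUMNS = ["parcel_id", "area_acres", "assessed_value", "beta_score"]

# Defaults calibrated so the lognormal price-per-acre marginal has mean
# 2.1e6 CAD/acre with 8% of draws below 1e5 CAD/acre:
#   sigma^2/2 + z_{0.08} * sigma = ln(2.1e6 / 1e5),  mu = ln(1e5) - z_{0.08} * sigma
_PRICE_LOG_SD = 1.434516
_PRICE_LOG_MEAN = 13.528590


@dataclass(frozen=True)
class Parcel:
    """One property: area (acres), assessed value (CAD), beta-diversity score."""

    id: int
    area_acres: float
    assessed_value: float
    beta_score: float

    def __post_init__(self) -> None:
        if self.area_acres <= 0:
            raise InputError("area_acres must be > 0")
        if self.assessed_value <= 0:
            raise InputError("assessed_value must be > 0")
        if self.beta_score < 0:
            raise InputError("beta_score must be >= 0")


@dataclass(frozen=True)
class PortfolioParams:
    """Parameters of the synthetic portfolio generator.

    Areas and prices per acre are lognormal; areas are truncated to
    ``[area_min_acres, area_max_acres]``.  ``price_beta_correlation`` is the
    Spearman rank correlation between price per acre and beta score,
    implemented through a Gaussian copula; it must lie in ``[-1, 0]``
    (affordable rural parcels tend to score high).
    """

    n_parcels: int = 20_000
    area_log_mean: float = math.log(5.0)
    area_log_sd: float = 1.5
    area_min_acres: float = 0.01
    area_max_acres: float = 5_830.0
    price_log_mean: float = _PRICE_LOG_MEAN
    price_log_sd: float = _PRICE_LOG_SD
    beta_log_mean: float = 0.0
    beta_log_sd: float = 1.0
    price_beta_correlation: float = -0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parcels < 1:
            raise ConfigurationError("n_parcels must be >= 1")
        numeric = (
            self.area_log_mean, self.area_log_sd, self.area_min_acres,
            self.area_max_acres, self.price_log_mean, self.price_log_sd,
            self.beta_log_mean, self.beta_log_sd, self.price_beta_correlation,
        )
        if not all(math.isfinite(v) for v in numeric):
            raise ConfigurationError("portfolio distribution parameters must be finite")
        if self.area_log_sd <= 0 or self.price_log_sd <= 0 or self.beta_log_sd <= 0:
            raise ConfigurationError("log-sd parameters must be > 0")
        if not (0 < self.area_min_acres < self.area_max_acres):
            raise ConfigurationError("require 0 < area_min_acres < area_max_acres")
        if not (-1.0 <= self.price_beta_correlation <= 0.0):
            raise ConfigurationError("price_beta_correlation must be in [-1, 0]")


class Portfolio:
    """A collection of parcels backed by a pandas DataFrame.

    The frame has columns ``parcel_id, area_acres, assessed_value,
    beta_score`` with unique integer ids sorted ascending.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in PARCEL_COLUMNS if c not in frame.columns]
        if missing:
            raise InputError(f"portfolio table missing columns: {missing}")
        frame = frame[PARCEL_COLUMNS].sort_values("parcel_id").reset_index(drop=True)
        if frame["parcel_id"].duplicated().any():
            raise InputError("parcel ids must be unique")
        if len(frame) == 0:
            raise InputError("portfolio must contain at least one parcel")
        if (frame["area_acres"] <= 0).any() or (frame["assessed_value"] <= 0).any():
            raise InputError("areas and assessed values must be > 0")
        if (frame["beta_score"] < 0).any():
            raise InputError("beta scores must be >= 0")
        self._frame = frame

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._frame)

    def __iter__(self) -> Iterator[Parcel]:
        return iter(self.parcels())

    def parcels(self) -> list[Parcel]:
        return [
            Parcel(int(r.parcel_id), float(r.area_acres),
                   float(r.assessed_value), float(r.beta_score))
            for r in self._frame.itertuples(index=False)
        ]

    # -- array views --------------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def ids(self) -> np.ndarray:
        return self._frame["parcel_id"].to_numpy()

    @property
    def areas(self) -> np.ndarray:
        return self._frame["area_acres"].to_numpy()

    @property
    def values(self) -> np.ndarray:
        return self._frame["assessed_value"].to_numpy()

    @property
    def betas(self) -> np.ndarray:
        return self._frame["beta_score"].to_numpy()

    @property
    def total_beta(self) -> float:
        return float(self._frame["beta_score"].sum())

    def subset_arrays(self, parcel_ids) -> pd.DataFrame:
        """Rows for the given ids, sorted by id (raises on unknown ids)."""
        wanted = sorted(int(i) for i in parcel_ids)
        sub = self._frame[self._frame["parcel_id"].isin(wanted)]
        if len(sub) != len(wanted):
            raise InputError("unknown parcel ids requested")
        return sub.reset_index(drop=True)

    # -- I/O ----------------------------------------------------------------
    def to_csv(self, path) -> None:
        self._frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Portfolio":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class ReserveNetwork:
    """A selected parcel subset with cached totals."""

    solution_id: int
    parcel_ids: frozenset
    total_beta: float
    total_area_acres: float
    total_assessed_value: float

    @classmethod
    def from_members(cls, portfolio: Portfolio, parcel_ids, solution_id: int = 0):
        sub = portfolio.subset_arrays(parcel_ids)
        return cls(
            solution_id=solution_id,
            parcel_ids=frozenset(int(i) for i in sub["parcel_id"]),
            total_beta=float(sub["beta_score"].sum()),
            total_area_acres=float(sub["area_acres"].sum()),
            total_assessed_value=float(sub["assessed_value"].sum()),
        )

    def __len__(self) -> int:
        return len(self.parcel_ids)


def generate_portfolio(params: PortfolioParams) -> Portfolio:
    """Draw a synthetic parcel portfolio; deterministic for a fixed seed.

    Assessed value is ``area * price_per_acre``; the beta score is drawn
    with the configured negative rank correlation to price per acre via a
    Gaussian copula.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_parcels

    # truncated lognormal areas via inverse-CDF on the log scale
    a = (math.log(params.area_min_acres) - params.area_log_mean) / params.area_log_sd
    b = (math.log(params.area_max_acres) - params.area_log_mean) / params.area_log_sd
    z_area = stats.truncnorm.ppf(rng.random(n), a, b)
    areas = np.exp(params.area_log_mean + params.area_log_sd * z_area)

    # Gaussian copula between price/acre and beta; Spearman -> Pearson on
    # normal scores via rho = 2*sin(pi*rho_s/6)
    rho = 2.0 * math.sin(math.pi * params.price_beta_correlation / 6.0)
    z_price = rng.standard_normal(n)
    z_indep = rng.standard_normal(n)
    z_beta = rho * z_price + math.sqrt(max(0.0, 1.0 - rho * rho)) * z_indep

    price_per_acre = np.exp(params.price_log_mean + params.price_log_sd * z_price)
    betas = np.exp(params.beta_log_mean + params.beta_log_sd * z_beta)

    frame = pd.DataFrame(
        {
            "parcel_id": np.arange(1, n + 1, dtype=int),
            "area_acres": areas,
            "assessed_value": areas * price_per_acre,
            "beta_score": betas,
        }
    )
    return Portfolio(frame)


def _target_beta(portfolio: Portfolio, target_fraction: float) -> float:
    if not (0.0 < target_fraction <= 1.0):
        raise ConfigurationError("target_fraction must be in (0, 1]")
    total = portfolio.total_beta
    if total <= 0:
        raise InputError("portfolio total beta must be > 0")
    return target_fraction * total


def _greedy_ids(
    ids: np.ndarray, betas: np.ndarray, costs: np.ndarray, target_beta: float
) -> list[int]:
    # descending beta/cost ratio, ties broken by smaller id
    ratio = betas / costs
    order = np.lexsort((ids, -ratio))
    cum = np.cumsum(betas[order])
    # first index where the target is met (target_beta <= total always holds)
    k = int(np.searchsorted(cum, target_beta - 1e-9 * max(1.0, target_beta)) + 1)
    k = min(k, len(ids))
    return [int(i) for i in ids[order[:k]]]


def select_network_greedy(
    portfolio: Portfolio,
    target_fraction: float,
    cost_values: np.ndarray | None = None,
    solution_id: int = 0,
) -> ReserveNetwork:
    """Greedy minimum-cost selection by descending beta/cost ratio.

    Parcels are added in descending ``beta_score / cost`` order (ties broken
    by smaller id) until the cumulative beta score reaches
    ``target_fraction`` of the portfolio total.  ``cost_values`` overrides
    the assessed values used for ranking (e.g. jittered costs); the target
    is always evaluated on true beta scores.
    """
    target = _target_beta(portfolio, target_fraction)
    costs = portfolio.values if cost_values is None else np.asarray(cost_values, float)
    if costs.shape != portfolio.values.shape or np.any(costs <= 0):
        raise InputError("cost_values must be positive and match the portfolio")
    chosen = _greedy_ids(portfolio.ids, portfolio.betas, costs, target)
    return ReserveNetwork.from_members(portfolio, chosen, solution_id)


@dataclass(frozen=True)
class AnnealSchedule:
    """Simulated-annealing schedule: geometric cooling over ``n_steps`` flips."""

    t_initial: float = 1.0
    t_final: float = 1e-4
    n_steps: int = 20_000

    def __post_init__(self) -> None:
        if not (0 < self.t_final <= self.t_initial) or self.n_steps < 1:
            raise ConfigurationError("invalid annealing schedule parameters")

    def temperatures(self) -> np.ndarray:
        return np.geomspace(self.t_initial, self.t_final, self.n_steps)


def select_network_annealed(
    portfolio: Portfolio,
    target_fraction: float,
    penalty_weight: float | None = None,
    schedule: AnnealSchedule | None = None,
    seed: int = 0,
    solution_id: int = 0,
) -> ReserveNetwork:
    """Minimum-set selection by simulated annealing.

    Minimizes ``total cost + penalty_weight * max(0, target - achieved beta)``
    with single-parcel flip moves and geometric cooling, starting from the
    greedy solution.  The result is repaired (greedy add) and pruned
    (drop redundant parcels) so the beta target is always met.  Deterministic
    for a fixed seed.
    """
    if schedule is None:
        schedule = AnnealSchedule()
    target = _target_beta(portfolio, target_fraction)
    ids, betas, costs = portfolio.ids, portfolio.betas, portfolio.values
    n = len(ids)
    if penalty_weight is None:
        # steep enough that any beta shortfall dominates buying every parcel
        penalty_weight = 10.0 * float(costs.sum()) / target
    if penalty_weight <= 0:
        raise ConfigurationError("penalty_weight must be > 0")

    rng = np.random.default_rng(seed)
    id_to_idx = {int(pid): k for k, pid in enumerate(ids)}
    start = select_network_greedy(portfolio, target_fraction)
    selected = np.zeros(n, dtype=bool)
    for pid in start.parcel_ids:
        selected[id_to_idx[pid]] = True

    beta_sum = float(betas[selected].sum())
    cost_sum = float(costs[selected].sum())

    def energy(cost: float, beta: float) -> float:
        return cost + penalty_weight * max(0.0, target - beta)

    current = energy(cost_sum, beta_sum)
    best = (current, selected.copy())

    temps = schedule.temperatures()
    flips = rng.integers(0, n, size=schedule.n_steps)
    accepts = rng.random(schedule.n_steps)
    scale = max(1.0, float(np.median(costs)))
    for step in range(schedule.n_steps):
        j = flips[step]
        sign = -1.0 if selected[j] else 1.0
        new_cost = cost_sum + sign * costs[j]
        new_beta = beta_sum + sign * betas[j]
        new_e = energy(new_cost, new_beta)
        delta = (new_e - current) / scale
        if delta <= 0 or accepts[step] < math.exp(-delta / temps[step]):
            selected[j] = ~selected[j]
            cost_sum, beta_sum, current = new_cost, new_beta, new_e
            if current < best[0] and beta_sum >= target:
                best = (current, selected.copy())

    selected = best[1]
    beta_sum = float(betas[selected].sum())

    # repair: greedy-add by ratio until the target is met
    if beta_sum < target:
        ratio = betas / costs
        for j in np.lexsort((ids, -ratio)):
            if beta_sum >= target:
                break
            if not selected[j]:
                selected[j] = True
                beta_sum += betas[j]

    # prune: drop expensive parcels whose removal keeps the target met
    for j in np.argsort(-costs):
        if selected[j] and beta_sum - betas[j] >= target:
            selected[j] = False
            beta_sum -= betas[j]

    chosen = [int(pid) for pid in ids[selected]]
    return ReserveNetwork.from_members(portfolio, chosen, solution_id)


def generate_solution_set(
    portfolio: Portfolio,
    n_solutions: int,
    target_fraction: float,
    jitter: float,
    seed: int = 0,
) -> list[ReserveNetwork]:
    """An ensemble of target-meeting networks with per-solution cost jitter.

    For each solution, parcel costs are multiplied by independent
    ``Uniform(1 - jitter, 1 + jitter)`` draws before greedy selection,
    emulating run-to-run variability of a stochastic reserve-design solver.
    Every network meets the target on true (unjittered) beta scores.
    """
    if n_solutions < 1:
        raise ConfigurationError("n_solutions must be >= 1")
    if not (0.0 <= jitter < 1.0):
        raise ConfigurationError("jitter must be in [0, 1)")
    rng = np.random.default_rng(seed)
    networks = []
    for s in range(n_solutions):
        if jitter > 0:
            factors = rng.uniform(1.0 - jitter, 1.0 + jitter, size=len(portfolio))
            costs = portfolio.values * factors
        else:
            costs = portfolio.values
        networks.append(
            select_network_greedy(portfolio, target_fraction, costs, solution_id=s)
        )
    return networks
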