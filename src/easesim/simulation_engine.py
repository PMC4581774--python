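"""Long-horizon trajectories of cost and protected biodiversity.

The purchase scenario pays the full (endowment-inflated) price at year 0
and keeps its biodiversity forever.  The easement scenario pays per-parcel
setup at year 0, then each year pays recurring costs and exposes every
easement independently to a Bernoulli dispute: PE disputes add a sampled
monetary cost, DE disputes multiply the easement's *remaining* beta score
by ``1 - loss_fraction`` (repeated disputes compound; scores never go
negative; easements persist and keep costing regardless of losses).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cost_models import (
    EasementCostSchedule,
    PurchaseCostModel,
    easement_recurring_annual,
    easement_setup_cost,
)
from .dispute_model import (
    DisputeCostProfile,
    DisputeEvent,
    DisputeKind,
    sample_dispute_costs,
    sample_loss_fractions,
)
from .errors import ConfigurationError
from .synthetic_landscape import (
    Portfolio,
    PortfolioParams,
    ReserveNetwork,
    generate_solution_set,
)

__all__ = [
    "ScenarioConfig",
    "Trajectory",
    "ExperimentResult",
    "simulate_purchase",
    "simulate_easement",
    "run_experiment",
]

DEFAULT_DISPUTE_RATES = (0.0, 0.00028, 0.0028, 0.028)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full configuration of one experiment.

    ``dispute_rates`` are per-easement per-year dispute probabilities; the
    zero rate is the no-dispute easement baseline.
    """

    dispute_rates: tuple = DEFAULT_DISPUTE_RATES
    years: int = 100
    pe_probability: float = 0.5
    loss_jitter_sd: float = 0.05
    protection_target: float = 0.20
    trust_fraction: float = 0.15
    n_solutions: int = 100
    solution_jitter: float = 0.05
    seed: int = 0
    schedule: EasementCostSchedule = field(default_factory=EasementCostSchedule)
    dispute_profile: DisputeCostProfile = field(default_factory=DisputeCostProfile)
    portfolio: PortfolioParams = field(default_factory=PortfolioParams)

    def __post_init__(self) -> None:
        rates = tuple(float(r) for r in self.dispute_rates)
        if not rates:
            raise ConfigurationError("dispute_rates must be non-empty")
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ConfigurationError("dispute rates must be in [0, 1]")
        object.__setattr__(self, "dispute_rates", rates)
        if self.years < 1:
            raise ConfigurationError("years must be >= 1")
        if not (0.0 <= self.pe_probability <= 1.0):
            raise ConfigurationError("pe_probability must be in [0, 1]")
        if self.loss_jitter_sd < 0 or not math.isfinite(self.loss_jitter_sd):
            raise ConfigurationError("loss_jitter_sd must be finite and >= 0")
        if not (0.0 < self.protection_target <= 1.0):
            raise ConfigurationError("protection_target must be in (0, 1]")
        if self.trust_fraction < 0:
            raise ConfigurationError("trust_fraction must be >= 0")
        if self.n_solutions < 1:
            raise ConfigurationError("n_solutions must be >= 1")
        if not (0.0 <= self.solution_jitter < 1.0):
            raise ConfigurationError("solution_jitter must be in [0, 1)")

    @property
    def purchase_model(self) -> PurchaseCostModel:
        return PurchaseCostModel(self.trust_fraction)


@dataclass
class Trajectory:
    """Per-year cumulative cost and remaining protected beta for one network."""

    scenario: str
    solution_id: int
    cumulative_cost: np.ndarray  # shape (years + 1,)
    protected_beta: np.ndarray  # shape (years + 1,)
    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cumulative_cost = np.asarray(self.cumulative_cost, dtype=float)
        self.protected_beta = np.asarray(self.protected_beta, dtype=float)
        if self.cumulative_cost.shape != self.protected_beta.shape:
            raise ConfigurationError("trajectory arrays must share a shape")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.cumulative_cost.size)

    @property
    def final_cost(self) -> float:
        return float(self.cumulative_cost[-1])

    @property
    def final_loss_fraction(self) -> float:
        b0 = self.protected_beta[0]
        return float(1.0 - self.protected_beta[-1] / b0) if b0 > 0 else 0.0


def simulate_purchase(network: ReserveNetwork, config: ScenarioConfig) -> Trajectory:
    """Fee-simple purchase: all cost at year 0, biodiversity constant, no events."""
    t = config.years
    cost = network.total_assessed_value * (1.0 + config.trust_fraction)
    return Trajectory(
        scenario="purchase",
        solution_id=network.solution_id,
        cumulative_cost=np.full(t + 1, cost),
        protected_beta=np.full(t + 1, network.total_beta),
    )


def simulate_easement(
    network: ReserveNetwork,
    portfolio: Portfolio,
    config: ScenarioConfig,
    dispute_rate: float,
    rng: np.random.Generator,
    record_events: bool = True,
) -> Trajectory:
    """Easement scenario for one network at one dispute rate.

    Year 0 charges the per-parcel setup cost.  Every later year charges the
    recurring cost per easement and samples disputes easement-by-easement
    (at most one per easement per year).
    """
    members = portfolio.subset_arrays(network.parcel_ids)
    ids = members["parcel_id"].to_numpy()
    areas = members["area_acres"].to_numpy()
    betas = members["beta_score"].to_numpy(dtype=float).copy()
    n = len(ids)
    t_max = config.years

    recurring = easement_recurring_annual(config.schedule) * n
    cost = np.empty(t_max + 1)
    beta = np.empty(t_max + 1)
    cost[0] = float(np.sum(easement_setup_cost(areas, config.schedule)))
    beta[0] = betas.sum()
    events: list[DisputeEvent] = []

    for t in range(1, t_max + 1):
        cost[t] = cost[t - 1] + recurring
        if dispute_rate > 0:
            disputed = np.flatnonzero(rng.random(n) < dispute_rate)
            if disputed.size:
                is_pe = rng.random(disputed.size) < config.pe_probability
                pe_idx = disputed[is_pe]
                de_idx = disputed[~is_pe]
                if pe_idx.size:
                    pe_costs = sample_dispute_costs(
                        config.dispute_profile, rng, pe_idx.size
                    )
                    cost[t] += pe_costs.sum()
                if de_idx.size:
                    losses = sample_loss_fractions(
                        config.dispute_profile, config.loss_jitter_sd, rng, de_idx.size
                    )
                    betas[de_idx] = np.maximum(0.0, betas[de_idx] * (1.0 - losses))
                if record_events:
                    for k, j in enumerate(pe_idx):
                        events.append(DisputeEvent(t, int(ids[j]), DisputeKind.PE,
                                                   cost=float(pe_costs[k])))
                    for k, j in enumerate(de_idx):
                        events.append(DisputeEvent(t, int(ids[j]), DisputeKind.DE,
                                                   loss_fraction=float(losses[k])))
        beta[t] = betas.sum()

    return Trajectory(
        scenario=f"easement_rate_{dispute_rate:g}",
        solution_id=network.solution_id,
        cumulative_cost=cost,
        protected_beta=beta,
        events=events,
    )


@dataclass
class ExperimentResult:
    """Per-scenario, per-solution trajectories plus ensemble summaries.

    ``easement_cost`` / ``easement_beta`` have shape
    ``(n_rates, n_solutions, years + 1)``; purchase arrays have shape
    ``(n_solutions, years + 1)``.
    """

    config: ScenarioConfig
    networks: list
    purchase_cost: np.ndarray
    purchase_beta: np.ndarray
    easement_cost: np.ndarray
    easement_beta: np.ndarray

    @property
    def rates(self) -> tuple:
        return self.config.dispute_rates

    def scenario_labels(self) -> list[str]:
        return ["purchase"] + [f"easement_rate_{r:g}" for r in self.rates]

    def final_loss_pct(self) -> np.ndarray:
        """Biodiversity loss %, per rate and solution, relative to year 0."""
        b0 = self.easement_beta[:, :, 0]
        return 100.0 * (1.0 - self.easement_beta[:, :, -1] / b0)

    def purchase_trajectory(self, solution: int) -> Trajectory:
        return Trajectory("purchase", solution,
                          self.purchase_cost[solution], self.purchase_beta[solution])

    def easement_trajectory(self, rate_index: int, solution: int) -> Trajectory:
        rate = self.rates[rate_index]
        return Trajectory(f"easement_rate_{rate:g}", solution,
                          self.easement_cost[rate_index, solution],
                          self.easement_beta[rate_index, solution])

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per scenario x solution x year."""
        n_sol, n_years = self.purchase_cost.shape
        rows = []
        years = np.arange(n_years)
        for s in range(n_sol):
            rows.append(pd.DataFrame({
                "scenario": "purchase",
                "dispute_rate": 0.0,
                "solution_id": s,
                "year": years,
                "cumulative_cost": self.purchase_cost[s],
                "protected_beta": self.purchase_beta[s],
            }))
        for i, r in enumerate(self.rates):
            for s in range(n_sol):
                rows.append(pd.DataFrame({
                    "scenario": f"easement_rate_{r:g}",
                    "dispute_rate": r,
                    "solution_id": s,
                    "year": years,
                    "cumulative_cost": self.easement_cost[i, s],
                    "protected_beta": self.easement_beta[i, s],
                }))
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExperimentResult":
        """Rebuild result arrays from a tidy trajectory table (see to_frame)."""
        required = {"scenario", "dispute_rate", "solution_id", "year",
                    "cumulative_cost", "protected_beta"}
        missing = required - set(frame.columns)
        if missing:
            raise ConfigurationError(f"trajectory table missing columns: {missing}")
        years = int(frame["year"].max())
        solutions = np.sort(frame["solution_id"].unique())
        n_sol = len(solutions)

        def pivot(sub: pd.DataFrame, column: str) -> np.ndarray:
            wide = sub.pivot(index="solution_id", columns="year", values=column)
            return wide.sort_index().to_numpy()

        purchase = frame[frame["scenario"] == "purchase"]
        ease = frame[frame["scenario"] != "purchase"]
        rates = tuple(sorted(ease["dispute_rate"].unique()))
        e_cost = np.empty((len(rates), n_sol, years + 1))
        e_beta = np.empty((len(rates), n_sol, years + 1))
        for i, r in enumerate(rates):
            sub = ease[ease["dispute_rate"] == r]
            e_cost[i] = pivot(sub, "cumulative_cost")
            e_beta[i] = pivot(sub, "protected_beta")
        config = ScenarioConfig(dispute_rates=rates, years=years, n_solutions=n_sol)
        return cls(
            config=config,
            networks=[],
            purchase_cost=pivot(purchase, "cumulative_cost"),
            purchase_beta=pivot(purchase, "protected_beta"),
            easement_cost=e_cost,
            easement_beta=e_beta,
        )


def run_experiment(
    portfolio: Portfolio,
    config: ScenarioConfig,
    networks: Sequence[ReserveNetwork] | None = None,
) -> ExperimentResult:
    """Build the solution ensemble and simulate every scenario for every solution.

    Deterministic for a fixed config (bit-identical arrays across calls):
    all randomness flows from ``config.seed`` through spawned generator
    streams, one per (rate, solution) simulation.
    """
    ss = np.random.SeedSequence(config.seed)
    sol_ss, sim_ss = ss.spawn(2)
    if networks is None:
        networks = generate_solution_set(
            portfolio,
            config.n_solutions,
            config.protection_target,
            config.solution_jitter,
            seed=sol_ss,
        )
    n_sol = len(networks)
    rates = config.dispute_rates
    t = config.years

    purchase_cost = np.empty((n_sol, t + 1))
    purchase_beta = np.empty((n_sol, t + 1))
    for s, net in enumerate(networks):
        traj = simulate_purchase(net, config)
        purchase_cost[s] = traj.cumulative_cost
        purchase_beta[s] = traj.protected_beta

    easement_cost = np.empty((len(rates), n_sol, t + 1))
    easement_beta = np.empty((len(rates), n_sol, t + 1))
    children = sim_ss.spawn(len(rates) * n_sol)
    for i, rate in enumerate(rates):
        for s, net in enumerate(networks):
            rng = np.random.default_rng(children[i * n_sol + s])
            traj = simulate_easement(net, portfolio, config, rate, rng,
                                     record_events=False)
            easement_cost[i, s] = traj.cumulative_cost
            easement_beta[i, s] = traj.protected_beta

    return ExperimentResult(
        config=config,
        networks=list(networks),
        purchase_cost=purchase_cost,
        purchase_beta=purchase_beta,
        easement_cost=easement_cost,
        easement_beta=easement_beta,
    )
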