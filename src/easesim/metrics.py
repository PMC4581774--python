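"""Cost-effectiveness and comparative summary statistics.

Cost-effectiveness of a scenario is the protected biodiversity fraction
divided by cumulative cost, standardized by the same quantity for the
purchase scenario.  Biodiversity loss percentages are always reported
relative to the initially protected amount (the protection target counts as
100%), never relative to the whole landscape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .simulation_engine import ExperimentResult, Trajectory

__all__ = [
    "CostEffectiveness",
    "relative_cost_effectiveness",
    "percent_reduction",
    "percent_of_baseline",
    "percent_increase",
    "summarize_table2",
]


@dataclass(frozen=True)
class CostEffectiveness:
    """Relative cost-effectiveness of one scenario by year (dimensionless)."""

    scenario: str
    ce_relative: np.ndarray

    @property
    def final(self) -> float:
        return float(self.ce_relative[-1])


def relative_cost_effectiveness(
    easement_traj: Trajectory, purchase_traj: Trajectory
) -> CostEffectiveness:
    """(biodiversity / cost) of the easement scenario over the purchase value.

    ``ce[t] = (B_e(t) / C_e(t)) / (B_p / C_p)`` where ``B`` is the protected
    beta fraction relative to the initially protected amount and ``C`` the
    cumulative cost at year ``t``.  With zero disputes the biodiversity
    terms cancel and the ratio reduces to the cost ratio.
    """
    if easement_traj.cumulative_cost.shape != purchase_traj.cumulative_cost.shape:
        raise InputError("trajectories must share the same horizon")
    c_e = easement_traj.cumulative_cost
    c_p = purchase_traj.cumulative_cost
    if np.any(c_e <= 0) or np.any(c_p <= 0):
        raise InputError("cost-effectiveness undefined at zero cost")
    b_e = easement_traj.protected_beta / easement_traj.protected_beta[0]
    b_p = purchase_traj.protected_beta / purchase_traj.protected_beta[0]
    ce = (b_e / c_e) / (b_p / c_p)
    return CostEffectiveness(easement_traj.scenario, ce)


def percent_reduction(cost: float, baseline: float) -> float:
    """Percent reduction of ``cost`` relative to ``baseline`` (positive = cheaper)."""
    if baseline <= 0:
        raise InputError("baseline must be > 0")
    return 100.0 * (1.0 - cost / baseline)


def percent_of_baseline(cost: float, baseline: float) -> float:
    """``cost`` expressed as a percentage of ``baseline``."""
    if baseline <= 0:
        raise InputError("baseline must be > 0")
    return 100.0 * cost / baseline


def percent_increase(cost: float, baseline: float) -> float:
    """Percent increase of ``cost`` over ``baseline``."""
    if baseline <= 0:
        raise InputError("baseline must be > 0")
    return 100.0 * (cost - baseline) / baseline


def summarize_table2(result: ExperimentResult) -> pd.DataFrame:
    """Comparative summary: one row per scenario with mean (min-max) columns.

    Rows: land purchase, easement setup (year-0 cost), then the 100-year
    easement scenario at each configured dispute rate.  Columns carry exact
    values; rounding to report precision is left to the presentation layer.
    """
    records = []

    def row(scenario, costs, losses, *, no_dispute_mean=None, purchase_mean=None):
        rec = {
            "scenario": scenario,
            "cost_mean": float(np.mean(costs)),
            "cost_min": float(np.min(costs)),
            "cost_max": float(np.max(costs)),
            "loss_pct_mean": float(np.mean(losses)),
            "loss_pct_min": float(np.min(losses)),
            "loss_pct_max": float(np.max(losses)),
        }
        rec["pct_cost_change_vs_no_dispute"] = (
            percent_increase(rec["cost_mean"], no_dispute_mean)
            if no_dispute_mean is not None else np.nan
        )
        rec["pct_cost_reduction_vs_purchase"] = (
            percent_reduction(rec["cost_mean"], purchase_mean)
            if purchase_mean is not None else np.nan
        )
        records.append(rec)
        return rec

    zeros = np.zeros(result.purchase_cost.shape[0])
    purchase = row("purchase", result.purchase_cost[:, -1], zeros)
    row("easement_setup", result.easement_cost[0, :, 0], zeros,
        purchase_mean=purchase["cost_mean"])

    rates = result.rates
    losses = result.final_loss_pct()
    try:
        base_idx = rates.index(0.0)
    except ValueError:
        base_idx = None
    no_dispute_mean = (
        float(result.easement_cost[base_idx, :, -1].mean())
        if base_idx is not None else None
    )
    for i, r in enumerate(rates):
        row(
            f"easement_rate_{r:g}",
            result.easement_cost[i, :, -1],
            losses[i],
            no_dispute_mean=no_dispute_mean,
            purchase_mean=purchase["cost_mean"],
        )
    return pd.DataFrame.from_records(records)
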