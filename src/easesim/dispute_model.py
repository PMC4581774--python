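"""Annual easement-dispute events: kinds, monetary costs, biodiversity losses.

Dispute costs follow a bounded power-law profile: a dispute "index" ``u`` is
drawn uniformly over the interval that maps onto the cost bounds, and the
cost is ``a * u**(-b)`` clamped to ``[L, U]``.  This is exactly a bounded
Pareto distribution on ``[L, U]`` with shape ``1/b`` — low costs are
frequent, high costs rare.  Optionally a heavy tail mixes in: with a small
probability the cost is instead drawn from a normal distribution truncated
below at its mean, allowing costs far above the base upper bound.

Disputes come in two kinds:

* PE (pre-emptive enforcement): monetary cost, no biodiversity loss;
* DE (damage enforcement): no monetary cost, a fractional biodiversity loss
  that follows the same bounded distribution rescaled onto ``[0, 1]``,
  optionally jittered with truncated Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable

import numpy as np
from scipy import stats

from .errors import ConfigurationError, InputError

__all__ = [
    "DisputeKind",
    "DisputeCostProfile",
    "DisputeEvent",
    "sample_dispute_cost",
    "sample_dispute_costs",
    "bounded_cost_cdf",
    "cost_to_loss_fraction",
    "sample_loss_fraction",
    "sample_loss_fractions",
    "assign_dispute_kind",
]


class DisputeKind(str, Enum):
    PE = "PE"  # pre-emptive enforcement: cost, no habitat loss
    DE = "DE"  # damage enforcement: habitat loss, no net cost


@dataclass(frozen=True)
class DisputeCostProfile:
    """Constants of the bounded power-law dispute-cost distribution.

    ``cost = coefficient * u**(-exponent)`` clamped to
    ``[lower_bound, upper_bound]``, with ``u`` uniform over the pre-image of
    the bounds.  The optional tail replaces the base draw with probability
    ``tail_probability`` by a left-truncated normal starting at ``tail_mean``.
    """

    coefficient: float = 4_845.78
    exponent: float = 0.701
    lower_bound: float = 1_000.0
    upper_bound: float = 400_000.0
    tail_enabled: bool = False
    tail_probability: float = 0.01
    tail_mean: float = 400_000.0
    tail_sd: float = 1_000_000.0

    def __post_init__(self) -> None:
        if not (0 < self.lower_bound < self.upper_bound):
            raise ConfigurationError("require 0 < lower_bound < upper_bound")
        if self.coefficient <= 0 or self.exponent <= 0:
            raise ConfigurationError("coefficient and exponent must be > 0")
        if not (0 <= self.tail_probability <= 1):
            raise ConfigurationError("tail_probability must be in [0, 1]")
        if self.tail_sd <= 0:
            raise ConfigurationError("tail_sd must be > 0")

    # Pre-image of the cost bounds under cost = a * u**(-b); cost decreases
    # in u, so u_min maps to the upper cost bound and u_max to the lower.
    @property
    def u_min(self) -> float:
        return (self.coefficient / self.upper_bound) ** (1.0 / self.exponent)

    @property
    def u_max(self) -> float:
        return (self.coefficient / self.lower_bound) ** (1.0 / self.exponent)

    @property
    def pareto_shape(self) -> float:
        """Shape of the equivalent bounded Pareto (``1/exponent``)."""
        return 1.0 / self.exponent


@dataclass(frozen=True)
class DisputeEvent:
    """One dispute on one easement in one simulation year."""

    year: int
    easement_id: object
    kind: DisputeKind
    cost: float = 0.0
    loss_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind is DisputeKind.PE and self.loss_fraction != 0.0:
            raise InputError("PE events carry no biodiversity loss")
        if self.kind is DisputeKind.DE and self.cost != 0.0:
            raise InputError("DE events carry no monetary cost")
        if not (0.0 <= self.loss_fraction <= 1.0):
            raise InputError("loss_fraction must be in [0, 1]")
        if self.cost < 0.0:
            raise InputError("cost must be non-negative")


def _sample_base_costs(
    profile: DisputeCostProfile, rng: np.random.Generator, size: int
) -> np.ndarray:
    u = rng.uniform(profile.u_min, profile.u_max, size=size)
    cost = profile.coefficient * u ** (-profile.exponent)
    return np.clip(cost, profile.lower_bound, profile.upper_bound)


def sample_dispute_costs(
    profile: DisputeCostProfile, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Vectorized dispute-cost draws (base profile plus optional tail mixture)."""
    cost = _sample_base_costs(profile, rng, size)
    if profile.tail_enabled and profile.tail_probability > 0:
        in_tail = rng.random(size) < profile.tail_probability
        n_tail = int(in_tail.sum())
        if n_tail:
            # left-truncated normal: lower bound at the mean ("left tail cut off")
            u = rng.random(n_tail)
            tail_draws = stats.truncnorm.ppf(
                u, 0.0, np.inf, loc=profile.tail_mean, scale=profile.tail_sd
            )
            cost[in_tail] = tail_draws
    return cost


def sample_dispute_cost(profile: DisputeCostProfile, rng: np.random.Generator) -> float:
    """Draw a single dispute cost in CAD."""
    return float(sample_dispute_costs(profile, rng, 1)[0])


def bounded_cost_cdf(profile: DisputeCostProfile, cost) -> np.ndarray:
    """Closed-form CDF of the base (tail-free) bounded cost distribution.

    Bounded Pareto on ``[L, U]`` with shape ``alpha = 1/exponent``:
    ``F(c) = (1 - (L/c)**alpha) / (1 - (L/U)**alpha)``.
    """
    c = np.clip(np.asarray(cost, dtype=float), profile.lower_bound, profile.upper_bound)
    alpha = profile.pareto_shape
    lo, hi = profile.lower_bound, profile.upper_bound
    return (1.0 - (lo / c) ** alpha) / (1.0 - (lo / hi) ** alpha)


def cost_to_loss_fraction(cost, profile: DisputeCostProfile):
    """Linearly rescale a cost in ``[L, U]`` to a loss fraction in ``[0, 1]``."""
    c = np.asarray(cost, dtype=float)
    if np.any(c < profile.lower_bound) or np.any(c > profile.upper_bound):
        raise InputError("cost outside the profile bounds")
    frac = (c - profile.lower_bound) / (profile.upper_bound - profile.lower_bound)
    return float(frac) if np.isscalar(cost) or c.ndim == 0 else frac

LossMapping = Callable[[np.ndarray, DisputeCostProfile], np.ndarray]


def sample_loss_fractions(
    profile: DisputeCostProfile,
    jitter_sd: float,
    rng: np.random.Generator,
    size: int,
    mapping: LossMapping = cost_to_loss_fraction,
) -> np.ndarray:
    """Vectorized biodiversity-loss fractions for DE events.

    A base cost draw is mapped onto ``[0, 1]`` (default: linear rescale of
    the bounded support; the mapping is pluggable) and jittered with
    ``Normal(0, jitter_sd)`` noise truncated back into ``[0, 1]``.  Loss
    draws always use the base profile — the monetary tail does not apply to
    habitat damage.
    """
    if not math.isfinite(jitter_sd) or jitter_sd < 0:
        raise ConfigurationError("jitter_sd must be finite and >= 0")
    base = np.asarray(mapping(_sample_base_costs(profile, rng, size), profile))
    if jitter_sd > 0:
        base = base + rng.normal(0.0, jitter_sd, size=size)
    return np.clip(base, 0.0, 1.0)


def sample_loss_fraction(
    profile: DisputeCostProfile,
    jitter_sd: float,
    rng: np.random.Generator,
    mapping: LossMapping = cost_to_loss_fraction,
) -> float:
    """Draw a single DE biodiversity-loss fraction in [0, 1]."""
    return float(sample_loss_fractions(profile, jitter_sd, rng, 1, mapping)[0])


def assign_dispute_kind(pe_probability: float, rng: np.random.Generator) -> DisputeKind:
    """Bernoulli assignment of a dispute to PE (prob ``pe_probability``) or DE."""
    if not (0.0 <= pe_probability <= 1.0):
        raise ConfigurationError("pe_probability must be in [0, 1]")
    return DisputeKind.PE if rng.random() < pe_probability else DisputeKind.DE
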