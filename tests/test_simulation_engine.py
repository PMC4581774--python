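import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from easesim import (
    ConfigurationError,
    DisputeKind,
    DisputeCostProfile,
    Portfolio,
    PortfolioParams,
    ScenarioConfig,
    generate_portfolio,
    run_experiment,
    select_network_greedy,
    simulate_easement,
    simulate_purchase,
)
from easesim.cost_models import easement_recurring_annual, easement_setup_cost
from easesim.simulation_engine import ExperimentResult


def uniform_portfolio(n, seed=0, beta=1.0):
    """n parcels with equal beta so network loss averages evenly."""
    r = np.random.default_rng(seed)
    return Portfolio(pd.DataFrame({
        "parcel_id": np.arange(1, n + 1),
        "area_acres": r.uniform(0.5, 20.0, n),
        "assessed_value": r.uniform(1e4, 1e6, n),
        "beta_score": np.full(n, beta),
    }))


def full_network(portfolio):
    return select_network_greedy(portfolio, 1.0)


class TestSimulatePurchase:
    def test_flat_cost_line_with_trust_markup(self):
        p = uniform_portfolio(20)
        net = full_network(p)
        traj = simulate_purchase(net, ScenarioConfig(years=10))
        assert np.all(traj.cumulative_cost == 1.15 * net.total_assessed_value)

    def test_biodiversity_never_changes(self):
        p = uniform_portfolio(20)
        traj = simulate_purchase(full_network(p), ScenarioConfig(years=50))
        assert np.all(traj.protected_beta == traj.protected_beta[0])
        assert traj.events == []

    def test_zero_trust_fraction(self):
        p = uniform_portfolio(5)
        net = full_network(p)
        traj = simulate_purchase(net, ScenarioConfig(years=3, trust_fraction=0.0))
        assert traj.final_cost == pytest.approx(net.total_assessed_value)


class TestSimulateEasement:
    def test_zero_rate_closed_form(self):
        p = uniform_portfolio(30)
        net = full_network(p)
        config = ScenarioConfig(years=100)
        traj = simulate_easement(net, p, config, 0.0, np.random.default_rng(0))
        setup = float(np.sum(easement_setup_cost(p.areas, config.schedule)))
        recurring = easement_recurring_annual(config.schedule)
        expected = setup + np.arange(101) * recurring * len(net)
        np.testing.assert_allclose(traj.cumulative_cost, expected, rtol=1e-12)
        assert np.all(traj.protected_beta == traj.protected_beta[0])

    def test_degenerate_rate_one_all_pe(self):
        p = uniform_portfolio(10)
        net = full_network(p)
        config = ScenarioConfig(years=5, pe_probability=1.0)
        traj = simulate_easement(net, p, config, 1.0, np.random.default_rng(1))
        assert len(traj.events) == 10 * 5  # one per easement per year
        assert all(e.kind is DisputeKind.PE for e in traj.events)
        assert np.all(traj.protected_beta == traj.protected_beta[0])

    def test_degenerate_rate_one_all_de_loses_beta(self):
        p = uniform_portfolio(10)
        net = full_network(p)
        config = ScenarioConfig(years=5, pe_probability=0.0)
        traj = simulate_easement(net, p, config, 1.0, np.random.default_rng(1))
        assert all(e.kind is DisputeKind.DE for e in traj.events)
        assert all(e.cost == 0.0 for e in traj.events)
        assert traj.protected_beta[-1] < traj.protected_beta[0]

    def test_monotone_trajectories(self):
        p = uniform_portfolio(50)
        net = full_network(p)
        config = ScenarioConfig(years=100)
        traj = simulate_easement(net, p, config, 0.028, np.random.default_rng(7))
        assert np.all(np.diff(traj.cumulative_cost) >= 0)
        assert np.all(np.diff(traj.protected_beta) <= 0)
        assert np.all(traj.protected_beta >= 0)

    def test_event_invariants(self):
        p = uniform_portfolio(50)
        net = full_network(p)
        config = ScenarioConfig(years=50)
        traj = simulate_easement(net, p, config, 0.1, np.random.default_rng(3))
        for e in traj.events:
            if e.kind is DisputeKind.PE:
                assert e.loss_fraction == 0.0
            else:
                assert e.cost == 0.0

    def test_binomial_event_count(self):
        # 1,000 easements x 100 years x rate 0.028: mean count 2,800,
        # per-run sd sqrt(n T p (1-p)) ~ 52.2, 50 runs -> SE of mean ~ 7.4
        p = uniform_portfolio(1_000)
        net = full_network(p)
        config = ScenarioConfig(years=100)
        counts = []
        for seed in range(50):
            traj = simulate_easement(net, p, config, 0.028,
                                     np.random.default_rng(seed))
            counts.append(len(traj.events))
        expected = 1_000 * 100 * 0.028
        se = np.sqrt(1_000 * 100 * 0.028 * 0.972) / np.sqrt(50)
        assert abs(np.mean(counts) - expected) < 3 * se


class TestSmallRateLinearization:
    def test_mean_loss_matches_analytic_approximation(self):
        # loss ~= T * r * (1 - pe) * E[loss per DE event] for r*T << 1
        profile = DisputeCostProfile()
        a, b = profile.coefficient, profile.exponent
        lo, hi = profile.lower_bound, profile.upper_bound

        def loss_of_u(u):
            c = np.clip(a * u ** (-b), lo, hi)
            return (c - lo) / (hi - lo)

        mean_loss, _ = integrate.quad(loss_of_u, profile.u_min, profile.u_max,
                                      limit=200)
        mean_loss /= profile.u_max - profile.u_min

        rate, years, pe = 0.002, 100, 0.5
        config = ScenarioConfig(years=years, pe_probability=pe, loss_jitter_sd=0.0)
        p = uniform_portfolio(200)
        net = full_network(p)
        fractions = []
        for seed in range(30):
            traj = simulate_easement(net, p, config, rate,
                                     np.random.default_rng(seed),
                                     record_events=False)
            fractions.append(traj.final_loss_fraction)
        predicted = years * rate * (1 - pe) * mean_loss
        se = np.std(fractions, ddof=1) / np.sqrt(len(fractions))
        assert abs(np.mean(fractions) - predicted) < 3 * se + 1e-6


@pytest.fixture(scope="module")
def small_setup():
    config = ScenarioConfig(
        n_solutions=10,
        years=60,
        seed=11,
        portfolio=PortfolioParams(n_parcels=2_000, seed=11),
    )
    portfolio = generate_portfolio(config.portfolio)
    return config, portfolio, run_experiment(portfolio, config)


class TestRunExperiment:

    def test_single_solution_degenerate_ensemble(self):
        config = ScenarioConfig(
            dispute_rates=(0.0,), n_solutions=1, years=10,
            portfolio=PortfolioParams(n_parcels=500, seed=3), seed=3)
        portfolio = generate_portfolio(config.portfolio)
        result = run_experiment(portfolio, config)
        cost = result.easement_cost[0]
        assert np.all(cost.min(axis=0) == cost.max(axis=0))

    def test_loss_strictly_increases_with_rate(self, small_setup):
        _, _, result = small_setup
        mean_loss = result.final_loss_pct().mean(axis=1)
        assert mean_loss[0] == 0.0  # no-dispute baseline
        assert np.all(np.diff(mean_loss) > 0)

    def test_mean_cost_ordered_by_rate(self, small_setup):
        _, _, result = small_setup
        final = result.easement_cost[:, :, -1].mean(axis=1)
        assert np.all(np.diff(final) >= 0)

    def test_bit_exact_reproducibility(self, small_setup):
        config, portfolio, result = small_setup
        again = run_experiment(portfolio, config)
        np.testing.assert_array_equal(result.easement_cost, again.easement_cost)
        np.testing.assert_array_equal(result.easement_beta, again.easement_beta)
        np.testing.assert_array_equal(result.purchase_cost, again.purchase_cost)

    def test_trajectory_monotonicity_everywhere(self, small_setup):
        _, _, result = small_setup
        assert np.all(np.diff(result.easement_cost, axis=2) >= 0)
        assert np.all(np.diff(result.easement_beta, axis=2) <= 0)
        assert np.all(result.easement_beta >= 0)

    def test_frame_round_trip(self, small_setup):
        _, _, result = small_setup
        frame = result.to_frame()
        rebuilt = ExperimentResult.from_frame(frame)
        np.testing.assert_allclose(rebuilt.easement_cost, result.easement_cost)
        np.testing.assert_allclose(rebuilt.purchase_beta, result.purchase_beta)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            ScenarioConfig(dispute_rates=(-0.1,))
        with pytest.raises(ConfigurationError):
            ScenarioConfig(years=0)
        with pytest.raises(ConfigurationError):
            ScenarioConfig(pe_probability=2.0)
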