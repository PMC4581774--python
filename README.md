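# easesim

Stochastic comparison of two strategies for conserving high-biodiversity
private land over a 100-year horizon:

* **fee-simple land purchase** — pay the assessed value plus a 15%
  stewardship endowment up front, keep the biodiversity forever;
* **conservation easements** — pay a one-time setup cost (fixed legal /
  financial / registration / endowment components plus three size-scaled
  cost curves) and a flat recurring annual cost, but face an annual risk of
  landowner disputes.  Pre-emptive-enforcement (PE) disputes add a monetary
  cost drawn from a bounded power-law (bounded Pareto) profile on
  [$1,000, $400,000]; damage-enforcement (DE) disputes cost nothing but
  remove a fraction of the easement's protected biodiversity score.

The package generates synthetic parcel portfolios calibrated to an
expensive coastal market (mean ≈ $2.1M/acre, ≈ 8% of parcels under
$100k/acre), selects ensembles of reserve networks protecting 20% of the
portfolio's total beta-diversity score (a greedy benefit/cost heuristic
plus an optional simulated-annealing minimum-set solver stand in for a full
systematic reserve-design run), simulates cost/biodiversity trajectories
under dispute rates {0, 0.028, 0.28, 2.8}% of easements per year, and
reports comparative summaries including relative cost-effectiveness
(biodiversity protected per dollar, standardized by the purchase scenario).

## CLI

The console script `easesim` provides four subcommands:

```sh
# synthetic parcel table (CSV: parcel_id,area_acres,assessed_value,beta_score)
easesim generate --n 20000 --seed 1 --out parcels.csv

# ensemble of reserve networks meeting the 20% beta-diversity target
easesim select --parcels parcels.csv --solutions 100 --jitter 0.05 \
    --seed 1 --out-dir networks/

# full experiment: purchase + easement scenarios at every dispute rate
easesim simulate --config scenario.yaml --seed 1 --out-dir results/

# comparison table and cost-effectiveness series from the tidy trajectories
easesim report --trajectories results/trajectories.csv --out-dir report/
```

`simulate` writes a tidy `trajectories.csv` (one row per scenario ×
solution × year), `summary.csv`/`summary.json` (one row per scenario with
mean/min/max cost and biodiversity loss), and a `manifest.json` capturing
the full config snapshot and seed so any run can be reproduced bit-exactly.

Configs are JSON or YAML; every field is optional and unknown keys are
rejected.  An empty file gives the documented defaults (100 years, 100
solutions, 20% protection target, the default cost schedule and dispute
profile).  Example:

```yaml
dispute_rates: [0.0, 0.00028, 0.0028, 0.028]
years: 100
n_solutions: 100
pe_probability: 0.5
seed: 1
portfolio:
  n_parcels: 20000
dispute_profile:
  tail_enabled: false
```

## Layout

| module                       | role                                                    |
|------------------------------|---------------------------------------------------------|
| `easesim.synthetic_landscape`| parcel portfolio generator, reserve-network selection   |
| `easesim.cost_models`        | purchase and easement cost schedules                    |
| `easesim.dispute_model`      | dispute kinds, bounded-Pareto costs, biodiversity loss  |
| `easesim.simulation_engine`  | per-year trajectories, full experiment driver           |
| `easesim.metrics`            | cost-effectiveness, comparison-table summaries          |
| `easesim.cli_io`             | config loading/validation, manifests, CLI               |
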