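# beeforage

A foraging-energetics pipeline for bumblebee behavioral event logs: from
timestamped activity records (fly / visit / drink / rest, landed or
hovering) to per-trip energy budgets, the two candidate foraging
currencies — rate of energy return (RER, J s⁻¹) and energetic efficiency
(EE, dimensionless) — per-ten-choice window series, counterfactual
alternative-strategy comparisons, choice-proportion statistics, and an
agent-based synthetic-data simulator with known ground truth.

## What it computes

- **event_model** — domain types (bees, treatments, events, visits), CSV
  readers/writers with a pluggable column dialect, and the
  event → visit → choice aggregation rules: drinking bouts on the same
  flower merge into one visit when the bee returns within 10 s with no
  intervening flower interaction, and a visit is a *choice* (drinking
  visit) when summed tongue contact exceeds 2 s.
- **physiology** — closed-form relations: mass power-law drinking rates
  (separate 35% and 50% w/w models, concentrations ≤ 35% plateau onto the
  35% model), consumed-volume estimation with the 2 s tasting exclusion
  and 15 μL per-flower cap, sucrose solution density/mass/energy,
  Génotelle-form viscosity, abdominal temperature, viscosity-dependent
  offloading time, and mass-specific metabolic rates for flight
  (0.435 J g⁻¹ s⁻¹; flying and any hovering interaction) and probing
  (0.034 J g⁻¹ s⁻¹; landed interaction, rest, and nest time).
- **energetics** — per-trip intake/expenditure with in-trip mass updating
  (bee mass grows with consumed solution), RER and EE, event-weighted
  window series per block of ten choices (windows spanning trip
  boundaries are weighted by the events of each trip), counterfactual
  energetics (donor behavior re-evaluated under substituted
  concentrations), and the slippery-flower cost estimator (final-window
  handling time and handling energy medians).
- **stats** — binomial random-intercept choice-curve model (direct
  maximum likelihood via Gauss–Hermite quadrature) with parametric
  bootstrap CIs for population-level predicted proportions, and a
  permutation test on group mean differences (Monte-Carlo with add-one
  correction, or exhaustive enumeration).
- **synthetic_data** — agent-based generator of the full two-phase
  experiment (36 bees, 12 per treatment over 3 colonies; familiarization
  to the 60th drinking visit, test to the 90th; 15 + 15 flowers with
  15 μL rewards; hover-dominated visits and partial-volume drinks on
  slippery vertical flowers). Drink durations are produced by inverting
  the drinking-rate model, so the analysis pipeline recovers the
  simulator's ground-truth intake exactly.
- **cli** — orchestration with manifests and distinct exit codes per
  error class.

## CLI

```sh
beeforage params [--simulate]                 # dump default parameters
beeforage simulate --out sim/ --seed 1        # synthetic experiment CSVs
beeforage energetics --events sim/events.csv --bees sim/bees.csv --out en/
beeforage choices    --events sim/events.csv --bees sim/bees.csv --out ch/ --at 90
beeforage randtest   --proportions props.csv --group-a low_difference \
                     --group-b high_difference --out rt/
beeforage reproduce  --accession-dir data/ --out rep/
```

`energetics` emits tidy tables: `trips.csv` (per-trip budgets),
`windows.csv` (per-ten-choice series for RER, EE, handling time, handling
energy, between-flower flight time), `counterfactual.csv`, and
`cost_summary.csv`. `reproduce` recomputes the headline results table
from a deposited-format dataset (events.csv + bees.csv, canonical or
custom dialect via `--dialect`) and grades it against reference values.

## Layout

```
src/beeforage/      event_model, physiology, energetics, stats,
                    synthetic_data, cli, errors
tests/              unit + property tests, test_acceptance.py
scripts/acceptance.py
```
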