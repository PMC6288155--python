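# saxsguide

SAXS-guided adaptive sampling on Markov state models.

Unbiased molecular simulations routinely spend most of their cost in
conformational states far from the structure of interest.  `saxsguide`
implements an experiment-guided way out: small-angle X-ray scattering
(SAXS) profiles — low-resolution, solution-state, cheap to measure — are
turned into a per-state discrepancy score that steers *where new short
simulations are started*, while the simulations themselves remain
unbiased (the energy function is never modified).  The package is aimed
at computational structural biologists who want to benchmark and apply
seed-selection strategies for Markov-state-model (MSM) based adaptive
sampling of protein folding and protein–protein association.

## What is inside

* **`saxsguide.saxs`** — scattering profiles `I(q)` with per-point
  errors; a vacuum Debye calculator for bead/atom models,
  `I(q) = Σᵢⱼ wᵢwⱼ sinc(q·rᵢⱼ)`; the reduced discrepancy
  `χ² = 1/(N−1) Σᵢ ((μ·I_state(qᵢ) − I_target(qᵢ))/σ_target(qᵢ))²`
  with the closed-form optimal scale μ; a log-scale two-parameter fit
  `χ² = 1/N Σᵢ (ln I_calc − ln(f·I_exp + c))²`; Guinier analysis
  (R_g from the low-q slope of ln I vs q²); Shannon channels
  `N_s = q_max·D_max/π`; ensemble aggregation; and an exact runs-based
  correlation-map goodness-of-fit test.
* **`saxsguide.structures`** — minimal PDB I/O, Kabsch RMSD, maximum
  diameter D_max, and evolutionary-coupling (EC) restraint tables with
  residue-pair distances.
* **`saxsguide.msm`** — transition counting, maximum-likelihood MSM
  estimation with ergodic trimming, stationary vector w, free energies
  `G_i = −RT ln w_i`, implied timescales `−τ/ln λ_k`, tICA, k-centers /
  k-means clustering, and mean first passage times.
* **`saxsguide.kmc`** — discrete-time kinetic Monte Carlo on a
  transition matrix, single-walker and vectorized-ensemble.
* **`saxsguide.adaptive`** — seed-selection strategies (random, SAXS,
  EC, SAXS+EC hybrid), the adaptive-sampling driver, and a benchmark
  harness measuring total sampling time to reach a target state.
* **`saxsguide.synthetic`** — a fully self-contained folding-funnel
  test system: kinetic network, per-state bead structures, target SAXS
  profile and EC-style restraints.

## Worked example

Compare the five sampling protocols on the stock synthetic funnel
(50 states, native state 0, start at an expanded state, 100 replicates
per protocol):

```python
from saxsguide.synthetic import make_benchmark_system
from saxsguide.adaptive import (default_benchmark_protocols,
                                benchmark_grid, summarize_benchmark)

system = make_benchmark_system()
table = benchmark_grid(system.model, system.scores,
                       list(default_benchmark_protocols().values()),
                       start=system.start_state,
                       target=[system.target_state],
                       replicates=100, master_seed=12345)
print(summarize_benchmark(table).to_string(index=False))
```

prints

```
protocol  n_runs  reach_fraction  mean_total_time  sem_total_time  mean_states_explored
    long     100             1.0          15000.0        0.000000                 50.00
  random     100             1.0           5195.5      127.533111                 48.93
    saxs     100             1.0           1907.5       39.359615                 44.10
      ec     100             1.0           1919.0       39.935428                 43.68
 saxs_ec     100             1.0           1895.5       40.057377                 43.82
```

Total times are in lag-time units of simulated trajectory.  Long
parallel trajectories are by far the most expensive route to the native
state; random adaptive seeding cuts the cost roughly threefold; seeding
from the states whose computed SAXS profiles best match the target
(`saxs`) cuts it by another factor of ~2.7, and the SAXS+EC hybrid is at
least as good.  The guided protocols also visit fewer irrelevant states
(last column): high-discrepancy expanded states are simply never
re-seeded.  On this system the per-state discrepancy spans `χ² ≈ 0.94`
at the native state to `χ² ≈ 3.8e4` at the fully extended chain, a
strong monotone signal along the folding coordinate.

The same pipeline is scriptable from the shell:

```sh
saxsguide synth-gen --out-dir system/           # model.json, target.dat, scores.json, ...
saxsguide chi2 system/target.dat system/target.dat --mu fixed:1
saxsguide benchmark system/model.json system/scores.json --config bench.yaml --out results.tsv
```

## Documentation

`docs/methods.md` describes the model assumptions, the synthetic-data
generator and its calibration, numerical choices, and known limitations.
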