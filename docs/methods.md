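# Methods

## The method in brief

A Markov state model (MSM) represents conformational dynamics as a
discrete-time Markov chain over clustered states with row-stochastic
transition matrix T(τ) at lag time τ.  Adaptive sampling runs iterative
rounds of short parallel simulations; after each round the states
visited so far are candidates, and a selection rule picks the seeds of
the next round.  The package's central rule scores every candidate
state by the reduced χ² between the SAXS profile computed from its
structures and a target profile, and seeds the lowest-discrepancy
states.  Selection only chooses *where to start* unbiased trajectories,
so the potential energy surface — and with it thermodynamics and
kinetics of every individual trajectory — is untouched.

Since running molecular dynamics is out of scope, sampling is
surrogated by kinetic Monte Carlo (KMC) on a known transition matrix:
from state i the next state is drawn from row i by inverting the
cumulative sum against a uniform variate.  On a surrogate chain whose
ground truth is known exactly, protocols can be compared in seconds and
validated against linear-algebra oracles (stationary vector, mean first
passage times, absorbing-chain hitting probabilities).

## SAXS scoring

* **Debye calculator.** `I(q) = Σᵢⱼ wᵢwⱼ sinc(q rᵢⱼ)`, unit weights per
  bead by default.  This is a vacuum calculation: no hydration-shell
  contrast or excluded-volume correction.  The scoring pipeline only
  needs *internally consistent* profiles — state and target profiles
  computed by the same forward model — so absolute χ² values against
  profiles from other engines are not comparable.
* **Reduced χ² (scale μ).** The scaling factor μ is set to its
  closed-form least-squares minimizer by default (the behavior of
  standard fitting programs); a fixed-μ mode exists for tests and for
  assessing unscaled fits.  When state and target live on different q
  grids, the state curve is linearly interpolated onto the target grid
  restricted to the overlap (never extrapolated), because the target
  errors are defined on the target grid.
* **Error floor.** Target σ values ≤ 0 are replaced by
  max(10⁻¹², 0.01·|I_target|).  χ² divides by σ; synthetic targets built
  from identical snapshots would otherwise be singular.
* **Log-scale fit.** χ² = 1/N Σ (ln I_cal − ln(f·I_exp + c))²,
  minimized over scale f and constant background c with a
  Levenberg-style least-squares solve started from the linear-fit scale.
  Natural logarithms are used; the choice of base rescales χ² uniformly
  and does not move the optimum.
* **Guinier analysis.** ln I is fit against q² on a low-q window shrunk
  iteratively until q·R_g ≤ 1.3 (at most 50 iterations, initial window
  = lowest-q quarter of the curve, minimum 3 points).  A positive slope
  is a flagged failure, not a number.
* **Shannon channels.** N_s = q_max·D_max/π rounded **up**: the count is
  used as a bound that sampling grids must exceed.
* **Correlation map.** Implemented as the longest run of identically
  signed residuals with an exact fair-Bernoulli null computed by
  dynamic programming over run lengths (zero residuals break runs;
  tail mass is accumulated directly so p-values down to ~10⁻³⁰⁰ do not
  underflow).  This is the decision statistic of the correlation-map
  family of tests, not the full pairwise correlation matrix of larger
  software suites.
* **Ensemble aggregation.** Mean intensity and *sample* (n−1) standard
  deviation per q point: the snapshots are a sample of the underlying
  ensemble.

## MSM estimation

* Counting is sliding-window (every frame starts a transition pair).
* The default estimator is the nonreversible row-normalized maximum
  likelihood `T_ij = C_ij/Σ_j C_ij`; a `symmetrized` mode (replace C by
  (C+Cᵀ)/2) guarantees detailed balance and is used in tests of the
  reversible contracts.  Absolute free energies differ slightly
  between modes on finite data.
* Estimation is restricted to the largest strongly connected component
  of the count graph; dropped states are reported in `active_set`.
* G_i = −RT ln w_i with R = 1.987204×10⁻³ kcal/(mol·K), T = 300 K by
  default.
* tICA solves C(τ)v = λC(0)v with the symmetrized lagged covariance
  and mean-free data over the usable frame range; a singular C(0) is
  ridge-regularized (ε = 10⁻⁸) with a warning.  Eigenvalues are
  reported clipped to [−1, 1].
* k-centers is the greedy farthest-point heuristic (deterministic given
  the seeded first center; classic 2-approximation of the cover
  radius) and accepts an arbitrary distance callback, e.g. RMSD;
  k-means delegates to scikit-learn's Lloyd/k-means++.
* Mean first passage times solve m = τ·1 + Q·m on the non-target block,
  after an explicit reverse-reachability check that names unreachable
  states.

## Kinetic Monte Carlo

The next state is the smallest n with cumulative row sum S_n ≥ u,
u ~ Uniform[0, 1) — measure-equivalent to assigning u to the interval
(S_n, S_{n+1}] and free of zero-probability edge ambiguity.  The last
cumulative entry is pinned to 1 to absorb rounding.  All randomness
flows through numpy's PCG64 generator (recorded in run metadata);
per-run and per-round streams are derived from a master seed through
`SeedSequence` spawning, so ensembles are reproducible and independent.

## Adaptive protocols and accounting

* Round r launches `n_parallel` walkers of `traj_len` steps assigned
  round-robin over the current seed states (round 1 seeds from the
  start state).  In the stock experiments one walker per chosen state
  is launched (seeds_per_round = n_parallel = 10).
* **Candidate pool.** All states visited in *all* rounds so far
  (cumulative), the conservative reading of picking "from the resulting
  trajectories" and standard MSM adaptive-sampling practice; a
  last-round-only mode is available as a toggle.
* **Time accounting.** A started round is charged in full
  (n_parallel × traj_len) even when the target is hit mid-round, so the
  grand total is always (number of trajectories) × (trajectory length);
  a `truncate` mode charges the hitting round up to the first hit.
* **Tie-breaking.** Score ties are broken by a seeded random
  permutation before a stable sort: selections are deterministic under
  a fixed seed, and with completely uninformative (constant) scores the
  SAXS strategy provably reduces to uniform random selection.  An
  `index` tie-break (lowest state first) is available where bitwise
  determinism across seeds matters more.
* **Hybrid de-duplication.** When the χ²-best and EC-best sets overlap,
  duplicates are dropped and the deficit backfilled alternately from
  the next-best of each ranking, so the requested number of *distinct*
  seeds is always returned.
* **Benchmark summaries.** Mean total time is computed over runs that
  reached the target; the reach fraction is reported alongside so the
  exclusion bias stays visible.

## The synthetic funnel

* **Kinetic network.** n = 50 states on a 1-D reaction coordinate,
  native at index 0, extended at 49.  Within a ±3 neighbor window the
  move i→j has weight exp(bias·(i−j)/(n−1)) with bias = 2 — a
  Metropolis-like downhill preference — and the diagonal carries a stay
  weight of 40, giving states the dominant self-transition probability
  typical of MSMs at a practical lag time.  With these defaults the
  extended→native mean first passage time is ≈1.6×10³ steps (by the
  linear solve), inside the intended 10³–10⁴ band: long enough that
  protocols separate cleanly, short enough for hundreds of desk-scale
  replicates.
* **Structures.** The native state is a boustrophedon walk on a cubic
  lattice at 3.8 Å bead spacing (self-avoiding, compact); the extended
  state a straight chain at the same spacing, rigid-body aligned onto
  the native geometry before interpolation so the radius of gyration
  grows monotonically along the coordinate (misoriented endpoints would
  otherwise produce a transient compaction).  State s interpolates the
  endpoint coordinates linearly and adds Gaussian jitter (σ = 0.5 Å)
  per sample; 100 samples per state are drawn by default, matching the
  per-state extraction depth used when scoring clustered simulation
  states.
* **Target profile.** Debye profiles of the native samples on a uniform
  51-point grid over 0–0.5 Å⁻¹, aggregated to mean and sample standard
  deviation; optional Gaussian noise injection on top.
* **EC restraints.** 5 bead pairs < 8 Å apart in the native structure
  but ≥ 5 positions apart in sequence, with synthetic scores in
  (0.3, 1] — the signature of informative coupled pairs.  Their mean
  distance grows monotonically toward the extended state.
* **Benchmark geometry.** The target is the native state; the start is
  an arbitrary expanded state at 80% of the reaction coordinate
  (state 39) rather than the extreme end.  This leaves the most
  extended, highest-discrepancy states as territory that informed
  seeding should *avoid*: uninformed random reseeding re-explores them
  while SAXS/EC-guided seeding does not, which is exactly the
  states-explored contrast the benchmark quantifies.  Starting at the
  extreme end would force every protocol to traverse the entire line
  and erase that contrast.
* **Stock protocols.** Adaptive protocols: 10 walkers × 5τ per round,
  up to 300 rounds; hybrid split 5 SAXS + 5 EC.  Long protocol: one
  round of 10 walkers × 1500τ, the trajectory length chosen near the
  extended→native MFPT so a single long round reaches the target with
  high probability (runs that never reach are excluded from mean
  totals, and a protocol that can never reach would have no mean at
  all).

### What the generator does and does not emulate

The funnel reproduces the *structure* of the sampling problem: a
monotone experimental signal along a slow coordinate, metastable
states, and a target basin far from the start.  It does not emulate
realistic folding thermodynamics, off-pathway traps, degenerate states
with identical SAXS profiles but different topologies, or clustering
error.  Passing benchmarks here therefore demonstrate that the
machinery — scoring, selection, bookkeeping — behaves as designed and
that informed seeding wins *when the signal is informative*; they do
not by themselves predict speed-up factors on real proteins, where
SAXS degeneracy can blunt the signal and hybrid restraints matter
more.

## Numerical choices

* Shannon-channel ceiling is taken after rounding the quotient to 9
  decimals, so exact multiples of π do not spill into the next integer.
* `reduced_chi2` refuses an all-zero state intensity in optimal-μ mode
  (the minimizer is undefined) and requires N ≥ 2 points (divisor N−1).
* Kabsch RMSD evaluates residuals explicitly after the fitted rotation
  rather than using the solver's reported residual sum, which loses
  half the significant digits to cancellation near congruence; proper
  rotations only (no reflections).
* The log-χ² fit guards the logarithm with a floor of 10⁻³⁰⁰ inside the
  optimizer; convergence tolerances are 10⁻¹⁵ so the identity fit
  recovers (f, c) = (1, 0) to ~10⁻⁸.
* Seeds derived from a master seed stay below 2³¹.

## Known limitations

* The Debye stand-in ignores solvent effects; χ² values are only
  comparable within one forward model.
* The correlation-map test uses the longest-run statistic only.
* The nonreversible estimator does not enforce detailed balance; for
  thermodynamic analyses of real trajectory data the symmetrized mode
  (or an external reversible estimator) is preferable.
* The funnel benchmark is 1-D; conclusions about *which* hybrid
  weighting is best on branched landscapes are outside its power.
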