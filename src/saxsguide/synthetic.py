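"""Self-contained synthetic test systems: a folding funnel with structures.

Benchmarking seed-selection protocols needs a kinetic network in which an
informed selection criterion has a real signal to exploit.  This module
builds one from scratch, with no external datasets:

* a 1-D folding-funnel Markov chain whose states run from the native
  conformation (index 0) to a fully extended chain (index n-1), with
  nearest-neighbor transitions biased energetically downhill;
* per-state bead structures interpolating linearly between a compact
  self-avoiding native geometry and a straight extended chain, plus
  Gaussian jitter emulating intra-state heterogeneity;
* a target SAXS profile averaged over native-state snapshots; and
* evolutionary-coupling-style restraints: bead pairs close in the native
  structure but distant in sequence.

Because the radius of gyration grows monotonically along the state index,
the per-state SAXS discrepancy and the mean EC pair distance both
increase away from the native state, so SAXS- and EC-guided selection
have the monotone signal the benchmark relies on.  The funnel is 1-D and
window-connected rather than a realistic folding network: the benchmark
only needs a tunable gap between informed and uninformed seeding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .adaptive import StateScores, state_discrepancy
from .errors import SaxsGuideError
from .msm import MarkovModel, _stationary
from .saxs import SAXSProfile, add_gaussian_noise, aggregate_profiles, debye_profile
from .structures import ECRestraintSet, Structure, residue_pair_distances

__all__ = [
    "FunnelSpec",
    "BenchmarkSystem",
    "make_funnel_msm",
    "make_bead_structures",
    "make_target_profile",
    "make_ec_restraints",
    "make_benchmark_system",
]

#: bead spacing along the chain, Angstrom (CA-CA virtual bond length)
BEAD_SPACING = 3.8


@dataclass(frozen=True)
class FunnelSpec:
    """Parameters of the synthetic folding funnel.

    ``bias`` controls the downhill preference toward the native state
    (state 0): a move from i to j carries weight exp(bias*(i-j)/(n-1)).
    ``connectivity`` is the neighbor window on the 1-D reaction
    coordinate, ``noise_sd`` the Gaussian structural jitter within a
    state (Angstrom), and ``stay_weight`` the unnormalized self-transition
    weight, which sets how metastable states are at the lag time (MSM
    states typically carry a dominant self-transition probability).
    """

    n_states: int = 50
    n_beads: int = 27
    bias: float = 2.0
    connectivity: int = 3
    noise_sd: float = 0.5
    seed: int = 0
    stay_weight: float = 40.0

    def __post_init__(self):
        if self.n_states < 3:
            raise SaxsGuideError("need at least 3 states")
        if self.n_beads < 4:
            raise SaxsGuideError("need at least 4 beads")
        if self.bias <= 0:
            raise SaxsGuideError("bias must be positive")
        if self.connectivity < 1:
            raise SaxsGuideError("connectivity window must be >= 1")
        if self.noise_sd < 0 or self.stay_weight < 0:
            raise SaxsGuideError("noise_sd and stay_weight must be nonnegative")


def make_funnel_msm(spec: FunnelSpec, lag_time: float = 1.0) -> MarkovModel:
    """Build the funnel transition matrix and wrap it in a MarkovModel.

    Within the connectivity window, the unnormalized weight of the move
    i -> j is exp(bias*(i-j)/(n-1)) (a Metropolis-like preference for the
    lower index); the diagonal carries ``stay_weight``.  Rows are then
    normalized.  The chain is irreducible (window >= 1 connects the
    line) and aperiodic (positive diagonal), and its stationary mass
    concentrates on low indices with the native state at the maximum.
    """
    n = spec.n_states
    W = np.zeros((n, n))
    for i in range(n):
        lo = max(0, i - spec.connectivity)
        hi = min(n - 1, i + spec.connectivity)
        for j in range(lo, hi + 1):
            if j == i:
                W[i, j] = spec.stay_weight
            else:
                W[i, j] = math.exp(spec.bias * (i - j) / (n - 1))
    if spec.stay_weight == 0:
        # keep the chain aperiodic even without an explicit stay weight
        W[np.arange(n), np.arange(n)] = 1e-9
    T = W / W.sum(axis=1, keepdims=True)
    w = _stationary(T)
    return MarkovModel(T, lag_time=lag_time, stationary=w)


def _native_coords(n_beads: int) -> np.ndarray:
    """Compact native geometry: a boustrophedon walk on a cubic lattice.

    Consecutive beads are lattice neighbors (spacing 3.8 A), so the path
    is self-avoiding and clearly more compact than the extended chain.
    """
    side = int(math.ceil(n_beads ** (1.0 / 3.0)))
    coords = []
    for k in range(n_beads):
        z = k // (side * side)
        rem = k % (side * side)
        # odd layers are traversed in reverse so consecutive beads stay adjacent
        m = rem if z % 2 == 0 else side * side - 1 - rem
        y = m // side
        x = m % side
        if y % 2 == 1:
            x = side - 1 - x
        coords.append((x, y, z))
    arr = np.array(coords, dtype=float) * BEAD_SPACING
    return arr - arr.mean(axis=0)


def _extended_coords(n_beads: int) -> np.ndarray:
    """Straight chain at 3.8 A spacing, rigid-body aligned onto the native
    geometry so that linear interpolation between the endpoints swells
    monotonically (no transient compaction from misoriented endpoints)."""
    x = np.arange(n_beads, dtype=float) * BEAD_SPACING
    arr = np.zeros((n_beads, 3))
    arr[:, 0] = x
    arr -= arr.mean(axis=0)
    import warnings

    from scipy.spatial.transform import Rotation

    with warnings.catch_warnings():
        # rotation about the chain axis is degenerate; any solution works
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(_native_coords(n_beads), arr)
    return rot.apply(arr)


def state_mean_coords(spec: FunnelSpec, state: int) -> np.ndarray:
    """Noise-free mean geometry of a state: linear interpolation between
    the native (state 0) and extended (state n-1) endpoints."""
    t = state / (spec.n_states - 1)
    return (1.0 - t) * _native_coords(spec.n_beads) + t * _extended_coords(
        spec.n_beads
    )


def make_bead_structures(
    spec: FunnelSpec, per_state: int = 100
) -> List[List[Structure]]:
    """Per-state structure samples: state mean geometry plus Gaussian jitter.

    Returns ``structures[state][sample]``; all samples of a state share
    its mean geometry, and the pre-jitter radius of gyration is
    non-decreasing in the state index.  Reproducible from ``spec.seed``.
    """
    if per_state < 1:
        raise SaxsGuideError("per_state must be >= 1")
    rng = np.random.default_rng(spec.seed)
    out: List[List[Structure]] = []
    for s in range(spec.n_states):
        mean = state_mean_coords(spec, s)
        samples = []
        for _ in range(per_state):
            jitter = (
                rng.normal(0.0, spec.noise_sd, mean.shape)
                if spec.noise_sd > 0
                else 0.0
            )
            samples.append(Structure(mean + jitter))
        out.append(samples)
    return out


def make_target_profile(
    native_samples: Sequence[Structure],
    q_max: float = 0.5,
    n_points: int = 51,
    noise_seed: Optional[int] = None,
) -> SAXSProfile:
    """Target SAXS curve: mean and spread over native-state snapshots.

    Debye profiles of the native samples are computed on a uniform grid
    from 0 to ``q_max`` and aggregated: the per-q mean becomes I_target
    and the per-q sample standard deviation sigma_target.  When
    ``noise_seed`` is given, Gaussian noise of scale sigma_target is added
    to the averaged curve to emulate measurement error.
    """
    if len(native_samples) < 2:
        raise SaxsGuideError("need at least 2 native samples")
    q = np.linspace(0.0, q_max, n_points)
    profiles = [debye_profile(s, q) for s in native_samples]
    target = aggregate_profiles(profiles)
    if noise_seed is not None:
        target = add_gaussian_noise(target, noise_seed)
    return target


def make_ec_restraints(
    native: Structure, n_pairs: int, seed: Optional[int] = None
) -> ECRestraintSet:
    """Synthetic evolutionary-coupling restraints from the native structure.

    Picks ``n_pairs`` bead pairs that are close in the native geometry
    (< 8 A) but distant in sequence (>= 5 positions), the signature of
    genuinely informative coupled pairs, with synthetic scores in
    (0.3, 1] sorted descending.
    """
    if n_pairs == 0:
        return ECRestraintSet(())
    d = np.linalg.norm(
        native.coords[:, None, :] - native.coords[None, :, :], axis=-1
    )
    n = native.n_atoms
    iu, ju = np.triu_indices(n, k=5)
    ok = np.where(d[iu, ju] < 8.0)[0]
    if ok.size < n_pairs:
        raise SaxsGuideError(
            f"only {ok.size} qualifying pairs available, need {n_pairs}"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(ok, size=n_pairs, replace=False)
    scores = np.sort(rng.uniform(0.31, 1.0, n_pairs))[::-1]
    pairs = tuple(
        ("A", int(native.residue_index[iu[k]]), "A", int(native.residue_index[ju[k]]))
        for k in pick
    )
    return ECRestraintSet(pairs, scores)


# ---------------------------------------------------------------------------
# One-call benchmark system


@dataclass(frozen=True)
class BenchmarkSystem:
    """Everything the adaptive-sampling benchmark needs, generated from a
    single :class:`FunnelSpec`."""

    spec: FunnelSpec
    model: MarkovModel
    scores: StateScores
    target_profile: SAXSProfile
    structures: list
    ec_restraints: ECRestraintSet
    start_state: int
    target_state: int


def make_benchmark_system(
    spec: Optional[FunnelSpec] = None,
    per_state: int = 100,
    n_ec_pairs: int = 5,
    lowest_k: Optional[int] = None,
) -> BenchmarkSystem:
    """Generate the funnel, its structures, target profile and state scores.

    The per-state SAXS discrepancy uses all ``per_state`` samples per
    state; the EC distance score of a state is the mean over its samples
    of the mean coupled-pair distance.  The benchmark target is the
    native state 0; the start is an arbitrary expanded state at 80% of
    the reaction coordinate rather than the extreme end, so the most
    extended, highest-discrepancy states exist to be *avoided*: informed
    seeding should skip them while uninformed reseeding re-explores them.
    """
    spec = spec or FunnelSpec()
    model = make_funnel_msm(spec)
    structures = make_bead_structures(spec, per_state)
    target = make_target_profile(structures[0])
    chi2 = state_discrepancy(
        structures, target, n_samples=per_state, lowest_k=lowest_k, seed=spec.seed
    )
    ec = make_ec_restraints(structures[0][0], n_ec_pairs, seed=spec.seed)
    ec_dist = np.empty(spec.n_states)
    for s, samples in enumerate(structures):
        ec_dist[s] = float(
            np.mean([residue_pair_distances(st, ec)[1] for st in samples])
        )
    scores = StateScores(
        chi2=chi2, ec_distance=ec_dist, free_energy=model.free_energy
    )
    return BenchmarkSystem(
        spec=spec,
        model=model,
        scores=scores,
        target_profile=target,
        structures=structures,
        ec_restraints=ec,
        start_state=int(round(0.8 * (spec.n_states - 1))),
        target_state=0,
    )
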