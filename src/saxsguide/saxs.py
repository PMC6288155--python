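"""Small-angle X-ray scattering profiles and profile-level analyses.

A SAXS experiment reduces a molecule's shape to a 1-D curve I(q), the
spherically averaged scattering intensity as a function of momentum
transfer q = 4*pi*sin(theta)/lambda.  This module provides

* a vacuum Debye calculator for point-scatterer (bead) models,
* the reduced chi-square discrepancy between a model and a target curve,
* a logarithmic-scale (f, c) fit used when the experimental curve has an
  unknown scale and constant background,
* Guinier analysis (radius of gyration from the low-q slope),
* the Shannon-channel count q_max * D_max / pi,
* ensemble aggregation (mean curve and per-point spread),
* Gaussian noise injection, and
* a runs-based correlation-map goodness-of-fit test.

Profiles are held in :class:`SAXSProfile`; plain-text ``.dat`` readers and
writers and a Crysol ``.int`` reader are at the bottom of the module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Iterable, Sequence, Union

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

from .errors import GridMismatchError, GuinierFitError, SaxsGuideError

__all__ = [
    "SAXSProfile",
    "ChiSquareResult",
    "GuinierResult",
    "debye_profile",
    "reduced_chi2",
    "log_chi2_fit",
    "guinier_rg",
    "shannon_channels",
    "aggregate_profiles",
    "add_gaussian_noise",
    "cormap_test",
    "longest_run_pvalue",
    "read_dat",
    "write_dat",
    "read_crysol_int",
]

#: absolute floor used when replacing nonpositive target errors
SIGMA_FLOOR_ABS = 1e-12
#: relative floor (fraction of |I_target|) for nonpositive target errors
SIGMA_FLOOR_REL = 0.01


@dataclass(frozen=True)
class SAXSProfile:
    """A scattering curve: q grid, intensities and per-point errors.

    Parameters
    ----------
    q : array-like
        Momentum transfer grid in inverse Angstrom; strictly increasing,
        nonnegative.
    intensity : array-like
        I(q) per grid point, arbitrary units; finite.
    sigma : array-like, optional
        Per-point error of the intensity; nonnegative.  Absent errors are
        stored as zeros and floored downstream where a division by sigma
        is required.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        s = (
            np.zeros_like(q)
            if self.sigma is None
            else np.asarray(self.sigma, dtype=float)
        )
        if q.ndim != 1 or q.size == 0:
            raise SaxsGuideError("q grid must be a nonempty 1-D array")
        if i.shape != q.shape or s.shape != q.shape:
            raise SaxsGuideError(
                "q, intensity and sigma must have identical lengths"
            )
        if np.any(q < 0):
            raise SaxsGuideError("q values must be nonnegative")
        if q.size > 1 and np.any(np.diff(q) <= 0):
            raise SaxsGuideError("q values must be strictly increasing")
        if not np.all(np.isfinite(i)):
            raise SaxsGuideError("intensities must be finite")
        if np.any(s < 0) or not np.all(np.isfinite(s)):
            raise SaxsGuideError("sigma must be finite and nonnegative")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        object.__setattr__(self, "sigma", s)

    def __len__(self) -> int:
        return self.q.size

    def same_grid(self, other: "SAXSProfile", rtol: float = 1e-9) -> bool:
        return self.q.shape == other.q.shape and np.allclose(
            self.q, other.q, rtol=rtol, atol=1e-12
        )


@dataclass(frozen=True)
class ChiSquareResult:
    """Outcome of a profile fit.

    ``scale`` is the fitted scaling factor mu for the linear reduced
    chi-square, or the pair ``(f, c)`` for the logarithmic fit.
    """

    chi2: float
    scale: Union[float, tuple]
    n_points: int


@dataclass(frozen=True)
class GuinierResult:
    rg: float
    i0: float
    q_range: tuple
    n_points: int


# ---------------------------------------------------------------------------
# Debye calculator


def debye_profile(structure, q_grid, weights=None) -> SAXSProfile:
    """Vacuum Debye scattering profile of a point-scatterer model.

    I(q) = sum_ij w_i w_j sinc(q r_ij), with sinc(x) = sin(x)/x and
    sinc(0) = 1, so I(0) = (sum_i w_i)**2.  No hydration shell or
    excluded-volume term is included: the calculator only needs to produce
    internally consistent profiles for discrepancy scoring.

    Parameters
    ----------
    structure : Structure
        Bead or atom model with an ``(n, 3)`` coordinate array.
    q_grid : array-like
        Nonnegative, strictly increasing q values (1/Angstrom).
    weights : array-like, optional
        Per-scatterer weight (e.g. effective electron count); defaults to
        1.0 per bead.
    """
    q = np.asarray(q_grid, dtype=float)
    coords = np.asarray(structure.coords, dtype=float)
    n = coords.shape[0]
    if n == 0:
        raise SaxsGuideError("debye_profile requires at least one scatterer")
    if np.any(q < 0):
        raise SaxsGuideError("negative q is not physical")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise SaxsGuideError("weights must match the number of scatterers")
    if n == 1:
        intensity = np.full(q.shape, w[0] ** 2)
    else:
        d = pdist(coords)
        iu, ju = np.triu_indices(n, k=1)
        wpair = w[iu] * w[ju]
        # np.sinc(x) = sin(pi x)/(pi x)
        intensity = np.sum(w**2) + 2.0 * (np.sinc(np.outer(q, d) / np.pi) @ wpair)
    return SAXSProfile(q, intensity, np.zeros_like(q))


# ---------------------------------------------------------------------------
# Discrepancy scoring


def _floor_sigma(sigma: np.ndarray, intensity: np.ndarray) -> np.ndarray:
    floor = np.maximum(SIGMA_FLOOR_ABS, SIGMA_FLOOR_REL * np.abs(intensity))
    return np.where(sigma > 0, sigma, floor)


def _align(state: SAXSProfile, target: SAXSProfile, interpolate: bool):
    """Put the state intensity onto the target q grid.

    Returns ``(I_state_on_target_grid, q, I_target, sigma_target)``.  When
    the grids differ the state curve is linearly interpolated onto the
    target grid restricted to the overlapping q range; extrapolation is
    never performed because the target errors live on the target grid.
    """
    if state.same_grid(target):
        return state.intensity, target.q, target.intensity, target.sigma
    if not interpolate:
        raise GridMismatchError(
            "profiles are on different q grids and interpolation is disabled"
        )
    lo = max(state.q[0], target.q[0])
    hi = min(state.q[-1], target.q[-1])
    mask = (target.q >= lo) & (target.q <= hi)
    if np.count_nonzero(mask) < 2:
        raise GridMismatchError("q-grid overlap has fewer than 2 points")
    qi = target.q[mask]
    return (
        np.interp(qi, state.q, state.intensity),
        qi,
        target.intensity[mask],
        target.sigma[mask],
    )


def reduced_chi2(
    state: SAXSProfile,
    target: SAXSProfile,
    scale_mode: Union[str, float] = "optimal",
    interpolate: bool = True,
) -> ChiSquareResult:
    """Reduced chi-square discrepancy between a state and a target profile.

    chi2 = 1/(N-1) * sum_i ((mu*I_state(q_i) - I_target(q_i)) / sigma_target(q_i))**2

    ``scale_mode='optimal'`` sets the scaling factor mu to its closed-form
    least-squares minimizer mu = sum(I_s I_t / s^2) / sum(I_s^2 / s^2);
    passing a float fixes mu at that value.  Nonpositive target errors are
    floored at ``max(1e-12, 0.01*|I_target|)``.
    """
    i_state, _, i_target, sigma = _align(state, target, interpolate)
    n = i_state.size
    if n < 2:
        raise SaxsGuideError("reduced_chi2 needs at least 2 points (divisor N-1)")
    sig = _floor_sigma(sigma, i_target)
    if isinstance(scale_mode, str):
        if scale_mode != "optimal":
            raise SaxsGuideError(f"unknown scale_mode {scale_mode!r}")
        denom = np.sum((i_state / sig) ** 2)
        if denom == 0.0:
            raise SaxsGuideError(
                "state intensity is identically zero; optimal mu undefined"
            )
        mu = float(np.sum(i_state * i_target / sig**2) / denom)
    else:
        mu = float(scale_mode)
    chi2 = float(np.sum(((mu * i_state - i_target) / sig) ** 2) / (n - 1))
    return ChiSquareResult(chi2=chi2, scale=mu, n_points=n)


def log_chi2_fit(
    calc: SAXSProfile, exp: SAXSProfile, interpolate: bool = True
) -> ChiSquareResult:
    """Fit an experimental curve to a calculated one on logarithmic scale.

    Minimizes chi2 = 1/N * sum_i (ln I_calc(q_i) - ln(f*I_exp(q_i) + c))**2
    over the scale f and constant background c, the two-parameter fit used
    when the experimental curve carries an arbitrary scale and a flat
    background.  All calculated intensities must be positive.
    """
    i_exp_on_calc, _, i_calc, _ = _align(exp, calc, interpolate)
    if np.any(i_calc <= 0):
        raise SaxsGuideError("log_chi2_fit requires positive calculated intensities")
    n = i_calc.size
    log_calc = np.log(i_calc)
    tiny = 1e-300

    def resid(p):
        f, c = p
        y = f * i_exp_on_calc + c
        return log_calc - np.log(np.maximum(y, tiny))

    f0 = float(
        np.sum(i_calc * i_exp_on_calc) / max(np.sum(i_exp_on_calc**2), tiny)
    )
    sol = least_squares(
        resid, x0=[f0, 0.0], xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000
    )
    f, c = (float(v) for v in sol.x)
    chi2 = float(np.mean(resid(sol.x) ** 2))
    return ChiSquareResult(chi2=chi2, scale=(f, c), n_points=n)


# ---------------------------------------------------------------------------
# Guinier analysis


def guinier_rg(
    profile: SAXSProfile,
    qrg_limit: float = 1.3,
    min_points: int = 3,
    max_iter: int = 50,
) -> GuinierResult:
    """Radius of gyration from the Guinier approximation I = I0*exp(-q^2 Rg^2/3).

    Fits ln I against q^2 over a low-q window shrunk iteratively until
    q*Rg <= ``qrg_limit`` for every point used.  The initial window is the
    lowest-q quarter of the curve (at least ``min_points`` points).  A
    positive slope (intensity rising at low q) is flagged as a failure.
    """
    pos = profile.intensity > 0
    q = profile.q[pos]
    lnI = np.log(profile.intensity[pos])
    if q.size < min_points:
        raise GuinierFitError("too few positive-intensity points for Guinier fit")
    q2 = q**2
    n_init = max(min_points, q.size // 4)
    window = np.zeros(q.size, dtype=bool)
    window[:n_init] = True
    slope = intercept = 0.0
    for _ in range(max_iter):
        if np.count_nonzero(window) < min_points:
            raise GuinierFitError("Guinier window shrank below 3 points")
        slope, intercept = np.polyfit(q2[window], lnI[window], 1)
        if slope > 1e-12:
            raise GuinierFitError(
                "positive low-q slope: intensity increases with q; no Guinier regime"
            )
        rg = math.sqrt(max(-3.0 * slope, 0.0))
        new_window = q * rg <= qrg_limit
        if not new_window.any():
            new_window[:min_points] = True
        if np.array_equal(new_window, window):
            break
        window = new_window
    rg = math.sqrt(max(-3.0 * slope, 0.0))
    q_used = q[window]
    return GuinierResult(
        rg=rg,
        i0=float(math.exp(intercept)),
        q_range=(float(q_used[0]), float(q_used[-1])),
        n_points=int(np.count_nonzero(window)),
    )


def shannon_channels(q_max: float, d_max: float) -> int:
    """Number of Shannon channels N_s = q_max * D_max / pi, rounded up.

    The channel count is the number of independent information channels a
    scattering curve truncated at ``q_max`` carries for a particle of
    maximum diameter ``d_max``; sampling grids are chosen to exceed it.
    """
    if q_max <= 0 or d_max <= 0:
        raise SaxsGuideError("q_max and d_max must be positive")
    # round to suppress floating jitter (e.g. pi * 1 / pi = 1 + eps)
    return int(math.ceil(round(q_max * d_max / math.pi, 9)))


# ---------------------------------------------------------------------------
# Ensemble aggregation and noise


def aggregate_profiles(profiles: Sequence[SAXSProfile]) -> SAXSProfile:
    """Average an ensemble of profiles on a shared q grid.

    The per-q mean becomes the intensity and the per-q sample standard
    deviation (n-1 divisor: the snapshots are a sample of the ensemble)
    becomes sigma, the convention used to turn an ensemble of native-state
    snapshots into a target profile with errors.
    """
    if len(profiles) < 2:
        raise SaxsGuideError("aggregate_profiles needs at least 2 profiles")
    ref = profiles[0]
    for p in profiles[1:]:
        if not ref.same_grid(p):
            raise GridMismatchError("profiles must share an identical q grid")
    stack = np.vstack([p.intensity for p in profiles])
    return SAXSProfile(ref.q, stack.mean(axis=0), stack.std(axis=0, ddof=1))


def add_gaussian_noise(profile: SAXSProfile, seed) -> SAXSProfile:
    """Perturb intensities with zero-mean Gaussian noise of scale sigma(q).

    Emulates measurement noise on a synthetic target: each intensity gets
    an independent draw from N(0, sigma(q_i)); points with sigma = 0 pass
    through unchanged.  ``seed`` may be an int or a numpy Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = profile.intensity + rng.normal(0.0, 1.0, profile.q.size) * profile.sigma
    return SAXSProfile(profile.q, noisy, profile.sigma.copy())


# ---------------------------------------------------------------------------
# Correlation-map (runs) test


def longest_run_pvalue(n: int, run: int) -> float:
    """P(longest same-sign run >= ``run``) among n independent fair signs.

    Exact dynamic programming over the length of the current run; the null
    is n i.i.d. fair Bernoulli signs.  ``run <= 1`` gives probability 1
    for n >= 1 (there is always a run of length 1).
    """
    if n < 1:
        raise SaxsGuideError("n must be >= 1")
    if run <= 1:
        return 1.0
    if run > n:
        return 0.0
    # v[k] = P(no run >= `run` so far, current run length == k+1);
    # mass leaking past run-1 is accumulated directly so tiny tail
    # probabilities do not underflow in 1 - sum(v)
    v = np.zeros(run - 1)
    v[0] = 1.0
    p_hit = 0.0
    for _ in range(n - 1):
        new = np.zeros_like(v)
        new[0] = 0.5 * v.sum()  # sign flips, run restarts at 1
        new[1:] = 0.5 * v[:-1]  # sign repeats
        p_hit += 0.5 * v[-1]  # run reached `run`
        v = new
    return float(min(p_hit, 1.0))


def cormap_test(a: SAXSProfile, b: SAXSProfile):
    """Runs-based correlation-map comparison of two profiles.

    Computes the longest contiguous stretch of identically signed
    residuals a - b (zero residuals break runs) and the exact probability,
    under a fair-sign null, that n independent signs contain a same-sign
    run at least that long.  A small p-value indicates systematic
    deviation between the curves; unlike the reduced chi-square it needs
    no error estimates.

    Returns ``(longest_run, p_value)``.
    """
    if not a.same_grid(b):
        raise GridMismatchError("cormap_test requires a common q grid")
    signs = np.sign(a.intensity - b.intensity)
    longest = run = 0
    prev = 0.0
    for s in signs:
        if s != 0 and s == prev:
            run += 1
        elif s != 0:
            run = 1
        else:
            run = 0
        prev = s
        longest = max(longest, run)
    return longest, longest_run_pvalue(signs.size, longest)


# ---------------------------------------------------------------------------
# File formats


def read_dat(source: Union[str, IO]) -> SAXSProfile:
    """Read a whitespace-separated 3-column (q, I, sigma) profile.

    Lines starting with '#' are comments; the sigma column is optional and
    defaults to zero.
    """
    data = np.loadtxt(source, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise SaxsGuideError(".dat file needs at least q and I columns")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return SAXSProfile(data[:, 0], data[:, 1], sigma)


def write_dat(profile: SAXSProfile, dest: Union[str, IO], header: str = "") -> None:
    """Write a profile as 3 whitespace-separated columns with '#' comments."""
    lines: Iterable[str] = (
        f"{q:.9g} {i:.9g} {s:.9g}"
        for q, i, s in zip(profile.q, profile.intensity, profile.sigma)
    )
    text = ""
    if header:
        text += "".join(f"# {ln}\n" for ln in header.splitlines())
    text += "# q intensity sigma\n"
    text += "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(dest, "w") as fh:
            fh.write(text)


def read_crysol_int(source: Union[str, IO]) -> SAXSProfile:
    """Read the Crysol ``.int`` dialect: one header line, then q and
    total intensity in the first two columns (remaining columns ignored)."""
    data = np.loadtxt(source, skiprows=1, ndmin=2)
    if data.shape[1] < 2:
        raise SaxsGuideError(".int file needs at least q and I columns")
    return SAXSProfile(data[:, 0], data[:, 1], None)
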