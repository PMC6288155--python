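"""Markov state models: estimation and analysis.

A Markov state model (MSM) describes conformational dynamics as a
discrete-time Markov chain over clustered conformational states at a
fixed lag time tau.  The propagation of any state-probability vector p is
p(t + k*tau) = p(t) T(tau)^k for the row-stochastic transition matrix T.
This module estimates T from discrete trajectories by maximum likelihood
on sliding-window transition counts, computes the stationary vector w
(left eigenvector of T at eigenvalue 1), per-state free energies
G_i = -R*T*ln(w_i), implied timescales -tau/ln(lambda_k), mean first
passage times, and provides the featurization (tICA) and clustering
(k-centers / k-means) front ends used to discretize trajectories.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import IO, List, Optional, Sequence, Union

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.csgraph

from .errors import ConnectivityError, SaxsGuideError

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DiscreteTrajectory",
    "MarkovModel",
    "count_transitions",
    "estimate_msm",
    "free_energies",
    "implied_timescales",
    "timescales_from_transition_matrix",
    "tica",
    "TICAModel",
    "cluster",
    "ClusterResult",
    "mfpt",
    "read_dtraj",
    "write_dtraj",
]

#: gas constant in kcal / (mol K)
GAS_CONSTANT_KCAL = 1.987204e-3


@dataclass(frozen=True)
class DiscreteTrajectory:
    """A time-ordered sequence of 0-based state indices.

    ``frame_interval`` is the physical time between consecutive frames (in
    ns or abstract tau units); it only matters when converting counts of
    frames into times.
    """

    states: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self):
        states = np.asarray(self.states, dtype=int)
        if states.ndim != 1 or states.size == 0:
            raise SaxsGuideError("a discrete trajectory must be a nonempty 1-D array")
        if np.any(states < 0):
            raise SaxsGuideError("state indices must be nonnegative")
        object.__setattr__(self, "states", states)

    def __len__(self) -> int:
        return self.states.size


@dataclass(frozen=True)
class MarkovModel:
    """An estimated MSM restricted to its largest strongly connected set.

    ``active_set[i]`` maps model state i back to the original cluster
    label; ``stationary`` is the equilibrium probability vector w and
    ``free_energy`` the vector G_i = -R*T*ln(w_i) in kcal/mol.
    """

    transition_matrix: np.ndarray
    lag_time: float = 1.0
    stationary: np.ndarray = None  # type: ignore[assignment]
    free_energy: np.ndarray = None  # type: ignore[assignment]
    active_set: np.ndarray = None  # type: ignore[assignment]
    mode: str = "nonreversible"
    temperature: float = 300.0

    def __post_init__(self):
        T = np.asarray(self.transition_matrix, dtype=float)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise SaxsGuideError("transition matrix must be square")
        if np.any(T < -1e-12) or np.any(T > 1 + 1e-12):
            raise SaxsGuideError("transition probabilities must lie in [0, 1]")
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-10):
            raise SaxsGuideError("every row of T must sum to 1")
        object.__setattr__(self, "transition_matrix", T)
        if self.stationary is None:
            object.__setattr__(self, "stationary", _stationary(T))
        else:
            object.__setattr__(
                self, "stationary", np.asarray(self.stationary, dtype=float)
            )
        if self.free_energy is None:
            object.__setattr__(
                self,
                "free_energy",
                free_energies(self.stationary, self.temperature),
            )
        else:
            object.__setattr__(
                self, "free_energy", np.asarray(self.free_energy, dtype=float)
            )
        if self.active_set is None:
            object.__setattr__(self, "active_set", np.arange(T.shape[0]))
        else:
            object.__setattr__(
                self, "active_set", np.asarray(self.active_set, dtype=int)
            )

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    # -- serialization: a single JSON document ------------------------------

    def to_json(self, dest: Optional[Union[str, IO]] = None, **meta) -> str:
        doc = {
            "n_states": self.n_states,
            "lag_time": self.lag_time,
            "mode": self.mode,
            "temperature": self.temperature,
            "transition_matrix": self.transition_matrix.tolist(),
            "stationary": self.stationary.tolist(),
            "free_energy": self.free_energy.tolist(),
            "active_set": self.active_set.tolist(),
        }
        if meta:
            doc["provenance"] = meta
        text = json.dumps(doc, indent=1)
        if dest is not None:
            if hasattr(dest, "write"):
                dest.write(text)
            else:
                with open(dest, "w") as fh:
                    fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: Union[str, IO]) -> "MarkovModel":
        if hasattr(source, "read"):
            doc = json.load(source)
        elif source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(
            np.array(doc["transition_matrix"]),
            lag_time=doc.get("lag_time", 1.0),
            stationary=np.array(doc["stationary"]),
            free_energy=np.array(doc["free_energy"]),
            active_set=np.array(doc["active_set"]),
            mode=doc.get("mode", "nonreversible"),
            temperature=doc.get("temperature", 300.0),
        )


# ---------------------------------------------------------------------------
# Counting and estimation


def count_transitions(
    dtrajs: Sequence, lag: int, n_states: Optional[int] = None
) -> np.ndarray:
    """Sliding-window transition counts C_ij = #{t: s(t)=i, s(t+lag)=j}.

    Every frame starts a window (the standard maximum-likelihood counting
    convention); counts are summed over all trajectories longer than the
    lag.
    """
    if lag < 1:
        raise SaxsGuideError("lag must be >= 1 frame")
    arrs = [
        t.states if isinstance(t, DiscreteTrajectory) else np.asarray(t, dtype=int)
        for t in dtrajs
    ]
    usable = [a for a in arrs if a.size > lag]
    if not usable:
        raise SaxsGuideError("no trajectory is longer than the lag")
    n = n_states if n_states is not None else int(max(a.max() for a in arrs)) + 1
    C = np.zeros((n, n))
    for a in usable:
        np.add.at(C, (a[:-lag], a[lag:]), 1.0)
    return C


def _stationary(T: np.ndarray) -> np.ndarray:
    """Leading left eigenvector of T, normalized to a probability vector."""
    vals, vecs = scipy.linalg.eig(T, left=True, right=False)
    k = int(np.argmin(np.abs(vals - 1.0)))
    w = np.real(vecs[:, k])
    w = np.abs(w)
    w = w / w.sum()
    if not np.allclose(w @ T, w, atol=1e-8):
        raise SaxsGuideError("failed to compute stationary distribution")
    return w


def estimate_msm(
    counts: np.ndarray,
    mode: str = "nonreversible",
    lag_time: float = 1.0,
    temperature: float = 300.0,
) -> MarkovModel:
    """Maximum-likelihood MSM from a transition count matrix.

    The estimate is restricted to the largest strongly connected component
    of the count graph (ergodic trimming), since the stationary vector is
    undefined otherwise.  ``mode='nonreversible'`` is the plain
    row-normalized MLE T_ij = C_ij / sum_j C_ij; ``mode='symmetrized'``
    replaces C by (C + C^T)/2 before normalizing, which guarantees
    detailed balance w_i T_ij = w_j T_ji.
    """
    C = np.asarray(counts, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise SaxsGuideError("count matrix must be square")
    if np.any(C < 0):
        raise SaxsGuideError("counts must be nonnegative")
    if mode not in ("nonreversible", "symmetrized"):
        raise SaxsGuideError(f"unknown estimation mode {mode!r}")
    adj = scipy.sparse.csr_matrix(C > 0)
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        adj, directed=True, connection="strong"
    )
    sizes = np.bincount(labels, minlength=n_comp)
    active = np.where(labels == int(np.argmax(sizes)))[0]
    Csub = C[np.ix_(active, active)]
    if mode == "symmetrized":
        Csub = 0.5 * (Csub + Csub.T)
    rows = Csub.sum(axis=1)
    if active.size == 0 or np.any(rows == 0):
        raise ConnectivityError("empty or disconnected active set")
    T = Csub / rows[:, None]
    w = _stationary(T)
    return MarkovModel(
        T,
        lag_time=lag_time,
        stationary=w,
        free_energy=free_energies(w, temperature),
        active_set=active,
        mode=mode,
        temperature=temperature,
    )


def free_energies(w: np.ndarray, temperature: float = 300.0) -> np.ndarray:
    """Per-state free energies G_i = -R*T*ln(w_i) in kcal/mol.

    R = 1.987204e-3 kcal/(mol K); ``w`` must be a strictly positive
    probability vector.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise SaxsGuideError("stationary probabilities must be strictly positive")
    if not np.isclose(w.sum(), 1.0, atol=1e-8):
        raise SaxsGuideError("stationary probabilities must sum to 1")
    return -GAS_CONSTANT_KCAL * temperature * np.log(w)


def implied_timescales(
    dtrajs: Sequence,
    lags: Sequence[int],
    n_timescales: int = 1,
    mode: str = "nonreversible",
) -> np.ndarray:
    """Implied timescales t_k(tau) = -tau / ln(lambda_k(tau)) per lag.

    For each lag an MSM is estimated and the eigenvalues of T sorted by
    descending real part; the unit eigenvalue is skipped.  Eigenvalues
    that are complex (beyond a small tolerance) or outside (0, 1) have no
    real relaxation time and are reported as nan; eigenvalues within
    tolerance of 1 give inf.  Returns an array of shape
    ``(len(lags), n_timescales)`` in frame units.
    """
    out = np.full((len(lags), n_timescales), np.nan)
    for li, lag in enumerate(lags):
        model = estimate_msm(count_transitions(dtrajs, lag), mode=mode)
        ts = timescales_from_transition_matrix(
            model.transition_matrix, lag, n_timescales
        )
        out[li, : ts.size] = ts
    return out


def timescales_from_transition_matrix(
    T: np.ndarray, lag: float, n_timescales: int = 1
) -> np.ndarray:
    """Map the sub-unit eigenvalues of T to timescales -lag/ln(lambda_k).

    Eigenvalues are sorted by descending real part and the unit eigenvalue
    skipped; eigenvalues at 1 (within tolerance) give inf, complex or
    nonpositive ones nan.
    """
    out = np.full(n_timescales, np.nan)
    vals = np.linalg.eigvals(np.asarray(T, dtype=float))
    vals = vals[np.argsort(-vals.real)][1:]  # drop lambda_1 = 1
    for k in range(min(n_timescales, vals.size)):
        lam = vals[k]
        if abs(lam.imag) > 1e-10:
            continue
        x = lam.real
        if x >= 1.0 - 1e-12:
            out[k] = np.inf
        elif x > 0.0:
            out[k] = -lag / np.log(x)
    return out


# ---------------------------------------------------------------------------
# tICA featurization


@dataclass(frozen=True)
class TICAModel:
    """Result of time-lagged independent component analysis.

    ``components`` holds one projection vector per column, ordered by
    descending eigenvalue of the symmetrized time-lagged covariance
    generalized eigenproblem C(tau) v = lambda C(0) v.  Eigenvalues are
    reported clipped to [-1, 1] (they are autocorrelations).
    """

    eigenvalues: np.ndarray
    components: np.ndarray
    mean: np.ndarray
    lag: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.components


def tica(
    feature_series: Sequence[np.ndarray], lag: int, n_components: int
):
    """Find the slowest linear coordinates of multivariate time series.

    Solves the generalized eigenproblem C(tau) v = lambda C(0) v with the
    symmetrized lagged covariance C(tau) = 0.5 (C + C^T) estimated from
    mean-free data over the usable frame range.  A singular instantaneous
    covariance is ridge-regularized (eps = 1e-8) with a warning.

    Returns ``(model, projections)`` where ``projections`` is the list of
    per-series projected arrays.
    """
    series = [np.atleast_2d(np.asarray(s, dtype=float)) for s in feature_series]
    series = [s if s.shape[0] > 1 else s.T for s in series]
    usable = [s for s in series if s.shape[0] > lag]
    if not usable:
        raise SaxsGuideError("every series is shorter than the lag")
    X0 = np.vstack([s[:-lag] for s in usable])
    Xt = np.vstack([s[lag:] for s in usable])
    mean = 0.5 * (X0.mean(axis=0) + Xt.mean(axis=0))
    X0c = X0 - mean
    Xtc = Xt - mean
    n = X0c.shape[0]
    C0 = (X0c.T @ X0c + Xtc.T @ Xtc) / (2.0 * n)
    Ct = 0.5 * (X0c.T @ Xtc + Xtc.T @ X0c) / n
    d = C0.shape[0]
    if np.linalg.matrix_rank(C0, tol=1e-10) < d:
        warnings.warn("singular instantaneous covariance; adding ridge 1e-8")
        C0 = C0 + 1e-8 * np.eye(d)
    vals, vecs = scipy.linalg.eigh(Ct, C0)
    order = np.argsort(-vals)[:n_components]
    model = TICAModel(
        eigenvalues=np.clip(vals[order], -1.0, 1.0),
        components=vecs[:, order],
        mean=mean,
        lag=lag,
    )
    return model, [model.transform(s) for s in series]


# ---------------------------------------------------------------------------
# Clustering


@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray
    centers: np.ndarray
    center_indices: Optional[np.ndarray] = None


def cluster(
    X: np.ndarray,
    k: int,
    algorithm: str = "kmeans",
    seed: Optional[int] = None,
    metric=None,
) -> ClusterResult:
    """Assign frames to ``k`` conformational clusters.

    ``algorithm='kcenters'`` runs the greedy farthest-point heuristic (the
    classic 2-approximation of the k-center cover radius); it accepts a
    custom ``metric(X, index) -> distances-to-frame`` callback, e.g. an
    RMSD kernel.  ``algorithm='kmeans'`` runs Lloyd iterations from
    k-means++ initialization (Euclidean only).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if k > n:
        raise SaxsGuideError("cannot form more clusters than frames")
    if algorithm == "kmeans":
        if metric is not None:
            raise SaxsGuideError("kmeans supports only the Euclidean metric")
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, random_state=seed, n_init=10, max_iter=500)
        labels = km.fit_predict(X)
        return ClusterResult(labels=labels, centers=km.cluster_centers_)
    if algorithm != "kcenters":
        raise SaxsGuideError(f"unknown clustering algorithm {algorithm!r}")

    def dist_to(idx: int) -> np.ndarray:
        if metric is not None:
            return np.asarray(metric(X, idx), dtype=float)
        return np.linalg.norm(X - X[idx], axis=1)

    rng = np.random.default_rng(seed)
    first = int(rng.integers(n))
    centers = [first]
    mind = dist_to(first)
    labels = np.zeros(n, dtype=int)
    for c in range(1, k):
        nxt = int(np.argmax(mind))  # ties -> lowest index
        centers.append(nxt)
        d = dist_to(nxt)
        closer = d < mind
        labels[closer] = c
        mind = np.where(closer, d, mind)
    idx = np.array(centers)
    return ClusterResult(labels=labels, centers=X[idx], center_indices=idx)


# ---------------------------------------------------------------------------
# Mean first passage times


def mfpt(model: MarkovModel, target) -> np.ndarray:
    """Expected first-hitting time of ``target`` from every state.

    Solves the linear system m_i = tau + sum_{j not in target} T_ij m_j
    with m_i = 0 on the target set.  States from which the target is
    unreachable make the system singular and are reported by index.
    """
    target = np.unique(np.asarray(list(target) if not np.isscalar(target) else [target]))
    n = model.n_states
    if target.size == 0:
        raise SaxsGuideError("target set must be nonempty")
    if np.any(target < 0) or np.any(target >= n):
        raise SaxsGuideError("target states outside the active set")
    T = model.transition_matrix
    # reverse reachability: states that can reach the target
    adj = scipy.sparse.csr_matrix((T > 0).T)
    reach = scipy.sparse.csgraph.breadth_first_order(
        adj, target[0], return_predecessors=False
    )
    reachable = np.zeros(n, dtype=bool)
    reachable[reach] = True
    for t in target[1:]:
        if not reachable[t]:
            more = scipy.sparse.csgraph.breadth_first_order(
                adj, t, return_predecessors=False
            )
            reachable[more] = True
    bad = np.where(~reachable)[0]
    if bad.size:
        raise ConnectivityError(
            f"target unreachable from states {bad.tolist()}"
        )
    non = np.setdiff1d(np.arange(n), target)
    m = np.zeros(n)
    if non.size:
        Q = T[np.ix_(non, non)]
        rhs = np.full(non.size, model.lag_time)
        m[non] = np.linalg.solve(np.eye(non.size) - Q, rhs)
    return m


# ---------------------------------------------------------------------------
# Discrete trajectory text files: one integer per line


def read_dtraj(
    source: Union[str, IO], one_based: bool = False, frame_interval: float = 1.0
) -> DiscreteTrajectory:
    states = np.loadtxt(source, comments="#", dtype=int, ndmin=1)
    if one_based:
        states = states - 1
    return DiscreteTrajectory(states, frame_interval)


def write_dtraj(
    dtraj: DiscreteTrajectory, dest: Union[str, IO], header: str = ""
) -> None:
    text = "".join(f"# {ln}\n" for ln in header.splitlines()) if header else ""
    text += "\n".join(str(int(s)) for s in dtraj.states) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(dest, "w") as fh:
            fh.write(text)
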