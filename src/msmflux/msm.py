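"""Markov state model estimation and validation.

From discrete microstate trajectories, transitions observed at a lag time
tau are recorded in a count matrix, restricted to the largest strongly
connected (ergodic) state set, and converted into a row-stochastic
transition matrix — either by simple row normalization or by the reversible
maximum-likelihood estimator that enforces detailed balance
(pi_i T_ij = pi_j T_ji). Model validation uses implied timescales
t_i = -tau / ln|lambda_i| (their tau-independence marks the Markov time)
and the Chapman-Kolmogorov test P(k tau) = P(tau)^k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.sparse.csgraph

from .containers import DEFAULT_DT_NS, validate_dtrajs

__all__ = [
    "count_transitions",
    "largest_connected_set",
    "estimate_transition_matrix",
    "MarkovStateModel",
    "MSMResults",
    "implied_timescales",
    "ck_test",
    "CKTestResult",
]


def count_transitions(dtrajs, lag: int, mode: str = "sliding",
                      n_states: int | None = None) -> np.ndarray:
    """Count (t, t+lag) label pairs over all trajectories.

    ``sliding`` counts every t; ``strided`` counts t = 0, lag, 2 lag, ...
    Trajectories not longer than the lag contribute nothing.
    """
    dtrajs = validate_dtrajs(dtrajs)
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if mode not in ("sliding", "strided"):
        raise ValueError("mode must be 'sliding' or 'strided'")
    n = n_states or (max(int(d.max()) for d in dtrajs if d.size) + 1)
    C = np.zeros((n, n), dtype=np.int64)
    for d in dtrajs:
        if len(d) <= lag:
            continue
        if mode == "sliding":
            i, j = d[:-lag], d[lag:]
        else:
            sub = d[::lag]
            i, j = sub[:-1], sub[1:]
        np.add.at(C, (i, j), 1)
    return C


def largest_connected_set(C: np.ndarray) -> np.ndarray:
    """Largest strongly connected component of the graph with edges where
    C > 0. Ties between equally large components go to the one containing
    the lowest state index."""
    C = np.asarray(C)
    n = C.shape[0]
    adj = scipy.sparse.csr_matrix((C > 0).astype(np.int8))
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        adj, directed=True, connection="strong"
    )
    sizes = np.bincount(labels, minlength=n_comp)
    best = max(range(n_comp), key=lambda c: (sizes[c], -int(np.where(labels == c)[0][0])))
    return np.where(labels == best)[0]


def estimate_transition_matrix(
    C: np.ndarray, reversible: bool = True,
    tol: float = 1e-10, max_iter: int = 1_000_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Transition matrix and stationary distribution from a count matrix.

    Non-reversible: T is the row-normalized count matrix and pi its leading
    left eigenvector. Reversible: the maximum-likelihood T satisfying
    detailed balance, via the standard fixed-point iteration on the
    symmetric auxiliary variables x_ij, converged when max|Delta T| < tol.
    """
    C = np.asarray(C, dtype=float)
    rowsums = C.sum(axis=1)
    if np.any(rowsums <= 0):
        raise ValueError(
            "count matrix has empty rows; restrict to the connected set first"
        )
    if not reversible:
        T = C / rowsums[:, None]
        pi = _stationary(T)
        return T, pi
    Csym = C + C.T
    x = Csym.copy()  # init: symmetrized counts already satisfy balance
    c_i = rowsums
    T_prev = x / x.sum(axis=1, keepdims=True)
    for _ in range(max_iter):
        x_i = x.sum(axis=1)
        denom = (c_i / x_i)[:, None] + (c_i / x_i)[None, :]
        x = Csym / denom
        np.fill_diagonal(x, np.diag(C) / (c_i / x_i))  # diagonal: closed form
        T = x / x.sum(axis=1, keepdims=True)
        delta = np.max(np.abs(T - T_prev))
        if delta < tol:
            break
        T_prev = T
    else:
        raise RuntimeError(
            f"reversible estimator did not converge in {max_iter} iterations "
            f"(residual {delta:.3e})"
        )
    pi = x.sum(axis=1) / x.sum()
    return T, pi


def _stationary(T: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eig(T.T)
    i = np.argmin(np.abs(w - 1.0))
    pi = np.abs(np.real(V[:, i]))
    return pi / pi.sum()


def _sorted_spectrum(T: np.ndarray, pi: np.ndarray | None, reversible: bool):
    """Eigenvalues (descending modulus) and right eigenvectors of T.

    For reversible T the symmetrized similarity transform
    D^{1/2} T D^{-1/2} guarantees a real spectrum.
    """
    if reversible and pi is not None:
        s = np.sqrt(pi)
        A = (T * s[:, None]) / s[None, :]
        A = 0.5 * (A + A.T)
        w, U = np.linalg.eigh(A)
        order = np.argsort(w)[::-1]
        w, U = w[order], U[:, order]
        R = U / s[:, None]  # right eigenvectors of T
        R /= np.sign(R[0, 0]) if R[0, 0] != 0 else 1.0
        return w, R
    w, R = np.linalg.eig(T)
    order = np.argsort(-np.abs(w))
    return w[order], R[:, order]


class MarkovStateModel:
    """MSM estimator over discrete trajectories.

    Parameters
    ----------
    dtrajs : sequence of 1-D int arrays
        Microstate label trajectories.
    lag : int
        Lag time tau in frames (default 10 frames = 1 ns at 0.1 ns/frame).
    reversible : bool
        Use the detailed-balance maximum-likelihood estimator (default);
        the committor back-relation q- = 1 - q+ holds in this case.
    count_mode : {"sliding", "strided"}
    dt : float
        Physical frame spacing in ns.
    """

    def __init__(self, dtrajs, lag: int = 10, reversible: bool = True,
                 count_mode: str = "sliding", dt: float = DEFAULT_DT_NS):
        self.dtrajs = validate_dtrajs(dtrajs)
        if lag < 1:
            raise ValueError("lag must be >= 1")
        if all(len(d) <= lag for d in self.dtrajs):
            raise ValueError("lag not shorter than any trajectory: no transitions")
        self.lag = int(lag)
        self.reversible = reversible
        self.count_mode = count_mode
        self.dt = dt

    def fit(self) -> "MSMResults":
        C_full = count_transitions(self.dtrajs, self.lag, mode=self.count_mode)
        active = largest_connected_set(C_full)
        C = C_full[np.ix_(active, active)]
        T, pi = estimate_transition_matrix(C, reversible=self.reversible)
        evals, evecs = _sorted_spectrum(T, pi, self.reversible)
        return MSMResults(
            lag=self.lag, dt=self.dt, count_matrix_full=C_full,
            count_matrix=C, active_set=active, transition_matrix=T,
            stationary_distribution=pi, eigenvalues=evals,
            right_eigenvectors=evecs, reversible=self.reversible,
            dtrajs=self.dtrajs, count_mode=self.count_mode,
        )


@dataclass
class MSMResults:
    """Estimated MSM: transition matrix on the active set, stationary
    distribution (Boltzmann state weights), and eigen-spectrum."""

    lag: int
    dt: float
    count_matrix_full: np.ndarray
    count_matrix: np.ndarray
    active_set: np.ndarray
    transition_matrix: np.ndarray
    stationary_distribution: np.ndarray
    eigenvalues: np.ndarray
    right_eigenvectors: np.ndarray
    reversible: bool
    count_mode: str = "sliding"
    dtrajs: list = field(default_factory=list, repr=False)

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def map_to_active(self, dtraj: np.ndarray) -> np.ndarray:
        """Relabel original microstates to active-set indices (-1 outside)."""
        lookup = -np.ones(int(self.count_matrix_full.shape[0]), dtype=int)
        lookup[self.active_set] = np.arange(len(self.active_set))
        return lookup[np.asarray(dtraj, dtype=int)]

    def timescales(self, n: int | None = None) -> np.ndarray:
        """Implied timescales -tau/ln|lambda_i| (frames), skipping the
        stationary eigenvalue; nan where lambda <= 0 or |lambda| >= 1."""
        n = n if n is not None else self.n_states - 1
        lam = self.eigenvalues[1 : n + 1]
        lam_r = np.real(lam)
        mod = np.abs(lam)
        with np.errstate(divide="ignore", invalid="ignore"):
            ts = -self.lag / np.log(mod)
        ts = np.where((lam_r <= 0) | (mod >= 1) | (np.abs(np.imag(lam)) > 1e-10), np.nan, ts)
        return ts

    def timescales_ns(self, n: int | None = None) -> np.ndarray:
        return self.timescales(n) * self.dt

    def pcca(self, m: int = 5):
        from .pcca import pcca_plus

        return pcca_plus(self, m)

    def ck_test(self, k_max: int = 5, partition=None) -> "CKTestResult":
        return ck_test(self, self.dtrajs, k_max=k_max, partition=partition)

    def summary(self) -> str:
        ts = self.timescales(min(5, self.n_states - 1)) if self.n_states > 1 else []
        lines = [
            "Markov State Model Results",
            f"  states (active/total): {self.n_states}/{self.count_matrix_full.shape[0]}"
            f"   lag: {self.lag} frames ({self.lag * self.dt:g} ns)"
            f"   reversible: {self.reversible}",
            f"  total counts: {int(self.count_matrix.sum())} ({self.count_mode})",
            "  i   eigenvalue   timescale(frames)   timescale(ns)",
        ]
        for i, t in enumerate(np.atleast_1d(ts)):
            lam = np.real(self.eigenvalues[i + 1])
            lines.append(
                f"  {i+2:<3d} {lam:10.6f}   {t:14.3f}   {t * self.dt:12.4f}"
            )
        pi_str = ", ".join(f"{p:.4f}" for p in self.stationary_distribution[:8])
        lines.append(f"  stationary distribution: [{pi_str}{'...' if self.n_states > 8 else ''}]")
        return "\n".join(lines)


def implied_timescales(dtrajs, lags, n_timescales: int = 5,
                       reversible: bool = True, dt: float = DEFAULT_DT_NS) -> pd.DataFrame:
    """Implied-timescale table over a grid of lags.

    One row per lag with columns t1..t_n in frames (and _ns variants);
    undefined timescales (non-real or non-positive eigenvalues) are NaN,
    reported rather than dropped.
    """
    rows = []
    for lag in lags:
        res = MarkovStateModel(dtrajs, lag=int(lag), reversible=reversible, dt=dt).fit()
        ts = res.timescales(min(n_timescales, res.n_states - 1))
        row = {"lag": int(lag), "lag_ns": lag * dt}
        for i in range(n_timescales):
            val = ts[i] if i < len(ts) else np.nan
            row[f"t{i+1}_frames"] = val
            row[f"t{i+1}_ns"] = val * dt
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CKTestResult:
    """Chapman-Kolmogorov test: estimated P(k tau) vs propagated P(tau)^k."""

    k_values: list
    estimated: list   # P(k tau) re-estimated at the longer lag
    propagated: list  # P(tau)^k
    max_relative_deviation: float
    deviations: list  # per-k max relative deviation over compared entries
    passed: bool
    threshold: float = 0.05
    floor: float = 1e-3
    flagged: list = field(default_factory=list)  # entries below the floor

    def plot(self, ax=None):
        """Diagonal-entry comparison plot (solid: estimated, dashed:
        propagated), mirroring the usual CK panels."""
        import matplotlib.pyplot as plt

        n = self.propagated[0].shape[0]
        if ax is None:
            _, ax = plt.subplots()
        ks = np.asarray(self.k_values)
        for i in range(n):
            est = [E[i, i] for E in self.estimated]
            prop = [P[i, i] for P in self.propagated]
            (line,) = ax.plot(ks, est, "-o", label=f"state {i} est.")
            ax.plot(ks, prop, "--", color=line.get_color())
        ax.set_xlabel("k (multiples of lag)")
        ax.set_ylabel("self-transition probability")
        ax.legend(fontsize="small")
        return ax


def ck_test(msm: MSMResults, dtrajs=None, k_max: int = 5, partition=None,
            threshold: float = 0.05, floor: float = 1e-3) -> CKTestResult:
    """Chapman-Kolmogorov test P(k tau) = P(tau)^k for k = 1..k_max.

    When a macrostate partition is given the test is run on set-to-set
    (crisp coarse-grained) transition probabilities, else on microstates.
    The pass criterion is a maximum relative deviation <= ``threshold``
    (default 5%) over entries whose propagated probability is at least
    ``floor``; smaller entries are flagged, not compared.
    """
    dtrajs = validate_dtrajs(dtrajs if dtrajs is not None else msm.dtrajs)
    if partition is not None:
        from .pcca import coarse_grain_dtrajs

        mapped = [msm.map_to_active(d) for d in dtrajs]
        for d in mapped:
            if np.any(d < 0):
                raise ValueError("trajectory visits states outside the active set")
        test_dtrajs = coarse_grain_dtrajs(partition, mapped)
    else:
        test_dtrajs = [msm.map_to_active(d) for d in dtrajs]
        for d in test_dtrajs:
            if np.any(d < 0):
                raise ValueError("trajectory visits states outside the active set")
    tau = msm.lag
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    usable = max(len(d) for d in test_dtrajs)
    if k_max * tau >= usable:
        raise ValueError(f"k_max*lag = {k_max * tau} exceeds the longest trajectory")

    def _estimate(lag):
        C = count_transitions(test_dtrajs, lag)
        lcs = largest_connected_set(C)
        T = np.full(C.shape, np.nan)
        Csub = C[np.ix_(lcs, lcs)].astype(float)
        rs = Csub.sum(axis=1)
        T[np.ix_(lcs, lcs)] = Csub / rs[:, None]
        return T

    T1 = _estimate(tau)
    estimated, propagated, deviations, flagged = [], [], [], []
    T1_clean = np.nan_to_num(T1)
    for k in range(1, k_max + 1):
        P_prop = np.linalg.matrix_power(T1_clean, k)
        P_est = _estimate(k * tau)
        valid = np.isfinite(P_est) & (P_prop >= floor)
        small = np.isfinite(P_est) & (P_prop < floor)
        dev = 0.0
        if np.any(valid):
            dev = float(np.max(np.abs(P_est[valid] - P_prop[valid]) / P_prop[valid]))
        estimated.append(P_est)
        propagated.append(P_prop)
        deviations.append(dev if k > 1 else 0.0)
        flagged.append(np.argwhere(small))
    max_dev = float(max(deviations))
    return CKTestResult(
        k_values=list(range(1, k_max + 1)), estimated=estimated,
        propagated=propagated, max_relative_deviation=max_dev,
        deviations=deviations, passed=max_dev <= threshold,
        threshold=threshold, floor=floor, flagged=flagged,
    )
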