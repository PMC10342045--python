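"""PCCA+ metastable coarse-graining.

Perron cluster cluster analysis groups the microstates of a reversible MSM
into m metastable macrostates: the first m right eigenvectors of the
transition matrix span an m-simplex whose vertices are the "purest"
microstates; memberships are the barycentric coordinates of every
microstate in that simplex (inner-simplex vertex search, tiny negative
entries clipped and rows renormalized). Crisp labels are the row-argmax.

Macrostates are named after the study's convention: the detected source is
SA, the sink SB, and remaining states S1, S2, ... in order of decreasing
stationary weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import validate_dtrajs

__all__ = [
    "MacrostatePartition",
    "pcca_plus",
    "coarse_grain_dtrajs",
    "assign_endpoint_states",
    "name_macrostates",
]


@dataclass
class MacrostatePartition:
    """Fuzzy membership matrix chi (microstates x m) plus crisp labels."""

    memberships: np.ndarray
    stationary_weights: np.ndarray
    names: list[str] | None = None

    def __post_init__(self) -> None:
        chi = np.asarray(self.memberships, dtype=float)
        if chi.ndim != 2:
            raise ValueError("memberships must be microstates x m")
        if np.any(chi < -1e-10):
            raise ValueError("memberships must be non-negative")
        if not np.allclose(chi.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("membership rows must sum to 1")
        self.memberships = chi
        crisp = chi.argmax(axis=1)
        if len(np.unique(crisp)) < chi.shape[1]:
            raise ValueError("empty macrostate in crisp labels; reduce m")
        self.stationary_weights = np.asarray(self.stationary_weights, dtype=float)
        if self.stationary_weights.shape != (chi.shape[1],):
            raise ValueError("one stationary weight per macrostate required")
        if not np.isclose(self.stationary_weights.sum(), 1.0, atol=1e-8):
            raise ValueError("macrostate weights must sum to 1")

    @property
    def m(self) -> int:
        return self.memberships.shape[1]

    @property
    def n_microstates(self) -> int:
        return self.memberships.shape[0]

    @property
    def crisp_labels(self) -> np.ndarray:
        return self.memberships.argmax(axis=1)

    def to_frame(self):
        import pandas as pd

        cols = self.names or [f"macro_{j}" for j in range(self.m)]
        df = pd.DataFrame(self.memberships, columns=cols)
        df.insert(0, "microstate", np.arange(self.n_microstates))
        df["crisp"] = self.crisp_labels
        return df


def _inner_simplex_vertices(X: np.ndarray) -> np.ndarray:
    """Indices of m rows of X spanning the membership simplex.

    Classic inner-simplex search: start from the row farthest from the
    origin, then repeatedly take the row farthest from the affine span of
    the vertices found so far (Gram-Schmidt deflation).
    """
    n, m = X.shape
    idx = np.empty(m, dtype=int)
    norms = np.linalg.norm(X, axis=1)
    idx[0] = int(np.argmax(norms))
    Xc = X - X[idx[0]]
    for j in range(1, m):
        norms = np.linalg.norm(Xc, axis=1)
        idx[j] = int(np.argmax(norms))
        v = Xc[idx[j]]
        nv = np.linalg.norm(v)
        if nv == 0:
            raise ValueError("degenerate eigenvector geometry; reduce m")
        v = v / nv
        Xc = Xc - np.outer(Xc @ v, v)
    return idx


def pcca_plus(msm, m: int = 5) -> MacrostatePartition:
    """PCCA+ partition of an MSM into m metastable macrostates.

    ``msm`` is an :class:`~msmflux.msm.MSMResults` (reversible, real
    spectrum) or a bare row-stochastic matrix. The first m eigenvalues must
    be real and positive — complex or negative values among them mean the
    spectrum carries no m-fold metastable structure, and a smaller m is
    advised.
    """
    from .msm import MSMResults, _sorted_spectrum, _stationary

    if isinstance(msm, MSMResults):
        T = msm.transition_matrix
        pi = msm.stationary_distribution
        evals, evecs = msm.eigenvalues, msm.right_eigenvectors
    else:
        T = np.asarray(msm, dtype=float)
        pi = _stationary(T)
        evals, evecs = _sorted_spectrum(T, pi, reversible=True)
    n = T.shape[0]
    if m < 2:
        raise ValueError("m must be >= 2")
    if m > n:
        raise ValueError(f"m={m} exceeds the number of microstates ({n})")
    lam = evals[:m]
    if np.any(np.abs(np.imag(lam)) > 1e-10) or np.any(np.real(lam) <= 0):
        raise ValueError(
            f"first {m} eigenvalues include complex or non-positive values; "
            "the spectrum supports fewer metastable states — reduce m"
        )
    X = np.real(evecs[:, :m]).copy()
    X[:, 0] = 1.0  # stationary eigenvector is constant up to scaling
    verts = _inner_simplex_vertices(X)
    A = np.linalg.inv(X[verts])
    chi = X @ A
    # feasibility clipping: tiny negatives from finite-precision simplex
    chi[np.abs(chi) < 1e-10] = 0.0
    chi = np.clip(chi, 0.0, None)
    chi /= chi.sum(axis=1, keepdims=True)
    weights = chi.T @ pi
    weights = weights / weights.sum()
    return MacrostatePartition(memberships=chi, stationary_weights=weights)


def coarse_grain_dtrajs(partition: MacrostatePartition, dtrajs) -> list[np.ndarray]:
    """Frame-wise crisp microstate -> macrostate mapping."""
    dtrajs = validate_dtrajs(dtrajs)
    crisp = partition.crisp_labels
    out = []
    for d in dtrajs:
        if d.size and d.max() >= partition.n_microstates:
            raise ValueError(
                f"label {int(d.max())} outside the partition domain "
                f"(n_microstates={partition.n_microstates})"
            )
        out.append(crisp[d])
    return out


def assign_endpoint_states(macro_dtrajs, window: int = 100,
                           override: tuple | None = None) -> tuple[set, set]:
    """Detect the source set A and sink set B of the slow transition.

    A is the modal macrostate of the first ``window`` frames of each
    trajectory (majority vote across trajectories), B the modal macrostate
    of the last ``window`` frames. A user override is respected verbatim.
    """
    if override is not None:
        A, B = override
        return set(A), set(B)
    macro_dtrajs = validate_dtrajs(macro_dtrajs)
    n = max(int(d.max()) for d in macro_dtrajs) + 1
    first = np.zeros(n, dtype=int)
    last = np.zeros(n, dtype=int)
    for d in macro_dtrajs:
        w = min(window, len(d))
        first += np.bincount(d[:w], minlength=n)
        last += np.bincount(d[-w:], minlength=n)
    A, B = int(first.argmax()), int(last.argmax())
    if A == B:
        raise ValueError(
            f"detected source and sink coincide (macrostate {A}); "
            "designate A and B manually"
        )
    return {A}, {B}


def name_macrostates(partition: MacrostatePartition, A: set, B: set) -> list[str]:
    """SA/SB/S1..Sk naming: source states are SA, sink states SB, the rest
    S1, S2, ... by decreasing stationary weight. Stored on the partition."""
    names = [None] * partition.m
    for a in A:
        names[a] = "SA"
    for b in B:
        names[b] = "SB"
    rest = [j for j in range(partition.m) if names[j] is None]
    rest.sort(key=lambda j: -partition.stationary_weights[j])
    for i, j in enumerate(rest):
        names[j] = f"S{i+1}"
    partition.names = names
    return names
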