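"""Synthetic trajectory generators with known ground truth.

Three families of generators make every downstream stage testable without
external data:

* exact discrete Markov chains (:func:`sample_markov_chain`,
  :func:`make_metastable_chain`) — ground truth for transition-matrix and
  stationary-distribution estimators and for PCCA+ block recovery;
* overdamped Langevin dynamics on simple potentials
  (:func:`simulate_langevin`) — a continuous stand-in for MD sampling with
  analytically known equilibrium statistics;
* a backbone-dihedral-like dataset (:func:`emulate_dihedral_dataset`)
  matching the shape of the BRD4 study inputs: 10 trajectories of 5000
  frames, 139 angular features each, 0.1 ns frame spacing, with a hidden
  metastable chain as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .containers import DEFAULT_DT_NS, FeatureTrajectory

__all__ = [
    "GroundTruthChain",
    "PotentialSpec",
    "SyntheticDataset",
    "sample_markov_chain",
    "make_metastable_chain",
    "simulate_langevin",
    "emulate_dihedral_dataset",
    "wrap_angles",
]


def _validate_stochastic(T: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(T < -tol) or np.any(T > 1 + tol):
        raise ValueError("transition matrix entries must lie in [0, 1]")
    rowsums = T.sum(axis=1)
    bad = np.where(np.abs(rowsums - 1.0) > 1e-10)[0]
    if bad.size:
        raise ValueError(
            f"transition matrix row {bad[0]} sums to {rowsums[bad[0]]:.12g}, not 1"
        )
    return T


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Leading left eigenvector of a stochastic matrix, normalized to sum 1."""
    w, V = np.linalg.eig(T.T)
    i = np.argmin(np.abs(w - 1.0))
    pi = np.real(V[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


@dataclass
class GroundTruthChain:
    """An exactly known Markov chain: transition matrix, stationary
    distribution (the Boltzmann weight of each state), and state labels."""

    transition_matrix: np.ndarray
    stationary: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.transition_matrix = _validate_stochastic(self.transition_matrix)
        n = self.transition_matrix.shape[0]
        if self.stationary is None:
            self.stationary = stationary_distribution(self.transition_matrix)
        else:
            self.stationary = np.asarray(self.stationary, dtype=float)
            if not np.allclose(
                self.stationary @ self.transition_matrix, self.stationary, atol=1e-10
            ):
                raise ValueError("stationary vector is not stationary for T")
        if self.labels is None:
            self.labels = np.arange(n)

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]


def sample_markov_chain(
    chain: GroundTruthChain | np.ndarray,
    n_steps: int,
    start: int | str | None = None,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw a label sequence of length ``n_steps`` from a Markov chain.

    ``start`` may be a state index, ``"stationary"`` (or None) for a draw
    from the stationary distribution. Identical seeds give identical output.
    """
    if not isinstance(chain, GroundTruthChain):
        chain = GroundTruthChain(np.asarray(chain))
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    T = chain.transition_matrix
    n = chain.n_states
    if start is None or start == "stationary":
        state = int(rng.choice(n, p=chain.stationary))
    else:
        state = int(start)
        if not 0 <= state < n:
            raise ValueError(f"start state {state} outside [0, {n})")
    # cumulative rows let each step be a single searchsorted
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(n_steps - 1)
    out = np.empty(n_steps, dtype=int)
    out[0] = state
    for t in range(1, n_steps):
        state = int(np.searchsorted(cum[state], u[t - 1], side="right"))
        out[t] = state
    return out


def make_metastable_chain(
    n_blocks: int,
    states_per_block: int,
    p_intra: float = 0.9,
    p_inter: float = 0.01,
    seed: int | None = None,
) -> GroundTruthChain:
    """Build a reversible block-structured chain with planted macrostates.

    Each state keeps probability mass ``1 - p_inter`` inside its block
    (spread over random symmetric intra-block weights) and leaks ``p_inter``
    to the other blocks, so the slowest ``n_blocks - 1`` processes are
    separated from the rest by a spectral gap. The chain is reversible by
    construction (row-normalized symmetric weights).
    """
    if n_blocks < 1 or states_per_block < 1:
        raise ValueError("n_blocks and states_per_block must be >= 1")
    if not (0 < p_intra < 1) or not (0 < p_inter < 1):
        raise ValueError("p_intra and p_inter must lie in (0, 1)")
    if p_inter >= p_intra:
        raise ValueError("p_inter must be smaller than p_intra for metastability")
    rng = np.random.default_rng(seed)
    n = n_blocks * states_per_block
    S = np.full((n, n), p_inter / max(n, 1))
    for b in range(n_blocks):
        sl = slice(b * states_per_block, (b + 1) * states_per_block)
        W = rng.uniform(0.5, 1.0, size=(states_per_block, states_per_block))
        W = 0.5 * (W + W.T)  # symmetric intra-block weights -> reversible
        # lazy chain: strong self-weight keeps the spectrum positive, as
        # befits metastable dynamics (and PCCA+'s positivity requirement)
        W[np.diag_indices(states_per_block)] += states_per_block
        S[sl, sl] = W
    T = S / S.sum(axis=1, keepdims=True)
    _validate_stochastic(T)
    pi = S.sum(axis=1) / S.sum()
    labels = np.repeat(np.arange(n_blocks), states_per_block)
    return GroundTruthChain(T, stationary=pi, labels=labels)


_POTENTIALS: dict[str, tuple[Callable, Callable]] = {
    # name -> (V(x), grad V(x)); x is an array of shape (dim,)
    "harmonic": (
        lambda x, k=1.0: 0.5 * k * float(np.sum(x**2)),
        lambda x, k=1.0: k * x,
    ),
    "double_well": (
        lambda x, a=1.0: float(a * np.sum((x**2 - 1.0) ** 2)),
        lambda x, a=1.0: a * 4.0 * x * (x**2 - 1.0),
    ),
}


@dataclass
class PotentialSpec:
    """Specification of an overdamped Langevin simulation.

    Parameters
    ----------
    form : str or callable
        ``"harmonic"`` (V = k/2 |x|^2), ``"double_well"``
        (V = a (x^2-1)^2, per dimension), or a callable gradient
        ``grad(x) -> ndarray``.
    dimension : int
        1 or 2.
    kT : float
        Thermal energy (energy units); > 0 (0 allowed for the
        deterministic gradient-flow limit).
    friction : float
        Friction coefficient gamma; > 0.
    timestep : float
        Integration step dt; > 0.
    params : dict
        Extra parameters forwarded to the potential (e.g. ``k`` or ``a``).
    x0 : ndarray, optional
        Initial position; defaults to the origin (harmonic) or a well
        minimum at +1 (double well) unless given.
    """

    form: str | Callable = "double_well"
    dimension: int = 1
    kT: float = 1.0
    friction: float = 1.0
    timestep: float = 1e-3
    params: dict = field(default_factory=dict)
    x0: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dimension not in (1, 2):
            raise ValueError("dimension must be 1 or 2")
        if self.kT < 0:
            raise ValueError("kT must be non-negative")
        if self.friction <= 0 or self.timestep <= 0:
            raise ValueError("friction and timestep must be positive")
        if isinstance(self.form, str) and self.form not in _POTENTIALS:
            raise ValueError(f"unknown potential form {self.form!r}")

    def gradient(self, x: np.ndarray) -> np.ndarray:
        if callable(self.form):
            return np.asarray(self.form(x, **self.params), dtype=float)
        return _POTENTIALS[self.form][1](x, **self.params)

    def initial_position(self) -> np.ndarray:
        if self.x0 is not None:
            return np.asarray(self.x0, dtype=float).reshape(self.dimension)
        if self.form == "double_well":
            return np.ones(self.dimension)
        return np.zeros(self.dimension)


def simulate_langevin(
    spec: PotentialSpec,
    n_steps: int,
    seed: int | None = None,
    dt_out: float = DEFAULT_DT_NS,
) -> FeatureTrajectory:
    """Euler-Maruyama integration of overdamped Langevin dynamics.

    dx = -grad V(x)/gamma dt + sqrt(2 kT dt / gamma) xi,  xi ~ N(0, I).

    Raises if the position becomes non-finite (reporting the step index).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    dt = spec.timestep
    gamma = spec.friction
    sigma = np.sqrt(2.0 * spec.kT * dt / gamma)
    x = spec.initial_position().copy()
    out = np.empty((n_steps, spec.dimension))
    noise = rng.standard_normal((n_steps, spec.dimension))
    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(n_steps):
            x = x - spec.gradient(x) / gamma * dt + sigma * noise[t]
            if not np.all(np.isfinite(x)):
                raise FloatingPointError(
                    f"Langevin trajectory diverged at step {t}; reduce the timestep"
                )
            out[t] = x
    return FeatureTrajectory(out, dt=dt_out, names=[f"x{i+1}" for i in range(spec.dimension)])


def wrap_angles(a: np.ndarray) -> np.ndarray:
    """Wrap angles in degrees onto (-180, 180]."""
    out = -((-np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0)
    return out


@dataclass
class SyntheticDataset:
    """Feature trajectories plus frame-aligned ground-truth state labels."""

    trajectories: list[FeatureTrajectory]
    ground_truth_labels: list[np.ndarray]
    chain: GroundTruthChain
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.trajectories) != len(self.ground_truth_labels):
            raise ValueError("one label sequence per trajectory required")
        for ft, lab in zip(self.trajectories, self.ground_truth_labels):
            if ft.n_frames != len(lab):
                raise ValueError("labels must align frame-for-frame with trajectories")


def emulate_dihedral_dataset(
    n_traj: int = 10,
    n_frames: int = 5000,
    n_features: int = 139,
    n_metastable: int = 5,
    seed: int | None = None,
    stay_probability: float = 0.995,
    noise_deg: float = 25.0,
    start_state: int | None = 0,
    end_state: int | None = None,
    endpoint_window: int = 100,
    dt: float = DEFAULT_DT_NS,
) -> SyntheticDataset:
    """Generate backbone-dihedral-like trajectories with planted metastability.

    A hidden ``n_metastable``-state chain (uniform leak, self-probability
    ``stay_probability``) drives hops between states; each state has a
    distinct mean angle vector and frames are wrapped-Gaussian perturbations
    of it. Defaults reproduce the study's data shape: 10 trajectories of
    5000 frames x 139 angular features at 0.1 ns spacing.

    ``start_state``/``end_state`` plant the source and sink of the slow
    transition: every hidden path starts in ``start_state`` and is resampled
    until the modal state of its final ``endpoint_window`` frames equals
    ``end_state`` (default: the last state). Pass ``None`` to disable either.
    """
    if min(n_traj, n_frames, n_features, n_metastable) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    m = n_metastable
    if m == 1:
        T = np.ones((1, 1))
    else:
        q = (1.0 - stay_probability) / (m - 1)
        T = np.full((m, m), q)
        np.fill_diagonal(T, stay_probability)
    chain = GroundTruthChain(T)

    means = rng.uniform(-180.0, 180.0, size=(m, n_features))
    metadata: dict = {
        "seed": seed,
        "n_metastable": m,
        "stay_probability": stay_probability,
        "noise_deg": noise_deg,
        "start_state": start_state,
        "end_state": end_state,
        "warnings": [],
    }
    # overlap warning: neighboring state means closer than the noise scale
    if m > 1:
        d = np.array(
            [
                np.abs(wrap_angles(means[i] - means[j])).mean()
                for i in range(m)
                for j in range(i + 1, m)
            ]
        )
        if np.any(d < 2 * noise_deg):
            metadata["warnings"].append(
                "some metastable states may be indistinguishable at this noise level"
            )

    if end_state is None and m > 1 and start_state is not None:
        end_state = m - 1
    w = min(endpoint_window, n_frames)

    trajs, labels = [], []
    for _ in range(n_traj):
        for attempt in range(200):
            lab = sample_markov_chain(
                chain, n_frames,
                start=start_state if start_state is not None else "stationary",
                seed=rng,
            )
            if end_state is None or m == 1:
                break
            tail = lab[-w:]
            if np.bincount(tail, minlength=m).argmax() == end_state:
                break
        else:
            metadata["warnings"].append(
                "endpoint enforcement failed; using last sampled path"
            )
        angles = wrap_angles(means[lab] + rng.normal(0.0, noise_deg, size=(n_frames, n_features)))
        trajs.append(
            FeatureTrajectory(
                angles,
                dt=dt,
                names=[f"angle_{i+1}" for i in range(n_features)],
                periodic=np.ones(n_features, dtype=bool),
            )
        )
        labels.append(lab)
    return SyntheticDataset(trajs, labels, chain, metadata)
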