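"""Shared data containers for trajectories and feature matrices.

A :class:`FeatureTrajectory` is the currency between featurization, TICA and
clustering: a (frames x features) real matrix with frame-spacing metadata.
Discrete (microstate/macrostate) trajectories are plain 1-D integer arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureTrajectory",
    "as_feature_trajectories",
    "load_feature_matrix",
    "save_feature_matrix",
    "load_dtraj",
    "save_dtraj",
]

#: Default frame spacing in nanoseconds (the BRD4 study stored one frame
#: every 0.1 ns).
DEFAULT_DT_NS = 0.1


@dataclass
class FeatureTrajectory:
    """Time-ordered real-valued feature matrix.

    Parameters
    ----------
    values : ndarray, shape (n_frames, n_features)
        Feature values; must be finite.
    dt : float
        Frame spacing in nanoseconds (> 0).
    names : list of str, optional
        One name per feature column.
    periodic : ndarray of bool, optional
        Per-feature flag marking angular features that live on
        (-180, 180] degrees.
    """

    values: np.ndarray
    dt: float = DEFAULT_DT_NS
    names: list[str] | None = None
    periodic: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise ValueError("feature trajectory must be 2-D (frames x features)")
        if self.values.shape[0] < 1:
            raise ValueError("feature trajectory needs at least one frame")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature trajectory contains non-finite values")
        if self.dt <= 0:
            raise ValueError("frame spacing dt must be positive")
        if self.names is not None and len(self.names) != self.values.shape[1]:
            raise ValueError(
                f"got {len(self.names)} feature names for "
                f"{self.values.shape[1]} features"
            )
        if self.periodic is not None:
            self.periodic = np.asarray(self.periodic, dtype=bool)
            if self.periodic.shape != (self.values.shape[1],):
                raise ValueError("periodic flags must have one entry per feature")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def __len__(self) -> int:
        return self.n_frames


def as_feature_trajectories(trajs, dt: float = DEFAULT_DT_NS) -> list[FeatureTrajectory]:
    """Coerce a trajectory, array, or list thereof into FeatureTrajectory list."""
    if isinstance(trajs, (FeatureTrajectory, np.ndarray)):
        trajs = [trajs]
    out = []
    for t in trajs:
        if isinstance(t, FeatureTrajectory):
            out.append(t)
        else:
            out.append(FeatureTrajectory(np.asarray(t, dtype=float), dt=dt))
    if not out:
        raise ValueError("no trajectories given")
    dims = {t.n_features for t in out}
    if len(dims) > 1:
        raise ValueError(f"inconsistent feature dimensions across trajectories: {sorted(dims)}")
    return out


def save_feature_matrix(path, ft: FeatureTrajectory | np.ndarray) -> None:
    """Write a feature matrix as whitespace-separated text.

    A ``# name1 name2 ...`` header line is emitted when names are present.
    """
    values = ft.values if isinstance(ft, FeatureTrajectory) else np.asarray(ft)
    header = ""
    if isinstance(ft, FeatureTrajectory) and ft.names is not None:
        header = " ".join(ft.names)
    np.savetxt(path, values, header=header)


def load_feature_matrix(path, dt: float = DEFAULT_DT_NS) -> FeatureTrajectory:
    """Read a feature matrix written by :func:`save_feature_matrix` (or any
    plain whitespace/CSV numeric text file; ``.npy`` is accepted too)."""
    spath = str(path)
    names = None
    if spath.endswith(".npy"):
        values = np.load(spath)
    else:
        delimiter = "," if spath.endswith(".csv") else None
        with open(spath) as fh:
            first = fh.readline()
        if first.startswith("#") and first[1:].strip():
            names = first[1:].split()
        values = np.loadtxt(spath, delimiter=delimiter)
    return FeatureTrajectory(values, dt=dt, names=names)


def save_dtraj(path, dtraj: np.ndarray) -> None:
    """Write a discrete trajectory as one integer label per line."""
    np.savetxt(path, np.asarray(dtraj, dtype=int), fmt="%d")


def load_dtraj(path) -> np.ndarray:
    return np.loadtxt(path, dtype=int).reshape(-1)


def validate_dtrajs(dtrajs) -> list[np.ndarray]:
    """Coerce to a list of 1-D non-negative integer arrays."""
    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        dtrajs = [dtrajs]
    out = []
    for d in dtrajs:
        d = np.asarray(d)
        if d.ndim != 1:
            raise ValueError("discrete trajectories must be 1-D label sequences")
        if d.size and not np.issubdtype(d.dtype, np.integer):
            if not np.allclose(d, np.round(d)):
                raise ValueError("discrete trajectory labels must be integers")
            d = d.astype(int)
        if d.size and d.min() < 0:
            raise ValueError("discrete trajectory labels must be non-negative")
        out.append(d.astype(int))
    if not out:
        raise ValueError("no discrete trajectories given")
    return out
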