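"""Time-lagged independent component analysis (TICA).

TICA finds linear projections of the input features that maximize
autocorrelation at a lag time, i.e. the slowest linearly resolvable
collective coordinates. It solves the generalized symmetric eigenproblem

    C_tau v = lambda C_0 v

on mean-free data, where C_0 is the instantaneous and C_tau the time-lagged
covariance, both symmetrized so the spectrum is real on finite data.
Lagged pairs never straddle trajectory boundaries: trajectories are
independent runs.

The estimator/results split follows the statsmodels convention:
``TICA(trajs, lag).fit()`` returns a :class:`TICAResults` that carries the
spectrum and performs projections.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .containers import FeatureTrajectory, as_feature_trajectories

__all__ = ["TICA", "TICAResults", "estimate_tica", "tica_transform"]


class TICA:
    """TICA estimator.

    Parameters
    ----------
    trajs : FeatureTrajectory, ndarray, or list thereof
        Input feature trajectories (consistent feature dimension).
    lag : int
        Lag time in frames; must be shorter than every trajectory.
    dim : int or float
        Number of components to retain, or a fraction in (0, 1): the
        smallest dimension capturing at least that share of kinetic
        variance (sum of squared eigenvalues). Default 0.95.
    regularization : float or None
        Ridge added to C_0 as ``eps * I``. ``None`` (default) uses
        ``1e-8 * trace(C_0)/d``, which keeps collinear sin/cos features
        solvable; 0 disables it.
    """

    def __init__(self, trajs, lag: int = 10, dim: int | float = 0.95,
                 regularization: float | None = None):
        self.trajs = as_feature_trajectories(trajs)
        if lag < 1:
            raise ValueError("lag must be >= 1")
        shortest = min(t.n_frames for t in self.trajs)
        if lag >= shortest:
            raise ValueError(
                f"lag {lag} is not shorter than the shortest trajectory ({shortest} frames)"
            )
        self.lag = int(lag)
        self.dim = dim
        self.regularization = regularization

    def fit(self) -> "TICAResults":
        lag = self.lag
        d = self.trajs[0].n_features
        n_pairs = sum(t.n_frames - lag for t in self.trajs)
        # mean over both pair endpoints (symmetric estimate)
        s = np.zeros(d)
        for t in self.trajs:
            X = t.values
            s += X[:-lag].sum(axis=0) + X[lag:].sum(axis=0)
        mean = s / (2 * n_pairs)

        C0 = np.zeros((d, d))
        Ct = np.zeros((d, d))
        for t in self.trajs:
            X0 = t.values[:-lag] - mean
            Xt = t.values[lag:] - mean
            C0 += X0.T @ X0 + Xt.T @ Xt
            Ct += X0.T @ Xt
        C0 /= 2 * n_pairs
        Ct = (Ct + Ct.T) / (2 * n_pairs)  # symmetrized -> real spectrum

        eps = self.regularization
        if eps is None:
            eps = 1e-8 * np.trace(C0) / d
        C0r = C0 + eps * np.eye(d)

        if eps == 0:
            # fail loudly on rank deficiency rather than returning noise
            if np.linalg.matrix_rank(C0, tol=1e-10 * max(np.trace(C0) / d, 1e-30)) < d:
                raise np.linalg.LinAlgError(
                    "C0 is rank deficient; pass a positive regularization"
                )
        if np.trace(C0) <= 0 or np.allclose(C0, 0):
            raise ValueError("data has zero variance; TICA undefined")

        evals, evecs = scipy.linalg.eigh(Ct, C0r)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        if np.max(np.abs(evals)) > 1 + 1e-6:
            # numerically possible with near-singular C0; clip for reporting
            evals = np.clip(evals, -1 - 1e-6, 1 + 1e-6)

        if isinstance(self.dim, float) and 0 < self.dim < 1:
            kv = np.cumsum(evals**2)
            total = kv[-1] if kv[-1] > 0 else 1.0
            n_keep = int(np.searchsorted(kv / total, self.dim) + 1)
        else:
            n_keep = int(self.dim)
            if n_keep < 1 or n_keep > d:
                raise ValueError(f"dim must be in [1, {d}]")
        return TICAResults(
            mean=mean, c0=C0, ctau=Ct, eigenvalues=evals, eigenvectors=evecs,
            lag=lag, dim=n_keep, dt=self.trajs[0].dt,
        )


class TICAResults:
    """Fitted TICA model: spectrum, projections, timescales."""

    def __init__(self, mean, c0, ctau, eigenvalues, eigenvectors, lag, dim, dt):
        self.mean = mean
        self.c0 = c0
        self.ctau = ctau
        self.eigenvalues = eigenvalues
        self.eigenvectors = eigenvectors
        self.lag = lag
        self.dim = dim
        self.dt = dt

    @property
    def n_features(self) -> int:
        return self.mean.shape[0]

    def kinetic_variance_fraction(self) -> np.ndarray:
        kv = np.cumsum(self.eigenvalues**2)
        return kv / kv[-1] if kv[-1] > 0 else kv

    def timescales(self, n: int | None = None) -> np.ndarray:
        """Implied timescales -lag/ln|lambda| in frames (nan where
        undefined, i.e. lambda <= 0 or >= 1)."""
        lam = self.eigenvalues[: n or self.dim]
        with np.errstate(divide="ignore", invalid="ignore"):
            ts = -self.lag / np.log(np.abs(lam))
        ts[(lam <= 0) | (np.abs(lam) >= 1)] = np.nan
        return ts

    def transform(self, ft: FeatureTrajectory | np.ndarray, dim: int | None = None) -> FeatureTrajectory:
        """Project mean-free data onto the retained components (IC1..ICd)."""
        values = ft.values if isinstance(ft, FeatureTrajectory) else np.asarray(ft, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        if values.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {values.shape[1]} does not match model ({self.n_features})"
            )
        d = dim or self.dim
        Y = (values - self.mean) @ self.eigenvectors[:, :d]
        dt = ft.dt if isinstance(ft, FeatureTrajectory) else self.dt
        return FeatureTrajectory(Y, dt=dt, names=[f"IC{i+1}" for i in range(d)])

    def save(self, path) -> None:
        np.savez(
            path, mean=self.mean, c0=self.c0, ctau=self.ctau,
            eigenvalues=self.eigenvalues, eigenvectors=self.eigenvectors,
            lag=self.lag, dim=self.dim, dt=self.dt,
        )

    @classmethod
    def load(cls, path) -> "TICAResults":
        z = np.load(path)
        return cls(
            mean=z["mean"], c0=z["c0"], ctau=z["ctau"],
            eigenvalues=z["eigenvalues"], eigenvectors=z["eigenvectors"],
            lag=int(z["lag"]), dim=int(z["dim"]), dt=float(z["dt"]),
        )

    def summary(self) -> str:
        lines = [
            "TICA Results",
            f"  features: {self.n_features}   lag: {self.lag} frames "
            f"({self.lag * self.dt:g} ns)   retained: {self.dim}",
            "  comp  eigenvalue  timescale(frames)",
        ]
        ts = self.timescales(min(self.dim, 10))
        for i in range(min(self.dim, 10)):
            lines.append(f"  IC{i+1:<3d} {self.eigenvalues[i]:10.6f}  {ts[i]:12.3f}")
        return "\n".join(lines)


def estimate_tica(trajs, lag: int = 10, dim: int | float = 0.95,
                  regularization: float | None = None) -> TICAResults:
    """Functional wrapper: fit TICA on feature trajectories."""
    return TICA(trajs, lag=lag, dim=dim, regularization=regularization).fit()


def tica_transform(model: TICAResults, ft) -> FeatureTrajectory:
    """Functional wrapper for :meth:`TICAResults.transform`."""
    return model.transform(ft)
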