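"""Microstate definition by restarted k-means, scored with VAMP-2.

Frames (typically TICA projections) are partitioned into k microstates by
best-of-restarts k-means (k-means++ seeding, Lloyd iterations); the
kinetic quality of a discretization is the VAMP-2 score — the sum of
squared singular values of the half-weighted transition operator estimated
on the discrete trajectories — and k is chosen by a cross-validated grid
search with a one-standard-error tie-break toward smaller k. Splits are
made over whole trajectories, never over frames, because frames are
autocorrelated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import as_feature_trajectories, validate_dtrajs

__all__ = [
    "MicrostateKMeans",
    "ClusterResults",
    "kmeans_fit",
    "assign",
    "vamp2_score",
    "select_k",
]


class MicrostateKMeans:
    """Best-of-restarts k-means estimator over feature trajectories."""

    def __init__(self, trajs, k: int, n_restarts: int = 10, seed: int | None = None,
                 max_iter: int = 300, tol: float = 1e-6):
        self.trajs = as_feature_trajectories(trajs)
        n_total = sum(t.n_frames for t in self.trajs)
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > n_total:
            raise ValueError(f"k={k} exceeds total frame count {n_total}")
        self.k = int(k)
        self.n_restarts = int(n_restarts)
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol

    def fit(self) -> "ClusterResults":
        X = np.vstack([t.values for t in self.trajs])
        km = KMeans(
            n_clusters=self.k,
            init="k-means++",
            n_init=self.n_restarts,
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=np.random.default_rng(self.seed).integers(2**31 - 1),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # duplicate-point convergence chatter
            km.fit(X)
        return ClusterResults(
            centers=km.cluster_centers_.astype(float),
            inertia=float(km.inertia_),
            n_restarts=self.n_restarts,
            seed=self.seed,
        )


@dataclass
class ClusterResults:
    """Fitted microstate definition: centers and fit metadata."""

    centers: np.ndarray
    inertia: float
    n_restarts: int = 1
    seed: int | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 2 or not np.all(np.isfinite(self.centers)):
            raise ValueError("centers must be a finite k x d matrix")
        if self.inertia < 0:
            raise ValueError("inertia must be non-negative")

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    def assign(self, ft) -> np.ndarray:
        return assign(self, ft)

    def save(self, path) -> None:
        np.savez(path, centers=self.centers, inertia=self.inertia,
                 n_restarts=self.n_restarts)

    @classmethod
    def load(cls, path) -> "ClusterResults":
        z = np.load(path)
        return cls(centers=z["centers"], inertia=float(z["inertia"]),
                   n_restarts=int(z["n_restarts"]))


def kmeans_fit(trajs, k: int, n_restarts: int = 10, seed: int | None = None) -> ClusterResults:
    """Fit k-means microstates (functional wrapper)."""
    return MicrostateKMeans(trajs, k, n_restarts=n_restarts, seed=seed).fit()


def assign(model: ClusterResults, ft) -> np.ndarray:
    """Nearest-center microstate labels; ties break to the lowest index."""
    values = ft.values if hasattr(ft, "values") else np.asarray(ft, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if values.shape[1] != model.centers.shape[1]:
        raise ValueError(
            f"feature dimension {values.shape[1]} does not match centers "
            f"({model.centers.shape[1]})"
        )
    d2 = (
        np.sum(values**2, axis=1)[:, None]
        - 2.0 * values @ model.centers.T
        + np.sum(model.centers**2, axis=1)[None, :]
    )
    # exact distances for tie stability near-equidistant points
    close = np.isclose(d2, d2.min(axis=1, keepdims=True), atol=1e-9)
    return np.argmax(close, axis=1)  # first (= lowest-index) minimal center


def vamp2_score(dtrajs, lag: int, n_components: int | None = None) -> float:
    """VAMP-2 score of the discretization at the given lag.

    With indicator (one-hot) features the half-weighted operator is
    K = C00^{-1/2} C0t Ctt^{-1/2}; the score is the sum of the squared top
    singular values. The constant function is always resolved, so the score
    is >= 1; a one-state discretization scores exactly 1.

    Disconnected discretizations are scored on the largest strongly
    connected state set (a warning is emitted).
    """
    from .msm import count_transitions, largest_connected_set

    dtrajs = validate_dtrajs(dtrajs)
    if lag < 1 or lag >= max(len(d) for d in dtrajs):
        raise ValueError("lag must be >= 1 and shorter than the longest trajectory")
    C = count_transitions(dtrajs, lag, mode="sliding")
    lcs = largest_connected_set(C)
    if len(lcs) < C.shape[0]:
        n_active = len(np.union1d(np.where(C.sum(0) > 0)[0], np.where(C.sum(1) > 0)[0]))
        if len(lcs) < n_active:
            warnings.warn(
                f"discretization not connected; scoring on largest connected set "
                f"({len(lcs)} of {n_active} visited states)"
            )
    C = C[np.ix_(lcs, lcs)].astype(float)
    c0 = C.sum(axis=1)
    ct = C.sum(axis=0)
    # half-weighted operator for indicator features
    K = (C / np.sqrt(c0)[:, None]) / np.sqrt(ct)[None, :]
    s = np.linalg.svd(K, compute_uv=False)
    if n_components is not None:
        s = s[: int(n_components)]
    s = np.minimum(s, 1.0)  # singular values of a stochastic kernel are <= 1
    return float(np.sum(s**2))


def select_k(
    trajs,
    k_grid,
    lag: int = 10,
    n_restarts: int = 10,
    seed: int | None = None,
    cv_folds: int = 5,
    test_fraction: float = 0.5,
    n_components: int | None = None,
) -> tuple[int, pd.DataFrame]:
    """Cross-validated VAMP-2 grid search over k.

    For each k and each shuffle split of the trajectories, k-means is fitted
    on the training trajectories and the VAMP-2 score evaluated on the
    held-out ones. The best k is the highest mean score with a
    one-standard-error tie-break toward smaller k. Returns (best_k, table)
    where the table has one row per grid value (mean, se, per-fold scores).
    """
    trajs = as_feature_trajectories(trajs)
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ValueError("k grid must be nonempty")
    n_traj = len(trajs)
    rng = np.random.default_rng(seed)
    rows = []
    for k in k_grid:
        scores = []
        for fold in range(cv_folds):
            if n_traj >= 2:
                perm = rng.permutation(n_traj)
                n_test = max(1, int(round(test_fraction * n_traj)))
                n_test = min(n_test, n_traj - 1)
                test_idx, train_idx = perm[:n_test], perm[n_test:]
            else:  # single trajectory: split in halves along time
                half = trajs[0].n_frames // 2
                train_idx = test_idx = None
            try:
                if train_idx is None:
                    train = [trajs[0].values[:half]]
                    test = [trajs[0].values[half:]]
                else:
                    train = [trajs[i] for i in train_idx]
                    test = [trajs[i] for i in test_idx]
                model = kmeans_fit(train, k, n_restarts=n_restarts,
                                   seed=int(rng.integers(2**31 - 1)))
                dtrajs = [model.assign(t) for t in test]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    scores.append(vamp2_score(dtrajs, lag, n_components=n_components))
            except (ValueError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"k={k} fold {fold} failed: {exc}")
        if scores:
            arr = np.asarray(scores)
            se = arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else 0.0
            rows.append({"k": k, "mean_score": arr.mean(), "se": se,
                         "n_folds": len(arr), "scores": list(arr)})
        else:
            rows.append({"k": k, "mean_score": np.nan, "se": np.nan,
                         "n_folds": 0, "scores": []})
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["mean_score"])
    if valid.empty:
        raise ValueError("every k in the grid failed to fit")
    best_row = valid.loc[valid["mean_score"].idxmax()]
    threshold = best_row["mean_score"] - best_row["se"]
    best_k = int(valid.loc[valid["mean_score"] >= threshold, "k"].min())
    return best_k, table
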