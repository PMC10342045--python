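"""MD trajectory observables: RMSD, RMSF, B-factor, Rg, DCCM, SASA,
inter-group distances.

All observables operate on a :class:`~msmflux.featurize.StructureEnsemble`
(frames x atoms x 3, Angstrom). Where a reference frame matters, frames are
first superposed by the Kabsch least-squares rigid fit (proper rotation
enforced), so the observables are invariant under global rigid motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .featurize import StructureEnsemble

__all__ = [
    "ObservableSeries",
    "CorrelationMatrix",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "b_factor",
    "radius_of_gyration",
    "dccm",
    "sasa_shrake_rupley",
    "group_distance",
    "ELEMENT_RADII",
]

#: van der Waals radii (Angstrom) for the common protein elements.
ELEMENT_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8}


@dataclass
class ObservableSeries:
    """A named per-frame (or per-atom) observable with units."""

    name: str
    values: np.ndarray
    units: str = ""
    selection: np.ndarray | None = None
    dt: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.name}: non-finite values")

    def to_csv(self, path) -> None:
        import pandas as pd

        t = np.arange(len(self.values)) * (self.dt or 1.0)
        pd.DataFrame({"time": t, self.name: self.values}).to_csv(path, index=False)


@dataclass
class CorrelationMatrix:
    """Normalized cross-correlation matrix of atomic displacements."""

    values: np.ndarray
    selection: np.ndarray | None = None

    def __post_init__(self) -> None:
        C = np.asarray(self.values, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("correlation matrix must be square")
        finite = np.isfinite(C)
        if np.any(np.abs(C[finite]) > 1 + 1e-8):
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = C


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation 3x3, translation 3, rmsd). The rotation is proper
    (det = +1). Requires >= 3 non-collinear atoms.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n_atoms, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 atoms")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * reference).sum(axis=0)
    X = mobile - mc
    Y = reference - rc
    H = (w[:, None] * X).T @ Y
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10 * max(S[0], 1e-30):
        raise ValueError("degenerate (collinear) atom set; superposition ill-defined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    moved = (R @ mobile.T).T + t
    rmsd = float(np.sqrt(np.sum(w[:, None] * (moved - reference) ** 2)))
    return R, t, rmsd


def _superposed_coords(coords: np.ndarray, reference: np.ndarray,
                       fit_sel: np.ndarray | None = None) -> np.ndarray:
    """Superpose every frame onto the reference (fit on ``fit_sel``)."""
    out = np.empty_like(coords)
    sel = slice(None) if fit_sel is None else fit_sel
    for f in range(coords.shape[0]):
        R, t, _ = kabsch_superpose(coords[f][sel], reference[sel])
        out[f] = (R @ coords[f].T).T + t
    return out


def _resolve_selection(ens: StructureEnsemble, selection) -> np.ndarray:
    if selection is None:
        return np.arange(ens.n_atoms)
    sel = np.asarray(selection)
    if sel.dtype == bool:
        sel = np.where(sel)[0]
    if sel.size == 0:
        raise ValueError("empty atom selection")
    return sel.astype(int)


def rmsd_series(ens: StructureEnsemble, reference: int = 0,
                selection=None) -> ObservableSeries:
    """Per-frame RMSD (Angstrom) to a reference frame after Kabsch
    superposition on the selected atoms."""
    sel = _resolve_selection(ens, selection)
    ref = ens.coordinates[reference][sel]
    vals = np.empty(ens.n_frames)
    for f in range(ens.n_frames):
        _, _, vals[f] = kabsch_superpose(ens.coordinates[f][sel], ref)
    return ObservableSeries("rmsd", vals, units="Å", selection=sel, dt=ens.dt)


def rmsf(ens: StructureEnsemble, selection=None, superpose: bool = True) -> ObservableSeries:
    """Per-atom root-mean-square fluctuation about the mean structure.

    With ``superpose`` the frames are iteratively aligned to the mean
    structure (two passes), the standard convention for removing global
    motion before measuring local fluctuation.
    """
    if ens.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = _resolve_selection(ens, selection)
    coords = ens.coordinates[:, sel, :]
    if superpose:
        ref = coords[0]
        for _ in range(2):  # align to running mean, twice
            aligned = _superposed_coords(coords, ref)
            ref = aligned.mean(axis=0)
        coords = aligned
    mean = coords.mean(axis=0)
    vals = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    return ObservableSeries("rmsf", vals, units="Å", selection=sel)


def b_factor(rmsf_values) -> np.ndarray:
    """Crystallographic B-factor B = (8 pi^2 / 3) RMSF^2 (Angstrom^2)."""
    r = np.asarray(rmsf_values, dtype=float)
    if np.any(r < 0):
        raise ValueError("RMSF values must be non-negative")
    return (8.0 * np.pi**2 / 3.0) * r**2


def radius_of_gyration(ens: StructureEnsemble, selection=None,
                       masses: np.ndarray | None = None) -> ObservableSeries:
    """Per-frame radius of gyration sqrt(sum w_i |r_i - r_com|^2 / sum w_i)."""
    sel = _resolve_selection(ens, selection)
    coords = ens.coordinates[:, sel, :]
    w = np.ones(len(sel)) if masses is None else np.asarray(masses, dtype=float)[sel]
    if w.sum() <= 0:
        raise ValueError("total weight must be positive")
    w = w / w.sum()
    com = np.einsum("fas,a->fs", coords, w)
    d2 = np.sum((coords - com[:, None, :]) ** 2, axis=2)
    vals = np.sqrt(np.einsum("fa,a->f", d2, w))
    return ObservableSeries("rg", vals, units="Å", selection=sel, dt=ens.dt)


def dccm(ens: StructureEnsemble, selection=None, superpose: bool = True) -> CorrelationMatrix:
    """Dynamical cross-correlation matrix of atomic displacements.

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>); frames are
    superposed first (unless disabled). Zero-fluctuation atoms yield NaN
    entries, flagged rather than silently dropped.
    """
    if ens.n_frames < 2:
        raise ValueError("DCCM needs at least 2 frames")
    sel = _resolve_selection(ens, selection)
    coords = ens.coordinates[:, sel, :]
    if superpose:
        ref = coords[0]
        aligned = _superposed_coords(coords, ref)
        coords = _superposed_coords(coords, aligned.mean(axis=0))
    dr = coords - coords.mean(axis=0)
    cov = np.einsum("fis,fjs->ij", dr, dr) / ens.n_frames
    var = np.diag(cov).copy()
    zero = var <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        C = cov / np.sqrt(np.outer(var, var))
    C[zero, :] = np.nan
    C[:, zero] = np.nan
    np.fill_diagonal(C, np.where(zero, np.nan, 1.0))
    C = np.where(np.isfinite(C), np.clip(C, -1.0, 1.0), C)
    return CorrelationMatrix(C, selection=sel)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden
    spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def sasa_shrake_rupley(coords: np.ndarray, radii, probe: float = 1.4,
                       n_points: int = 960) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area of one frame.

    Each atom's accessible sphere (radius = vdW + probe) is sampled with
    ``n_points`` quasi-uniform points; points inside any neighbor's
    accessible sphere are occluded. Returns (per-atom areas, total), in
    Angstrom^2.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0) or probe < 0:
        raise ValueError("radii must be positive and probe non-negative")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    n = coords.shape[0]
    R = radii + probe
    unit = _sphere_points(n_points)
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + R[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d = np.linalg.norm(coords[j] - coords[i])
            if d >= R[i] + R[j]:
                continue
            accessible &= np.sum((pts - coords[j]) ** 2, axis=1) > R[j] ** 2
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * R[i] ** 2 * accessible.mean()
    return areas, float(areas.sum())


def group_distance(ens: StructureEnsemble, selection_a, selection_b,
                   masses: np.ndarray | None = None) -> ObservableSeries:
    """Per-frame distance between the (mass-weighted) centers of two atom
    groups — e.g. the ZA-loop / BC-loop opening of a bromodomain pocket."""
    sa = _resolve_selection(ens, selection_a)
    sb = _resolve_selection(ens, selection_b)

    def center(sel):
        c = ens.coordinates[:, sel, :]
        w = np.ones(len(sel)) if masses is None else np.asarray(masses, dtype=float)[sel]
        w = w / w.sum()
        return np.einsum("fas,a->fs", c, w)

    vals = np.linalg.norm(center(sa) - center(sb), axis=1)
    return ObservableSeries("group_distance", vals, units="Å", dt=ens.dt)
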