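"""Structure input and backbone-dihedral featurization.

Multi-model PDB files are read into a :class:`StructureEnsemble`; backbone
phi/psi torsions quantify the residual skeleton of each frame as angular
features, optionally embedded as sine/cosine pairs to remove the
periodicity seam before linear methods (TICA, k-means).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .containers import DEFAULT_DT_NS, FeatureTrajectory
from .synthetic import wrap_angles

__all__ = [
    "StructureEnsemble",
    "read_multi_model_pdb",
    "write_multi_model_pdb",
    "compute_dihedral",
    "backbone_dihedral_features",
    "sincos_embed",
]


@dataclass
class StructureEnsemble:
    """Coordinates (frames x atoms x 3, in Angstrom) plus atom records.

    All models of the source file must share one atom table; frame spacing
    carries the time axis for downstream observables.
    """

    coordinates: np.ndarray
    atom_names: np.ndarray
    res_names: np.ndarray
    res_ids: np.ndarray
    chain_ids: np.ndarray
    dt: float = DEFAULT_DT_NS

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")
        n_atoms = self.coordinates.shape[1]
        for name in ("atom_names", "res_names", "res_ids", "chain_ids"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n_atoms:
                raise ValueError(f"{name} length {arr.shape[0]} != atom count {n_atoms}")
            setattr(self, name, arr)
        if self.dt <= 0:
            raise ValueError("frame spacing dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def select(self, atom_name: str | None = None, res_ids=None) -> np.ndarray:
        """Atom indices matching an atom name and/or residue id set."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if atom_name is not None:
            mask &= self.atom_names == atom_name
        if res_ids is not None:
            mask &= np.isin(self.res_ids, np.asarray(list(res_ids)))
        return np.where(mask)[0]


def read_multi_model_pdb(path, dt: float = DEFAULT_DT_NS) -> StructureEnsemble:
    """Parse a (possibly multi-model) PDB file into a StructureEnsemble.

    All MODELs must carry identical atom tables; inconsistent atom counts
    raise with the offending model index.
    """
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure()  # AtomArrayStack
    except Exception as exc:  # biotite raises on inconsistent models
        counts = _model_atom_counts(str(path))
        if len(set(counts)) > 1:
            ref = counts[0]
            bad = next(i + 1 for i, c in enumerate(counts) if c != ref)
            raise ValueError(
                f"MODEL {bad} has {counts[bad - 1]} atoms, expected {ref}: "
                "all models must share one atom table"
            ) from exc
        raise ValueError(f"could not parse PDB file {path}: {exc}") from exc
    if stack.array_length() == 0:
        raise ValueError(f"PDB file {path} contains no atoms")
    return StructureEnsemble(
        coordinates=np.asarray(stack.coord, dtype=float).reshape(-1, stack.array_length(), 3),
        atom_names=np.asarray(stack.atom_name),
        res_names=np.asarray(stack.res_name),
        res_ids=np.asarray(stack.res_id),
        chain_ids=np.asarray(stack.chain_id),
        dt=dt,
    )


def _model_atom_counts(path: str) -> list[int]:
    counts, current, in_model = [], 0, False
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model, current = True, 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                current += 1
    if not counts:  # single implicit model
        counts = [current] if current else []
    elif in_model:
        counts.append(current)
    return counts


def write_multi_model_pdb(path, ens: StructureEnsemble) -> None:
    """Write the ensemble as a multi-model PDB (fixed columns, 3 decimals)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = ens.n_atoms
    stack = struc.AtomArrayStack(ens.n_frames, n)
    stack.coord = np.asarray(ens.coordinates, dtype=np.float32)
    stack.atom_name = np.asarray(ens.atom_names, dtype="U6")
    stack.res_name = np.asarray(ens.res_names, dtype="U5")
    stack.res_id = np.asarray(ens.res_ids, dtype=int)
    stack.chain_id = np.asarray(ens.chain_ids, dtype="U4")
    stack.element = np.array([a[:1] for a in np.asarray(ens.atom_names, dtype=str)], dtype="U2")
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def compute_dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle of four points, in degrees on (-180, 180].

    Sign follows the IUPAC convention (clockwise positive looking from p2
    toward p3). Uses the atan2 construction, which is stable near 0 and 180
    degrees. Collinear p1-p2-p3 or p2-p3-p4 is a degenerate geometry error.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for a, b, which in ((b1, b2, "p1-p2-p3"), (b2, b3, "p2-p3-p4")):
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            raise ValueError("consecutive points coincide")
        if np.linalg.norm(np.cross(a, b)) < 1e-10 * na * nb:
            raise ValueError(f"collinear points {which}: torsion undefined")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    u2 = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), u2))
    return float(wrap_angles(np.degrees(np.arctan2(y, x))))


def _backbone_table(ens: StructureEnsemble):
    """Per-residue indices of N, CA, C atoms, in residue order."""
    residues = []
    seen = {}
    for i in range(ens.n_atoms):
        key = (str(ens.chain_ids[i]), int(ens.res_ids[i]))
        if key not in seen:
            seen[key] = {"res_id": int(ens.res_ids[i]), "chain": str(ens.chain_ids[i])}
            residues.append(seen[key])
        name = str(ens.atom_names[i])
        if name in ("N", "CA", "C"):
            seen[key][name] = i
    return residues


def backbone_dihedral_features(
    ens: StructureEnsemble,
    which: str = "phi_psi",
    res_ids=None,
) -> FeatureTrajectory:
    """Backbone phi/psi torsions per frame.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1).
    Interior residues only (each torsion needs a neighbor); an n-residue
    chain therefore yields n-1 phi and n-1 psi columns. ``res_ids``
    restricts the central residue of each torsion, letting users match a
    specific feature count.
    """
    if which not in ("phi", "psi", "phi_psi"):
        raise ValueError("which must be 'phi', 'psi' or 'phi_psi'")
    residues = _backbone_table(ens)
    for r in residues:
        for at in ("N", "CA", "C"):
            if at not in r:
                raise ValueError(
                    f"residue {r['res_id']} (chain {r['chain']}) lacks backbone atom {at}"
                )
    wanted = None if res_ids is None else set(int(r) for r in res_ids)
    quads, names = [], []
    for i, r in enumerate(residues):
        if wanted is not None and r["res_id"] not in wanted:
            continue
        if which in ("phi", "phi_psi") and i > 0 and residues[i - 1]["chain"] == r["chain"]:
            quads.append((residues[i - 1]["C"], r["N"], r["CA"], r["C"]))
            names.append(f"phi_{r['res_id']}")
        if which in ("psi", "phi_psi") and i + 1 < len(residues) and residues[i + 1]["chain"] == r["chain"]:
            quads.append((r["N"], r["CA"], r["C"], residues[i + 1]["N"]))
            names.append(f"psi_{r['res_id']}")
    values = np.empty((ens.n_frames, len(quads)))
    for f in range(ens.n_frames):
        xyz = ens.coordinates[f]
        for c, (a, b, cc, d) in enumerate(quads):
            values[f, c] = compute_dihedral(xyz[a], xyz[b], xyz[cc], xyz[d])
    return FeatureTrajectory(
        values, dt=ens.dt, names=names, periodic=np.ones(len(quads), dtype=bool)
    )


def sincos_embed(ft: FeatureTrajectory) -> FeatureTrajectory:
    """Replace each periodic (angular, degrees) feature by its sine and
    cosine; non-periodic features pass through unchanged."""
    if ft.periodic is None:
        raise ValueError("sincos_embed requires per-feature periodic flags")
    cols, names = [], []
    src_names = ft.names or [f"f{i+1}" for i in range(ft.n_features)]
    for j in range(ft.n_features):
        if ft.periodic[j]:
            rad = np.radians(ft.values[:, j])
            cols.extend([np.sin(rad), np.cos(rad)])
            names.extend([f"sin_{src_names[j]}", f"cos_{src_names[j]}"])
        else:
            cols.append(ft.values[:, j])
            names.append(src_names[j])
    values = np.column_stack(cols)
    return FeatureTrajectory(
        values, dt=ft.dt, names=names, periodic=np.zeros(values.shape[1], dtype=bool)
    )
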