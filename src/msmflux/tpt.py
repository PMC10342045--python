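"""Transition-path theory: committors, reactive flux, pathway decomposition.

Given a source set A (initial conformations) and a sink set B (final
conformations) of an MSM, the forward committor q+_i is the probability
that a trajectory started in state i reaches B before A; it solves

    q+_i = sum_{j in B} T_ij + sum_{j not in A u B} T_ij q+_j,

with q+ = 0 on A and 1 on B. Under detailed balance the backward committor
is q-_i = 1 - q+_i. The reactive (effective) flux between states is

    f_ij = pi_i q-_i T_ij q+_j,

the net flux f+_ij = max(f_ij - f_ji, 0), and the total A->B flux is
conserved: flux out of A equals flux into B. Pathway decomposition
repeatedly removes the maximum-bottleneck (widest) A->B path, so the total
flux splits into ranked pathways whose percentages P_i = f_i / sum_j f_j
are the path probabilities reported in flux tables.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "committors",
    "reactive_flux",
    "FluxNetwork",
    "coarse_grain_flux",
    "decompose_pathways",
    "PathwayDecomposition",
    "path_percentages",
    "flux_table",
    "format_flux_table",
    "parse_flux_table",
]


def committors(T: np.ndarray, A, B, backward: str = "reversible",
               pi: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Forward and backward committor probabilities.

    ``backward="reversible"`` (default) applies q- = 1 - q+, valid under
    detailed balance; ``backward="general"`` solves the backward-committor
    system of the time-reversed chain and requires ``pi``.
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    A = np.asarray(sorted(set(int(a) for a in A)))
    B = np.asarray(sorted(set(int(b) for b in B)))
    if A.size == 0 or B.size == 0:
        raise ValueError("A and B must be nonempty")
    if np.intersect1d(A, B).size:
        raise ValueError("A and B must be disjoint")
    if A.max() >= n or B.max() >= n:
        raise ValueError("A/B contain states outside the matrix")
    inter = np.setdiff1d(np.arange(n), np.union1d(A, B))
    q_plus = np.zeros(n)
    q_plus[B] = 1.0
    if inter.size:
        M = np.eye(inter.size) - T[np.ix_(inter, inter)]
        rhs = T[np.ix_(inter, B)].sum(axis=1)
        try:
            q_plus[inter] = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError as exc:
            # singular exactly when some intermediate reaches neither A nor B
            reach = _states_reaching(T, np.concatenate([A, B]))
            trapped = [int(s) for s in inter if s not in reach]
            raise np.linalg.LinAlgError(
                f"committor system singular; trapped states "
                f"(cannot reach A or B): {trapped}"
            ) from exc
    q_plus = np.clip(q_plus, 0.0, 1.0)
    if backward == "reversible":
        q_minus = 1.0 - q_plus
    elif backward == "general":
        if pi is None:
            raise ValueError("general backward committor requires pi")
        pi = np.asarray(pi, dtype=float)
        Trev = (T.T * pi[None, :]) / pi[:, None]
        q_minus = np.zeros(n)
        q_minus[A] = 1.0
        if inter.size:
            M = np.eye(inter.size) - Trev[np.ix_(inter, inter)]
            rhs = Trev[np.ix_(inter, A)].sum(axis=1)
            q_minus[inter] = np.linalg.solve(M, rhs)
        q_minus = np.clip(q_minus, 0.0, 1.0)
    else:
        raise ValueError("backward must be 'reversible' or 'general'")
    return q_plus, q_minus


def _states_reaching(T: np.ndarray, B) -> set:
    """States from which B is reachable along positive-probability edges."""
    n = T.shape[0]
    rev_adj = [np.where(T[:, j] > 0)[0] for j in range(n)]
    seen = set(int(b) for b in B)
    stack = list(seen)
    while stack:
        j = stack.pop()
        for i in rev_adj[j]:
            if int(i) not in seen:
                seen.add(int(i))
                stack.append(int(i))
    return seen


@dataclass
class FluxNetwork:
    """Reactive flux between states: committors, gross and net flux."""

    A: set
    B: set
    q_plus: np.ndarray
    q_minus: np.ndarray
    gross_flux: np.ndarray
    net_flux: np.ndarray
    total_flux: float
    dt: float | None = None
    state_names: list[str] | None = None

    @property
    def n_states(self) -> int:
        return self.gross_flux.shape[0]

    def pathways(self, max_paths: int | None = None,
                 residual_fraction_stop: float = 1e-3) -> "PathwayDecomposition":
        return decompose_pathways(self, max_paths=max_paths,
                                  residual_fraction_stop=residual_fraction_stop)

    def edge_list(self) -> pd.DataFrame:
        """Net-flux edges (from, to, net_flux) for graph tooling."""
        i, j = np.nonzero(self.net_flux)
        names = self.state_names or [str(s) for s in range(self.n_states)]
        return pd.DataFrame({
            "from": [names[a] for a in i],
            "to": [names[b] for b in j],
            "net_flux": self.net_flux[i, j],
        })

    def summary(self) -> str:
        names = self.state_names or [str(s) for s in range(self.n_states)]
        lines = [
            "Reactive Flux Network",
            f"  A = {{{', '.join(names[a] for a in sorted(self.A))}}}"
            f"   B = {{{', '.join(names[b] for b in sorted(self.B))}}}",
            f"  total A->B flux: {self.total_flux:.6g} per lag step",
            "  state  q+       q-",
        ]
        for s in range(self.n_states):
            lines.append(f"  {names[s]:<6s} {self.q_plus[s]:.5f}  {self.q_minus[s]:.5f}")
        return "\n".join(lines)


def reactive_flux(T: np.ndarray, pi: np.ndarray, A, B,
                  committor_pair=None, dt: float | None = None,
                  state_names=None) -> FluxNetwork:
    """Gross and net reactive flux networks for the A -> B transition.

    f_ij = pi_i q-_i T_ij q+_j (zero diagonal); f+_ij = max(f_ij - f_ji, 0).
    ``pi`` must be stationary for T (checked to 1e-6).
    """
    T = np.asarray(T, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if np.max(np.abs(pi @ T - pi)) > 1e-6:
        raise ValueError("pi is not stationary for T (residual > 1e-6)")
    if committor_pair is None:
        q_plus, q_minus = committors(T, A, B)
    else:
        q_plus, q_minus = committor_pair
    F = pi[:, None] * q_minus[:, None] * T * q_plus[None, :]
    np.fill_diagonal(F, 0.0)
    net = np.maximum(F - F.T, 0.0)
    A = set(int(a) for a in A)
    B = set(int(b) for b in B)
    a_idx = sorted(A)
    total = float(sum(net[i, j] for i in a_idx for j in range(T.shape[0]) if j not in A))
    into_b = float(sum(net[i, j] for j in sorted(B) for i in range(T.shape[0]) if i not in B))
    if abs(total - into_b) > 1e-10 * max(total, 1e-30) + 1e-14:
        warnings.warn(
            f"flux conservation residual {abs(total - into_b):.3e}; "
            "network may contain cycles through A/B"
        )
    return FluxNetwork(A=A, B=B, q_plus=q_plus, q_minus=q_minus,
                       gross_flux=F, net_flux=net, total_flux=total,
                       dt=dt, state_names=state_names)


def coarse_grain_flux(net: FluxNetwork, groups) -> FluxNetwork:
    """Aggregate a flux network onto groups of states (e.g. macrostates).

    ``groups`` is a microstate -> group label array (crisp), or a
    MacrostatePartition. A and B must be unions of groups. Macro net flux
    sums microstate net flux across group boundaries and re-antisymmetrizes
    (max(F_IJ - F_JI, 0)); conservation is re-checked.
    """
    if hasattr(groups, "crisp_labels"):
        groups = groups.crisp_labels
    groups = np.asarray(groups, dtype=int)
    if groups.shape[0] != net.n_states:
        raise ValueError("partition does not cover the flux network's states")
    m = int(groups.max()) + 1
    A_macro = {int(groups[a]) for a in net.A}
    B_macro = {int(groups[b]) for b in net.B}
    for macro, micro_set, name in ((A_macro, net.A, "A"), (B_macro, net.B, "B")):
        members = set(np.where(np.isin(groups, list(macro)))[0].tolist())
        if members != set(micro_set):
            raise ValueError(f"{name} is not a union of groups")
    if A_macro & B_macro:
        raise ValueError("A and B map to overlapping groups")
    G = np.zeros((m, m))
    np.add.at(G, (groups[:, None].repeat(net.n_states, 1),
                  groups[None, :].repeat(net.n_states, 0)), net.net_flux)
    np.fill_diagonal(G, 0.0)
    macro_net = np.maximum(G - G.T, 0.0)
    # pi-weighted committors for reporting
    w = np.zeros(m)
    qp = np.zeros(m)
    qm = np.zeros(m)
    pi_like = net.q_plus * 0 + 1.0  # uniform weights when pi unavailable
    for s in range(net.n_states):
        w[groups[s]] += pi_like[s]
        qp[groups[s]] += net.q_plus[s]
        qm[groups[s]] += net.q_minus[s]
    qp, qm = qp / w, qm / w
    total = float(sum(macro_net[i, j] for i in A_macro for j in range(m) if j not in A_macro))
    into_b = float(sum(macro_net[i, j] for j in B_macro for i in range(m) if i not in B_macro))
    if abs(total - into_b) > 1e-10 * max(total, 1e-30) + 1e-14:
        warnings.warn(f"coarse flux conservation residual {abs(total - into_b):.3e}")
    return FluxNetwork(A=A_macro, B=B_macro, q_plus=qp, q_minus=qm,
                       gross_flux=G, net_flux=macro_net, total_flux=total,
                       dt=net.dt)


def _widest_path(F: np.ndarray, A: set, B: set) -> tuple[list[int], float] | None:
    """Maximum-bottleneck A->B path on the net-flux graph.

    Modified Dijkstra maximizing the minimum edge flux; ties in width break
    to the lexicographically smallest path. Returns (path, width) or None.
    """
    n = F.shape[0]
    # heap entries: (-width, path_tuple); path comparison = lexicographic
    heap = [(-np.inf, (a,)) for a in sorted(A)]
    heapq.heapify(heap)
    best_width = {a: np.inf for a in A}
    best_path: dict[int, tuple] = {a: (a,) for a in A}
    settled: set[int] = set()
    while heap:
        negw, path = heapq.heappop(heap)
        width = -negw
        u = path[-1]
        if u in settled:
            continue
        settled.add(u)
        best_path[u] = path
        if u in B:
            return list(path), float(width)
        for v in np.where(F[u] > 0)[0]:
            v = int(v)
            if v in settled or v in A:
                continue
            w = min(width, F[u, v])
            if w > best_width.get(v, -np.inf) or (
                w == best_width.get(v, -np.inf)
                and path + (v,) < best_path.get(v, (np.inf,))
            ):
                best_width[v] = w
                best_path[v] = path + (v,)
                heapq.heappush(heap, (-w, path + (v,)))
    return None


@dataclass
class PathwayDecomposition:
    """Ranked A->B pathways with fluxes and percentages of the total."""

    paths: list[list[int]]
    fluxes: np.ndarray
    total_flux: float
    residual_flux: float
    state_names: list[str] | None = None
    dt: float | None = None

    def __post_init__(self) -> None:
        self.fluxes = np.asarray(self.fluxes, dtype=float)
        if np.any(self.fluxes <= 0):
            raise ValueError("path fluxes must be positive")
        if self.fluxes.size and np.any(np.diff(self.fluxes) > 1e-9 * self.fluxes.max()):
            raise ValueError("path fluxes must be non-increasing")

    @property
    def percentages(self) -> np.ndarray:
        return path_percentages(self.fluxes)

    @property
    def decomposed_flux(self) -> float:
        return float(self.fluxes.sum())


def decompose_pathways(net: FluxNetwork, max_paths: int | None = None,
                       residual_fraction_stop: float = 1e-3) -> PathwayDecomposition:
    """Iterative widest-path (maximum-bottleneck) pathway decomposition.

    Repeatedly extract the A->B path maximizing the minimum edge net flux,
    subtract its bottleneck flux along the path, and continue until the
    residual falls below ``residual_fraction_stop`` of the total, no path
    remains, or ``max_paths`` is reached.
    """
    F = net.net_flux.copy()
    total = net.total_flux
    paths: list[list[int]] = []
    fluxes: list[float] = []
    if total <= 0:
        warnings.warn("no reactive A->B flux; empty decomposition")
        return PathwayDecomposition([], np.empty(0), total, 0.0,
                                    state_names=net.state_names, dt=net.dt)
    removed = 0.0
    while True:
        if max_paths is not None and len(paths) >= max_paths:
            break
        if residual_fraction_stop > 0 and (total - removed) < residual_fraction_stop * total:
            break
        hit = _widest_path(F, net.A, net.B)
        if hit is None:
            break
        path, width = hit
        if width <= 0:
            break
        for u, v in zip(path[:-1], path[1:]):
            F[u, v] -= width
            if F[u, v] < 1e-15 * total:
                F[u, v] = 0.0
        paths.append(path)
        fluxes.append(width)
        removed += width
    return PathwayDecomposition(paths, np.asarray(fluxes), total,
                                residual_flux=total - removed,
                                state_names=net.state_names, dt=net.dt)


def path_percentages(fluxes, denominator: float | None = None) -> np.ndarray:
    """Path probabilities P_i = 100 * f_i / sum_j f_j (percent, unrounded).

    ``denominator`` overrides the sum, e.g. to reproduce published tables
    whose printed totals are rounded.
    """
    fluxes = np.asarray(fluxes, dtype=float)
    if fluxes.size == 0 or np.all(fluxes <= 0):
        raise ValueError("at least one positive path flux required")
    denom = float(denominator) if denominator is not None else float(fluxes.sum())
    return 100.0 * fluxes / denom


def _sci3(x: float) -> str:
    """3-significant-figure scientific notation, table style (4.00e-03)."""
    return f"{x:.2e}"


def flux_table(decomp: PathwayDecomposition, state_names=None,
               dt: float | None = None, per_second: bool = False) -> pd.DataFrame:
    """Pathway table in the three-column layout of published flux tables.

    Columns: Pathways (SA->S3->SB arrows), Path Flux (per lag step, or per
    second when ``per_second`` with frame spacing ``dt`` in ns), Percentage
    of Total Coarse Flux (%). A Total row closes the table.
    """
    names = state_names or decomp.state_names
    if names is None:
        names = [str(i) for i in range(max((max(p) for p in decomp.paths), default=0) + 1)]
    scale = 1.0
    unit = "per lag step"
    if per_second:
        dt_ns = dt or decomp.dt
        if dt_ns is None:
            raise ValueError("per-second conversion requires the frame spacing dt")
        scale = 1.0 / (dt_ns * 1e-9)
        unit = "s^-1"
    rows = []
    if len(decomp.paths):
        pct = decomp.percentages
        for p, f, c in zip(decomp.paths, decomp.fluxes, pct):
            rows.append({
                "Pathways": "→".join(names[s] for s in p),
                f"Path Flux ({unit})": f * scale,
                "Percentage of Total Coarse Flux (%)": round(float(c), 2),
            })
        total = decomp.decomposed_flux * scale
    else:
        total = 0.0
    rows.append({
        "Pathways": "Total",
        f"Path Flux ({unit})": total,
        "Percentage of Total Coarse Flux (%)": 100.0 if len(decomp.paths) else 0.0,
    })
    return pd.DataFrame(rows)


def format_flux_table(table: pd.DataFrame) -> str:
    """Render the flux table as aligned text with 3-sig-fig fluxes."""
    flux_col = [c for c in table.columns if c.startswith("Path Flux")][0]
    lines = ["\t".join(table.columns)]
    for _, row in table.iterrows():
        lines.append(
            f"{row['Pathways']}\t{_sci3(row[flux_col])}\t"
            f"{row['Percentage of Total Coarse Flux (%)']:.2f}"
        )
    return "\n".join(lines)


def parse_flux_table(text: str) -> pd.DataFrame:
    """Parse a table produced by :func:`format_flux_table`."""
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    header = lines[0].split("\t")
    rows = []
    for ln in lines[1:]:
        path, flux, pct = ln.split("\t")
        rows.append({header[0]: path, header[1]: float(flux), header[2]: float(pct)})
    return pd.DataFrame(rows)
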