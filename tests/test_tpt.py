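"""Committors, reactive flux, pathway decomposition, flux tables."""

import numpy as np
import pytest

import msmflux as mf
from msmflux.tpt import (
    FluxNetwork,
    decompose_pathways,
    format_flux_table,
    parse_flux_table,
)

from .conftest import THREE_STATE_T


class TestCommittors:
    def test_boundary_conditions(self):
        chain = mf.make_metastable_chain(3, 2, p_inter=0.02, seed=0)
        qp, qm = mf.committors(chain.transition_matrix, A=[0, 1], B=[4, 5])
        assert np.allclose(qp[[0, 1]], 0.0) and np.allclose(qp[[4, 5]], 1.0)
        assert np.allclose(qm, 1.0 - qp)

    def test_symmetric_three_state_chain(self):
        qp, _ = mf.committors(THREE_STATE_T, A=[0], B=[2])
        assert np.allclose(qp, [0.0, 0.5, 1.0], atol=1e-12)

    def test_matches_fixed_point_iteration(self):
        # oracle: iterate the defining recursion to convergence
        rng = np.random.default_rng(1)
        for _ in range(5):
            n = int(rng.integers(3, 7))
            C = rng.integers(1, 30, size=(n, n)).astype(float)
            T, _ = mf.estimate_transition_matrix(C, reversible=True)
            A, B = [0], [n - 1]
            qp, _ = mf.committors(T, A, B)
            q = np.zeros(n)
            q[B] = 1.0
            inter = [s for s in range(n) if s not in A + B]
            for _ in range(100_000):
                new = q.copy()
                for i in inter:
                    new[i] = T[i, B].sum() + sum(T[i, j] * q[j] for j in inter)
                if np.max(np.abs(new - q)) < 1e-14:
                    q = new
                    break
                q = new
            assert np.allclose(qp, q, atol=1e-10)

    def test_trapped_states_reported(self):
        # state 2 is absorbing and reaches neither endpoint: singular system
        T = np.array([
            [0.5, 0.5, 0.0, 0.0],
            [0.4, 0.5, 0.0, 0.1],
            [0.0, 0.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ])
        with pytest.raises(np.linalg.LinAlgError, match=r"\[2\]"):
            mf.committors(T, A=[0], B=[3])

    def test_monotone_along_one_dimensional_chain(self):
        # birth-death chain: q+ must be non-decreasing from A to B
        n = 7
        T = np.zeros((n, n))
        for i in range(n):
            if i > 0:
                T[i, i - 1] = 0.3
            if i < n - 1:
                T[i, i + 1] = 0.2
            T[i, i] = 1.0 - T[i].sum()
        qp, _ = mf.committors(T, A=[0], B=[n - 1])
        assert np.all(np.diff(qp) >= -1e-12)


class TestReactiveFlux:
    def test_three_state_hand_evaluation(self):
        net = mf.reactive_flux(THREE_STATE_T, np.ones(3) / 3, A=[0], B=[2])
        assert net.gross_flux[0, 1] == pytest.approx(1 / 60, abs=1e-15)
        assert net.total_flux == pytest.approx(1 / 60, abs=1e-12)

    def test_disconnected_endpoints_have_zero_flux(self):
        T = np.array([[0.9, 0.1, 0.0, 0.0], [0.1, 0.9, 0.0, 0.0],
                      [0.0, 0.0, 0.9, 0.1], [0.0, 0.0, 0.1, 0.9]])
        pi = np.ones(4) / 4
        net = mf.reactive_flux(T, pi, A=[0], B=[3])
        assert net.total_flux == 0.0

    def test_flux_conservation(self):
        chain = mf.make_metastable_chain(4, 3, p_inter=0.02, seed=2)
        net = mf.reactive_flux(chain.transition_matrix, chain.stationary,
                               A=[0, 1, 2], B=[9, 10, 11])
        out_of_A = sum(net.net_flux[i, j] for i in net.A
                       for j in range(net.n_states) if j not in net.A)
        into_B = sum(net.net_flux[i, j] for j in net.B
                     for i in range(net.n_states) if i not in net.B)
        assert out_of_A == pytest.approx(into_B, abs=1e-12)
        assert net.total_flux == pytest.approx(out_of_A, abs=1e-15)

    def test_net_flux_antisymmetric_support(self):
        chain = mf.make_metastable_chain(3, 2, p_inter=0.05, seed=3)
        net = mf.reactive_flux(chain.transition_matrix, chain.stationary, A=[0], B=[5])
        assert np.all(net.net_flux * net.net_flux.T == 0)
        assert np.all(net.net_flux >= 0)

    def test_non_stationary_pi_rejected(self):
        with pytest.raises(ValueError, match="stationary"):
            mf.reactive_flux(THREE_STATE_T, np.array([0.6, 0.3, 0.1]), A=[0], B=[2])


class TestCoarseGrainFlux:
    def test_identity_partition_unchanged(self):
        chain = mf.make_metastable_chain(2, 2, p_inter=0.02, seed=4)
        net = mf.reactive_flux(chain.transition_matrix, chain.stationary, A=[0], B=[3])
        out = mf.coarse_grain_flux(net, np.arange(4))
        assert np.allclose(out.net_flux, net.net_flux)
        assert out.total_flux == pytest.approx(net.total_flux, abs=1e-15)

    def test_merging_intermediates_preserves_total(self):
        chain = mf.make_metastable_chain(4, 2, p_inter=0.02, seed=5)
        net = mf.reactive_flux(chain.transition_matrix, chain.stationary,
                               A=[0, 1], B=[6, 7])
        groups = np.array([0, 0, 1, 1, 1, 1, 2, 2])
        out = mf.coarse_grain_flux(net, groups)
        assert out.total_flux == pytest.approx(net.total_flux, rel=1e-10)

    def test_macro_flux_equals_direct_pair_summation(self):
        chain = mf.make_metastable_chain(5, 3, p_inter=0.01, seed=6)
        part = mf.pcca_plus(chain.transition_matrix, m=5)
        labels = part.crisp_labels
        A = np.where(labels == labels[0])[0]
        B_block = labels[np.argmax(labels != labels[0])] if labels[-1] == labels[0] else labels[-1]
        B = np.where(labels == B_block)[0]
        net = mf.reactive_flux(chain.transition_matrix, chain.stationary, A=A, B=B)
        out = mf.coarse_grain_flux(net, labels)
        m = int(labels.max()) + 1
        brute = np.zeros((m, m))
        for i in range(chain.n_states):
            for j in range(chain.n_states):
                brute[labels[i], labels[j]] += net.net_flux[i, j]
        np.fill_diagonal(brute, 0.0)
        brute = np.maximum(brute - brute.T, 0.0)
        assert np.allclose(out.net_flux, brute, atol=1e-15)

    def test_partition_must_cover_endpoints(self):
        chain = mf.make_metastable_chain(2, 2, p_inter=0.02, seed=7)
        net = mf.reactive_flux(chain.transition_matrix, chain.stationary, A=[0], B=[3])
        with pytest.raises(ValueError, match="union"):
            mf.coarse_grain_flux(net, np.array([0, 0, 1, 1]))  # A={0} not a union


def toy_network(edges, n, A, B):
    F = np.zeros((n, n))
    for (i, j), f in edges.items():
        F[i, j] = f
    total = sum(F[i, j] for i in A for j in range(n) if j not in A)
    return FluxNetwork(A=set(A), B=set(B), q_plus=np.zeros(n), q_minus=np.zeros(n),
                       gross_flux=F, net_flux=F, total_flux=total)


class TestDecomposePathways:
    def test_linear_chain_single_path(self):
        net = toy_network({(0, 1): 0.5, (1, 2): 0.5}, 3, [0], [2])
        d = decompose_pathways(net)
        assert d.paths == [[0, 1, 2]]
        assert d.fluxes[0] == pytest.approx(0.5)
        assert d.percentages[0] == pytest.approx(100.0)

    def test_four_node_enumeration_oracle(self):
        net = toy_network({(0, 1): 3, (0, 2): 1, (1, 3): 2, (1, 2): 1, (2, 3): 1},
                          4, [0], [3])
        d = decompose_pathways(net, residual_fraction_stop=0)
        assert d.paths == [[0, 1, 3], [0, 1, 2, 3]]
        assert np.allclose(d.fluxes, [2.0, 1.0])
        assert np.allclose(d.percentages, [200 / 3, 100 / 3])
        assert d.decomposed_flux == pytest.approx(3.0)

    def test_complete_decomposition_recovers_total(self):
        chain = mf.make_metastable_chain(3, 2, p_inter=0.03, seed=8)
        part = mf.pcca_plus(chain.transition_matrix, m=3)
        labels = part.crisp_labels
        A = np.where(labels == labels[0])[0]
        B = np.where(labels == labels[-1])[0]
        net = mf.reactive_flux(chain.transition_matrix, chain.stationary, A=A, B=B)
        macro = mf.coarse_grain_flux(net, labels)
        d = macro.pathways(residual_fraction_stop=0)
        assert d.decomposed_flux == pytest.approx(macro.total_flux, abs=1e-10)
        assert np.all(np.diff(d.fluxes) <= 1e-12)

    def test_no_path_gives_empty_decomposition(self):
        net = toy_network({}, 3, [0], [2])
        with pytest.warns(UserWarning, match="no reactive"):
            d = decompose_pathways(net)
        assert d.paths == []


class TestPathPercentages:
    def test_printed_table_reproduction_ms436(self):
        fluxes = [4.00e-3, 2.00e-3, 6.00e-4, 1.00e-4, 3.00e-5, 3.00e-5]
        pct = mf.path_percentages(fluxes, denominator=sum(fluxes))
        assert np.allclose(np.round(pct, 2), [59.17, 29.59, 8.88, 1.48, 0.44, 0.44])

    def test_single_flux_is_100(self):
        assert mf.path_percentages([0.123])[0] == pytest.approx(100.0)

    def test_double_binding_table_leading_percentage(self):
        fluxes = [6.00e-3, 3.00e-4, 9.00e-5, 1.00e-5, 1.00e-5, 1.00e-5]
        pct = mf.path_percentages(fluxes, denominator=6.42e-3)
        assert round(pct[0], 2) == 93.46

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            mf.path_percentages([0.0, 0.0])


class TestFluxTable:
    def test_six_path_table_totals(self):
        fluxes = np.array([4.00e-3, 2.00e-3, 6.00e-4, 1.00e-4, 3.00e-5, 3.00e-5])
        paths = [[0, 4], [0, 3, 4], [0, 3, 2, 4], [0, 2, 4], [0, 3, 2, 1, 4], [0, 2, 1, 4]]
        d = mf.PathwayDecomposition(paths, fluxes, total_flux=fluxes.sum(),
                                    residual_flux=0.0)
        table = mf.flux_table(d, state_names=["SA", "S1", "S2", "S3", "SB"])
        total_row = table.iloc[-1]
        assert total_row["Pathways"] == "Total"
        assert f"{total_row['Path Flux (per lag step)']:.2e}" == "6.76e-03"
        assert table["Percentage of Total Coarse Flux (%)"][:-1].sum() == pytest.approx(100.0, abs=0.1)

    def test_empty_decomposition_renders_zero_total(self):
        d = mf.PathwayDecomposition([], np.empty(0), total_flux=0.0, residual_flux=0.0)
        table = mf.flux_table(d)
        assert len(table) == 1
        assert table.iloc[0]["Pathways"] == "Total"
        assert table.iloc[0]["Path Flux (per lag step)"] == 0.0

    def test_round_trip_three_significant_figures(self):
        fluxes = np.array([4.00e-4, 1.00e-5, 1.00e-5])
        paths = [[0, 2, 4], [0, 1, 2, 4], [0, 3, 1, 2, 4]]
        d = mf.PathwayDecomposition(paths, fluxes, total_flux=4.2e-4, residual_flux=0.0)
        text = format_flux_table(mf.flux_table(d, state_names=["SA", "S1", "S2", "S3", "SB"]))
        back = parse_flux_table(text)
        got = back.iloc[:-1, 1].to_numpy()
        assert np.allclose(got, fluxes, rtol=5e-3)


class TestDoubleWellEndToEnd:
    def test_committor_half_at_barrier_top(self):
        # symmetric double well: by symmetry the barrier-top state commits
        # half-half; discretize x, estimate an MSM, solve the committor
        from msmflux.synthetic import PotentialSpec

        spec = PotentialSpec(form="double_well", kT=0.8, timestep=0.01)
        traj = mf.simulate_langevin(spec, 300_000, seed=9)
        x = traj.values[:, 0]
        edges = np.linspace(-1.8, 1.8, 13)
        dtraj = np.clip(np.digitize(x, edges), 0, len(edges))
        msm = mf.MarkovStateModel([dtraj], lag=20).fit()
        n = msm.n_states
        # map bins to active set; A = leftmost bins, B = rightmost bins
        centers_bins = msm.active_set
        A = [int(np.argmin(centers_bins))]
        B = [int(np.argmax(centers_bins))]
        qp, _ = mf.committors(msm.transition_matrix, A, B)
        # the bin containing x = 0 is the barrier top
        barrier_bin = np.digitize(0.0, edges)
        idx = int(np.where(centers_bins == barrier_bin)[0][0])
        assert abs(qp[idx] - 0.5) < 0.05
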