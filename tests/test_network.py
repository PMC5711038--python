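"""Reaction-network assembly, mass-action right-hand side and Jacobian."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import srexchange as sx
from srexchange.equilibrium import equilibrium_state
from srexchange.network import build_network
from srexchange.simulate import simulate


class TestTopology:
    def test_base_two_receptor_cycle_has_seven_reversible_reactions(
        self, params, totals_100_560
    ):
        net = build_network(params, totals_100_560)
        assert len(net.reactions) == 7
        assert len(net.degradations) == 0
        # canonical state ordering of the reduced five-dimensional system
        assert net.state_names == [
            "Cul1.SR1", "Cul1.SR2", "Cul1.Cand1",
            "Cul1.Cand1.SR1", "Cul1.Cand1.SR2",
        ]

    def test_sequential_substrate_adds_one_binding_and_one_degradation(
        self, params, totals_30_630, fast_substrate
    ):
        net = build_network(params, totals_30_630, [fast_substrate])
        assert len(net.reactions) == 8
        assert len(net.degradations) == 1
        assert net.degradations[0].source == "Cul1.SR1.S1"
        assert net.degradations[0].product == "Cul1.SR1"

    def test_random_order_adds_dimer_and_ternary_routes(
        self, params, totals_30_630
    ):
        sub = sx.SubstrateParameters(binding_mode="random_order")
        net = build_network(params, totals_30_630, [sub])
        for species in ("SR1.S1", "Cul1.Cand1.SR1.S1"):
            assert net.has_species(species)
        assert len(net.reactions) == 7 + 5

    def test_gamma_rescales_binary_dissociation_only(
        self, params, totals_100_560
    ):
        net1 = build_network(params, totals_100_560)
        net10 = build_network(params.with_gamma(10.0), totals_100_560)
        by_product = lambda net: {r.c: r for r in net.reactions}
        r1, r10 = by_product(net1), by_product(net10)
        assert r10["Cul1.SR1"].Kd == pytest.approx(10 * r1["Cul1.SR1"].Kd)
        assert r10["Cul1.Cand1"].Kd == pytest.approx(10 * r1["Cul1.Cand1"].Kd)
        assert r10["Cul1.Cand1.SR1"].Kd == pytest.approx(
            r1["Cul1.Cand1.SR1"].Kd)
        # association rates k/K are untouched by gamma
        assert r10["Cul1.SR1"].kon == pytest.approx(r1["Cul1.SR1"].kon)

    def test_substrate_on_missing_receptor_rejected(self, params):
        totals = sx.PoolTotals(300.0, 100.0, (30.0,), (300.0,))
        with pytest.raises(ValueError, match="receptor"):
            build_network(params, totals,
                          [sx.SubstrateParameters(receptor=5)])

    def test_mismatched_receptor_gamma_rejected(self, params, totals_100_560):
        with pytest.raises(ValueError, match="gamma"):
            build_network(params, totals_100_560,
                          receptor_params=[params.with_gamma(2.0), params])


class TestRhs:
    def test_equilibrium_is_a_fixed_point(self, balanced_params,
                                          totals_100_560):
        net = build_network(balanced_params, totals_100_560)
        y = equilibrium_state(net)
        assert np.max(np.abs(net.rhs(0.0, y))) < 1e-9

    def test_empty_state_gives_pure_association_flux(self, params,
                                                     totals_100_560):
        net = build_network(params, totals_100_560)
        dydt = net.rhs(0.0, np.zeros(net.n_states))
        expected = (params.ksr / params.Ksr
                    * totals_100_560.cul1_total
                    * totals_100_560.sr_totals[0])
        assert dydt[net.state_index("Cul1.SR1")] == pytest.approx(expected)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_rhs_reproduces_canonical_five_ode_form(self, seed):
        """For the base two-receptor cycle the assembled mass-action rhs
        matches the hand-written five-ODE system term for term, with the
        free species eliminated through the conservation relations."""
        params = sx.cellular_parameters()
        totals = sx.PoolTotals(300.0, 390.0, (100.0, 560.0))
        net = build_network(params, totals)
        y = np.random.default_rng(seed).uniform(0.0, 50.0, 5)
        y1, y2, y3, y4, y5 = y
        cul1 = totals.cul1_total - y.sum()
        sr1 = totals.sr_totals[0] - (y1 + y4)
        sr2 = totals.sr_totals[1] - (y2 + y5)
        cand1 = totals.cand1_total - (y3 + y4 + y5)
        ksr, Ksr = params.ksr, params.Ksr
        ksr_p, Ksr_p = params.ksr_prime, params.Ksr_prime
        eta, alpha, beta = params.eta, params.alpha, params.beta
        expected = np.array([
            ksr * (cul1 * sr1 / Ksr - y1)
            - beta * ksr_p * (y1 * cand1 / (eta * Ksr_p) - y4),
            ksr * (cul1 * sr2 / Ksr - y2)
            - beta * ksr_p * (y2 * cand1 / (eta * Ksr_p) - y5),
            alpha * ksr * (cul1 * cand1 / (eta * Ksr) - y3)
            - ksr_p * (y3 * (sr1 + sr2) / Ksr_p - (y4 + y5)),
            beta * ksr_p * (y1 * cand1 / (eta * Ksr_p) - y4)
            + ksr_p * (y3 * sr1 / Ksr_p - y4),
            beta * ksr_p * (y2 * cand1 / (eta * Ksr_p) - y5)
            + ksr_p * (y3 * sr2 / Ksr_p - y5),
        ])
        np.testing.assert_allclose(net.rhs(0.0, y), expected,
                                   rtol=1e-9, atol=1e-9)

    def test_substrate_conserved_without_degradation(self, params,
                                                     totals_30_630):
        sub = sx.SubstrateParameters(kdeg=0.0)
        net = build_network(params, totals_30_630, [sub])
        y = np.random.default_rng(0).uniform(0.0, 10.0, net.n_states)
        assert abs(net.sub_matrix @ net.rhs(0.0, y)) < 1e-12

    def test_jacobian_matches_finite_differences(self, params,
                                                 totals_30_630,
                                                 fast_substrate):
        net = build_network(params, totals_30_630, [fast_substrate])
        y = np.random.default_rng(1).uniform(0.0, 15.0, net.n_states)
        J = net.jacobian(0.0, y)
        eps = 1e-6
        for j in range(net.n_states):
            dy = np.zeros(net.n_states)
            dy[j] = eps
            col = (net.rhs(0.0, y + dy) - net.rhs(0.0, y - dy)) / (2 * eps)
            assert np.allclose(J[:, j], col, rtol=1e-5, atol=1e-8)


class TestSymmetry:
    def test_receptor_relabeling_swaps_trajectories_exactly(self, params):
        t_eval = np.linspace(0.0, 2e4, 40)
        tcs = []
        for sr in [(100.0, 560.0), (560.0, 100.0)]:
            net = build_network(params, sx.PoolTotals(300.0, 390.0, sr))
            tcs.append(simulate(net, t_end=2e4, t_eval=t_eval))
        a, b = tcs
        assert np.array_equal(a.t, b.t)
        np.testing.assert_allclose(
            a.concentration("Cul1.SR1"), b.concentration("Cul1.SR2"),
            rtol=1e-6, atol=1e-10)
        np.testing.assert_allclose(
            a.concentration("Cul1.Cand1.SR1"),
            b.concentration("Cul1.Cand1.SR2"), rtol=1e-6, atol=1e-10)


class TestConservationAlongTrajectories:
    def test_free_species_never_meaningfully_negative(self, params,
                                                      totals_30_630,
                                                      fast_substrate):
        net = build_network(params, totals_30_630, [fast_substrate])
        tc = simulate(net, t_end=5e4, t_eval=np.linspace(0, 5e4, 30))
        for k in range(len(net.eliminated)):
            free = net.eliminated_totals[k] - net.comp_matrix[k] @ tc.y
            assert np.all(free >= -1e-9)

    def test_substrate_total_constant_along_trajectory_without_degradation(
        self, params, totals_30_630
    ):
        sub = sx.SubstrateParameters(kdeg=0.0)
        net = build_network(params, totals_30_630, [sub])
        tc = simulate(net, t_end=5e4, t_eval=np.linspace(0, 5e4, 30))
        st_t = tc.total_substrate(0)
        np.testing.assert_allclose(st_t, st_t[0], rtol=1e-6)

    def test_formation_constants_are_route_independent(self, params,
                                                       totals_100_560):
        net = build_network(params, totals_100_560)
        G = net.formation_constants()
        # ternary complex reachable through both cycle branches
        via_binary = (1.0 / net.reactions[0].Kd) / params.Kca_prime
        assert G["Cul1.Cand1.SR1"] == pytest.approx(via_binary, rel=1e-9)
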