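"""Steady states, occupancy approximations and exchange-rate analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import srexchange as sx
from srexchange.equilibrium import (
    analyze_steady_state,
    equilibrium_state,
    exchange_rate_low_cand1,
    relax_to_equilibrium,
    with_eta,
)
from srexchange.network import build_network


@pytest.fixture(scope="module")
def cellular_ss(params, totals_100_560):
    return sx.solve_equilibrium(params, totals_100_560, cross_check=True)


class TestSolveEquilibrium:
    def test_cellular_occupancy_near_6_4_nM(self, cellular_ss):
        assert cellular_ss.occupancy("Cul1.SR1") == pytest.approx(6.4,
                                                                  rel=0.02)

    def test_total_scf_pool_near_42_5_nM(self, cellular_ss):
        total = (cellular_ss.occupancy("Cul1.SR1")
                 + cellular_ss.occupancy("Cul1.SR2"))
        assert total == pytest.approx(42.5, rel=0.02)

    def test_saturated_partitioning_without_cand1(self, params):
        # with Cand1 absent and picomolar binding the scaffold simply
        # partitions among receptors by abundance: 300*100/660
        ss = sx.solve_equilibrium(params,
                                  sx.cellular_totals(cand1_total=0.0))
        assert ss.occupancy("Cul1.SR1") == pytest.approx(300 * 100 / 660,
                                                         rel=1e-3)

    def test_symmetric_split_gives_equal_occupancies(self, params):
        ss = sx.solve_equilibrium(
            params, sx.cellular_totals(sr1_total=330.0, sr2_total=330.0))
        assert ss.occupancy("Cul1.SR1") == pytest.approx(
            ss.occupancy("Cul1.SR2"), rel=1e-9)

    def test_algebraic_and_relaxation_routes_agree(self, params,
                                                   totals_100_560):
        net = build_network(params, totals_100_560)
        y_alg = equilibrium_state(net)
        y_ode = relax_to_equilibrium(net)
        mask = np.abs(y_alg) > 1e-3
        np.testing.assert_allclose(y_ode[mask], y_alg[mask], rtol=1e-6)

    def test_substrate_pool_rejected(self, params, totals_30_630):
        with pytest.raises(ValueError, match="substrate"):
            sx.solve_equilibrium(params, totals_30_630)


class TestSpectrum:
    def test_all_eigenvalues_stable(self, cellular_ss):
        assert np.all(cellular_ss.spectrum.real < 0)

    def test_exchange_rate_near_0_11_per_s(self, cellular_ss):
        assert cellular_ss.exchange_rate == pytest.approx(0.11, rel=0.02)

    def test_tau_is_reciprocal_rate(self, cellular_ss):
        assert cellular_ss.tau_s * cellular_ss.exchange_rate == pytest.approx(
            1.0, rel=1e-12)

    def test_rhs_vanishes_at_reported_state(self, cellular_ss):
        resid = cellular_ss.network.rhs(0.0, cellular_ss.state)
        assert np.max(np.abs(resid)) < 1e-10


class TestOccupancyApproximations:
    def test_slope_f_matches_published_value(self, params, totals_100_560):
        assert sx.slope_f(params, totals_100_560) == pytest.approx(0.94,
                                                                   abs=0.005)

    def test_slope_vanishes_when_ternary_affinity_dominates(self, params,
                                                            totals_100_560):
        # eta*Ksr' >> Cul1_T drives the slope to its lower bound
        p = with_eta(params, 1e4)
        assert sx.slope_f(p, totals_100_560) < 0.01

    def test_slope_requires_receptor_saturation(self, params):
        with pytest.raises(ValueError, match="SR_T > Cul1_T"):
            sx.slope_f(params, sx.cellular_totals(sr1_total=10.0,
                                                  sr2_total=20.0))

    @given(eta=st.floats(1e-3, 1e2), ksr_prime_scale=st.floats(0.01, 100.0),
           excess=st.floats(1.0, 2000.0))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_slope_bounded_between_zero_and_one(self, eta, ksr_prime_scale,
                                                excess):
        p = with_eta(sx.KineticParameters(
            Ksr=2.25e-4, Ksr_prime=650.0 * ksr_prime_scale,
            Kca=2.25e-4 * 0.0769230769230769,
            Kca_prime=50.0 * ksr_prime_scale), eta)
        totals = sx.cellular_totals(sr1_total=100.0,
                                    sr2_total=200.0 + excess)
        f = sx.slope_f(p, totals)
        assert 0.0 < f < 1.0

    def test_low_dose_occupancy_formula(self, params):
        totals = sx.cellular_totals(cand1_total=50.0)
        f = sx.slope_f(params, totals)
        expected = (100.0 / 660.0) * (300.0 - f * 50.0)
        assert sx.occupancy_low_cand1(params, totals) == pytest.approx(
            expected, rel=1e-12)
        assert expected == pytest.approx(38.3, abs=0.1)

    def test_high_dose_power_law(self, params):
        t1 = sx.cellular_totals(cand1_total=3000.0)
        v1 = sx.occupancy_high_cand1(params, t1)
        assert v1 == pytest.approx(
            params.eta * 650.0 * (300.0 / 3000.0) * 100.0 / 1610.0, rel=1e-12)
        assert v1 == pytest.approx(0.31, abs=0.01)
        v2 = sx.occupancy_high_cand1(params,
                                     sx.cellular_totals(cand1_total=6000.0))
        assert v2 == pytest.approx(v1 / 2.0, rel=1e-12)

    def test_high_dose_formula_tracks_numeric_equilibrium(self, params):
        # the power law is a leading-order asymptote; the deviation from
        # the numeric equilibrium shrinks with dose (17% at 10x Cul1_T,
        # 11% at ~33x) and the formula always underestimates
        devs = []
        for cand1 in (3000.0, 10000.0, 30000.0):
            totals = sx.cellular_totals(cand1_total=cand1)
            numeric = sx.solve_equilibrium(params, totals).occupancy("Cul1.SR1")
            approx = sx.occupancy_high_cand1(params, totals)
            assert approx < numeric
            devs.append(abs(approx / numeric - 1.0))
        assert devs[0] < 0.20 and devs[-1] < 0.10
        assert devs[0] > devs[1] > devs[2]

    def test_low_and_high_approximations_bracket_the_transition(self, params):
        # linear law accurate below Cand1_T = Cul1_T, power law above
        lo = sx.cellular_totals(cand1_total=30.0)
        hi = sx.cellular_totals(cand1_total=10000.0)
        num_lo = sx.solve_equilibrium(params, lo).occupancy("Cul1.SR1")
        num_hi = sx.solve_equilibrium(params, hi).occupancy("Cul1.SR1")
        assert sx.occupancy_low_cand1(params, lo) == pytest.approx(num_lo,
                                                                   rel=0.05)
        assert sx.occupancy_high_cand1(params, hi) == pytest.approx(num_hi,
                                                                    rel=0.15)


class TestExchangeRateLimits:
    def test_zero_dose_limit_is_spontaneous_dissociation(self, params):
        assert exchange_rate_low_cand1(params, 0.0) == pytest.approx(9e-7)

    def test_low_dose_formula_tracks_numeric_eigenvalue(self, params):
        # the closed form captures the dose dependence up to a systematic
        # ~25% prefactor offset across the low-dose decade
        for cand1 in (1.0, 10.0):
            numeric = sx.solve_equilibrium(
                params, sx.cellular_totals(cand1_total=cand1)).exchange_rate
            approx = exchange_rate_low_cand1(params, cand1)
            assert approx == pytest.approx(numeric, rel=0.30)

    def test_high_dose_limit_value_and_agreement(self, params,
                                                 totals_100_560):
        limit = sx.exchange_rate_high_limit(params, totals_100_560)
        assert limit == pytest.approx(1.65, abs=0.01)
        numeric = sx.solve_equilibrium(
            params, sx.cellular_totals(cand1_total=1e4)).exchange_rate
        assert limit == pytest.approx(numeric, rel=0.10)


@pytest.fixture(scope="module")
def curves(params, totals_100_560):
    return sx.tradeoff_scan(params, totals_100_560,
                            cand1_grid=np.logspace(0, 4, 40),
                            eta_values=(params.eta, 1.0, 10.0))


class TestTradeoffScan:
    def test_monotone_tradeoff(self, curves):
        for c in curves:
            assert np.all(np.diff(c.occupancy) < 0)
            assert np.all(np.diff(c.exchange_rate) > -1e-12)

    def test_parametric_curves_overlap_within_5_percent(self, curves):
        ref = curves[0]

        def rate_at(c, occ):
            return np.exp(np.interp(np.log(occ),
                                    np.log(c.occupancy[::-1]),
                                    np.log(c.exchange_rate[::-1])))

        for c in curves[1:]:
            lo = max(ref.occupancy.min(), c.occupancy.min()) * 1.1
            hi = min(ref.occupancy.max(), c.occupancy.max()) * 0.9
            occ = np.geomspace(lo, hi, 25)
            np.testing.assert_allclose(rate_at(c, occ), rate_at(ref, occ),
                                       rtol=0.05)

    def test_zero_dose_occupancy_equals_competitive_value(self, params):
        curve, = sx.tradeoff_scan(params, sx.cellular_totals(),
                                  cand1_grid=np.array([1e-6]))
        assert curve.occupancy[0] == pytest.approx(300 * 100 / 660, rel=1e-3)


class TestSrAdditionTransient:
    def test_final_state_matches_pooled_equilibrium(self, params):
        totals = sx.cellular_totals(cand1_total=390.0)
        tr = sx.sr_addition_transient(params, totals, added_sr1=100.0)
        expected = sx.solve_equilibrium(params, totals).occupancy("Cul1.SR1")
        assert tr.final_occupancy == pytest.approx(expected, rel=1e-6)

    def test_zero_addition_gives_flat_trajectory(self, params):
        tr = sx.sr_addition_transient(
            params, sx.cellular_totals(cand1_total=390.0), added_sr1=0.0,
            t_end=1e3)
        occ = tr.timecourse.concentration("Cul1.SR1")
        assert np.max(np.abs(occ - occ[0])) < 1e-9

    def test_equilibration_minutes_at_low_dose_seconds_at_high(self, params):
        slow = sx.sr_addition_transient(
            params, sx.cellular_totals(cand1_total=30.0), added_sr1=100.0)
        fast = sx.sr_addition_transient(
            params, sx.cellular_totals(cand1_total=3000.0), added_sr1=100.0)
        assert slow.tau_estimate > 60.0         # minutes
        assert fast.tau_estimate < 10.0         # seconds
        # relaxation time consistent with 1/|rho_l| within a factor of two
        for tr, cand1 in ((slow, 30.0), (fast, 3000.0)):
            ss = sx.solve_equilibrium(params,
                                      sx.cellular_totals(cand1_total=cand1))
            assert 0.5 < tr.tau_estimate / ss.tau_s < 2.0
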