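"""Steady states, occupancy approximations and exchange-timescale analysis.

Because every closed cycle of the binding-only network satisfies detailed
balance, its unique steady state is a thermodynamic equilibrium: each
complex concentration is a formation constant times a product of free
component concentrations.  The equilibrium is therefore obtained by
root-finding on the component conservation equations in log-space, with
ODE relaxation available as an independent cross-check.

The substrate-receptor exchange rate is quantified by the leading
eigenvalue of the reduced Jacobian at the steady state (the slowest
relaxation mode); closed-form limits for low and high exchange-factor
abundance are provided alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .network import ReactionNetwork, build_network
from .parameters import KineticParameters, PoolTotals
from .simulate import SolverSettings, Timecourse, simulate

__all__ = [
    "SteadyStateResult",
    "TradeoffCurve",
    "solve_equilibrium",
    "equilibrium_state",
    "relax_to_equilibrium",
    "with_eta",
    "slope_f",
    "occupancy_low_cand1",
    "occupancy_high_cand1",
    "exchange_rate_low_cand1",
    "exchange_rate_high_limit",
    "tradeoff_scan",
    "sr_addition_transient",
]


class EquilibriumError(RuntimeError):
    """Raised when neither the algebraic nor the relaxation route converges."""


def equilibrium_state(network: ReactionNetwork, rtol: float = 1e-11) -> np.ndarray:
    """Thermodynamic equilibrium of a binding-only network.

    Solves the conservation system ``free_k + sum_c n_kc G_c prod_m
    free_m^n_mc = T_k`` for the free component concentrations in
    log-space (robust across the ~12 orders of magnitude the affinities
    span), then assembles the complex concentrations from the formation
    constants.
    """
    if network.degradations:
        raise ValueError("equilibrium is defined for binding-only networks")
    comps = list(network.eliminated) + list(network.substrate_names)
    totals = np.concatenate([network.eliminated_totals, network.substrate_totals])
    G = network.formation_constants()
    names = network.complex_names
    # N[k, c]: copies of component k in complex c
    N = np.array(
        [[network.composition[c].get(k, 0) for c in names] for k in comps],
        dtype=float,
    )
    Gv = np.array([G[c] for c in names])

    active = totals > 0.0
    # a complex is feasible only if all its components are present
    feasible = ~((N[~active] > 0).any(axis=0)) if (~active).any() else \
        np.ones(len(names), dtype=bool)
    Na = N[np.ix_(active, feasible)]
    Ga = Gv[feasible]
    Ta = totals[active]

    def complexes(u: np.ndarray) -> np.ndarray:
        # cap the exponent: intermediate hybr trial points can otherwise
        # overflow; the residual still points back toward the root
        return Ga * np.exp(np.minimum(Na.T @ u, 500.0))

    def residual(u: np.ndarray) -> np.ndarray:
        return (np.exp(np.minimum(u, 500.0)) + Na @ complexes(u) - Ta) / Ta

    def jac(u: np.ndarray) -> np.ndarray:
        c = complexes(u)
        return (np.diag(np.exp(np.minimum(u, 500.0)))
                + (Na * c) @ Na.T) / Ta[:, None]

    sol_u = None
    if active.any():
        for shift in (0.0, -6.0, -14.0, 3.0):
            u0 = np.log(Ta) + shift
            res = optimize.root(residual, u0, jac=jac, method="hybr",
                                options={"xtol": 1e-13})
            if res.success and np.max(np.abs(residual(res.x))) < rtol:
                sol_u = res.x
                break
        if sol_u is None:
            raise EquilibriumError(
                "conservation system did not converge from any initial guess"
            )

    y = np.zeros(network.n_states)
    if sol_u is not None:
        conc = complexes(sol_u)
        for idx_c, name in enumerate(np.array(names)[feasible]):
            y[network.state_index(name)] = conc[idx_c]
        free = np.exp(sol_u)
        for k, name in enumerate(np.array(comps)[active]):
            if name in network.substrate_names:
                y[network.state_index(name)] = free[k]
    return y


def relax_to_equilibrium(
    network: ReactionNetwork,
    t_end: float = 1e9,
    settings: SolverSettings = SolverSettings(),
) -> np.ndarray:
    """Steady state by long-time integration from the empty-complex state.

    Independent of the algebraic route; used as fallback and cross-check.
    The default horizon exceeds the slowest relaxation time (1/ksr ~ 1e6 s)
    by three orders of magnitude.
    """
    tc = simulate(network, t_end=t_end, settings=settings)
    return tc.final_state()


@dataclass
class SteadyStateResult:
    """Equilibrium state with its local linearization.

    ``exchange_rate`` is |Re| of the leading (largest real part, nonzero)
    eigenvalue of the reduced Jacobian; ``tau_s`` its reciprocal, the
    timescale on which the receptor repertoire re-equilibrates.
    """

    network: ReactionNetwork
    state: np.ndarray
    jacobian: np.ndarray
    spectrum: np.ndarray
    leading_eigenvalue: complex
    exchange_rate: float
    tau_s: float

    def occupancy(self, name: str = "Cul1.SR1") -> float:
        return float(self.network.concentration(name, self.state))

    def free(self, name: str) -> float:
        return float(self.network.concentration(name, self.state))


def _leading_eigenvalue(spectrum: np.ndarray) -> complex:
    """Nonzero eigenvalue with the largest real part."""
    scale = np.max(np.abs(spectrum)) if len(spectrum) else 1.0
    nonzero = spectrum[np.abs(spectrum) > 1e-12 * max(scale, 1.0)]
    if len(nonzero) == 0:
        raise ValueError("spectrum contains only zero eigenvalues")
    return nonzero[np.argmax(nonzero.real)]


def analyze_steady_state(network: ReactionNetwork, y: np.ndarray) -> SteadyStateResult:
    """Linearize the dynamics at ``y`` and extract the exchange timescale."""
    J = network.jacobian(0.0, y)
    spectrum = np.linalg.eigvals(J)
    lead = _leading_eigenvalue(spectrum)
    rate = abs(lead.real)
    return SteadyStateResult(
        network=network,
        state=y,
        jacobian=J,
        spectrum=spectrum,
        leading_eigenvalue=lead,
        exchange_rate=rate,
        tau_s=1.0 / rate,
    )


def solve_equilibrium(
    params: KineticParameters,
    totals: PoolTotals,
    cross_check: bool = False,
) -> SteadyStateResult:
    """Equilibrium of the binding-only exchange cycle with eigen-analysis.

    With ``cross_check=True`` the algebraic equilibrium is verified
    against ODE relaxation to relative 1e-6 (on concentrations above
    0.1% of the Cul1 pool).
    """
    if totals.substrate_totals:
        raise ValueError("equilibrium analysis expects a substrate-free pool")
    network = build_network(params, totals)
    try:
        y = equilibrium_state(network)
    except EquilibriumError:
        y = relax_to_equilibrium(network)
    if cross_check:
        y_ode = relax_to_equilibrium(network)
        scale = max(1e-3 * totals.cul1_total, 1e-12)
        mask = np.maximum(np.abs(y), np.abs(y_ode)) > scale
        if mask.any():
            rel = np.max(np.abs(y[mask] - y_ode[mask])
                         / np.maximum(np.abs(y[mask]), scale))
            if rel > 1e-6:
                raise EquilibriumError(
                    f"algebraic and relaxation steady states disagree ({rel:.2e})"
                )
    return analyze_steady_state(network, y)


# -- closed-form occupancy approximations ---------------------------------

def with_eta(params: KineticParameters, eta: float) -> KineticParameters:
    """Rescale the exchange-factor affinities so Kca/Ksr = Kca'/Ksr' = eta.

    Dissociation rate constants are kept fixed; only the dissociation
    constants of Cand1 move, preserving detailed balance.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    return replace(params, Kca=eta * params.Ksr, Kca_prime=eta * params.Ksr_prime)


def slope_f(params: KineticParameters, totals: PoolTotals) -> float:
    """Slope of the linear occupancy decrease at low exchange-factor dose.

    f = (Ksr' + SR_T - Cul1_T) /
        (Ksr' + (1 + eta*Ksr'/Cul1_T) * (SR_T - Cul1_T)),  with 0 < f < 1.

    Valid in the receptor-saturated regime SR_T > Cul1_T.
    """
    sr_t, cul1_t = totals.sr_total, totals.cul1_total
    if sr_t <= cul1_t:
        raise ValueError("slope requires the saturated regime SR_T > Cul1_T")
    ksr_p = params.Ksr_prime
    excess = sr_t - cul1_t
    return (ksr_p + excess) / (ksr_p + (1.0 + params.eta * ksr_p / cul1_t) * excess)


def occupancy_low_cand1(
    params: KineticParameters, totals: PoolTotals, receptor: int = 0
) -> float:
    """Linear low-dose approximation of the scaffold-receptor occupancy:
    [Cul1.SRi] ~ (SRi_T/SR_T) * (Cul1_T - f * Cand1_T)."""
    f = slope_f(params, totals)
    frac = totals.sr_totals[receptor] / totals.sr_total
    return frac * (totals.cul1_total - f * totals.cand1_total)


def occupancy_high_cand1(
    params: KineticParameters, totals: PoolTotals, receptor: int = 0
) -> float:
    """Power-law high-dose approximation (~ 1/Cand1_T):
    [Cul1.SRi] ~ eta*Ksr' * (Cul1_T/Cand1_T) * SRi_T/(Ksr'+SR_T+Cul1_T)."""
    ksr_p = params.Ksr_prime
    return (
        params.eta * ksr_p
        * (totals.cul1_total / totals.cand1_total)
        * totals.sr_totals[receptor]
        / (ksr_p + totals.sr_total + totals.cul1_total)
    )


# -- exchange-rate limits ---------------------------------------------------

def exchange_rate_low_cand1(params: KineticParameters, cand1_total: float) -> float:
    """Low-dose approximation of the exchange rate:
    |rho_l| ~ ksr + 1 / (1/ksr' + Ksr'/(kca' * Cand1_T))."""
    if cand1_total <= 0:
        return params.ksr_eff
    return params.ksr_eff + 1.0 / (
        1.0 / params.ksr_prime
        + params.Ksr_prime / (params.kca_prime * cand1_total)
    )


def exchange_rate_high_limit(params: KineticParameters, totals: PoolTotals) -> float:
    """Saturating exchange rate, independent of eta and of the dose:
    |rho_l_inf| ~ ksr' * (1 + (Cul1_T/Ksr') * (Cul1_T+Ksr')/(Cul1_T+SR_T+Ksr')).

    Depends only on the ternary-to-Cul1.Cand1 dissociation channel, which
    ultimately limits how fast new receptors gain access to the scaffold.
    """
    c, ksr_p = totals.cul1_total, params.Ksr_prime
    return params.ksr_prime * (
        1.0 + (c / ksr_p) * (c + ksr_p) / (c + totals.sr_total + ksr_p)
    )


# -- trade-off scan ---------------------------------------------------------

@dataclass
class TradeoffCurve:
    """Occupancy/exchange-rate trade-off along an exchange-factor dose grid."""

    eta: float
    cand1_grid: np.ndarray
    occupancy: np.ndarray       # [Cul1.SR1], nM
    exchange_rate: np.ndarray   # s^-1

    @property
    def tau_s(self) -> np.ndarray:
        return 1.0 / self.exchange_rate


def tradeoff_scan(
    params: KineticParameters,
    totals: PoolTotals,
    cand1_grid: np.ndarray | None = None,
    eta_values: tuple[float, ...] | None = None,
) -> list[TradeoffCurve]:
    """Occupancy and exchange rate across a dose grid, per eta.

    Grid default: 60 log-spaced points over 1..1e4 nM, bracketing the
    Cand1_T = Cul1_T transition from both sides.  Solver failures at a
    grid point yield NaN for that point and do not abort the scan.
    """
    if cand1_grid is None:
        cand1_grid = np.logspace(0, 4, 60)
    cand1_grid = np.asarray(cand1_grid, float)
    if eta_values is None:
        eta_values = (params.eta,)
    curves = []
    for eta in eta_values:
        p = with_eta(params, eta)
        occ = np.full(len(cand1_grid), np.nan)
        rate = np.full(len(cand1_grid), np.nan)
        for i, ca in enumerate(cand1_grid):
            try:
                res = solve_equilibrium(p, totals.with_cand1(ca))
            except (EquilibriumError, ValueError):
                continue
            occ[i] = res.occupancy("Cul1.SR1")
            rate[i] = res.exchange_rate
        curves.append(TradeoffCurve(eta=eta, cand1_grid=cand1_grid,
                                    occupancy=occ, exchange_rate=rate))
    return curves


# -- receptor-addition transient -------------------------------------------

@dataclass
class AdditionTransient:
    """Assembly of Cul1.SR1 after adding SR1 to a pre-equilibrated mixture."""

    timecourse: Timecourse
    tau_estimate: float      # time to cover 1-1/e of the response (s)
    final_occupancy: float   # [Cul1.SR1] at the end of the run (nM)


def sr_addition_transient(
    params: KineticParameters,
    totals: PoolTotals,
    added_sr1: float,
    t_end: float | None = None,
    settings: SolverSettings = SolverSettings(),
) -> AdditionTransient:
    """Add ``added_sr1`` nM of receptor 1 to the SR1-free steady state and
    follow the assembly of Cul1.SR1.

    ``totals.sr_totals[0]`` is ignored (pre-stimulus SR1 is absent); the
    post-addition pool has SR1_T = added_sr1.
    """
    pre = replace(totals, sr_totals=(0.0, *totals.sr_totals[1:]))
    post = replace(totals, sr_totals=(float(added_sr1), *totals.sr_totals[1:]))
    net_pre = build_network(params, pre)
    y0 = equilibrium_state(net_pre)
    net_post = build_network(params, post)
    if t_end is None:
        # several multiples of the slow exchange timescale of the new state
        rate = analyze_steady_state(
            net_post, equilibrium_state(net_post)
        ).exchange_rate
        t_end = 20.0 / rate
    tc = simulate(net_post, y0=y0, t_end=t_end, settings=settings)
    occ = tc.concentration("Cul1.SR1")
    final = float(occ[-1])
    start = float(occ[0])
    if abs(final - start) < 1e-12:
        tau = 0.0
    else:
        target = start + (1.0 - math.exp(-1.0)) * (final - start)
        idx = np.argmax(occ >= target) if final > start else np.argmax(occ <= target)
        tau = float(tc.t[idx])
    return AdditionTransient(timecourse=tc, tau_estimate=tau, final_occupancy=final)
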