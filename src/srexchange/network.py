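"""Mass-action reaction network for the exchange cycle and its extensions.

The state vector integrates *complex* concentrations (plus free substrate,
which is depleted by degradation and therefore not conserved); the free
concentrations of the conserved components (Cul1, Cand1, each SR) are
eliminated algebraically through the mass-conservation relations.  This
makes conservation of the component totals exact by construction and
reduces the base two-receptor cycle to the canonical five-dimensional
system

    y1 = [Cul1.SR1], y2 = [Cul1.SR2], y3 = [Cul1.Cand1],
    y4 = [Cul1.Cand1.SR1], y5 = [Cul1.Cand1.SR2].

All association rate constants are derived as (dissociation rate
constant) / (dissociation constant), so a joint gamma-rescale of ksr and
kca leaves the association rates untouched while weakening both binary
affinities.

The network stores an exactly balanced value of Kca (recomputed as
eta * Ksr from the ternary-side constants) so that the binding-only
steady state is a true thermodynamic equilibrium; the published rounded
constants leave a cycle residual of ~4e-4 which would otherwise shift
the fixed point away from the algebraic equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .parameters import (
    BindingMode,
    KineticParameters,
    PoolTotals,
    SubstrateParameters,
    detailed_balance_residual,
)

__all__ = ["Reaction", "Degradation", "ReactionNetwork", "build_network"]

#: numerical floor below which a concentration is treated as zero (nM)
CONC_FLOOR = 1e-9


@dataclass(frozen=True)
class Reaction:
    """Reversible bimolecular association A + B <-> C."""

    a: str
    b: str
    c: str
    kon: float   # nM^-1 s^-1
    koff: float  # s^-1

    @property
    def Kd(self) -> float:
        return self.koff / self.kon


@dataclass(frozen=True)
class Degradation:
    """Irreversible first-order removal of substrate: source -> product."""

    source: str
    product: str
    kdeg: float  # s^-1


def _species_name(*parts: str) -> str:
    return ".".join(parts)


class ReactionNetwork:
    """Reaction list plus the index machinery for rhs/Jacobian evaluation.

    Construct through :func:`build_network`.
    """

    def __init__(
        self,
        eliminated: Sequence[str],
        eliminated_totals: Sequence[float],
        complex_names: Sequence[str],
        complex_composition: dict[str, dict[str, int]],
        substrate_names: Sequence[str],
        substrate_totals: Sequence[float],
        reactions: Sequence[Reaction],
        degradations: Sequence[Degradation],
    ):
        self.eliminated = list(eliminated)
        self.eliminated_totals = np.asarray(eliminated_totals, dtype=float)
        self.complex_names = list(complex_names)
        self.substrate_names = list(substrate_names)
        self.substrate_totals = np.asarray(substrate_totals, dtype=float)
        self.state_names = self.complex_names + self.substrate_names
        self.reactions = list(reactions)
        self.degradations = list(degradations)
        self.composition = dict(complex_composition)
        for s in self.substrate_names:
            self.composition.setdefault(s, {s: 1})
        for e in self.eliminated:
            self.composition.setdefault(e, {e: 1})

        n = self.n_states
        self._state_index = {name: i for i, name in enumerate(self.state_names)}
        self._elim_index = {name: i for i, name in enumerate(self.eliminated)}

        # comp_matrix[k, i]: copies of eliminated component k inside state i
        self.comp_matrix = np.zeros((len(self.eliminated), n))
        for i, name in enumerate(self.complex_names):
            for comp, cnt in self.composition[name].items():
                if comp in self._elim_index:
                    self.comp_matrix[self._elim_index[comp], i] = cnt
        # sub_matrix[j, i]: copies of substrate j inside state i
        self.sub_matrix = np.zeros((len(self.substrate_names), n))
        for j, sub in enumerate(self.substrate_names):
            self.sub_matrix[j, self._state_index[sub]] = 1.0
            for i, name in enumerate(self.complex_names):
                self.sub_matrix[j, i] = self.composition[name].get(sub, 0)

        # precompute per-species (value-kind, index, gradient-row) lookups
        self._grad = {}
        for name in self.state_names:
            g = np.zeros(n)
            g[self._state_index[name]] = 1.0
            self._grad[name] = g
        for name in self.eliminated:
            self._grad[name] = -self.comp_matrix[self._elim_index[name]]

        self._rxn_idx = []
        for r in self.reactions:
            self._rxn_idx.append(tuple(self._accessor(s) for s in (r.a, r.b, r.c)))
        self._deg_idx = [
            (self._state_index[d.source], self._state_index[d.product])
            for d in self.degradations
        ]

    # -- bookkeeping ------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_complexes(self) -> int:
        return len(self.complex_names)

    def _accessor(self, name: str):
        if name in self._state_index:
            return ("state", self._state_index[name])
        if name in self._elim_index:
            return ("elim", self._elim_index[name])
        raise KeyError(f"unknown species {name!r}")

    def state_index(self, name: str) -> int:
        return self._state_index[name]

    def has_species(self, name: str) -> bool:
        return name in self._state_index or name in self._elim_index

    # -- evaluation -------------------------------------------------------
    def free_eliminated(self, y: np.ndarray) -> np.ndarray:
        """Free concentrations of the conserved components at state ``y``."""
        return self.eliminated_totals - self.comp_matrix @ np.asarray(y, float)

    def concentration(self, name: str, y: np.ndarray):
        """Concentration of any species (complex, free substrate or
        eliminated free component); ``y`` may be 1-D or (n_states, nt)."""
        y = np.asarray(y, float)
        if name in self._state_index:
            return y[self._state_index[name]]
        k = self._elim_index[name]
        return self.eliminated_totals[k] - self.comp_matrix[k] @ y

    def _values(self, y, elim_free):
        def val(acc):
            kind, idx = acc
            return y[idx] if kind == "state" else elim_free[idx]
        return val

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        """Time derivative of the state vector (nM/s)."""
        elim_free = self.eliminated_totals - self.comp_matrix @ y
        val = self._values(y, elim_free)
        dydt = np.zeros_like(y)
        for (acc_a, acc_b, acc_c), r in zip(self._rxn_idx, self.reactions):
            rate = r.kon * val(acc_a) * val(acc_b) - r.koff * val(acc_c)
            if acc_a[0] == "state":
                dydt[acc_a[1]] -= rate
            if acc_b[0] == "state":
                dydt[acc_b[1]] -= rate
            dydt[acc_c[1]] += rate
        for (i_src, i_prod), d in zip(self._deg_idx, self.degradations):
            rate = d.kdeg * y[i_src]
            dydt[i_src] -= rate
            dydt[i_prod] += rate
        return dydt

    def jacobian(self, t: float, y: np.ndarray) -> np.ndarray:
        """Analytic Jacobian of :meth:`rhs` with the conserved components
        eliminated (the "reduced" Jacobian whose spectrum carries no
        structural zero modes)."""
        elim_free = self.eliminated_totals - self.comp_matrix @ y
        val = self._values(y, elim_free)
        n = self.n_states
        J = np.zeros((n, n))
        for (acc_a, acc_b, acc_c), r in zip(self._rxn_idx, self.reactions):
            ga = self._grad[r.a]
            gb = self._grad[r.b]
            gc = self._grad[r.c]
            drate = r.kon * (val(acc_b) * ga + val(acc_a) * gb) - r.koff * gc
            if acc_a[0] == "state":
                J[acc_a[1]] -= drate
            if acc_b[0] == "state":
                J[acc_b[1]] -= drate
            J[acc_c[1]] += drate
        for (i_src, i_prod), d in zip(self._deg_idx, self.degradations):
            J[i_src, i_src] -= d.kdeg
            J[i_prod, i_src] += d.kdeg
        return J

    # -- states and conserved quantities ----------------------------------
    def initial_state(self, inject_substrates: bool = True) -> np.ndarray:
        """All-complexes-empty state; free substrate set to its total
        (the injection bolus) unless ``inject_substrates`` is False."""
        y = np.zeros(self.n_states)
        if inject_substrates:
            for j, sub in enumerate(self.substrate_names):
                y[self._state_index[sub]] = self.substrate_totals[j]
        return y

    def conserved_totals(self, y: np.ndarray) -> dict[str, float]:
        """Recover every component total from the state by summation."""
        y = np.asarray(y, float)
        out = {}
        elim_free = self.free_eliminated(y)
        for k, name in enumerate(self.eliminated):
            out[name] = float(elim_free[k] + self.comp_matrix[k] @ y)
        for j, name in enumerate(self.substrate_names):
            out[name] = float(self.sub_matrix[j] @ y)
        return out

    def total_substrate(self, y: np.ndarray, substrate: int = 0):
        """Total (free plus complexed) substrate concentration S_T."""
        return self.sub_matrix[substrate] @ np.asarray(y, float)

    # -- thermodynamics ----------------------------------------------------
    def formation_constants(self) -> dict[str, float]:
        """Association ("formation") constant of each complex relative to
        its free components: [C] = G_C * prod_k [free_k]^n_k at
        equilibrium.  Well defined because every closed reaction cycle
        satisfies detailed balance; route-inconsistencies above 1%
        raise ``ValueError``."""
        G: dict[str, float] = {name: 1.0 for name in self.eliminated}
        G.update({name: 1.0 for name in self.substrate_names})
        pending = list(self.reactions)
        progress = True
        while pending and progress:
            progress = False
            remaining = []
            for r in pending:
                if r.a in G and r.b in G:
                    val = G[r.a] * G[r.b] / r.Kd
                    if r.c in G:
                        if abs(val - G[r.c]) > 1e-2 * abs(G[r.c]):
                            raise ValueError(
                                f"reaction cycle through {r.c} violates "
                                "detailed balance"
                            )
                    else:
                        G[r.c] = val
                    progress = True
                else:
                    remaining.append(r)
            pending = remaining
        if pending:
            raise ValueError("reaction graph is not connected to free species")
        return G


def build_network(
    params: KineticParameters,
    totals: PoolTotals,
    substrates: Sequence[SubstrateParameters] = (),
    receptor_params: Sequence[KineticParameters] | None = None,
) -> ReactionNetwork:
    """Assemble the reaction network of the exchange cycle.

    Per receptor i the base cycle contributes

        Cul1 + SRi          <-> Cul1.SRi          (gamma*ksr,  gamma*Ksr)
        Cul1.SRi + Cand1    <-> Cul1.Cand1.SRi    (kca',       Kca')
        Cul1.Cand1 + SRi    <-> Cul1.Cand1.SRi    (ksr',       Ksr')

    plus the shared  Cul1 + Cand1 <-> Cul1.Cand1  (gamma*kca, gamma*Kca)
    reaction.  ``receptor_params`` optionally supplies per-receptor
    constants (e.g. a receptor with 5-fold weaker scaffold affinity); each
    per-receptor cycle must close thermodynamically against the shared
    Cul1.Cand1 equilibrium.

    Substrate reactions are appended per ``binding_mode``: in sequential
    mode substrate binds Cul1.SRi (and the ternary complex when
    ``binds_ternary``); in random-order mode it additionally binds free
    SRi, and SRi.S binds Cul1 and Cul1.Cand1.  The exchange factor never
    binds a substrate-loaded scaffold, and degradation proceeds only from
    Cul1.SRi.S.
    """
    n_rec = totals.n_receptors
    if receptor_params is None:
        receptor_params = [params] * n_rec
    if len(receptor_params) != n_rec:
        raise ValueError("receptor_params must match the number of receptors")
    for p in receptor_params:
        if p.gamma != params.gamma:
            raise ValueError("gamma must rescale all receptors jointly")

    # exactly balanced shared Cand1 affinity (gamma-scaled); see module docs
    Kca_exact = params.eta * params.Ksr * params.gamma
    kca_eff = params.kca_eff
    for i, p in enumerate(receptor_params):
        res = detailed_balance_residual(
            p.Ksr_eff, p.Ksr_prime, Kca_exact, p.Kca_prime
        )
        if res > 1e-3:
            raise ValueError(
                f"receptor {i + 1} cycle violates detailed balance against "
                f"the shared Cul1.Cand1 equilibrium (residual {res:.2e})"
            )

    if len(substrates) != len(totals.substrate_totals):
        raise ValueError("one substrate total per substrate is required")
    seen_receptors = set()
    for sub in substrates:
        if sub.receptor >= n_rec:
            raise ValueError(
                f"substrate references receptor {sub.receptor + 1} but only "
                f"{n_rec} receptors exist"
            )
        if sub.receptor in seen_receptors:
            raise ValueError("at most one substrate per receptor is supported")
        seen_receptors.add(sub.receptor)

    sr = [f"SR{i + 1}" for i in range(n_rec)]
    eliminated = ["Cul1", "Cand1"] + sr
    eliminated_totals = [totals.cul1_total, totals.cand1_total, *totals.sr_totals]

    complexes: list[str] = []
    comp: dict[str, dict[str, int]] = {}

    def add_complex(name: str, composition: dict[str, int]) -> None:
        if name not in comp:
            complexes.append(name)
            comp[name] = composition

    reactions: list[Reaction] = []
    degradations: list[Degradation] = []

    # base cycle: binary complexes first (y1..y2), then Cul1.Cand1 (y3),
    # then ternaries (y4..y5), matching the canonical state ordering
    for i in range(n_rec):
        add_complex(f"Cul1.{sr[i]}", {"Cul1": 1, sr[i]: 1})
    add_complex("Cul1.Cand1", {"Cul1": 1, "Cand1": 1})
    for i in range(n_rec):
        add_complex(f"Cul1.Cand1.{sr[i]}", {"Cul1": 1, "Cand1": 1, sr[i]: 1})

    for i, p in enumerate(receptor_params):
        reactions.append(Reaction("Cul1", sr[i], f"Cul1.{sr[i]}",
                                  kon=p.ksr_eff / p.Ksr_eff, koff=p.ksr_eff))
    reactions.append(Reaction("Cul1", "Cand1", "Cul1.Cand1",
                              kon=kca_eff / Kca_exact, koff=kca_eff))
    for i, p in enumerate(receptor_params):
        tern = f"Cul1.Cand1.{sr[i]}"
        reactions.append(Reaction(f"Cul1.{sr[i]}", "Cand1", tern,
                                  kon=p.kca_prime / p.Kca_prime,
                                  koff=p.kca_prime))
        reactions.append(Reaction("Cul1.Cand1", sr[i], tern,
                                  kon=p.ksr_prime / p.Ksr_prime,
                                  koff=p.ksr_prime))

    substrate_names = [f"S{j + 1}" for j in range(len(substrates))]
    for j, sub in enumerate(substrates):
        i = sub.receptor
        p = receptor_params[i]
        s = substrate_names[j]
        scf = f"Cul1.{sr[i]}"
        tern = f"Cul1.Cand1.{sr[i]}"
        loaded = f"{scf}.{s}"
        add_complex(loaded, {"Cul1": 1, sr[i]: 1, s: 1})
        reactions.append(Reaction(s, scf, loaded,
                                  kon=sub.kon_nM, koff=sub.koff))
        if sub.binds_ternary or sub.cand1_exchange_on_loaded:
            tern_loaded = f"{tern}.{s}"
            add_complex(tern_loaded, {"Cul1": 1, "Cand1": 1, sr[i]: 1, s: 1})
            if sub.binds_ternary:
                reactions.append(Reaction(s, tern, tern_loaded,
                                          kon=sub.kon_nM, koff=sub.koff))
            if sub.cand1_exchange_on_loaded:
                reactions.append(Reaction(loaded, "Cand1", tern_loaded,
                                          kon=p.kca_prime / p.Kca_prime,
                                          koff=p.kca_prime))
        if sub.binding_mode is BindingMode.RANDOM_ORDER:
            dimer = f"{sr[i]}.{s}"
            add_complex(dimer, {sr[i]: 1, s: 1})
            reactions.append(Reaction(s, sr[i], dimer,
                                      kon=sub.kon_nM, koff=sub.koff))
            reactions.append(Reaction(dimer, "Cul1", loaded,
                                      kon=p.ksr_eff / p.Ksr_eff,
                                      koff=p.ksr_eff))
            reactions.append(Reaction(dimer, "Cul1.Cand1", f"{tern}.{s}",
                                      kon=p.ksr_prime / p.Ksr_prime,
                                      koff=p.ksr_prime))
        if sub.kdeg > 0:
            degradations.append(Degradation(loaded, scf, sub.kdeg))

    return ReactionNetwork(
        eliminated=eliminated,
        eliminated_totals=eliminated_totals,
        complex_names=complexes,
        complex_composition=comp,
        substrate_names=substrate_names,
        substrate_totals=totals.substrate_totals,
        reactions=reactions,
        degradations=degradations,
    )
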