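"""Rate constants, pool sizes and thermodynamic-consistency checks.

The exchange cycle couples four reversible binding equilibria into a closed
thermodynamic cycle::

    Cul1 + SR   <->  Cul1.SR          (K_sr,  k_sr)
    Cul1 + Cand1 <-> Cul1.Cand1       (K_ca,  k_ca)
    Cul1.SR + Cand1 <-> Cul1.Cand1.SR (K_ca', k_ca')
    Cul1.Cand1 + SR <-> Cul1.Cand1.SR (K_sr', k_sr')

Because the free-energy change of forming the ternary complex cannot depend
on the order of assembly, the dissociation constants must satisfy the
detailed-balance relation ``K_ca * K_sr' == K_ca' * K_sr``.  The preference
of the exchange factor over receptors for the scaffold is summarised by
``eta = K_ca / K_sr = K_ca' / K_sr'`` (eta < 1: Cand1 binds tighter).

Units: concentrations and dissociation constants in nM, time in seconds.
Substrate association rates are accepted in M^-1 s^-1 and converted to
nM^-1 s^-1 internally; half-lives are reported in minutes downstream.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "KineticParameters",
    "PoolTotals",
    "SubstrateParameters",
    "BindingMode",
    "detailed_balance_residual",
    "cellular_parameters",
    "cellular_totals",
]

#: relative tolerance for the detailed-balance and scale-factor invariants;
#: the published constants are rounded to 2-3 significant figures and leave
#: a residual of ~4e-4.
CONSISTENCY_RTOL = 1e-3

M_TO_NM = 1e-9  # converts M^-1 s^-1 association rates to nM^-1 s^-1


class BindingMode(str, enum.Enum):
    """How a substrate gains access to its cognate receptor.

    ``sequential``   -- substrate binds the receptor only after the receptor
                        is mounted on the scaffold (Cul1.SR and, optionally,
                        the ternary Cul1.Cand1.SR).
    ``random_order`` -- substrate additionally binds the free receptor, and
                        the receptor-substrate dimer itself binds Cul1 and
                        Cul1.Cand1.
    """

    SEQUENTIAL = "sequential"
    RANDOM_ORDER = "random_order"


def detailed_balance_residual(
    Ksr: float, Ksr_prime: float, Kca: float, Kca_prime: float
) -> float:
    """Relative residual of the thermodynamic-cycle constraint.

    Returns ``|Kca*Ksr' - Kca'*Ksr| / (Kca'*Ksr)``; zero for a perfectly
    consistent cycle.
    """
    return abs(Kca * Ksr_prime - Kca_prime * Ksr) / (Kca_prime * Ksr)


@dataclass(frozen=True)
class KineticParameters:
    """Dissociation constants (nM) and dissociation rate constants (s^-1)
    of the four-reaction exchange cycle, plus the affinity-rescale factor
    ``gamma`` used to construct weak-binding (exchange-factor-free)
    architectures.

    ``gamma`` multiplies the *binary* dissociation rate constants ``ksr``
    and ``kca`` jointly, so ``Ksr`` and ``Kca`` scale by gamma while the
    ternary constants, ``eta`` and detailed balance are untouched.  The
    stored fields are always the gamma=1 values; accessors ending in
    ``_eff`` return the rescaled ones.
    """

    Ksr: float = 2.25e-4
    Ksr_prime: float = 650.0
    Kca: float = 1.73e-5
    Kca_prime: float = 50.0
    ksr: float = 9e-7
    ksr_prime: float = 1.3
    kca: float = 1e-5
    kca_prime: float = 0.04
    gamma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("Ksr", "Ksr_prime", "Kca", "Kca_prime",
                     "ksr", "ksr_prime", "kca", "kca_prime"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v!r}")
        if self.gamma < 1.0:
            raise ValueError(f"gamma must be >= 1, got {self.gamma!r}")
        res = self.detailed_balance_residual()
        if res > CONSISTENCY_RTOL:
            raise ValueError(
                "dissociation constants violate detailed balance: "
                f"relative residual {res:.2e} > {CONSISTENCY_RTOL:g}"
            )
        eta1, eta2 = self.Kca / self.Ksr, self.Kca_prime / self.Ksr_prime
        if abs(eta1 - eta2) > CONSISTENCY_RTOL * abs(eta2):
            raise ValueError(
                f"inconsistent affinity preference: Kca/Ksr={eta1:.4g} vs "
                f"Kca'/Ksr'={eta2:.4g}"
            )

    # -- derived dimensionless scale factors ------------------------------
    @property
    def eta(self) -> float:
        """Relative binding preference of Cand1 vs. SR for Cul1 (Kca'/Ksr')."""
        return self.Kca_prime / self.Ksr_prime

    @property
    def alpha(self) -> float:
        """Ratio of binary-complex dissociation rate constants, kca/ksr."""
        return self.kca / self.ksr

    @property
    def beta(self) -> float:
        """Ratio of ternary-complex dissociation rate constants, kca'/ksr'."""
        return self.kca_prime / self.ksr_prime

    # -- gamma-rescaled (effective) binary constants ----------------------
    @property
    def Ksr_eff(self) -> float:
        return self.gamma * self.Ksr

    @property
    def Kca_eff(self) -> float:
        return self.gamma * self.Kca

    @property
    def ksr_eff(self) -> float:
        return self.gamma * self.ksr

    @property
    def kca_eff(self) -> float:
        return self.gamma * self.kca

    def detailed_balance_residual(self) -> float:
        return detailed_balance_residual(
            self.Ksr, self.Ksr_prime, self.Kca, self.Kca_prime
        )

    def with_gamma(self, gamma: float) -> "KineticParameters":
        """Return a copy with the affinity-rescale factor set to ``gamma``."""
        return replace(self, gamma=float(gamma))

    def scale_receptor_affinity(self, factor: float) -> "KineticParameters":
        """Weaken the Cul1-SR interaction ``factor``-fold for one receptor.

        Multiplies ``ksr`` (hence ``Ksr``) and ``ksr_prime`` (hence
        ``Ksr_prime``) by ``factor`` so that detailed balance is preserved,
        mirroring the construction used for receptors of unequal scaffold
        affinity.
        """
        if factor <= 0:
            raise ValueError("factor must be positive")
        return replace(
            self,
            ksr=self.ksr * factor,
            Ksr=self.Ksr * factor,
            ksr_prime=self.ksr_prime * factor,
            Ksr_prime=self.Ksr_prime * factor,
        )


@dataclass(frozen=True)
class PoolTotals:
    """Conserved total concentrations (nM).

    ``sr_totals`` is ordered: index i is the total of receptor SR(i+1).
    ``substrate_totals`` holds the amount of each substrate injected at
    t=0 (may be empty for binding-only systems).
    """

    cul1_total: float
    cand1_total: float
    sr_totals: tuple[float, ...]
    substrate_totals: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sr_totals", tuple(float(x) for x in self.sr_totals))
        object.__setattr__(
            self, "substrate_totals", tuple(float(x) for x in self.substrate_totals)
        )
        if len(self.sr_totals) < 1:
            raise ValueError("at least one substrate receptor is required")
        for name, v in [("cul1_total", self.cul1_total),
                        ("cand1_total", self.cand1_total),
                        *[(f"sr_totals[{i}]", v) for i, v in enumerate(self.sr_totals)],
                        *[(f"substrate_totals[{i}]", v)
                          for i, v in enumerate(self.substrate_totals)]]:
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def n_receptors(self) -> int:
        return len(self.sr_totals)

    @property
    def sr_total(self) -> float:
        """Combined receptor pool SR_T = sum_i SRi_T (nM)."""
        return float(sum(self.sr_totals))

    def with_cand1(self, cand1_total: float) -> "PoolTotals":
        return replace(self, cand1_total=float(cand1_total))

    def with_substrates(self, substrate_totals) -> "PoolTotals":
        return replace(self, substrate_totals=tuple(float(x) for x in substrate_totals))


@dataclass(frozen=True)
class SubstrateParameters:
    """Binding and turnover constants of one degradation substrate.

    kon is given in M^-1 s^-1 (the field stores that unit); ``kon_nM``
    returns the internally used nM^-1 s^-1 value.  ``receptor`` is the
    0-based index of the cognate receptor.  ``binds_ternary`` allows the
    substrate to also dock onto the ternary Cul1.Cand1.SR complex; it is
    implied (and forced on) in random-order mode.  Degradation proceeds
    only from Cul1.SR.S in every mode.

    Two neddylation proxies are supported.  By default the exchange
    factor cannot touch a substrate-loaded scaffold at all (shielding).
    With ``cand1_exchange_on_loaded`` the Cand1 <-> Cul1.SR.S exchange
    reaction stays active (rate kca', affinity Kca') and neddylation is
    mimicked solely by restricting degradation to the Cand1-free loaded
    complex.
    """

    kon: float = 1e8
    koff: float = 1.0
    kdeg: float = 0.004
    receptor: int = 0
    binding_mode: BindingMode = BindingMode.SEQUENTIAL
    binds_ternary: bool = False
    cand1_exchange_on_loaded: bool = False

    def __post_init__(self) -> None:
        for name in ("kon", "koff"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v!r}")
        if not (math.isfinite(self.kdeg) and self.kdeg >= 0):
            raise ValueError(f"kdeg must be finite and >= 0, got {self.kdeg!r}")
        if self.receptor < 0:
            raise ValueError("receptor index must be >= 0")
        object.__setattr__(self, "binding_mode", BindingMode(self.binding_mode))
        if self.binding_mode is BindingMode.RANDOM_ORDER:
            object.__setattr__(self, "binds_ternary", True)

    @property
    def kon_nM(self) -> float:
        """Association rate constant in nM^-1 s^-1."""
        return self.kon * M_TO_NM

    @property
    def Kd(self) -> float:
        """Substrate-receptor dissociation constant in nM."""
        return self.koff / self.kon_nM


def cellular_parameters() -> KineticParameters:
    """Default rate constants measured for the SCF(Fbxw7) ligase."""
    return KineticParameters()


def cellular_totals(
    sr1_total: float = 100.0,
    sr2_total: float = 560.0,
    cand1_total: float = 390.0,
    cul1_total: float = 300.0,
) -> PoolTotals:
    """Cellular pool sizes: 300 nM Cul1, 660 nM total SR, 390 nM Cand1."""
    return PoolTotals(
        cul1_total=cul1_total,
        cand1_total=cand1_total,
        sr_totals=(sr1_total, sr2_total),
    )
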