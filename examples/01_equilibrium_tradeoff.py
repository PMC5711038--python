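"""Steady-state occupancy versus receptor-exchange speed.

Solves the binding-only exchange cycle at the cellular pool sizes
(300 nM Cul1, 100 + 560 nM receptors, 390 nM Cand1) and reports the
SCF occupancy [Cul1.SR1], the exchange rate |rho_l| from the leading
Jacobian eigenvalue, and how both move along a Cand1 dose grid.
"""

import numpy as np

import srexchange as sx

params = sx.cellular_parameters()
totals = sx.cellular_totals()  # SR1 100, SR2 560, Cand1 390, Cul1 300 nM

ss = sx.solve_equilibrium(params, totals, cross_check=True)
print(f"[Cul1.SR1] at steady state : {ss.occupancy('Cul1.SR1'):.2f} nM")
print(f"exchange rate |rho_l|      : {ss.exchange_rate:.3f} 1/s")
print(f"exchange timescale tau_s   : {ss.tau_s:.1f} s")
print(f"slope f (low-dose approx.) : {sx.slope_f(params, totals):.3f}")
print(f"high-dose rate limit       : "
      f"{sx.exchange_rate_high_limit(params, totals):.2f} 1/s")

curves = sx.tradeoff_scan(params, totals,
                          cand1_grid=np.logspace(0, 4, 15))
c = curves[0]
print("\nCand1_T (nM)  [Cul1.SR1] (nM)  |rho_l| (1/s)")
for ca, occ, rate in zip(c.cand1_grid, c.occupancy, c.exchange_rate):
    print(f"{ca:12.1f}  {occ:15.2f}  {rate:12.2e}")
print("\nHigh occupancy and fast exchange are mutually exclusive: raising "
      "the exchange-factor dose speeds up receptor exchange at the cost "
      "of assembled-ligase abundance.")
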