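# Methods

## Model

The package models the competition of substrate receptors (SRs) for the
Cul1 scaffold of SCF-type cullin-RING ligases and its catalysis by the
exchange factor Cand1. Each receptor participates in a thermodynamic
cycle of four reversible binding reactions (see README); because the
free energy of the ternary complex Cul1·Cand1·SR cannot depend on the
assembly order, the four dissociation constants obey detailed balance,
`K_ca·K_sr' = K_ca'·K_sr`. The cycle is summarised by three
dimensionless factors: the affinity preference `η = K_ca/K_sr =
K_ca'/K_sr'` and the rate ratios `α = k_ca/k_sr`, `β = k_ca'/k_sr'`.

Dynamics are deterministic mass action. The state vector holds complex
concentrations (plus free substrate, which is depleted by degradation);
free Cul1, Cand1 and each SR are eliminated algebraically through the
conservation relations. This reproduces the canonical five-ODE reduced
form of the two-receptor cycle and guarantees conservation of every
component pool to machine precision along any trajectory (verified in
the tests). Association rate constants are always derived as
(dissociation rate)/(dissociation constant).

### Default parameters

Concentrations in nM, time in seconds; substrate `kon` is accepted in
M⁻¹s⁻¹ and converted internally.

| quantity | default | meaning |
|---|---|---|
| K_sr, k_sr | 2.25e-4 nM, 9e-7 s⁻¹ | Cul1·SR binary dissociation |
| K_sr', k_sr' | 650 nM, 1.3 s⁻¹ | SR release from the ternary complex |
| K_ca', k_ca' | 50 nM, 0.04 s⁻¹ | Cand1 release from the ternary complex |
| K_ca, k_ca | 1.73e-5 nM, 1e-5 s⁻¹ | Cul1·Cand1 binary dissociation |
| Cul1_T, SR_T, Cand1_T | 300, 660, 390 nM | cellular pools |
| kon, koff | 1e8 M⁻¹s⁻¹, 1 s⁻¹ | substrate binding (K_D = 10 nM) |
| kdeg | 0.004 s⁻¹ | lumped degradation of Cul1.SR.S |

The published constants are rounded to 2–3 significant figures, which
leaves a relative cycle residual of ≈ 4.4e-4. Inside the network
builder the shared Cand1 affinity is therefore recomputed exactly as
`K_ca = η·K_sr` with `η = K_ca'/K_sr'`, so that the binding-only steady
state is a true thermodynamic equilibrium and the algebraic and
ODE-relaxation routes agree to 1e-6. User-facing parameters keep the
printed values; a residual above 1e-3 is rejected as inconsistent.

### Substrate binding topologies and the neddylation proxy

Substrate binding is context-independent (one kon/koff per substrate
wherever it binds), which preserves detailed balance in every added
cycle. Three topologies exist:

- **sequential** (default): substrate binds only the assembled ligase
  Cul1.SR; optionally also the ternary complex (`binds_ternary`).
- **random order**: substrate additionally binds the free receptor, and
  the SR·S dimer binds Cul1 and Cul1·Cand1 with the receptor's own
  constants.

Degradation always proceeds only from Cul1.SR.S. Neddylation — which in
vivo blocks Cand1 binding to substrate-engaged, Nedd8-conjugated
ligases — is represented by one of two proxies:

1. **Shielding** (default; degradation pipeline): no reaction couples
   Cand1 to any substrate-loaded species. This kinetic ratchet is what
   lets the engaged-ligase pool transiently overshoot its equilibrium
   value (repertoire remodeling) and produces the optimal-dose minimum.
2. **Degradation-restriction** (`cand1_exchange_on_loaded`; architecture
   comparison): Cand1 exchange on the loaded complex stays active
   (k_ca', K_ca') and only degradation is restricted to the Cand1-free
   complex. All extended cycles then satisfy detailed balance exactly.

The two proxies are genuinely different models and give different
quantitative answers; which one each analysis uses follows the scheme
of the corresponding in-silico experiment (see "Design choices").

## Numerics

- **Integration**: implicit BDF with the analytic reduced Jacobian,
  rtol 1e-8, atol 1e-12 nM. The implied rates span ~12 orders of
  magnitude (association up to 0.58 nM⁻¹s⁻¹ against k_sr = 9e-7 s⁻¹),
  so the system is stiff; half-lives shift by < 0.1% when tolerances
  are tightened a further two orders.
- **Equilibrium**: for binding-only networks the steady state is a
  thermodynamic equilibrium; each complex is a formation constant times
  a product of free component concentrations, and the conservation
  system is solved by Newton root-finding in log-concentration space
  (several deterministic restarts; residual < 1e-11 relative). ODE
  relaxation from the empty state (horizon 1e9 s ≫ 1/k_sr) is the
  independent cross-check and fallback.
- **Exchange rate**: |Re| of the leading (largest-real-part, nonzero)
  eigenvalue of the reduced Jacobian at the steady state. The reduced
  system carries no structural zero modes; eigenvalues below 1e-12 of
  the spectral scale are excluded defensively.
- **Half-life**: first crossing of S_T(0)/2 located by Brent
  root-finding on the solver's dense output; runs that do not reach
  half-degradation by t_max are flagged censored. S_T counts free plus
  all bound substrate.
- **Dose optimum**: grid argmin refined by golden-section search to
  ~1 nM between the neighbouring grid points; a minimum at zero dose
  classifies the curve as monotone.
- **γ-matching**: scalar Brent root-finding on log10(γ) in [1, 1e12]
  for equal pre-stimulus [Cul1.SR1]; occupancy is strictly decreasing
  in γ so the root is unique.
- **Exponential fit**: nonlinear least squares of A(1−e^(−kt))+c on the
  0.5 s resampled trace with the first 5 s discarded (the multi-step
  onset is not exponential).
- **Pre-equilibration** is always the exact algebraic equilibrium, not
  a fixed-duration burn-in.

## Closed-form approximations

The low-dose occupancy law `[Cul1.SR1] ≈ (SR1_T/SR_T)(Cul1_T −
f·Cand1_T)` with slope `f = (K_sr'+SR_T−Cul1_T)/(K_sr' +
(1+ηK_sr'/Cul1_T)(SR_T−Cul1_T))` (f ≈ 0.94 at defaults, always in
(0,1)), the high-dose power law `∝ 1/Cand1_T`, and the two
exchange-rate limits are implemented as stated closed forms. They are
leading-order asymptotics: measured against the numeric equilibrium the
high-dose occupancy law is ~17% low at 10× Cul1_T (improving with
dose), and the low-dose rate formula carries a systematic ~25%
prefactor offset while capturing the dose dependence; the high-dose
rate limit (≈1.65 s⁻¹) agrees with the numeric eigenvalue to < 10% at
10⁴ nM. Tests assert these measured accuracies, not idealised ones.

## Synthetic data

The generator samples a deterministic trajectory on a uniform grid and
adds i.i.d. Gaussian noise (absolute or fraction-of-amplitude), clipping
negatives at zero with the clipped fraction reported. One seeded
generator per experiment spawns per-replicate substreams, so recovery
tables are bit-reproducible from (seed, config). Real fluorescence data
additionally contain drift, photobleaching and correlated noise; passing
recovery tests therefore demonstrates estimator correctness under the
model's own assumptions, not robustness to real instrument artefacts.
The kca'-recovery estimator inverts the precomputed monotone
kca' → k_obs map by interpolation, which is equivalent to per-replicate
root-finding at a fraction of the cost.

## Design choices

- The architecture comparison holds the natural (+Cand1, γ=1) system
  fixed as its reference: substrate is scaffold-routed (binds Cul1.SR1
  and the ternary complex) with the degradation-restriction proxy, while
  the weak-binding (−Cand1, matched γ) architecture carries the binding
  topology under comparison. Running both architectures with the
  random-order topology instead makes them thermodynamically equivalent
  (no redistribution in either, ratio ≈ 1): under context-independent
  binding the substrate's free energy is available on and off the
  scaffold alike, so the comparison would not probe the trapping
  mechanism it is designed to expose.
- The degradation pipeline (optimal dose, remodeling, hierarchy) uses
  the shielding proxy with substrate binding to Cul1.SR only, the
  scheme of the corresponding experiment. Under this scheme the peak
  engaged-pool fold increase at 100 nM Cand1 computes to 2.80 (the
  degradation-restriction proxy yields 2.50 but is inconsistent with
  the 48/28/95-min half-life triple, which pins the shielding scheme).
- The exchange-assay simulation pre-equilibrates Cand1 with the blocked
  scaffold (Cul1·SR2) before the reporter receptor is added; only then
  does kca' = 0.04 s⁻¹ reproduce k_obs ≈ 0.07 s⁻¹. The reporter amount
  is not constrained by the assay description; the default 70 nM is
  symmetric with the scaffold, and k_obs moves < 15% across 35–140 nM.
- Hierarchy variants modify exactly one asymmetry against a symmetric
  reference; the receptor-affinity variant scales k_sr and k_sr'
  jointly 5-fold so every cycle still closes. The unequal-abundance
  variant defaults to a 30/90 nM split (the source analysis states no
  numbers); it is configurable.
- In-memory containers are plain dataclasses plus pandas DataFrames for
  tabular output; configs are YAML; all file output is TSV/JSON.

## Problem sizes

All analyses are desk-scale: ODE systems of 5–12 states, single
integrations of 1e4–1e6 s of model time, dose scans of ~20 grid points,
and recovery suites of ~20 replicates. The full test suite runs in a
few minutes on one CPU; the acceptance script in a few seconds.

## Known limitations

- No explicit neddylation/deneddylation, E2/ubiquitin-chain or
  proteasome kinetics: everything downstream of substrate engagement is
  lumped into kdeg.
- Deterministic mass action only; no stochastic (Gillespie) engine, so
  low-copy-number effects are out of scope.
- One substrate per receptor; substrates do not compete for the same
  receptor.
- The two neddylation proxies bracket, but do not resolve, the true
  coupling between substrate load and Cand1 accessibility.
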