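# Methods

## Model

The package simulates a community of `m` competing microbial species in a
well-mixed, dilution-limited habitat (a chemostat-like setting) in which
every species carries a mobile genetic element (MGE) that it can pass to
its competitors by horizontal gene transfer (HGT).

Without transfer, the dynamics are generalized Lotka–Volterra competition
with dilution:

    ds_i/dt = mu_i s_i (1 − s_i − Σ_{j≠i} γ_ji s_j) − D s_i

with carrying-capacity-normalized abundances `s_i`, growth rates `mu_i`
(1/h), competition strengths `γ_ji` (the inhibition species `j` exerts on
`i`, dimensionless; self-limitation is 1), and the dilution rate `D`
(1/h). For two species, the outcome is determined in closed form by
`φ_i = (mu_i − D)/mu_i`: stable coexistence holds exactly when
`γ₁ < φ₂/φ₁ < 1/γ₂` (with both `φ` positive). That closed form, and the
associated fixed point obtained from a 2×2 linear solve, are implemented
in `hgtlv.analytic` and used as exact oracles throughout the test suite.

With transfer, each growth rate decomposes into a basal part `mu_i⁰`
(non-mobilizable genome) and the fitness effect of the mobilizable part,
`lam`: by default multiplicatively, `mu_i = mu_i⁰ (1 + λ_ii)`, with an
additive variant (`mu_i = mu_i⁰ + λ_ii`) selectable via the
`composition` switch. `λ_ij` is the effect of the species-`j`-originated
element in host `i`; positive values are benefits, negative values
burdens, and host-independent effects (constant columns) are the default.
Transconjugant subpopulations `p_ij` (cells of species `i` carrying the
`j`-originated element; `p_ii ≡ s_i` by convention and never integrated)
obey

    dp_ij/dt = mu_i (1 + λ_ij) [Π_{k≠i,j} (1 + λ_ik p_ik/s_i)] p_ij C_i
               + (s_i − p_ij) Σ_k η_jki p_kj − (D + κ_ij) p_ij,

where `C_i` is the shared competition factor, `η_jki` the transfer rate
of the `j`-originated element from donor species `k` to recipient `i`
(1/h; the donor sum runs over *all* carriers, including the origin
species `p_jj = s_j` and the recipient's own transconjugants), and
`κ_ij` the segregation-loss rate. Penetrance of foreign elements makes
the species-level growth rate dynamic:

    mu_i^e = mu_i Π_{j≠i} (1 + λ_ij p_ij/s_i).

For `m = 2` these equations reduce term by term to the classic
four-equation two-species system, which the tests verify against an
independently transcribed oracle. Model transfer rates relate to
empirically measured conjugation rates `η^c` (mL cell⁻¹ h⁻¹) through the
carrying capacity: `η = η^c · N_m` (`convert_empirical_rate`).

## Standard constants and protocols

Unless stated otherwise: `D = 0.2/h`, `κ = 0.005/h`, `mu⁰ = 0.5/h`,
survival threshold `0.01`, initial abundances equal and summing to 1
(`(0.5, 0.5)` for pairs), no initial transconjugants. Two-species
feasibility protocols use `γ = 0.99` (or a scanned set) with
`mu ~ U(0, 1)` i.i.d.; multi-species protocols use `γ_ij = 0.9` with
`mu ~ U(0.4, 0.6)` and host-independent `λ` derived from the drawn rates
(`λ_ji = mu_i/mu_i⁰ − 1`). Coexistence feasibility is the fraction of
growth-rate draws for which every species ends above the survival
threshold at steady state; its uncertainty is the binomial standard
error.

## Numerical choices

* **Integrator.** `scipy.integrate.solve_ivp` with LSODA, `rtol = 1e-8`,
  `atol = 1e-10` — tight enough to resolve outcomes at the 0.01
  threshold. Integration is deterministic; all randomness lives in
  parameter draws.
* **Steady-state targeting.** The nominal horizon is 200 h, but
  competitive exclusion near a phase boundary can take thousands of
  hours, so outcome-classification protocols integrate under an early-
  stopping steady-state event (RMS derivative norm below `1e-8`/h) with
  an extended cap of 20 000 h. `reached_steady` certifies the final RHS
  norm. Both the cap and the event are caller-controllable.
* **Non-negativity.** States are clipped at zero (and penetrance to
  [0, 1]) only inside derivative evaluation, never in stored
  trajectories, preserving the solver's error control.
* **Saturation boundary.** On `p_ij ≥ s_i` the RHS evaluates the exact
  boundary dynamics `dp_ij/dt = ds_i/dt − κ_ij p_ij`, which the interior
  form approaches continuously. This keeps `0 ≤ p_ij ≤ s_i` exact even
  after solver overshoot of an extinction (otherwise a residual
  subpopulation of an extinct species can regrow unphysically).
* **Tie-breaks.** Analytic classification treats boundary equalities
  (ratio exactly `γ₁` or `1/γ₂`) as non-coexistence; they are
  measure-zero under the continuous growth-rate distributions used.
* **Analytic feasibility integral.** For uniform growth-rate
  distributions the 2-D probability reduces exactly to a 1-D quadrature
  (inner interval inverted in closed form through the monotone map
  `mu ↦ φ`), accurate to well below 1e-4; the Gaussian variant uses a
  dense truncated-normal midpoint grid over ±6 sd.

## Randomization and reproducibility

A single master seed reproduces every experiment bit-exactly. Each draw
(or replicate) receives its own `numpy.random.SeedSequence` child stream,
so results are independent of execution order; scan points derive their
seeds from `(master, m, eta-index)` so any single point can be re-run in
isolation. Fluctuation ensembles are seed-paired: the with- and
without-transfer arms consume identical duration/perturbation streams,
making paired differences meaningful replicate by replicate.

## Synthetic experiment design

All inputs are generated by the package's own randomization routines —
there is no external data. Conventions chosen where the protocol leaves
freedom (each exposed as a parameter):

* **Gaussian growth-rate variant:** mean 0.5/h, sd 0.1/h, truncated at
  zero.
* **Distribution-width experiment:** "width" is the full support `w` of
  `U(0.5 − w/2, 0.5 + w/2)`, drawn uniformly from [0, 0.5].
* **Epistasis modes:** magnitude epistasis rescales off-host effect
  magnitudes by a per-host factor `U(0.5, 1.5)`; sign epistasis flips
  off-host signs with probability 0.5 (both parameterized). The host's
  own diagonal effect is never perturbed, since it defines the carrier's
  static rate.
* **Fluctuation protocol:** interval durations exponential with mean
  25 h clipped to [1, 100] h; perturbations are relative
  (`mu ← mu (1 + U(−0.05, 0.05))`), applied to the static rates with the
  fitness effects recomputed afterwards (a frozen-`λ` alternative, where
  perturbations are absorbed by the basal rates, is behind the
  `recompute_lambda` flag). Species below `1e-6` are floored to zero
  between intervals so numerical residues cannot revive them.

These simulations emulate well-mixed communities with purely
growth-rate-mediated MGE effects. They do not emulate spatial structure,
demographic noise, resource dynamics, MGE effects on competition
strengths themselves, or MGE counts different from the species count —
so passing tests support the model's internal claims, not those
extensions.

## Problem sizes

The bundled acceptance checks run the protocols at sizes chosen for a
single-CPU workstation: 2000 draws for two-species concordance, 500–2000
per feasibility point, 100 draws per community-size point on
`m ∈ {2, 4, …, 16}`, 500 draws for the variability–diversity relation,
60 draws for rate convergence, and 10 paired fluctuation replicates over
2000 h. Draw counts scale the binomial noise only; all structural
parameters are the protocol values above.

## Known limitations

* The `m + m(m−1)` ODE system grows quadratically in species number;
  communities much beyond ~30 species become slow at the default
  tolerances.
* Near-boundary draws are intrinsically ambiguous at any finite horizon:
  exclusion times diverge at the phase boundary, so a sliver of
  parameter space around it is classified by the steady-state cap rather
  than by true asymptotics.
* Washout draws (`mu_i ≤ D`) stay in the feasibility denominator, per
  the standard protocol; feasibility under distributions concentrated
  near `D` is therefore sensitive to that convention.
* The analytic module covers two species only; multi-species feasibility
  is simulation-only.
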