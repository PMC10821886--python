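# hgtlv

**Lotka–Volterra competition with horizontal gene transfer: simulation and
coexistence-feasibility analysis.**

Classic competition theory predicts a hard limit on the diversity of
competing species: in a generalized Lotka–Volterra (gLV) community the
fraction of growth-rate combinations that lets everyone coexist —
the *coexistence feasibility*, a structural-stability measure — collapses
to zero as the number of competitors grows. Real microbial communities
violate this prediction cheerfully. One thing classic theory ignores is
that microbes trade genes: mobile genetic elements (plasmids, ICEs) carry
growth benefits or burdens between competitors, making fitness *dynamic*
on ecological timescales.

`hgtlv` implements a gLV extension in which every species carries an MGE
with fitness effect `λ` and passes it to competitors at rate `η`,
creating transconjugant subpopulations `p_ij` whose penetrance modulates
each species' effective growth rate

```
mu_i^e = mu_i · Π_{j≠i} (1 + λ_ij · p_ij / s_i),
ds_i/dt = mu_i^e s_i (1 − s_i − Σ_{j≠i} γ_ji s_j) − D s_i,
```

plus the transfer/loss kinetics of every `p_ij`. The library is aimed at
theoretical ecologists and microbiome engineers who want to quantify when
gene flow rescues diversity: it provides exact two-species theory
(`γ₁ < φ₂/φ₁ < 1/γ₂` with `φ_i = (mu_i − D)/mu_i`), steady-state ODE
simulation, Monte-Carlo feasibility ensembles and diversity-limit scans,
effective-growth-rate convergence experiments, and a paired
fluctuation protocol testing diversity robustness under random
growth-rate perturbations. Outcome diversity is reported as the
exponential Shannon index (Hill number of order 1).

## Worked example

```python
import numpy as np
from hgtlv import (CommunityModel, CommunityState, integrate,
                   classify_two_species, analytic_feasibility_2sp,
                   EnsembleSpec, estimate_feasibility, shannon_index)

# Two competitors, strong symmetric competition, no transfer:
print(classify_two_species(mu1=0.5, mu2=0.55, gamma1=0.99, gamma2=0.99, D=0.2))
# OutcomeLabel.S2_WINS   -- the 10% faster grower excludes the slower one

# Same pair, but the species exchange their elements at eta = 0.1/h:
model = CommunityModel.from_growth_rates(
    [0.5, 0.55], mu0=0.5, gamma=0.99, eta=0.1, kappa=0.005, D=0.2)
res = integrate(model, CommunityState(s=[0.5, 0.5]), t_max=20000.0)
print(res.survivors, np.round(res.final_state.s, 3))
# frozenset({0, 1}) [0.221 0.417]   -- gene flow rescues coexistence

# How much of growth-rate space coexists? Exact integral vs Monte Carlo:
print(round(analytic_feasibility_2sp(0.99, 0.99, 0.2), 4))
# 0.0228   -- without transfer, 2.3% of mu-combinations coexist
est = estimate_feasibility(EnsembleSpec(
    m=2, gamma=0.99, eta=0.1, n_draws=500, seed=1, t_max=20000.0))
print(f"{est.feasibility:.3f} +/- {est.se:.3f}")
# 0.298 +/- 0.020   -- with eta = 0.1/h, thirteen-fold more

print(round(shannon_index(res.final_state.s), 3))
# 1.906   -- effective species count of the rescued pair
```

The same machinery scales to `m`-species communities
(`feasibility_vs_species_number`, `diversity_limit`) and to the
fluctuation protocol (`run_fluctuation_ensemble`), which pairs
with/without-transfer replicates on shared perturbation seeds.

## Command line

Every experiment is also a subcommand writing CSV tables plus a JSON
manifest (full resolved configuration, master seed, package version) so
any run can be reproduced bit-exactly:

```bash
hgtlv feasibility --m 2 --gamma 0.99 --eta 0.1 --n-draws 500 --seed 1 --out runs/f1
hgtlv feasibility-scan --m-min 2 --m-max 16 --m-step 2 --eta 0 --eta 0.2 --out runs/scan
hgtlv fluctuate --m 20 --replicates 50 --eta 0.2 --magnitude 0.05 --out runs/fluc
hgtlv analytic --gamma1 0.99 --gamma2 0.99 --out runs/ana
```

Model constants can come from a YAML/JSON config (`--config`); defaults
are the standard protocol constants (`D=0.2/h`, `κ=0.005/h`, `γ=0.9`,
`mu⁰=0.5/h`, threshold 0.01).

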