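"""Monte-Carlo ensembles over randomized growth rates.

Coexistence feasibility — the structural-stability measure used throughout
the package — is the fraction of growth-rate combinations, drawn from a
stated distribution, for which every species in the community persists
above the 0.01 survival threshold at steady state. The ensembles here
estimate that fraction by direct simulation, scan it against community
size (locating the diversity limit N*), and probe the mechanism: the
dependence of steady-state diversity on growth-rate spread, and the
convergence of effective growth rates under gene transfer.

Reproducibility: every draw integrates a deterministic ODE; all randomness
lives in the parameter draws. One independent RNG stream per draw is
derived from (master seed, draw index) via ``numpy.random.SeedSequence``
spawning, so results are bit-identical regardless of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .diversity import shannon_index, survivor_count
from .errors import EnsembleError, IntegrationError, ParameterError
from .model import CommunityModel, CommunityState, effective_growth_rates
from .simulate import integrate

__all__ = [
    "EnsembleSpec",
    "FeasibilityEstimate",
    "sample_growth_rates",
    "fitness_effects_from_rates",
    "estimate_feasibility",
    "feasibility_vs_species_number",
    "diversity_limit",
    "diversity_vs_rate_spread",
    "rate_convergence_experiment",
    "derive_seed",
]

MAX_FAILURE_FRACTION = 0.01


def derive_seed(master: int, *keys: int) -> int:
    """Deterministic sub-seed from a master seed plus integer role keys.

    Used to give every (species-number, transfer-rate) point of a scan its
    own reproducible stream while a single master seed reproduces the whole
    experiment. Returned value fits in 31 bits.
    """
    ss = np.random.SeedSequence([int(master), *map(int, keys)])
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


@dataclass
class EnsembleSpec:
    """Full specification of one feasibility ensemble.

    Growth rates are i.i.d. per species: ``uniform`` on ``mu_range`` or
    ``gaussian`` with ``(mu_mean, mu_sd)`` truncated at zero (the Gaussian
    moments are a package convention, exposed to the user). Remaining model
    constants are shared across draws. ``epistasis_mode`` controls whether
    an element's fitness effect depends on the host genome: ``none`` (host-
    independent), ``magnitude`` (per-host rescaling preserving sign, jitter
    factor uniform on 1 +/- ``epistasis_spread``), or ``sign`` (per-host
    sign flips with probability ``sign_flip_prob``).
    """

    m: int = 2
    distribution: str = "uniform"
    mu_range: tuple = (0.0, 1.0)
    mu_mean: float = 0.5
    mu_sd: float = 0.1
    n_draws: int = 2000
    seed: int = 0
    mu0: float = 0.5
    gamma: float = 0.9
    eta: float = 0.0
    kappa: float = 0.005
    D: float = 0.2
    composition: str = "multiplicative"
    epistasis_mode: str = "none"
    epistasis_spread: float = 0.5
    sign_flip_prob: float = 0.5
    truncate_above_D: bool = False
    t_max: float = 200.0
    threshold: float = 0.01

    def __post_init__(self):
        if self.n_draws < 1:
            raise ParameterError("n_draws must be >= 1")
        if self.distribution not in ("uniform", "gaussian"):
            raise ParameterError(f"unknown distribution {self.distribution!r}")
        if self.distribution == "uniform":
            lo, hi = self.mu_range
            if not (0 <= lo < hi):
                raise ParameterError("mu_range must satisfy 0 <= lo < hi")
        elif self.mu_sd <= 0:
            raise ParameterError("mu_sd must be positive")
        if self.epistasis_mode not in ("none", "magnitude", "sign"):
            raise ParameterError(f"unknown epistasis_mode {self.epistasis_mode!r}")
        if not 0 <= self.epistasis_spread < 1:
            raise ParameterError("epistasis_spread must be in [0, 1)")


@dataclass
class FeasibilityEstimate:
    """Feasibility fraction with binomial uncertainty and audit records."""

    n_draws: int
    n_coexist: int
    feasibility: float
    se: float
    settings: dict
    records: pd.DataFrame = field(repr=False)
    n_failures: int = 0


def sample_growth_rates(spec: EnsembleSpec, rng: np.random.Generator) -> np.ndarray:
    """One i.i.d. growth-rate vector per the spec's distribution.

    With ``truncate_above_D`` draws below the dilution rate are rejected
    (off by default: the standard protocols keep non-viable draws in the
    denominator).
    """
    if spec.distribution == "uniform":
        lo, hi = spec.mu_range
        mu = rng.uniform(lo, hi, size=spec.m)
        floor = spec.D if spec.truncate_above_D else 0.0
        while np.any(mu <= floor):
            bad = mu <= floor
            mu[bad] = rng.uniform(lo, hi, size=int(bad.sum()))
    else:
        mu = rng.normal(spec.mu_mean, spec.mu_sd, size=spec.m)
        floor = spec.D if spec.truncate_above_D else 0.0
        while np.any(mu <= floor):
            bad = mu <= floor
            mu[bad] = rng.normal(spec.mu_mean, spec.mu_sd, size=int(bad.sum()))
    return mu


def fitness_effects_from_rates(
    mu,
    mu0,
    composition: str = "multiplicative",
    epistasis_mode: str = "none",
    rng: np.random.Generator | None = None,
    *,
    spread: float = 0.5,
    flip_prob: float = 0.5,
) -> np.ndarray:
    """Fitness-effect matrix lam[host, origin] implied by the drawn rates.

    The element carried by species j has the base effect
    ``mu_j / mu0_j - 1`` (multiplicative) or ``mu_j - mu0_j`` (additive).
    With no epistasis the effect is host-independent (constant columns).
    Magnitude epistasis rescales the off-host magnitudes per host without
    changing signs; sign epistasis flips off-host signs at random. The
    host's own diagonal entry is never perturbed — it is what defines the
    carrier's static growth rate.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    m = mu.shape[0]
    mu0 = np.broadcast_to(np.asarray(mu0, dtype=float), (m,))
    if composition == "multiplicative":
        base = mu / mu0 - 1.0
    elif composition == "additive":
        base = mu - mu0
    else:
        raise ParameterError(f"unknown composition {composition!r}")
    lam = np.tile(base, (m, 1))
    if epistasis_mode == "none":
        return lam
    if rng is None:
        raise ParameterError("epistasis modes require an rng")
    off = ~np.eye(m, dtype=bool)
    if epistasis_mode == "magnitude":
        jitter = rng.uniform(1.0 - spread, 1.0 + spread, size=(m, m))
        lam[off] = (lam * jitter)[off]
    elif epistasis_mode == "sign":
        flips = rng.random((m, m)) < flip_prob
        signs = np.where(flips, -1.0, 1.0)
        lam[off] = (lam * signs)[off]
    else:
        raise ParameterError(f"unknown epistasis_mode {epistasis_mode!r}")
    return lam


def _build_model(spec: EnsembleSpec, mu: np.ndarray, rng: np.random.Generator) -> CommunityModel:
    lam = fitness_effects_from_rates(
        mu,
        spec.mu0,
        spec.composition,
        spec.epistasis_mode,
        rng,
        spread=spec.epistasis_spread,
        flip_prob=spec.sign_flip_prob,
    )
    return CommunityModel.from_growth_rates(
        mu,
        mu0=spec.mu0,
        gamma=spec.gamma,
        eta=spec.eta,
        kappa=spec.kappa,
        D=spec.D,
        composition=spec.composition,
        lam=lam,
    )


def estimate_feasibility(spec: EnsembleSpec, *, keep_records: bool = True) -> FeasibilityEstimate:
    """Monte-Carlo coexistence feasibility for one parameter setting.

    Each draw samples a growth-rate vector, derives the implied fitness
    effects, integrates the community from equal abundances, and scores
    full coexistence (every species above threshold). Per-draw integrator
    failures are recorded; more than 1% of failed draws aborts the
    ensemble.
    """
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_draws)
    rows = []
    n_coexist = 0
    n_failures = 0
    initial = CommunityState.equal_abundances(spec.m)
    for idx, child in enumerate(children):
        rng = np.random.default_rng(child)
        mu = sample_growth_rates(spec, rng)
        model = _build_model(spec, mu, rng)
        try:
            res = integrate(
                model, initial, spec.t_max, threshold=spec.threshold
            )
        except IntegrationError as exc:
            n_failures += 1
            rows.append(
                {"draw": idx, "coexist": False, "failed": True, "error": str(exc)}
            )
            continue
        coexist = len(res.survivors) == spec.m
        n_coexist += int(coexist)
        if keep_records:
            # integrator residues can sit a few ulp below zero; diversity is
            # computed on the physically meaningful non-negative abundances
            s = np.clip(res.final_state.s, 0.0, None)
            rec = {
                "draw": idx,
                "coexist": coexist,
                "failed": False,
                "n_survivors": len(res.survivors),
                "min_final_abundance": float(s.min()),
                "std_mu": float(np.std(mu)),
                "shannon_raw": shannon_index(s) if s.sum() > 0 else np.nan,
                "shannon_surviving": (
                    shannon_index(np.where(s > spec.threshold, s, 0.0))
                    if np.any(s > spec.threshold)
                    else np.nan
                ),
                "reached_steady": res.reached_steady,
            }
            rec.update({f"mu_{i}": float(v) for i, v in enumerate(mu)})
            rows.append(rec)
    if n_failures > MAX_FAILURE_FRACTION * spec.n_draws:
        raise EnsembleError(
            f"{n_failures}/{spec.n_draws} draws failed integration"
        )
    f = n_coexist / spec.n_draws
    se = float(np.sqrt(f * (1 - f) / spec.n_draws))
    return FeasibilityEstimate(
        n_draws=spec.n_draws,
        n_coexist=n_coexist,
        feasibility=f,
        se=se,
        settings=asdict(spec),
        records=pd.DataFrame(rows),
        n_failures=n_failures,
    )


def feasibility_vs_species_number(
    template: EnsembleSpec,
    m_values=tuple(range(2, 27)),
    etas=(0.0, 0.1, 0.2),
    *,
    keep_records: bool = False,
):
    """Feasibility curve over community size, one curve per transfer rate.

    Each (m, eta) point runs a full :func:`estimate_feasibility` ensemble
    whose seed is derived from the template's master seed via
    :func:`derive_seed` — re-running a single point with that derived seed
    reproduces it exactly. Returns ``(curve, estimates)``: a tidy DataFrame
    of feasibility per point and the underlying estimate objects keyed by
    ``(m, eta)`` (these carry the per-draw Shannon indices when
    ``keep_records``).
    """
    import dataclasses as _dc

    rows = []
    estimates = {}
    for ei, eta in enumerate(etas):
        for m in m_values:
            spec = _dc.replace(
                template, m=int(m), eta=float(eta),
                seed=derive_seed(template.seed, int(m), ei),
            )
            est = estimate_feasibility(spec, keep_records=keep_records)
            estimates[(int(m), float(eta))] = est
            rows.append(
                {
                    "m": int(m),
                    "eta": float(eta),
                    "n_draws": est.n_draws,
                    "n_coexist": est.n_coexist,
                    "feasibility": est.feasibility,
                    "se": est.se,
                }
            )
    return pd.DataFrame(rows), estimates


BEYOND_RANGE = "beyond_range"


def diversity_limit(feasibility, m_values, epsilon: float | None = None):
    """Diversity limit N*: smallest community size whose feasibility is ~zero.

    ``epsilon`` defaults to one observed coexistence event in the ensemble
    (1/n is impossible to know here, so pass it explicitly when the curve
    does not carry draw counts); any feasibility strictly below epsilon
    counts as zero. Returns the sentinel :data:`BEYOND_RANGE` when the
    curve never crosses.
    """
    feasibility = np.asarray(feasibility, dtype=float)
    m_values = np.asarray(m_values)
    if feasibility.shape != m_values.shape:
        raise ParameterError("feasibility and m_values must have matching shapes")
    if epsilon is None:
        epsilon = 1e-12
    below = feasibility < epsilon
    if not below.any():
        return BEYOND_RANGE
    return int(m_values[int(np.argmax(below))])


def _sample_width_rates(m, rng, *, mu_center=0.5, width_max=0.5):
    """Growth rates uniform on a random-width window around mu_center."""
    width = rng.uniform(0.0, width_max)
    mu = rng.uniform(mu_center - width / 2.0, mu_center + width / 2.0, size=m)
    return mu, width


def diversity_vs_rate_spread(
    m: int = 20,
    n_draws: int = 5000,
    *,
    seed: int = 0,
    width_max: float = 0.5,
    mu_center: float = 0.5,
    gamma: float = 0.9,
    D: float = 0.2,
    t_max: float = 200.0,
    threshold: float = 0.01,
) -> pd.DataFrame:
    """Steady-state diversity against growth-rate spread (classic LV, no HGT).

    Per draw, a uniform distribution width is itself drawn uniformly on
    [0, ``width_max``]; species rates are sampled from that window around
    ``mu_center``; the community is integrated without transfer and the
    realized std of the drawn rates is recorded next to the steady-state
    Shannon index (raw and survivor-thresholded variants).
    """
    children = np.random.SeedSequence(seed).spawn(n_draws)
    initial = CommunityState.equal_abundances(m)
    rows = []
    for idx, child in enumerate(children):
        rng = np.random.default_rng(child)
        mu, width = _sample_width_rates(m, rng, mu_center=mu_center, width_max=width_max)
        model = CommunityModel.from_growth_rates(
            mu, mu0=mu_center, gamma=gamma, eta=0.0, kappa=0.0, D=D
        )
        res = integrate(model, initial, t_max, threshold=threshold)
        s = np.clip(res.final_state.s, 0.0, None)
        rows.append(
            {
                "draw": idx,
                "width": width,
                "std_mu": float(np.std(mu)),
                "shannon_raw": shannon_index(s) if s.sum() > 0 else np.nan,
                "shannon_surviving": (
                    shannon_index(np.where(s > threshold, s, 0.0))
                    if np.any(s > threshold)
                    else np.nan
                ),
                "n_survivors": survivor_count(s, threshold),
            }
        )
    return pd.DataFrame(rows)


def rate_convergence_experiment(
    etas=(0.05, 0.1, 0.2),
    m: int = 20,
    n_draws: int = 100,
    *,
    seed: int = 0,
    width_max: float = 0.5,
    mu_center: float = 0.5,
    gamma: float = 0.9,
    kappa: float = 0.005,
    D: float = 0.2,
    t_max: float = 200.0,
) -> pd.DataFrame:
    """Convergence of effective growth rates under gene transfer.

    For each transfer rate, the same growth-rate draws (paired across
    rates via shared per-draw seeds) are integrated with HGT and the
    standard deviation of the steady-state effective growth rates mu^e is
    recorded — over all species and over the surviving subset. Gene flow
    homogenizes fitness, so the spread shrinks as eta grows; at eta = 0 it
    equals the spread of the drawn static rates exactly.
    """
    children = np.random.SeedSequence(seed).spawn(n_draws)
    initial = CommunityState.equal_abundances(m)
    rows = []
    for eta in etas:
        for idx, child in enumerate(children):
            rng = np.random.default_rng(child)
            mu, width = _sample_width_rates(
                m, rng, mu_center=mu_center, width_max=width_max
            )
            model = CommunityModel.from_growth_rates(
                mu, mu0=mu_center, gamma=gamma, eta=float(eta), kappa=kappa, D=D
            )
            res = integrate(model, initial, t_max)
            mu_e = effective_growth_rates(res.final_state, model)
            alive = res.final_state.s > res.threshold
            rows.append(
                {
                    "eta": float(eta),
                    "draw": idx,
                    "std_mu": float(np.std(mu)),
                    "std_mu_e": float(np.std(mu_e)),
                    "std_mu_e_surviving": (
                        float(np.std(mu_e[alive])) if alive.any() else np.nan
                    ),
                    "n_survivors": int(alive.sum()),
                }
            )
    return pd.DataFrame(rows)
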