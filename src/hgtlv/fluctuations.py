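"""Piecewise-deterministic dynamics under random growth-rate perturbations.

The protocol probes whether gene transfer stabilizes diversity against
environmental fluctuation. A community starts perfectly neutral (all
species share the same growth rate and abundance). Time is split into
random intervals; within an interval the dynamics are deterministic, and
at each interval boundary every species' growth rate is multiplied by an
independent factor ``1 + u``, ``u ~ U(-magnitude, +magnitude)`` (default
magnitude 5%). Without transfer, such perturbations break neutrality and
competitive exclusion erodes diversity; with transfer, gene flow keeps
pulling effective growth rates back together.

Replicates are paired: the with- and without-HGT arms of an ensemble share
perturbation seeds, so toggling transfer changes nothing about the random
environment — only the community's response to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import shannon_index, survivor_count
from .errors import IntegrationError, ParameterError
from .model import CommunityModel, CommunityState
from .simulate import integrate

__all__ = [
    "FluctuationProtocol",
    "DiversityTrajectory",
    "FluctuationEnsemble",
    "perturb_growth_rates",
    "run_fluctuation_replicate",
    "run_fluctuation_ensemble",
]


@dataclass
class FluctuationProtocol:
    """Settings of one fluctuation experiment.

    Interval durations are exponential with mean ``mean_interval`` hours,
    clipped to ``interval_bounds`` (a convention: the protocol only asks
    for randomized durations; memoryless intervals with a mean long enough
    for a transient response are the natural default, and the parameters
    are exposed). ``recompute_lambda`` controls whether the mobile
    elements' fitness effects track the perturbed rates (default) or stay
    frozen at their initial values, in which case perturbations are
    absorbed by the basal rates.
    """

    m: int = 20
    horizon: float = 2000.0
    mean_interval: float = 25.0
    interval_bounds: tuple = (1.0, 100.0)
    magnitude: float = 0.05
    n_replicates: int = 50
    seed: int = 0
    mu_init: float = 0.5
    mu0: float = 0.5
    gamma: float = 0.9
    eta: float = 0.2
    kappa: float = 0.005
    D: float = 0.2
    composition: str = "multiplicative"
    recompute_lambda: bool = True
    extinction_floor: float = 1e-6
    threshold: float = 0.01

    def __post_init__(self):
        if not 0 <= self.magnitude < 1:
            raise ParameterError("magnitude must be in [0, 1)")
        if self.horizon <= 0:
            raise ParameterError("horizon must be positive")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")
        lo, hi = self.interval_bounds
        if not 0 < lo <= hi:
            raise ParameterError("interval_bounds must satisfy 0 < lo <= hi")


@dataclass
class DiversityTrajectory:
    """Shannon-diversity time series of one replicate."""

    replicate: int
    times: np.ndarray
    shannon: np.ndarray
    final_survivors: int
    final_state: CommunityState = field(repr=False)
    mu_final: np.ndarray = field(repr=False)
    failed_intervals: int = 0

    @property
    def final_shannon(self) -> float:
        return float(self.shannon[-1])

    def on_grid(self, grid) -> np.ndarray:
        """Diversity linearly interpolated onto a common time grid."""
        return np.interp(grid, self.times, self.shannon)


def perturb_growth_rates(mu, magnitude: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative i.i.d. perturbation: mu_i * (1 + U(-magnitude, +magnitude)).

    Relative (not additive) variation, so rates stay positive for any
    magnitude < 1.
    """
    if not 0 <= magnitude < 1:
        raise ParameterError("magnitude must be in [0, 1)")
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    return mu * (1.0 + rng.uniform(-magnitude, magnitude, size=mu.shape))


def _interval_model(protocol: FluctuationProtocol, mu, lam0, eta_val) -> CommunityModel:
    if protocol.recompute_lambda:
        return CommunityModel.from_growth_rates(
            mu,
            mu0=protocol.mu0,
            gamma=protocol.gamma,
            eta=eta_val,
            kappa=protocol.kappa,
            D=protocol.D,
            composition=protocol.composition,
        )
    # frozen fitness effects: perturbations are absorbed by the basal rates
    lam_own = np.diag(lam0)
    if protocol.composition == "multiplicative":
        mu0 = mu / (1.0 + lam_own)
    else:
        mu0 = mu - lam_own
    return CommunityModel(
        m=protocol.m, mu0=mu0, mu=mu, lam=lam0, gamma=protocol.gamma,
        eta=eta_val, kappa=protocol.kappa, D=protocol.D,
        composition=protocol.composition,
    )


def run_fluctuation_replicate(
    protocol: FluctuationProtocol,
    with_hgt: bool,
    seed,
    *,
    replicate: int = 0,
    **integrate_kwargs,
) -> DiversityTrajectory:
    """One replicate: alternate deterministic intervals and rate perturbations.

    The community state (including transconjugant subpopulations) carries
    over across intervals; after each interval, species below the
    extinction floor are set to zero so numerical residues cannot revive
    them, diversity is recorded, and the growth rates are perturbed. The
    RNG consumption per interval (one duration, one perturbation vector)
    is identical whichever arm runs, which is what makes seed-paired arm
    comparisons valid.
    """
    rng = np.random.default_rng(seed)
    m = protocol.m
    mu = np.full(m, protocol.mu_init)
    if protocol.composition == "multiplicative":
        lam0 = np.tile(mu / protocol.mu0 - 1.0, (m, 1))
    else:
        lam0 = np.tile(mu - protocol.mu0, (m, 1))
    eta_val = protocol.eta if with_hgt else 0.0
    state = CommunityState.equal_abundances(m)
    lo, hi = protocol.interval_bounds

    times = [0.0]
    diversity = [shannon_index(state.s)]
    t = 0.0
    failed = 0
    while t < protocol.horizon - 1e-9:
        duration = float(np.clip(rng.exponential(protocol.mean_interval), lo, hi))
        duration = min(duration, protocol.horizon - t)
        model = _interval_model(protocol, mu, lam0, eta_val)
        try:
            res = integrate(model, state, duration, **integrate_kwargs)
            state = res.final_state
        except IntegrationError:
            failed += 1  # keep the pre-interval state; the replicate is flagged
        s = state.s.copy()
        p = state.p.copy()
        dead = s < protocol.extinction_floor
        s[dead] = 0.0
        p[dead, :] = 0.0
        p = np.clip(p, 0.0, s[:, None])
        state = CommunityState(s=s, p=p)
        t += duration
        times.append(t)
        diversity.append(shannon_index(s) if s.sum() > 0 else np.nan)
        mu = perturb_growth_rates(mu, protocol.magnitude, rng)
    return DiversityTrajectory(
        replicate=replicate,
        times=np.asarray(times),
        shannon=np.asarray(diversity),
        final_survivors=survivor_count(state.s, protocol.threshold),
        final_state=state,
        mu_final=mu,
        failed_intervals=failed,
    )


@dataclass
class FluctuationEnsemble:
    """Paired replicate sets with and without gene transfer."""

    protocol: FluctuationProtocol
    with_hgt: list
    without_hgt: list

    def summary(self) -> pd.DataFrame:
        """Tidy per-replicate endpoint summary for both arms."""
        rows = []
        for arm, trajs in (("hgt", self.with_hgt), ("no_hgt", self.without_hgt)):
            for tr in trajs:
                rows.append(
                    {
                        "arm": arm,
                        "replicate": tr.replicate,
                        "final_shannon": tr.final_shannon,
                        "final_survivors": tr.final_survivors,
                        "failed_intervals": tr.failed_intervals,
                    }
                )
        return pd.DataFrame(rows)

    def paired_differences(self) -> np.ndarray:
        """Final-diversity difference (with HGT minus without), per seed pair."""
        return np.array(
            [a.final_shannon - b.final_shannon for a, b in zip(self.with_hgt, self.without_hgt)]
        )

    def trajectory_summary(self, n_grid: int = 81) -> pd.DataFrame:
        """Mean +/- sd diversity per arm on a common time grid."""
        grid = np.linspace(0.0, self.protocol.horizon, n_grid)
        rows = []
        for arm, trajs in (("hgt", self.with_hgt), ("no_hgt", self.without_hgt)):
            curves = np.array([tr.on_grid(grid) for tr in trajs])
            rows.append(
                pd.DataFrame(
                    {
                        "arm": arm,
                        "time": grid,
                        "mean_shannon": curves.mean(axis=0),
                        "sd_shannon": curves.std(axis=0, ddof=1) if len(trajs) > 1 else 0.0,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def run_fluctuation_ensemble(
    protocol: FluctuationProtocol, **integrate_kwargs
) -> FluctuationEnsemble:
    """Run both arms over ``n_replicates`` shared perturbation seeds."""
    children = np.random.SeedSequence(protocol.seed).spawn(protocol.n_replicates)
    with_hgt = [
        run_fluctuation_replicate(protocol, True, child, replicate=i, **integrate_kwargs)
        for i, child in enumerate(children)
    ]
    without_hgt = [
        run_fluctuation_replicate(protocol, False, child, replicate=i, **integrate_kwargs)
        for i, child in enumerate(children)
    ]
    return FluctuationEnsemble(protocol=protocol, with_hgt=with_hgt, without_hgt=without_hgt)
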