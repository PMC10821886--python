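"""Numerical integration of community dynamics and outcome classification.

Trajectories are integrated with adaptive-step solvers from
``scipy.integrate.solve_ivp`` at tight tolerances (rtol 1e-8, atol 1e-10 by
default — tight enough to resolve the 0.01 survival threshold reliably).
Integration runs to the 200 h horizon used throughout the protocols, with
an optional early stop once the dynamics are numerically at steady state
(max |d/dt| below ``steady_tol``).

A community with no transfer (eta = 0) started without transconjugants
keeps all off-diagonal subpopulations at exactly zero, so such runs
integrate only the m classic species equations; the result is identical
and much cheaper for large Monte-Carlo ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .analytic import OutcomeLabel
from .errors import IntegrationError, ParameterError
from .model import (
    CommunityModel,
    CommunityState,
    classic_rhs_flat,
    hgt_rhs_flat,
    _offdiag_indices,
)

__all__ = [
    "SimulationResult",
    "integrate",
    "classify_outcome",
    "phase_diagram",
]

DEFAULT_T_MAX = 200.0
DEFAULT_THRESHOLD = 0.01
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
DEFAULT_STEADY_TOL = 1e-8


@dataclass
class SimulationResult:
    """A completed community trajectory.

    Attributes
    ----------
    times : array (n_t,)
        Output time grid, h, strictly increasing.
    s : array (n_t, m)
        Species-abundance trajectory.
    p : array (n_t, m, m)
        Subpopulation trajectory (diagonal aliased to ``s``).
    reached_steady : bool
        Whether the RHS norm fell below ``steady_tol`` before/at the end.
    survivors : frozenset[int]
        Species with final abundance above the survival threshold.
    final_state : CommunityState
    model : CommunityModel
    threshold : float
    """

    times: np.ndarray
    s: np.ndarray
    p: np.ndarray
    reached_steady: bool
    survivors: frozenset
    final_state: CommunityState
    model: CommunityModel
    threshold: float

    @property
    def coexists(self) -> bool:
        """True when every species survives above threshold."""
        return len(self.survivors) == self.model.m


def integrate(
    model: CommunityModel,
    initial: CommunityState | None = None,
    t_max: float = DEFAULT_T_MAX,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    steady_tol: float = DEFAULT_STEADY_TOL,
    stop_at_steady: bool = True,
    threshold: float = DEFAULT_THRESHOLD,
    n_out: int = 201,
    method: str = "LSODA",
    check_invariants: bool = True,
) -> SimulationResult:
    """Integrate the community ODEs from ``initial`` up to ``t_max`` hours.

    The default initial condition is equal abundances summing to 1 with no
    transconjugants. Integration stops early when ``stop_at_steady`` and
    the max-norm of the derivative drops below ``steady_tol``.
    """
    if t_max <= 0:
        raise ParameterError("t_max must be positive")
    m = model.m
    if initial is None:
        initial = CommunityState.equal_abundances(m)
    if initial.m != m:
        raise ParameterError(f"initial state has m={initial.m}, model has m={m}")
    if check_invariants:
        initial.validate()

    rows, cols = _offdiag_indices(m)
    classic_only = (not model.has_transfer) and not np.any(initial.p[rows, cols] != 0)
    if classic_only:
        y0 = initial.s.copy()
        rhs = classic_rhs_flat
    else:
        y0 = initial.to_flat()
        rhs = hgt_rhs_flat

    events = None
    if stop_at_steady:
        # smooth (RMS) event; the max-norm certificate is re-checked on the
        # final state below
        def steady(t, y, model=model):
            f = rhs(t, y, model)
            return float(np.sqrt(np.mean(f * f))) - steady_tol

        steady.terminal = True
        steady.direction = -1
        if steady(0.0, y0) > 0:
            events = steady

    t_eval = np.linspace(0.0, t_max, n_out)

    def _solve(with_events):
        return solve_ivp(
            rhs,
            (0.0, t_max),
            y0,
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            args=(model,),
            events=events if with_events else None,
            dense_output=False,
        )

    try:
        sol = _solve(events is not None)
    except ValueError:
        # root bracketing of the event can fail when the derivative norm
        # chatters around the tolerance; the run is then already at steady
        # state for practical purposes — redo without early stopping
        sol = _solve(False)
    if sol.status == -1:
        raise IntegrationError(
            f"integrator failed: {sol.message}", state=sol.y[:, -1] if sol.y.size else y0
        )

    times = sol.t
    ys = sol.y.T
    stopped_early = sol.status == 1
    if stopped_early and sol.t_events[0].size:
        t_ev = float(sol.t_events[0][-1])
        if times.size == 0 or t_ev > times[-1]:
            times = np.append(times, t_ev)
            ys = np.vstack([ys, sol.y_events[0][-1]])
    if times.size == 0:  # t_max smaller than first grid point spacing edge case
        times = np.array([t_max])
        ys = sol.y[:, -1][None, :]

    if classic_only:
        s_traj = ys
        p_traj = np.zeros((times.size, m, m))
        p_traj[:, np.arange(m), np.arange(m)] = s_traj
    else:
        s_traj = ys[:, :m]
        p_traj = np.zeros((times.size, m, m))
        p_traj[:, rows, cols] = ys[:, m:]
        p_traj[:, np.arange(m), np.arange(m)] = s_traj

    final_state = CommunityState(s=s_traj[-1].copy(), p=p_traj[-1].copy())
    if check_invariants:
        # guards against structural violations (e.g. runaway subpopulations),
        # not solver-accuracy-scale undershoot on long horizons
        final_state.validate(tol=1e-6)

    reached_steady = stopped_early
    if not reached_steady:
        f_end = rhs(times[-1], ys[-1], model)
        reached_steady = bool(np.max(np.abs(f_end)) < steady_tol)

    survivors = frozenset(np.flatnonzero(final_state.s > threshold).tolist())
    return SimulationResult(
        times=times,
        s=s_traj,
        p=p_traj,
        reached_steady=reached_steady,
        survivors=survivors,
        final_state=final_state,
        model=model,
        threshold=threshold,
    )


def classify_outcome(result: SimulationResult, threshold: float = DEFAULT_THRESHOLD) -> frozenset:
    """Survivor set by final-state thresholding (abundance strictly above)."""
    return frozenset(np.flatnonzero(result.final_state.s > threshold).tolist())


def _label_from_survivors(survivors: frozenset) -> OutcomeLabel:
    if survivors == {0, 1}:
        return OutcomeLabel.COEXIST
    if survivors == {0}:
        return OutcomeLabel.S1_WINS
    if survivors == {1}:
        return OutcomeLabel.S2_WINS
    return OutcomeLabel.WASHOUT


def phase_diagram(
    model_template: CommunityModel,
    mu1_grid,
    mu2_grid,
    *,
    t_max: float = DEFAULT_T_MAX,
    threshold: float = DEFAULT_THRESHOLD,
    **integrate_kwargs,
):
    """Simulated outcome label for every (mu1, mu2) growth-rate cell.

    The template supplies everything except the growth rates; for each cell
    the fitness effects are re-derived from the cell's rates (host-
    independent), the system is integrated from the standard (0.5, 0.5)
    start, and the outcome is classified by survivor thresholding.

    Returns an (len(mu1_grid), len(mu2_grid)) array of
    :class:`~hgtlv.analytic.OutcomeLabel`; per-cell integration failures
    are recorded as ``None`` and reported in the companion failure list.
    """
    if model_template.m != 2:
        raise ParameterError("phase_diagram requires a two-species template")
    mu1_grid = np.asarray(mu1_grid, dtype=float)
    mu2_grid = np.asarray(mu2_grid, dtype=float)
    labels = np.empty((mu1_grid.size, mu2_grid.size), dtype=object)
    failures = []
    initial = CommunityState.equal_abundances(2)
    for i, mu1 in enumerate(mu1_grid):
        for j, mu2 in enumerate(mu2_grid):
            model = CommunityModel.from_growth_rates(
                [mu1, mu2],
                mu0=model_template.mu0,
                gamma=model_template.gamma,
                eta=model_template.eta,
                kappa=model_template.kappa,
                D=model_template.D,
                composition=model_template.composition,
            )
            try:
                res = integrate(
                    model, initial, t_max, threshold=threshold, **integrate_kwargs
                )
            except IntegrationError as exc:
                labels[i, j] = None
                failures.append((i, j, str(exc)))
                continue
            labels[i, j] = _label_from_survivors(res.survivors)
    return labels, failures
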