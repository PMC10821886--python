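"""Parameterization and vector fields of competitive Lotka-Volterra dynamics
with horizontal gene transfer (HGT).

The community holds ``m`` competing species. Each species ``i`` carries a
mobile genetic element (MGE) whose fitness effect on a host is ``lam``;
through conjugation-like transfer at rate ``eta`` the element spreads into
other species, creating transconjugant subpopulations ``p[i, j]`` (cells of
species ``i`` carrying the species-``j``-originated element). Growth rates
thereby become dynamic: a species' effective growth rate depends on the
penetrance ``p[i, j] / s[i]`` of every foreign element it hosts.

Dynamics (multiplicative composition, the default):

    ds_i/dt = mu_i^e * s_i * (1 - s_i - sum_{j != i} gamma[j, i] * s_j) - D * s_i
    dp_ij/dt = mu_i * (1 + lam[i, j]) * prod_{k != i, j}(1 + lam[i, k] * p_ik / s_i)
               * p_ij * (1 - s_i - sum_{j != i} gamma[j, i] * s_j)
               + (s_i - p_ij) * sum_k eta[j, k, i] * p_kj
               - (D + kappa[i, j]) * p_ij          (i != j)

with the effective growth rate

    mu_i^e = mu_i * prod_{j != i} (1 + lam[i, j] * p_ij / s_i).

The diagonal ``p[i, i]`` is by convention the species abundance ``s_i``
itself (every cell carries its own element) and is never integrated
separately; the donor sum above therefore automatically includes the
original donor species (``p_jj = s_j``) and the recipient species' own
transconjugants.

Setting every transfer rate and fitness effect to zero recovers the classic
generalized Lotka-Volterra competition model with dilution, available
directly as :func:`classic_rhs`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .errors import InvariantError, ParameterError

__all__ = [
    "CommunityModel",
    "CommunityState",
    "classic_rhs",
    "hgt_rhs",
    "effective_growth_rates",
    "convert_empirical_rate",
]

Composition = Literal["multiplicative", "additive"]

_LAM_CONSISTENCY_TOL = 1e-9


def _as_vector(x, m: int, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim == 0:
        v = np.full(m, float(v))
    if v.shape != (m,):
        raise ParameterError(f"{name}: expected scalar or shape ({m},), got {v.shape}")
    return v


def _as_matrix(x, m: int, name: str, *, diag=None) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim == 0:
        a = np.full((m, m), float(a))
    if a.shape != (m, m):
        raise ParameterError(f"{name}: expected scalar or shape ({m},{m}), got {a.shape}")
    a = a.copy()
    if diag is not None:
        np.fill_diagonal(a, diag)
    return a


def _as_transfer_tensor(eta, m: int) -> np.ndarray:
    """Normalize a transfer-rate spec to the full tensor eta[j, k, i].

    Accepted forms:
      * scalar -- uniform fully connected transfer network;
      * (m, m) matrix -- donor -> recipient rates (or an adjacency mask
        scaled by a rate), broadcast over the gene-origin axis j;
      * (m, m, m) tensor -- fully general eta[j, k, i].
    """
    a = np.asarray(eta, dtype=float)
    if a.ndim == 0:
        return np.full((m, m, m), float(a))
    if a.shape == (m, m):
        # a[k, i]: donor k -> recipient i, identical for every gene origin
        return np.broadcast_to(a[None, :, :], (m, m, m)).copy()
    if a.shape == (m, m, m):
        return a.copy()
    raise ParameterError(
        f"eta: expected scalar, ({m},{m}) donor->recipient matrix, or "
        f"({m},{m},{m}) tensor, got shape {a.shape}"
    )


@dataclass
class CommunityModel:
    """All rate parameters of the m-species HGT Lotka-Volterra system.

    Parameters
    ----------
    m : int
        Number of competing species (>= 1).
    mu0 : array (m,)
        Basal growth rates (non-mobilizable genome), 1/h.
    mu : array (m,)
        Static growth rates of species carrying their own MGE, 1/h. Under
        multiplicative composition ``mu = mu0 * (1 + diag(lam))``; under
        additive composition ``mu = mu0 + diag(lam)``.
    lam : array (m, m)
        ``lam[i, j]``: fitness effect of the species-j-originated MGE in
        host species i (dimensionless, > -1). Host-independent effects mean
        constant columns.
    gamma : array (m, m)
        ``gamma[j, i]``: competition strength species j imposes on species
        i; the diagonal (self-limitation) is fixed at 1.
    eta : array (m, m, m)
        ``eta[j, k, i]``: transfer rate of the species-j-originated element
        from donor species k to recipient species i, 1/h.
    kappa : array (m, m)
        ``kappa[i, j]``: loss (segregation) rate of the j-originated element
        from host i, 1/h.
    D : float
        Dilution rate, 1/h.
    composition : {"multiplicative", "additive"}
        How basal rate and fitness effect combine into growth rates.
    """

    m: int
    mu0: np.ndarray
    mu: np.ndarray
    lam: np.ndarray
    gamma: np.ndarray
    eta: np.ndarray
    kappa: np.ndarray
    D: float
    composition: Composition = "multiplicative"
    # cached scalar when the transfer network is uniform, else None
    _eta_scalar: float | None = field(init=False, repr=False, default=None)

    def __post_init__(self):
        m = int(self.m)
        if m < 1:
            raise ParameterError(f"m must be >= 1, got {m}")
        self.m = m
        self.mu0 = _as_vector(self.mu0, m, "mu0")
        self.mu = _as_vector(self.mu, m, "mu")
        self.lam = _as_matrix(self.lam, m, "lam")
        self.gamma = _as_matrix(self.gamma, m, "gamma", diag=1.0)
        self.eta = _as_transfer_tensor(self.eta, m)
        self.kappa = _as_matrix(self.kappa, m, "kappa")
        self.D = float(self.D)
        if self.composition not in ("multiplicative", "additive"):
            raise ParameterError(f"unknown composition {self.composition!r}")
        self._validate()
        self._eta_scalar = (
            float(self.eta.flat[0]) if np.all(self.eta == self.eta.flat[0]) else None
        )

    def _validate(self):
        problems = []
        for name in ("mu0", "mu", "eta", "kappa"):
            if np.any(getattr(self, name) < 0):
                problems.append(f"{name} must be non-negative")
        if self.D < 0:
            problems.append("D must be non-negative")
        if np.any(self.lam <= -1):
            problems.append("lam entries must be > -1")
        if np.any(self.gamma < 0):
            problems.append("gamma entries must be non-negative")
        if problems:
            raise ParameterError("; ".join(problems))
        # mu, mu0 and the diagonal of lam must agree under the composition rule
        lam_own = np.diag(self.lam)
        if self.composition == "multiplicative":
            expected = self.mu0 * (1.0 + lam_own)
        else:
            expected = self.mu0 + lam_own
        if not np.allclose(self.mu, expected, rtol=0, atol=_LAM_CONSISTENCY_TOL):
            raise ParameterError(
                "mu inconsistent with mu0 and diag(lam) under "
                f"{self.composition} composition"
            )

    @classmethod
    def from_growth_rates(
        cls,
        mu,
        *,
        mu0=0.5,
        gamma=0.9,
        eta=0.0,
        kappa=0.005,
        D=0.2,
        composition: Composition = "multiplicative",
        lam=None,
    ) -> "CommunityModel":
        """Build a model from static growth rates.

        When ``lam`` is omitted the fitness effect of each species' MGE is
        host-independent and derived from its carrier's rates:
        ``lam[:, j] = mu_j / mu0_j - 1`` (multiplicative) or
        ``mu_j - mu0_j`` (additive).
        """
        mu = np.atleast_1d(np.asarray(mu, dtype=float))
        m = mu.shape[0]
        mu0v = _as_vector(mu0, m, "mu0")
        if np.any(mu0v <= 0) and composition == "multiplicative":
            raise ParameterError("mu0 must be positive under multiplicative composition")
        if lam is None:
            if composition == "multiplicative":
                col = mu / mu0v - 1.0
            else:
                col = mu - mu0v
            lam = np.tile(col, (m, 1))
        return cls(
            m=m, mu0=mu0v, mu=mu, lam=lam, gamma=gamma, eta=eta, kappa=kappa,
            D=D, composition=composition,
        )

    def with_transfer_rate(self, eta) -> "CommunityModel":
        """Copy of the model with a different transfer network."""
        return replace(self, eta=_as_transfer_tensor(eta, self.m))

    @property
    def has_transfer(self) -> bool:
        return bool(np.any(self.eta > 0))

    @property
    def n_equations(self) -> int:
        """Length of the flat integration vector: m + m(m-1)."""
        return self.m * self.m

    def to_dict(self) -> dict:
        """JSON-serializable parameter document (full arrays, no broadcast)."""
        return {
            "m": self.m,
            "mu0": self.mu0.tolist(),
            "mu": self.mu.tolist(),
            "lam": self.lam.tolist(),
            "gamma": self.gamma.tolist(),
            "eta": self.eta.tolist(),
            "kappa": self.kappa.tolist(),
            "D": self.D,
            "composition": self.composition,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "CommunityModel":
        return cls(
            m=doc["m"], mu0=doc["mu0"], mu=doc["mu"], lam=doc["lam"],
            gamma=doc["gamma"], eta=np.asarray(doc["eta"], dtype=float),
            kappa=doc["kappa"], D=doc["D"],
            composition=doc.get("composition", "multiplicative"),
        )


def _offdiag_indices(m: int):
    rows, cols = np.where(~np.eye(m, dtype=bool))  # row-major order
    return rows, cols


@dataclass
class CommunityState:
    """Species abundances plus transconjugant subpopulations.

    ``s[i]`` is the carrying-capacity-normalized abundance of species i;
    ``p[i, j]`` the abundance of cells of species i carrying the
    j-originated MGE, with the diagonal aliased to ``s`` (``p[i, i] = s[i]``
    always, maintained by this class and never integrated).
    """

    s: np.ndarray
    p: np.ndarray | None = None

    def __post_init__(self):
        self.s = np.atleast_1d(np.asarray(self.s, dtype=float))
        m = self.s.shape[0]
        if self.p is None:
            self.p = np.zeros((m, m))
        else:
            self.p = np.asarray(self.p, dtype=float).copy()
            if self.p.shape != (m, m):
                raise ParameterError(f"p: expected shape ({m},{m}), got {self.p.shape}")
        np.fill_diagonal(self.p, self.s)

    @property
    def m(self) -> int:
        return self.s.shape[0]

    def validate(self, tol: float = 1e-8):
        if np.any(self.s < -tol):
            raise InvariantError(f"negative abundance beyond tolerance: min s = {self.s.min()}")
        if np.any(self.p < -tol):
            raise InvariantError(f"negative subpopulation beyond tolerance: min p = {self.p.min()}")
        excess = self.p - self.s[:, None]
        if np.any(excess > tol):
            raise InvariantError(
                f"subpopulation exceeds its species beyond tolerance: max p - s = {excess.max()}"
            )

    def to_flat(self) -> np.ndarray:
        """Flat integration vector: s, then off-diagonal p row-major."""
        rows, cols = _offdiag_indices(self.m)
        return np.concatenate([self.s, self.p[rows, cols]])

    @classmethod
    def from_flat(cls, y: np.ndarray, m: int) -> "CommunityState":
        y = np.asarray(y, dtype=float)
        if y.shape != (m * m,):
            raise ParameterError(f"flat state: expected length {m * m}, got {y.shape}")
        s = y[:m]
        p = np.zeros((m, m))
        rows, cols = _offdiag_indices(m)
        p[rows, cols] = y[m:]
        return cls(s=s, p=p)

    @classmethod
    def equal_abundances(cls, m: int, total: float = 1.0) -> "CommunityState":
        """Equal species abundances summing to ``total``, no transconjugants.

        For m = 2 with the default total this is the (0.5, 0.5) start used
        throughout the two-species protocols.
        """
        return cls(s=np.full(m, total / m))


def _growth_fields(s, p, model: CommunityModel):
    """Clipped state, penetrance-based growth factors, competition term.

    States are clipped at zero (and penetrance to [0, 1]) only here, for
    derivative evaluation; stored trajectories are never clipped.
    """
    s_c = np.clip(s, 0.0, None)
    p_c = np.clip(p, 0.0, None)
    np.fill_diagonal(p_c, s_c)
    denom = np.where(s_c > 0, s_c, 1.0)
    ratio = np.clip(p_c / denom[:, None], 0.0, 1.0)
    ratio[s_c <= 0, :] = 0.0
    np.fill_diagonal(ratio, 0.0)
    comp = 1.0 - s_c @ model.gamma  # diag(gamma)=1 supplies the self term
    return s_c, p_c, ratio, comp


def _effective_mu(ratio, model: CommunityModel):
    """(mu_e, per-subpopulation growth prefactor G[i, j])."""
    if model.composition == "multiplicative":
        F = 1.0 + model.lam * ratio  # diag = 1 because diag(ratio) = 0
        prodF = np.prod(F, axis=1)
        mu_e = model.mu * prodF
        G = model.mu[:, None] * (1.0 + model.lam) * (prodF[:, None] / F)
    else:
        contrib = model.lam * ratio
        tot = contrib.sum(axis=1)
        mu_e = model.mu + tot
        G = model.mu[:, None] + model.lam + (tot[:, None] - contrib)
    return mu_e, G


def effective_growth_rates(state: CommunityState, model: CommunityModel) -> np.ndarray:
    """Effective growth rates mu_i^e given current MGE penetrance.

    Equals ``mu`` when all off-diagonal penetrance or all fitness effects
    vanish; for an extinct species (s_i = 0) the static ``mu_i`` is
    returned.
    """
    _, _, ratio, _ = _growth_fields(state.s, state.p, model)
    mu_e, _ = _effective_mu(ratio, model)
    return mu_e


def classic_rhs(state: CommunityState | np.ndarray, model: CommunityModel) -> np.ndarray:
    """Right-hand side of the classic competitive LV system with dilution.

    ds_i/dt = mu_i s_i (1 - s_i - sum_{j!=i} gamma_ji s_j) - D s_i.
    Transfer and fitness-effect parameters of the model are ignored.
    """
    s = state.s if isinstance(state, CommunityState) else np.asarray(state, dtype=float)
    if s.shape != (model.m,):
        raise ParameterError(f"state: expected shape ({model.m},), got {s.shape}")
    s_c = np.clip(s, 0.0, None)
    comp = 1.0 - s_c @ model.gamma
    return model.mu * s_c * comp - model.D * s_c


def hgt_rhs(state: CommunityState, model: CommunityModel):
    """Right-hand side of the HGT-extended system.

    Returns ``(ds, dp)`` where ``dp`` is the full matrix of subpopulation
    derivatives with a zero diagonal (the diagonal is the species itself and
    follows ``ds``).
    """
    if state.m != model.m:
        raise ParameterError(f"state has m={state.m}, model has m={model.m}")
    ds, dp = _hgt_rhs_arrays(state.s, state.p, model)
    return ds, dp


def _hgt_rhs_arrays(s, p, model: CommunityModel):
    s_c, p_c, ratio, comp = _growth_fields(s, p, model)
    mu_e, G = _effective_mu(ratio, model)
    ds = mu_e * s_c * comp - model.D * s_c
    if model._eta_scalar is not None:
        # uniform network: the donor pool of gene j is every carrier, column sum of p
        transfer = model._eta_scalar * p_c.sum(axis=0)[None, :]
    else:
        transfer = np.einsum("jki,kj->ij", model.eta, p_c)
    dp = (
        G * p_c * comp[:, None]
        + (s_c[:, None] - p_c) * transfer
        - (model.D + model.kappa) * p_c
    )
    # On the saturation boundary p_ij = s_i the exact dynamics reduce to
    # d(p_ij)/dt = d(s_i)/dt - kappa_ij p_ij (transfer vanishes and the
    # subpopulation growth factor equals the species' effective one), and the
    # interior RHS matches this continuously. Evaluating the boundary form
    # whenever p_ij >= s_i keeps the bound exact even after solver overshoot
    # — in particular it stops extinct species' residual subpopulations from
    # regrowing as unphysical ghosts.
    saturated = p_c >= s_c[:, None]
    if np.any(saturated):
        dp = np.where(saturated, ds[:, None] - model.kappa * p_c, dp)
    np.fill_diagonal(dp, 0.0)
    return ds, dp


def hgt_rhs_flat(t: float, y: np.ndarray, model: CommunityModel) -> np.ndarray:
    """Flat-vector RHS for ODE integrators (layout: s, then off-diagonal p)."""
    m = model.m
    s = y[:m]
    p = np.zeros((m, m))
    rows, cols = _offdiag_indices(m)
    p[rows, cols] = y[m:]
    ds, dp = _hgt_rhs_arrays(s, p, model)
    return np.concatenate([ds, dp[rows, cols]])


def classic_rhs_flat(t: float, y: np.ndarray, model: CommunityModel) -> np.ndarray:
    return classic_rhs(y, model)


def convert_empirical_rate(eta_c: float, N_m: float) -> float:
    """Convert an empirical conjugation rate to the model's transfer rate.

    Empirical transfer rates eta_c are measured per donor-recipient pair per
    volume (mL cell^-1 h^-1); the model works with carrying-capacity-
    normalized abundances, so the rate must be scaled by the maximum
    carrying capacity N_m (cells/mL): eta = eta_c * N_m, in 1/h.
    """
    if eta_c < 0 or N_m < 0:
        raise ParameterError("eta_c and N_m must be non-negative")
    return eta_c * N_m
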