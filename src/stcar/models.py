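"""The four Poisson space-time model structures as evaluable log densities.

Counts follow ``Y_it ~ Poisson(mu_it)`` with

.. math::

    \\log \\mu_{it} = \\eta_{it}
        = x_{it}' \\beta + \\log n_{it} + \\psi_{it},

where ``n_it`` is the population offset and ``psi_it`` a space-time random
effect.  Four decompositions of ``psi`` are supported, all built on the
Leroux CAR prior over the spatial graph W (and the path graph Z over time):

``linear``
    Area-specific linear trends:
    ``psi_it = omega_1 + phi_i + (omega_2 + theta_i) (t - tbar) / T`` with
    ``tbar = (T + 1) / 2``; ``phi`` (intercepts) and ``theta`` (slopes) are
    CAR fields with their own (rho, tau2).
``anova``
    Knorr-Held ANOVA: ``psi_it = phi_i + theta_t + gamma_it`` with spatial
    main effect ``phi ~ CAR(rho_s, tau2_s, W)``, temporal main effect
    ``theta ~ CAR(rho_t, tau2_t, Z)`` and i.i.d. interaction
    ``gamma_it ~ N(0, tau2_int)``.
``separable``
    One spatial CAR field per year plus an overall temporal trend:
    ``psi_it = phi_it + theta_t``, ``phi_.t ~ CAR(rho_s, tau2_(t), W)``,
    ``theta ~ CAR(rho_t, tau2, Z)``.
``ar``
    First-order autoregressive space-time field: ``psi_it = phi_it`` with
    ``phi_1 ~ N(0, tau2 Q(W, rho_s)^{-1})`` and
    ``phi_t | phi_{t-1} ~ N(rho_t phi_{t-1}, tau2 Q(W, rho_s)^{-1})``.

Priors: vague normal N(0, beta_var) for beta and omega, inverse-gamma
(shape, scale) for every variance, Uniform(0, 1) for every dependence
parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import yaml
from scipy.special import gammaln

from .graphs import SpatialGraph, TemporalGraph, car_quad_logpdf, leroux_logdet
from .panel import PanelData

__all__ = [
    "VARIANTS",
    "canonical_variant",
    "PriorSpec",
    "ModelSpec",
    "LatentState",
    "design_matrix",
    "spacetime_effect",
    "linear_predictor",
    "poisson_loglik",
    "log_prior",
]

VARIANTS = ("linear", "anova", "separable", "ar")

_ALIASES = {
    "linear": "linear", "spltm": "linear", "stltm": "linear",
    "anova": "anova", "spam": "anova",
    "separable": "separable", "stsm": "separable",
    "ar": "ar", "tms": "ar",
}

# variance / dependence blocks required by each variant; "spatial" for the
# separable variant is a length-T vector (one variance per year)
_TAU2_KEYS = {
    "linear": ("intercept", "slope"),
    "anova": ("spatial", "temporal", "interaction"),
    "separable": ("spatial", "temporal"),
    "ar": ("spatial",),
}
_RHO_KEYS = {
    "linear": ("intercept", "slope"),
    "anova": ("spatial", "temporal"),
    "separable": ("spatial", "temporal"),
    "ar": ("spatial", "temporal"),
}


def canonical_variant(name: str) -> str:
    try:
        return _ALIASES[str(name).lower()]
    except KeyError:
        raise ValueError(
            f"unknown model variant {name!r}; expected one of {VARIANTS} "
            "(aliases SPLTM/SPAM/STSM/TMS accepted)"
        ) from None


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters shared by all variants.

    beta_var is the variance of the vague normal prior on fixed effects
    (and on omega for the linear-trend variant); tau2_shape/tau2_scale are
    the inverse-gamma hyperparameters for every variance component.
    """

    beta_var: float = 1e5
    tau2_shape: float = 1.0
    tau2_scale: float = 0.01

    def __post_init__(self):
        if self.beta_var <= 0 or self.tau2_shape <= 0 or self.tau2_scale <= 0:
            raise ValueError("prior hyperparameters must be positive")


@dataclass(frozen=True)
class ModelSpec:
    """Which psi decomposition to fit, with its priors.

    ``n_covariates`` counts the columns of the panel's covariate matrix
    (excluding the intercept).  ``intercept`` adds a leading column of ones
    to the design matrix; the linear-trend variant carries its intercept in
    ``omega_1`` instead and refuses the flag.
    """

    variant: str = "anova"
    n_covariates: int = 5
    intercept: bool = True
    prior: PriorSpec = field(default_factory=PriorSpec)
    pooled_spatial_variance: bool = False  # separable variant only

    def __post_init__(self):
        object.__setattr__(self, "variant", canonical_variant(self.variant))
        if self.n_covariates < 0:
            raise ValueError("n_covariates must be >= 0")
        if self.variant == "linear" and self.intercept:
            object.__setattr__(self, "intercept", False)

    @property
    def n_fixed(self) -> int:
        return self.n_covariates + int(self.intercept)

    @property
    def tau2_keys(self) -> tuple:
        return _TAU2_KEYS[self.variant]

    @property
    def rho_keys(self) -> tuple:
        return _RHO_KEYS[self.variant]

    # -- serialization -------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        d = dict(d)
        if "prior" in d and isinstance(d["prior"], Mapping):
            d["prior"] = PriorSpec(**d["prior"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class LatentState:
    """Current values of every sampled block for one variant.

    Shapes (n areas, T years):

    ==========  ========  =======  ==========  =======
    block       linear    anova    separable   ar
    ==========  ========  =======  ==========  =======
    beta        (p,)      (p,)     (p,)        (p,)
    omega       (2,)      --       --          --
    phi         (n,)      (n,)     (n, T)      (n, T)
    theta       (n,)      (T,)     (T,)        --
    gamma       --        (n, T)   --          --
    ==========  ========  =======  ==========  =======

    ``tau2`` / ``rho`` are dicts keyed per variant (see ModelSpec); the
    separable variant's ``tau2['spatial']`` is a length-T array.
    """

    beta: np.ndarray
    tau2: dict
    rho: dict
    phi: np.ndarray | None = None
    theta: np.ndarray | None = None
    gamma: np.ndarray | None = None
    omega: np.ndarray | None = None

    def validate(self, spec: ModelSpec, n: int, T: int) -> None:
        v = spec.variant
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.beta.shape != (spec.n_fixed,):
            raise ValueError(
                f"beta has shape {self.beta.shape}, expected ({spec.n_fixed},)"
            )
        shapes = {
            "linear": {"omega": (2,), "phi": (n,), "theta": (n,), "gamma": None},
            "anova": {"omega": None, "phi": (n,), "theta": (T,), "gamma": (n, T)},
            "separable": {"omega": None, "phi": (n, T), "theta": (T,), "gamma": None},
            "ar": {"omega": None, "phi": (n, T), "theta": None, "gamma": None},
        }[v]
        for name, want in shapes.items():
            have = getattr(self, name)
            if want is None:
                if have is not None:
                    raise ValueError(f"variant {v!r} does not define block {name!r}")
            else:
                if have is None:
                    raise ValueError(f"variant {v!r} requires block {name!r}")
                arr = np.asarray(have, dtype=float)
                if arr.shape != want:
                    raise ValueError(
                        f"block {name!r} has shape {arr.shape}, expected {want}"
                    )
                setattr(self, name, arr)
        want_tau = set(spec.tau2_keys)
        if set(self.tau2) != want_tau:
            raise ValueError(f"tau2 keys {set(self.tau2)} != required {want_tau}")
        want_rho = set(spec.rho_keys)
        if set(self.rho) != want_rho:
            raise ValueError(f"rho keys {set(self.rho)} != required {want_rho}")
        if v == "separable":
            self.tau2["spatial"] = np.asarray(self.tau2["spatial"], dtype=float)
            if self.tau2["spatial"].shape != (T,):
                raise ValueError("separable variant needs one spatial variance per year")

    def copy(self) -> "LatentState":
        return LatentState(
            beta=self.beta.copy(),
            tau2={k: (np.copy(v) if isinstance(v, np.ndarray) else v)
                  for k, v in self.tau2.items()},
            rho=dict(self.rho),
            phi=None if self.phi is None else self.phi.copy(),
            theta=None if self.theta is None else self.theta.copy(),
            gamma=None if self.gamma is None else self.gamma.copy(),
            omega=None if self.omega is None else self.omega.copy(),
        )


# ---------------------------------------------------------------------------
# linear predictor and likelihood
# ---------------------------------------------------------------------------

def design_matrix(panel: PanelData, spec: ModelSpec) -> np.ndarray:
    """Covariate matrix seen by the model: panel X plus optional intercept."""
    if panel.n_covariates != spec.n_covariates:
        raise ValueError(
            f"panel has {panel.n_covariates} covariates, spec expects "
            f"{spec.n_covariates}"
        )
    if spec.intercept:
        return np.column_stack([np.ones(panel.n_cells), panel.X])
    return panel.X


def time_trend(T: int) -> np.ndarray:
    """Centred, scaled time covariate (t - tbar)/T with tbar = (T + 1)/2, t = 1..T."""
    t = np.arange(1, T + 1, dtype=float)
    return (t - (T + 1) / 2.0) / T


def spacetime_effect(state: LatentState, spec: ModelSpec, n: int, T: int) -> np.ndarray:
    """Assemble psi_it (n, T) from the variant's blocks."""
    v = spec.variant
    if v == "linear":
        c = time_trend(T)
        return (
            state.omega[0]
            + state.phi[:, None]
            + (state.omega[1] + state.theta)[:, None] * c[None, :]
        )
    if v == "anova":
        return state.phi[:, None] + state.theta[None, :] + state.gamma
    if v == "separable":
        return state.phi + state.theta[None, :]
    if v == "ar":
        return state.phi
    raise AssertionError(v)


def linear_predictor(
    state: LatentState, panel: PanelData, spec: ModelSpec
) -> np.ndarray:
    """eta_it = x_it' beta + log n_it + psi_it, shape (n, T)."""
    n, T = panel.n_areas, panel.n_times
    state.validate(spec, n, T)
    Xb = (design_matrix(panel, spec) @ state.beta).reshape(n, T)
    return Xb + panel.log_offset + spacetime_effect(state, spec, n, T)


def poisson_loglik(
    panel: PanelData, eta: np.ndarray, mask: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Poisson log-likelihood at log-mean ``eta``.

    Returns ``(total, pointwise)`` where ``pointwise[i, t] =
    y log mu - mu - log y!``.  With a boolean ``mask`` (True = observed)
    the total sums over observed cells only; the pointwise matrix is always
    full.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape != panel.y.shape:
        raise ValueError(f"eta has shape {eta.shape}, expected {panel.y.shape}")
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    pointwise = panel.y * eta - np.exp(eta) - gammaln(panel.y + 1.0)
    total = float(pointwise[mask].sum()) if mask is not None else float(pointwise.sum())
    return total, pointwise


# ---------------------------------------------------------------------------
# prior
# ---------------------------------------------------------------------------

def _ig_logpdf(x: float, shape: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return shape * np.log(scale) - gammaln(shape) - (shape + 1) * np.log(x) - scale / x


def _normal_logpdf(u: np.ndarray, var: float) -> float:
    u = np.asarray(u, dtype=float)
    return float(-0.5 * u.size * np.log(2 * np.pi * var) - 0.5 * (u ** 2).sum() / var)


def ar_car_quad(phi: np.ndarray, Q: np.ndarray, rho_t: float) -> float:
    """sum_t (phi_t - rho_t phi_{t-1})' Q (phi_t - rho_t phi_{t-1}), phi_0 = 0."""
    R = phi.copy()
    R[:, 1:] -= rho_t * phi[:, :-1]
    return float(np.einsum("it,ij,jt->", R, Q, R))


def log_prior(
    state: LatentState,
    spec: ModelSpec,
    spatial: SpatialGraph,
    temporal: TemporalGraph,
) -> float:
    """Joint log-prior of every block in ``state`` under ``spec``.

    Uniform(0, 1) priors on the rho parameters contribute a constant (zero)
    inside the support; out-of-support values return -inf.
    """
    n, T = spatial.n_areas, temporal.n_times
    state.validate(spec, n, T)
    p = spec.prior
    for r in state.rho.values():
        if not 0.0 <= r < 1.0:
            return -np.inf
    tau_vals = np.concatenate(
        [np.atleast_1d(np.asarray(v, dtype=float)) for v in state.tau2.values()]
    )
    if np.any(tau_vals <= 0.0):
        return -np.inf

    lp = _normal_logpdf(state.beta, p.beta_var)
    for v in tau_vals:
        lp += _ig_logpdf(float(v), p.tau2_shape, p.tau2_scale)

    def car_term(u, graph, rho, tau2):
        Q = rho * graph.structure + (1 - rho) * np.eye(graph.n_nodes)
        return car_quad_logpdf(
            float(u @ Q @ u), leroux_logdet(graph.eigenvalues, rho),
            graph.n_nodes, tau2,
        )

    v = spec.variant
    if v == "linear":
        lp += _normal_logpdf(state.omega, p.beta_var)
        lp += car_term(state.phi, spatial, state.rho["intercept"], state.tau2["intercept"])
        lp += car_term(state.theta, spatial, state.rho["slope"], state.tau2["slope"])
    elif v == "anova":
        lp += car_term(state.phi, spatial, state.rho["spatial"], state.tau2["spatial"])
        lp += car_term(state.theta, temporal, state.rho["temporal"], state.tau2["temporal"])
        lp += _normal_logpdf(state.gamma, state.tau2["interaction"])
    elif v == "separable":
        rho_s = state.rho["spatial"]
        Q = rho_s * spatial.structure + (1 - rho_s) * np.eye(n)
        ld = leroux_logdet(spatial.eigenvalues, rho_s)
        tau_t = state.tau2["spatial"]
        for t in range(T):
            lp += car_quad_logpdf(
                float(state.phi[:, t] @ Q @ state.phi[:, t]), ld, n, float(tau_t[t])
            )
        lp += car_term(state.theta, temporal, state.rho["temporal"], state.tau2["temporal"])
    elif v == "ar":
        rho_s, rho_t = state.rho["spatial"], state.rho["temporal"]
        tau2 = float(state.tau2["spatial"])
        Q = rho_s * spatial.structure + (1 - rho_s) * np.eye(n)
        ld = leroux_logdet(spatial.eigenvalues, rho_s)
        quad = ar_car_quad(state.phi, Q, rho_t)
        lp += car_quad_logpdf(quad, T * ld, n * T, tau2)
    return float(lp)


def log_posterior(
    state: LatentState,
    panel: PanelData,
    spec: ModelSpec,
    spatial: SpatialGraph,
    temporal: TemporalGraph,
    mask: np.ndarray | None = None,
) -> float:
    """log prior + Poisson log-likelihood (observed cells only)."""
    lp = log_prior(state, spec, spatial, temporal)
    if not np.isfinite(lp):
        return lp
    eta = linear_predictor(state, panel, spec)
    total, _ = poisson_loglik(panel, eta, mask)
    return lp + total
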