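"""Metropolis-within-Gibbs sampler for the four space-time Poisson models.

One sweep updates, in order: the fixed effects (block random-walk
Metropolis), the overall intercept/slope pair when present, every latent
random-effect block (single-site random-walk Metropolis with the CAR full
conditional supplying the prior term), the variance components (exact
inverse-gamma Gibbs draws) and the dependence parameters rho (random-walk
Metropolis on the logit scale, using the eigenvalue form of
``log det Q(W, rho)``).

Single-site latent updates are *chromatic*: the graph is partitioned into
independent sets (colours), and all sites of one colour are proposed and
accepted simultaneously — their full conditionals given the rest are
mutually independent, so this is exactly the single-site kernel, executed
as a handful of vectorised operations per sweep.

Proposal scales are site-wise informed (inverse square root of likelihood
curvature plus prior precision) times a per-block factor adapted during
burn-in to a 40-50% acceptance target for scalar updates (lower for the
fixed-effect block); kernels are frozen after burn-in so the post-burn-in
chain has the exact target as its stationary distribution.

Identifiability: the additive decompositions are invariant to shifting a
random-effect block and compensating the intercept, so after each sweep
structured blocks are re-centred to mean zero with the subtracted mean
added to the intercept (or omega, or the temporal main effect), leaving
the linear predictor untouched.  ``ChainConfig(recenter=False)`` disables
this, which is the correct setting when validating the raw kernels (e.g.
prior-recovery runs with the likelihood switched off).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .graphs import SpatialGraph, TemporalGraph, leroux_logdet
from .models import (
    LatentState,
    ModelSpec,
    design_matrix,
    linear_predictor,
    time_trend,
)
from .panel import PanelData

__all__ = ["ChainConfig", "PosteriorSamples", "run_chain", "run_chains", "Sampler"]


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run configuration.

    Defaults follow the reference analysis for this model family:
    N = 120,000 iterations, 20,000 burn-in, thinning 10, hence 10,000
    retained draws.
    """

    n_iter: int = 120_000
    burn_in: int = 20_000
    thin: int = 10
    seed: int = 0
    n_chains: int = 1
    adapt_interval: int = 50
    target_scalar: float = 0.45
    target_vector: float = 0.25
    recenter: bool = True

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in - 1) // self.thin + 1


@dataclass
class PosteriorSamples:
    """Retained MCMC draws plus chain metadata.

    ``draws`` maps block names to arrays whose first axis indexes retained
    iterations: ``beta`` (S, p), latent blocks at their natural shapes,
    ``tau2_*`` / ``rho_*`` scalars, ``eta`` and ``loglik_pointwise``
    (S, n, T), ``loglik`` (S,).
    """

    draws: dict
    acceptance: dict
    config: ChainConfig
    spec: ModelSpec
    seed: int
    area_ids: tuple
    years: tuple
    mask: np.ndarray | None = None

    @property
    def n_retained(self) -> int:
        return len(self.draws["loglik"])

    def credible_interval(self, key: str, level: float = 0.95) -> np.ndarray:
        lo = 100 * (1 - level) / 2
        return np.percentile(self.draws[key], [lo, 100 - lo], axis=0)

    def summary(self, covariate_names=None) -> pd.DataFrame:
        """Posterior summaries of all scalar parameters (Table-style)."""
        rows = []

        def add(name, x):
            q = np.percentile(x, [2.5, 50, 97.5])
            rows.append(
                {"parameter": name, "mean": float(np.mean(x)), "sd": float(np.std(x)),
                 "q2.5": q[0], "q50": q[1], "q97.5": q[2]}
            )

        beta = self.draws["beta"]
        names = list(covariate_names) if covariate_names else None
        p = beta.shape[1]
        offset = 0
        if self.spec.intercept:
            add("intercept", beta[:, 0])
            offset = 1
        for j in range(offset, p):
            label = names[j - offset] if names else f"beta_{j - offset + 1}"
            add(label, beta[:, j])
        if "omega" in self.draws:
            add("omega_1", self.draws["omega"][:, 0])
            add("omega_2", self.draws["omega"][:, 1])
        for key, val in self.draws.items():
            if key.startswith("tau2_") or key.startswith("rho_"):
                if val.ndim == 1:
                    add(key, val)
                else:  # per-year variances
                    for t in range(val.shape[1]):
                        add(f"{key}[{t + 1}]", val[:, t])
        return pd.DataFrame(rows)

    def fitted_mean(self) -> np.ndarray:
        """Posterior mean of mu_it = exp(eta_it), shape (n, T)."""
        return np.exp(self.draws["eta"]).mean(axis=0)

    # -- persistence ---------------------------------------------------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for key, val in self.draws.items():
            np.save(d / f"{key}.npy", val)
        if self.mask is not None:
            np.save(d / "_mask.npy", self.mask)
        manifest = {
            "seed": self.seed,
            "config": asdict(self.config),
            "spec": self.spec.to_dict(),
            "acceptance": self.acceptance,
            "area_ids": list(self.area_ids),
            "years": list(self.years),
            "draw_keys": sorted(self.draws),
        }
        with open(d / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "PosteriorSamples":
        d = Path(directory)
        with open(d / "manifest.json") as fh:
            manifest = json.load(fh)
        draws = {k: np.load(d / f"{k}.npy") for k in manifest["draw_keys"]}
        mask_path = d / "_mask.npy"
        return cls(
            draws=draws,
            acceptance=manifest["acceptance"],
            config=ChainConfig(**manifest["config"]),
            spec=ModelSpec.from_dict(manifest["spec"]),
            seed=manifest["seed"],
            area_ids=tuple(manifest["area_ids"]),
            years=tuple(manifest["years"]),
            mask=np.load(mask_path) if mask_path.exists() else None,
        )


def metropolis_accept(log_ratio, rng) -> np.ndarray:
    """Vectorised Metropolis accept decision: u < min(1, exp(log_ratio))."""
    log_ratio = np.asarray(log_ratio, dtype=float)
    with np.errstate(invalid="ignore"):
        ok = np.log(rng.random(log_ratio.shape)) < log_ratio
    return ok & np.isfinite(log_ratio) | (log_ratio >= 0)


class Sampler:
    """Metropolis-within-Gibbs sampler bound to one panel + model spec."""

    def __init__(
        self,
        panel: PanelData,
        spec: ModelSpec,
        config: ChainConfig,
        graph: SpatialGraph | None = None,
        mask: np.ndarray | None = None,
    ):
        self.panel = panel
        self.spec = spec
        self.config = config
        self.graph = graph if graph is not None else panel.graph
        if self.graph is None:
            raise ValueError("a spatial graph is required (panel.graph or graph=)")
        if self.graph.area_ids != panel.area_ids:
            raise ValueError("graph area ids do not match panel area ids")
        n, T = panel.n_areas, panel.n_times
        self.n, self.T = n, T
        self.tgraph = TemporalGraph(T)
        self.y = panel.y.astype(float)
        self.logn = panel.log_offset
        self.Xd = design_matrix(panel, spec)
        if mask is None:
            mask = np.ones((n, T), dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (n, T):
            raise ValueError(f"mask has shape {mask.shape}, expected {(n, T)}")
        self.mask = mask
        self.maskf = mask.astype(float)
        self.ym = self.y * self.maskf
        self.gammaln_y = gammaln(self.y + 1.0)
        self.ctrend = time_trend(T)

        # per-block independent RNG streams from the master seed
        blocks = ["beta", "omega", "phi", "theta", "gamma", "tau2", "rho", "init"]
        children = np.random.SeedSequence(config.seed).spawn(len(blocks))
        self.rngs = {b: np.random.default_rng(s) for b, s in zip(blocks, children)}

        self.state = self._init_state()
        self.state.validate(spec, n, T)
        self._refresh_eta()

        # adaptive proposal factors (log scale) and acceptance ledgers
        self.log_f = {b: 0.0 for b in self._proposal_blocks()}
        self._adapt_count = {b: 0 for b in self.log_f}
        self._window = {b: [0, 0] for b in self.log_f}   # accepted, proposed
        self._total = {b: [0, 0] for b in self.log_f}
        self.adapting = True
        if spec.variant == "ar":
            self._update_Qs()

    # ------------------------------------------------------------------
    def _proposal_blocks(self):
        v = self.spec.variant
        blocks = ["beta"]
        if v == "linear":
            blocks += ["omega_1", "omega_2", "phi", "theta",
                       "rho_intercept", "rho_slope"]
        elif v == "anova":
            blocks += ["phi", "theta", "gamma", "rho_spatial", "rho_temporal"]
        elif v == "separable":
            blocks += ["phi", "theta", "rho_spatial", "rho_temporal"]
        elif v == "ar":
            blocks += ["phi", "rho_spatial", "rho_temporal"]
        return blocks

    def _tally(self, block, accepted, proposed):
        self._window[block][0] += int(accepted)
        self._window[block][1] += int(proposed)
        self._total[block][0] += int(accepted)
        self._total[block][1] += int(proposed)

    def _adapt(self):
        for block, (acc, prop) in self._window.items():
            if prop == 0:
                continue
            rate = acc / prop
            target = (
                self.config.target_vector if block == "beta"
                else self.config.target_scalar
            )
            self._adapt_count[block] += 1
            step = max(0.05, 1.0 / np.sqrt(self._adapt_count[block]))
            self.log_f[block] = float(
                np.clip(self.log_f[block] + step * (rate - target), -15.0, 15.0)
            )
            self._window[block] = [0, 0]

    def _f(self, block) -> float:
        return float(np.exp(self.log_f[block]))

    # ------------------------------------------------------------------
    def _init_state(self) -> LatentState:
        """GLM-based initialisation: MLE fixed effects, residual-based blocks."""
        n, T, spec = self.n, self.T, self.spec
        p = self.Xd.shape[1]
        yflat = self.y.reshape(-1)
        obs = self.mask.reshape(-1)
        beta = np.zeros(p)
        self.beta_scale = np.full(p, 0.1)
        if p and obs.sum() > p:
            try:
                import statsmodels.api as sm

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.GLM(
                        yflat[obs], self.Xd[obs],
                        family=sm.families.Poisson(),
                        offset=self.logn.reshape(-1)[obs],
                    ).fit()
                if np.all(np.isfinite(res.params)):
                    beta = np.asarray(res.params)
                    bse = np.asarray(res.bse)
                    self.beta_scale = np.clip(
                        np.where(np.isfinite(bse), bse, 0.1), 1e-8, 10.0
                    )
            except Exception:
                pass
        elif p:
            self.beta_scale = np.full(p, np.sqrt(spec.prior.beta_var) / p)

        # working residuals on the log scale, zero at unobserved cells
        Xb = (self.Xd @ beta).reshape(n, T)
        r = np.where(
            self.mask, np.log(self.y + 0.5) - self.logn - Xb, 0.0
        )
        r = np.clip(r, -5.0, 5.0)
        nobs_row = np.maximum(self.maskf.sum(axis=1), 1.0)
        nobs_col = np.maximum(self.maskf.sum(axis=0), 1.0)
        row_mean = r.sum(axis=1) / nobs_row
        col_mean = r.sum(axis=0) / nobs_col

        def v0(x):
            return float(np.clip(np.var(x), 0.05, 2.0))

        v = spec.variant
        if v == "linear":
            grand = float(row_mean.mean())
            c = self.ctrend
            slope = float((col_mean * c).sum() / (c @ c))
            phi = row_mean - grand
            rc = r - row_mean[:, None]
            theta = (rc @ c) / (c @ c) - slope
            theta = np.clip(theta, -5, 5)
            return LatentState(
                beta=beta, omega=np.array([grand, slope]),
                phi=phi, theta=theta,
                tau2={"intercept": v0(phi), "slope": v0(theta)},
                rho={"intercept": 0.5, "slope": 0.5},
            )
        if v == "anova":
            grand = float(row_mean.mean())
            phi = row_mean - grand
            theta = col_mean - grand
            gamma = np.where(
                self.mask, r - row_mean[:, None] - theta[None, :], 0.0
            )
            beta = beta.copy()
            if spec.intercept:
                beta[0] += grand
            return LatentState(
                beta=beta, phi=phi, theta=theta, gamma=gamma,
                tau2={"spatial": v0(phi), "temporal": v0(theta),
                      "interaction": v0(gamma)},
                rho={"spatial": 0.5, "temporal": 0.5},
            )
        if v == "separable":
            grand = float(col_mean.mean())
            theta = col_mean - grand
            phi = np.where(self.mask, r - col_mean[None, :], 0.0)
            beta = beta.copy()
            if spec.intercept:
                beta[0] += grand
            tau_t = np.clip(np.var(phi, axis=0), 0.05, 2.0)
            return LatentState(
                beta=beta, phi=phi, theta=theta,
                tau2={"spatial": tau_t, "temporal": v0(theta)},
                rho={"spatial": 0.5, "temporal": 0.5},
            )
        if v == "ar":
            grand = float(row_mean.mean())
            phi = np.where(self.mask, r - grand, 0.0)
            beta = beta.copy()
            if spec.intercept:
                beta[0] += grand
            return LatentState(
                beta=beta, phi=phi,
                tau2={"spatial": v0(phi)},
                rho={"spatial": 0.5, "temporal": 0.5},
            )
        raise AssertionError(v)

    # ------------------------------------------------------------------
    def _refresh_eta(self):
        self.eta = linear_predictor(self.state, self.panel, self.spec)
        self.expm = np.exp(self.eta) * self.maskf

    def _update_Qs(self):
        """Dense Leroux precision at the current spatial rho (ar variant)."""
        rho = self.state.rho["spatial"]
        self.Qs = rho * self.graph.structure + (1 - rho) * np.eye(self.n)

    # -- fixed effects -------------------------------------------------
    def update_beta(self):
        """Block random-walk Metropolis on the fixed effects."""
        p = self.Xd.shape[1]
        if p == 0:
            return
        rng = self.rngs["beta"]
        delta = self._f("beta") * self.beta_scale * rng.standard_normal(p)
        deta = (self.Xd @ delta).reshape(self.n, self.T)
        new_expm = np.exp(self.eta + deta) * self.maskf
        beta = self.state.beta
        dll = float((self.ym * deta).sum() - (new_expm - self.expm).sum())
        dlp = -0.5 * float(((beta + delta) ** 2 - beta ** 2).sum()) / self.spec.prior.beta_var
        if np.isfinite(dll) and metropolis_accept(dll + dlp, rng):
            self.state.beta = beta + delta
            self.eta = self.eta + deta
            self.expm = new_expm
            self._tally("beta", 1, 1)
        else:
            self._tally("beta", 0, 1)

    def _update_global_scalar(self, block, idx, mult=None):
        """Scalar RW Metropolis on omega_1 (mult None) or omega_2 (mult c_t)."""
        rng = self.rngs["omega"]
        if mult is None:
            info = self.expm.sum()
            ysum = self.ym.sum()
        else:
            info = float((self.expm * (mult ** 2)[None, :]).sum())
            ysum = float((self.ym * mult[None, :]).sum())
        prec0 = 1.0 / self.spec.prior.beta_var
        scale = self._f(block) / np.sqrt(info + prec0)
        delta = scale * rng.standard_normal()
        cur = self.state.omega[idx]
        if mult is None:
            dll = ysum * delta - self.expm.sum() * np.expm1(delta)
            deta = delta
        else:
            grow = np.expm1(delta * mult)[None, :]
            dll = ysum * delta - float((self.expm * grow).sum())
        dlp = -0.5 * prec0 * ((cur + delta) ** 2 - cur ** 2)
        if metropolis_accept(dll + dlp, rng):
            self.state.omega[idx] = cur + delta
            if mult is None:
                self.eta += delta
                self.expm *= np.exp(delta)
            else:
                self.eta += delta * mult[None, :]
                self.expm *= np.exp(delta * mult)[None, :]
            self._tally(block, 1, 1)
        else:
            self._tally(block, 0, 1)

    # -- latent blocks -------------------------------------------------
    def _update_area_block(self, block, values, rho, tau2, mult=None):
        """Chromatic single-site MH over an area-indexed CAR block.

        ``mult`` is an optional (T,) multiplier on the block's contribution
        to eta (the scaled time trend for the slope block).
        """
        rng = self.rngs[block if block in self.rngs else "phi"]
        W, d = self.graph.W, self.graph.degrees
        denom = rho * d + 1.0 - rho
        prec = denom / tau2
        if mult is None:
            info = self.expm.sum(axis=1)
            ycontrib = self.ym.sum(axis=1)
        else:
            info = self.expm @ (mult ** 2)
            ycontrib = self.ym @ mult
        scale = self._f(block) / np.sqrt(info + prec)
        for cls in self.graph.coloring:
            k = cls.size
            delta = scale[cls] * rng.standard_normal(k)
            nbr = W[cls] @ values
            m = rho * nbr / denom[cls]
            cur = values[cls]
            if mult is None:
                dll = ycontrib[cls] * delta - self.expm[cls].sum(axis=1) * np.expm1(delta)
            else:
                grow = np.expm1(np.outer(delta, mult))
                dll = ycontrib[cls] * delta - (self.expm[cls] * grow).sum(axis=1)
            dlp = -0.5 * prec[cls] * ((cur + delta - m) ** 2 - (cur - m) ** 2)
            acc = metropolis_accept(dll + dlp, rng)
            idx = cls[acc]
            if idx.size:
                values[idx] += delta[acc]
                if mult is None:
                    self.eta[idx, :] += delta[acc][:, None]
                    self.expm[idx, :] *= np.exp(delta[acc])[:, None]
                else:
                    step = delta[acc][:, None] * mult[None, :]
                    self.eta[idx, :] += step
                    self.expm[idx, :] *= np.exp(step)
            self._tally(block, int(acc.sum()), k)

    def _update_time_block(self, block, values, rho, tau2):
        """Chromatic single-site MH over the temporal CAR block theta."""
        rng = self.rngs["theta"]
        Z, d = self.tgraph.W, self.tgraph.degrees
        denom = rho * d + 1.0 - rho
        prec = denom / tau2
        info = self.expm.sum(axis=0)
        ysum = self.ym.sum(axis=0)
        scale = self._f(block) / np.sqrt(info + prec)
        for cls in self.tgraph.coloring:
            k = cls.size
            delta = scale[cls] * rng.standard_normal(k)
            nbr = Z[cls] @ values
            m = rho * nbr / denom[cls]
            cur = values[cls]
            dll = ysum[cls] * delta - self.expm[:, cls].sum(axis=0) * np.expm1(delta)
            dlp = -0.5 * prec[cls] * ((cur + delta - m) ** 2 - (cur - m) ** 2)
            acc = metropolis_accept(dll + dlp, rng)
            idx = cls[acc]
            if idx.size:
                values[idx] += delta[acc]
                self.eta[:, idx] += delta[acc][None, :]
                self.expm[:, idx] *= np.exp(delta[acc])[None, :]
            self._tally(block, int(acc.sum()), k)

    def _update_cells(self, block, values, prior_prec, prior_mean, cells, rng):
        """Vectorised MH over conditionally independent cells.

        ``cells`` is a boolean (n, T) matrix marking one independent set;
        ``prior_prec`` / ``prior_mean`` are full (n, T) conditional prior
        parameters (valid for the marked cells given all others).
        """
        scale = self._f(block) / np.sqrt(self.expm + prior_prec)
        delta = np.where(cells, scale * rng.standard_normal(values.shape), 0.0)
        dll = self.ym * delta - self.expm * np.expm1(delta)
        dev_new = values + delta - prior_mean
        dev_old = values - prior_mean
        dlp = -0.5 * prior_prec * (dev_new ** 2 - dev_old ** 2)
        acc = metropolis_accept(dll + dlp, rng) & cells
        if acc.any():
            step = np.where(acc, delta, 0.0)
            values += step
            self.eta += step
            self.expm *= np.exp(step)
        self._tally(block, int(acc.sum()), int(cells.sum()))

    def update_random_effects(self):
        """One single-site Metropolis sweep over every latent block."""
        st, v = self.state, self.spec.variant
        if v == "linear":
            self._update_global_scalar("omega_1", 0)
            self._update_global_scalar("omega_2", 1, self.ctrend)
            self._update_area_block(
                "phi", st.phi, st.rho["intercept"], st.tau2["intercept"]
            )
            self._update_area_block(
                "theta", st.theta, st.rho["slope"], st.tau2["slope"], self.ctrend
            )
        elif v == "anova":
            self._update_area_block("phi", st.phi, st.rho["spatial"], st.tau2["spatial"])
            self._update_time_block("theta", st.theta, st.rho["temporal"], st.tau2["temporal"])
            all_cells = np.ones((self.n, self.T), dtype=bool)
            prec = np.full((self.n, self.T), 1.0 / st.tau2["interaction"])
            self._update_cells(
                "gamma", st.gamma, prec, np.zeros((self.n, self.T)),
                all_cells, self.rngs["gamma"],
            )
        elif v == "separable":
            rho = st.rho["spatial"]
            d = self.graph.degrees
            denom = rho * d + 1.0 - rho
            prec = denom[:, None] / st.tau2["spatial"][None, :]
            rng = self.rngs["phi"]
            for cls in self.graph.coloring:
                nbr = self.graph.W @ st.phi      # (n, T), current values
                mean = rho * nbr / denom[:, None]
                cells = np.zeros((self.n, self.T), dtype=bool)
                cells[cls, :] = True
                self._update_cells("phi", st.phi, prec, mean, cells, rng)
            self._update_time_block("theta", st.theta, st.rho["temporal"], st.tau2["temporal"])
        elif v == "ar":
            self._update_ar_field()

    def _ar_prior_conditional(self):
        """Sitewise Gaussian conditional of the AR-CAR field at current values."""
        st = self.state
        rho_t = st.rho["temporal"]
        tau2 = float(st.tau2["spatial"])
        phi = st.phi
        R = phi.copy()
        R[:, 1:] -= rho_t * phi[:, :-1]
        QR = self.Qs @ R
        G = QR.copy()
        G[:, :-1] -= rho_t * QR[:, 1:]
        G /= tau2
        qd = np.diag(self.Qs)
        prec = np.repeat(qd[:, None] * (1.0 + rho_t ** 2), self.T, axis=1) / tau2
        prec[:, -1] = qd / tau2
        mean = phi - G / prec
        return mean, prec

    def _update_ar_field(self):
        """Chromatic sweep over the AR-CAR space-time field.

        Colour classes are (spatial colour) x (time parity): two sites in a
        class are never coupled by the prior (spatial coupling is within a
        year, temporal coupling is lag one) nor by the likelihood.
        """
        st = self.state
        rng = self.rngs["phi"]
        parity = np.arange(self.T) % 2
        for cls in self.graph.coloring:
            for par in (0, 1):
                mean, prec = self._ar_prior_conditional()
                cells = np.zeros((self.n, self.T), dtype=bool)
                cells[np.ix_(cls, np.flatnonzero(parity == par))] = True
                self._update_cells("phi", st.phi, prec, mean, cells, rng)

    # -- recentering ---------------------------------------------------
    def recenter(self):
        """Shift block means into the intercept, leaving eta unchanged."""
        st, v = self.state, self.spec.variant

        def into_intercept(amount):
            if self.spec.intercept:
                st.beta[0] += amount
                return True
            return False

        if v == "linear":
            m = st.phi.mean()
            st.phi -= m
            st.omega[0] += m
            m2 = st.theta.mean()
            st.theta -= m2
            st.omega[1] += m2
        elif v == "anova":
            for blk in (st.phi, st.theta, st.gamma):
                m = blk.mean()
                if into_intercept(m):
                    blk -= m
        elif v == "separable":
            col = st.phi.mean(axis=0)
            st.phi -= col[None, :]
            st.theta += col
            m = st.theta.mean()
            if into_intercept(m):
                st.theta -= m
        elif v == "ar":
            m = st.phi.mean()
            if into_intercept(m):
                st.phi -= m

    # -- variance components -------------------------------------------
    def _draw_ig(self, shape, scale):
        return float(scale / self.rngs["tau2"].gamma(shape))

    def update_tau2(self):
        """Exact conjugate Gibbs draws for every variance component."""
        st, v = self.state, self.spec.variant
        a, b = self.spec.prior.tau2_shape, self.spec.prior.tau2_scale
        LS, LT = self.graph.structure, self.tgraph.structure
        n, T = self.n, self.T

        def quad(u, L, rho):
            return rho * float(u @ L @ u) + (1 - rho) * float(u @ u)

        if v == "linear":
            st.tau2["intercept"] = self._draw_ig(
                a + n / 2, b + quad(st.phi, LS, st.rho["intercept"]) / 2
            )
            st.tau2["slope"] = self._draw_ig(
                a + n / 2, b + quad(st.theta, LS, st.rho["slope"]) / 2
            )
        elif v == "anova":
            st.tau2["spatial"] = self._draw_ig(
                a + n / 2, b + quad(st.phi, LS, st.rho["spatial"]) / 2
            )
            st.tau2["temporal"] = self._draw_ig(
                a + T / 2, b + quad(st.theta, LT, st.rho["temporal"]) / 2
            )
            st.tau2["interaction"] = self._draw_ig(
                a + n * T / 2, b + float((st.gamma ** 2).sum()) / 2
            )
        elif v == "separable":
            rho = st.rho["spatial"]
            aq = np.einsum("it,ij,jt->t", st.phi, LS, st.phi)
            bq = (st.phi ** 2).sum(axis=0)
            quads = rho * aq + (1 - rho) * bq
            if self.spec.pooled_spatial_variance:
                pooled = self._draw_ig(a + n * T / 2, b + quads.sum() / 2)
                st.tau2["spatial"] = np.full(T, pooled)
            else:
                g = self.rngs["tau2"].gamma(a + n / 2, size=T)
                st.tau2["spatial"] = (b + quads / 2) / g
            st.tau2["temporal"] = self._draw_ig(
                a + T / 2, b + quad(st.theta, LT, st.rho["temporal"]) / 2
            )
        elif v == "ar":
            rho_t = st.rho["temporal"]
            R = st.phi.copy()
            R[:, 1:] -= rho_t * st.phi[:, :-1]
            q = float(np.sum(R * (self.Qs @ R)))
            st.tau2["spatial"] = self._draw_ig(a + n * T / 2, b + q / 2)

    # -- dependence parameters -----------------------------------------
    def _mh_rho(self, block, key, logtarget):
        rng = self.rngs["rho"]
        cur = self.state.rho[key]
        th = logit(cur) + self._f(block) * rng.standard_normal()
        new = float(np.clip(expit(th), 1e-12, 1 - 1e-12))
        lr = (
            logtarget(new) - logtarget(cur)
            + np.log(new * (1 - new)) - np.log(cur * (1 - cur))
        )
        if metropolis_accept(lr, rng):
            self.state.rho[key] = new
            self._tally(block, 1, 1)
            return True
        self._tally(block, 0, 1)
        return False

    def update_rho(self):
        """Random-walk Metropolis on each rho (logit scale, Uniform(0,1) prior)."""
        st, v = self.state, self.spec.variant
        lamS = self.graph.eigenvalues
        lamT = self.tgraph.eigenvalues
        LS, LT = self.graph.structure, self.tgraph.structure

        def car_target(u, L, lam, tau2):
            aq = float(u @ L @ u)
            bq = float(u @ u)

            def lt(rho):
                return 0.5 * leroux_logdet(lam, rho) - (rho * aq + (1 - rho) * bq) / (2 * tau2)

            return lt

        if v == "linear":
            self._mh_rho(
                "rho_intercept", "intercept",
                car_target(st.phi, LS, lamS, st.tau2["intercept"]),
            )
            self._mh_rho(
                "rho_slope", "slope",
                car_target(st.theta, LS, lamS, st.tau2["slope"]),
            )
        elif v == "anova":
            self._mh_rho(
                "rho_spatial", "spatial",
                car_target(st.phi, LS, lamS, st.tau2["spatial"]),
            )
            self._mh_rho(
                "rho_temporal", "temporal",
                car_target(st.theta, LT, lamT, st.tau2["temporal"]),
            )
        elif v == "separable":
            aq = np.einsum("it,ij,jt->t", st.phi, LS, st.phi)
            bq = (st.phi ** 2).sum(axis=0)
            w = 1.0 / (2.0 * st.tau2["spatial"])

            def lt_s(rho):
                return self.T * 0.5 * leroux_logdet(lamS, rho) - float(
                    ((rho * aq + (1 - rho) * bq) * w).sum()
                )

            self._mh_rho("rho_spatial", "spatial", lt_s)
            self._mh_rho(
                "rho_temporal", "temporal",
                car_target(st.theta, LT, lamT, st.tau2["temporal"]),
            )
        elif v == "ar":
            tau2 = float(st.tau2["spatial"])
            rho_t = st.rho["temporal"]
            R = st.phi.copy()
            R[:, 1:] -= rho_t * st.phi[:, :-1]
            aq = float(np.einsum("it,ij,jt->", R, LS, R))
            bq = float((R ** 2).sum())

            def lt_s(rho):
                return self.T * 0.5 * leroux_logdet(lamS, rho) - (
                    rho * aq + (1 - rho) * bq
                ) / (2 * tau2)

            if self._mh_rho("rho_spatial", "spatial", lt_s):
                self._update_Qs()
            QP = self.Qs @ st.phi
            A = float(np.sum(st.phi[:, 1:] * QP[:, 1:]))
            B = float(np.sum(st.phi[:, 1:] * QP[:, :-1]))
            C = float(np.sum(st.phi[:, :-1] * QP[:, :-1]))

            def lt_t(rho):
                return -(A - 2 * rho * B + rho ** 2 * C) / (2 * tau2)

            self._mh_rho("rho_temporal", "temporal", lt_t)

    # ------------------------------------------------------------------
    def sweep(self, iteration: int):
        self.update_beta()
        self.update_random_effects()
        if self.config.recenter:
            self.recenter()
        self.update_tau2()
        self.update_rho()
        if self.adapting and (iteration + 1) % self.config.adapt_interval == 0:
            self._adapt()
        if (iteration + 1) % 500 == 0:
            self._refresh_eta()   # kill accumulated float drift

    def pointwise_loglik(self) -> np.ndarray:
        return self.y * self.eta - np.exp(self.eta) - self.gammaln_y

    def run(self, progress: bool = False) -> PosteriorSamples:
        cfg = self.config
        S = cfg.n_retained
        n, T = self.n, self.T
        p = self.Xd.shape[1]
        st = self.state
        out = {
            "beta": np.empty((S, p)),
            "eta": np.empty((S, n, T)),
            "loglik_pointwise": np.empty((S, n, T)),
            "loglik": np.empty(S),
        }
        for name in ("phi", "theta", "gamma", "omega"):
            blk = getattr(st, name)
            if blk is not None:
                out[name] = np.empty((S,) + blk.shape)
        for key, val in st.tau2.items():
            out[f"tau2_{key}"] = np.empty(
                (S,) + (np.shape(val) if np.ndim(val) else ())
            )
        for key in st.rho:
            out[f"rho_{key}"] = np.empty(S)

        s = 0
        for it in range(cfg.n_iter):
            if it == cfg.burn_in:
                self.adapting = False
                self._refresh_eta()
                for block in self._total:
                    self._total[block] = [0, 0]
            self.sweep(it)
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                if not np.all(np.isfinite(self.eta)):
                    bad = "eta"
                    raise RuntimeError(
                        f"divergence: non-finite values in block {bad!r} at iteration {it}"
                    )
                out["beta"][s] = st.beta
                out["eta"][s] = self.eta
                pw = self.pointwise_loglik()
                out["loglik_pointwise"][s] = pw
                out["loglik"][s] = float(pw[self.mask].sum())
                for name in ("phi", "theta", "gamma", "omega"):
                    blk = getattr(st, name)
                    if blk is not None:
                        out[name][s] = blk
                for key, val in st.tau2.items():
                    out[f"tau2_{key}"][s] = val
                for key, val in st.rho.items():
                    out[f"rho_{key}"][s] = val
                s += 1
            if progress and (it + 1) % 1000 == 0:
                rates = {
                    b: (c[0] / c[1] if c[1] else float("nan"))
                    for b, c in self._total.items()
                }
                print(f"iter {it + 1}/{cfg.n_iter} acceptance " +
                      " ".join(f"{b}={r:.2f}" for b, r in rates.items()))
        assert s == S
        acceptance = {
            b: (c[0] / c[1] if c[1] else float("nan"))
            for b, c in self._total.items()
        }
        return PosteriorSamples(
            draws=out, acceptance=acceptance, config=cfg, spec=self.spec,
            seed=cfg.seed, area_ids=self.panel.area_ids, years=self.panel.years,
            mask=None if self.mask.all() else self.mask,
        )


def run_chain(
    panel: PanelData,
    spec: ModelSpec,
    config: ChainConfig | None = None,
    graph: SpatialGraph | None = None,
    mask: np.ndarray | None = None,
    progress: bool = False,
) -> PosteriorSamples:
    """Fit one model variant to a panel; fully reproducible given the seed."""
    config = config or ChainConfig()
    return Sampler(panel, spec, config, graph=graph, mask=mask).run(progress=progress)


def run_chains(
    panel: PanelData,
    spec: ModelSpec,
    config: ChainConfig,
    graph: SpatialGraph | None = None,
    mask: np.ndarray | None = None,
) -> list[PosteriorSamples]:
    """Run ``config.n_chains`` independent chains with derived seeds."""
    seeds = [config.seed + 1000003 * c for c in range(config.n_chains)]
    out = []
    for sd in seeds:
        cfg = ChainConfig(**{**asdict(config), "seed": sd, "n_chains": 1})
        out.append(run_chain(panel, spec, cfg, graph=graph, mask=mask))
    return out


def diagnostics(chains: list[PosteriorSamples]) -> pd.DataFrame:
    """Split-Rhat and effective sample size for scalar parameters (via arviz)."""
    import arviz as az

    keys = [
        k for k, v in chains[0].draws.items()
        if v.ndim == 1 and k != "loglik" or (k == "beta")
    ]
    data = {}
    for k in keys:
        stacked = np.stack([c.draws[k] for c in chains])
        if stacked.ndim == 2:
            data[k] = stacked
        else:
            for j in range(stacked.shape[2]):
                data[f"{k}[{j}]"] = stacked[:, :, j]
    idata = az.from_dict(posterior=data)
    ess = az.ess(idata)
    rhat = az.rhat(idata)
    return pd.DataFrame(
        {
            "ess": {k: float(ess[k].values) for k in data},
            "rhat": {k: float(rhat[k].values) for k in data},
        }
    )
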