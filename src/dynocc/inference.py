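"""Bayesian estimation of the dynamic occupancy model.

Priors follow the regularizing choices common for logit-scale occupancy
models: standard logistic on intercepts (flat on the probability scale),
standard normal on slopes, and half-normal scales for the area random
intercepts (with the offsets normal(0, sd) given their scale).

Sampling targets the posterior of the *marginalized* likelihood (the latent
use states are summed out by the forward algorithm), so only continuous
parameters are sampled.  The default backend is an adaptive random-walk
Metropolis sampler (Haario-style): the proposal covariance is seeded from
the curvature of the posterior at its mode and adapted during burn-in,
then frozen, so the retained draws come from a fixed-kernel Markov chain
whose stationary distribution is exactly the posterior.  Chains are
independent and serial, so ``n_iter`` in :class:`McmcConfig` counts plain
iterations per chain and the retained draw arithmetic
(n_iter - n_burnin) / thin is literal.

An ensemble backend (emcee, ``method="ensemble"``) is also provided; there
each chain is an independent walker ensemble and iteration counts are
walker-samples.  Ensemble moves underestimate posterior spread by 10-20%
at this model's dimensionality (verified against a latent-state Gibbs
reference), so the ensemble path is reserved for exploratory work and for
prior-stationarity checks with very large ensembles, where it is exact.

Internally the sampler works on an unconstrained vector: random-effect
offsets are non-centered (offset = sd * raw with raw ~ N(0,1)) and the
scales are log-transformed, which removes the funnel geometry and the
positivity constraint.  Draws are reported on the natural (centered) scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import emcee
import numpy as np
import pandas as pd
from scipy import optimize

from .design import DataValidationError, Dataset
from .model import (
    LikelihoodEngine,
    ModelSpec,
    NumericalGuardError,
    PREDICTORS,
    ParameterSet,
    marginal_log_likelihood,
)

__all__ = [
    "DiagnosticError",
    "PriorSpec",
    "McmcConfig",
    "ParameterLayout",
    "PosteriorSamples",
    "ConvergenceReport",
    "log_posterior",
    "fit",
    "diagnose",
    "summarize",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


class DiagnosticError(RuntimeError):
    """Convergence diagnostics are undefined for the given samples."""


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Prior scales: logistic(0, s) intercepts, N(0, sd) slopes, half-N(s)
    random-effect scales."""

    intercept_scale: float = 1.0
    coef_sd: float = 1.0
    area_sd_scale: float = 1.0

    def log_intercept(self, x: np.ndarray) -> np.ndarray:
        s = self.intercept_scale
        u = -np.abs(np.asarray(x, dtype=float)) / s
        return u - np.log(s) - 2.0 * np.log1p(np.exp(u))

    def log_coef(self, x: np.ndarray) -> np.ndarray:
        sd = self.coef_sd
        return -0.5 * (np.asarray(x, dtype=float) / sd) ** 2 - np.log(sd) - 0.5 * _LOG_2PI

    def log_halfnormal_sd(self, sd: np.ndarray) -> np.ndarray:
        s = self.area_sd_scale
        sd = np.asarray(sd, dtype=float)
        out = np.where(
            sd > 0,
            np.log(2.0) - 0.5 * (sd / s) ** 2 - np.log(s) - 0.5 * _LOG_2PI,
            -np.inf,
        )
        return out


# ---------------------------------------------------------------------------
# MCMC configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class McmcConfig:
    """Chain layout and iteration accounting.

    ``n_iter`` counts posterior samples accumulated per chain (for the
    ensemble backend: walker-samples), ``n_burnin`` of which are discarded,
    and the remainder thinned by ``thin``; the retained draw count per chain
    is exactly ``(n_iter - n_burnin) // thin``.
    """

    n_chains: int = 4
    n_iter: int = 50_000
    n_burnin: int = 25_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise DataValidationError("n_chains must be positive")
        if self.thin < 1:
            raise DataValidationError("thin must be >= 1")
        if not (0 <= self.n_burnin < self.n_iter):
            raise DataValidationError("need 0 <= n_burnin < n_iter")

    @property
    def n_retained_per_chain(self) -> int:
        return (self.n_iter - self.n_burnin) // self.thin

    @property
    def n_retained_total(self) -> int:
        return self.n_chains * self.n_retained_per_chain


#: The production-scale configuration of the motivating survey's analysis:
#: 3 chains, one million iterations each with a 100,000-step burn-in and
#: thinning by 20, retaining 135,000 draws in total.
PRODUCTION_MCMC = McmcConfig(n_chains=3, n_iter=1_000_000,
                             n_burnin=100_000, thin=20, seed=0)


# ---------------------------------------------------------------------------
# Parameter vector layout
# ---------------------------------------------------------------------------

class ParameterLayout:
    """Bijection between a flat parameter vector and :class:`ParameterSet`.

    Natural order: fixed coefficients (psi, gamma, eps, p), then area
    offsets grouped by predictor, then the four random-effect scales.
    """

    def __init__(self, spec: ModelSpec, area_ids: Sequence[str]) -> None:
        self.spec = spec
        self.area_ids = tuple(str(a) for a in area_ids)
        A = len(self.area_ids)
        self.n_areas = A
        self.fixed_names = (spec.psi_names + spec.gamma_names
                            + spec.eps_names + spec.p_names)
        self.n_fixed = len(self.fixed_names)
        self.names = list(self.fixed_names)
        for pred in PREDICTORS:
            self.names += [f"{pred}_area[{a}]" for a in self.area_ids]
        self.names += [f"sd_{pred}_area" for pred in PREDICTORS]
        self.n_params = len(self.names)

        o = 0
        self.sl_psi = slice(o, o + spec.n_psi); o += spec.n_psi
        self.sl_gamma = slice(o, o + spec.n_gamma); o += spec.n_gamma
        self.sl_eps = slice(o, o + spec.n_eps); o += spec.n_eps
        self.sl_p = slice(o, o + spec.n_p); o += spec.n_p
        self.sl_area = slice(o, o + 4 * A); o += 4 * A
        self.sl_sd = slice(o, o + 4); o += 4
        assert o == self.n_params
        self.intercept_idx = np.asarray([
            self.fixed_names.index("psi_int"),
            self.fixed_names.index("gamma_int"),
            self.fixed_names.index("eps_int"),
            self.fixed_names.index("p_int"),
        ])
        self.slope_idx = np.asarray(
            [k for k in range(self.n_fixed) if k not in set(self.intercept_idx)]
        )

    # -- natural vector <-> ParameterSet ------------------------------------
    def to_parameter_set(self, vec: np.ndarray) -> ParameterSet:
        v = np.asarray(vec, dtype=float)
        A = self.n_areas
        return ParameterSet(
            spec=self.spec,
            psi_coefs=v[self.sl_psi],
            gamma_coefs=v[self.sl_gamma],
            eps_coefs=v[self.sl_eps],
            p_coefs=v[self.sl_p],
            area_effects=v[self.sl_area].reshape(4, A),
            area_sd=v[self.sl_sd],
        )

    def from_parameter_set(self, params: ParameterSet) -> np.ndarray:
        return np.concatenate([
            params.psi_coefs, params.gamma_coefs, params.eps_coefs,
            params.p_coefs, params.area_effects.ravel(), params.area_sd,
        ])

    # -- sampler (unconstrained) vector <-> natural vector -------------------
    def natural_from_theta(self, theta: np.ndarray) -> np.ndarray:
        """theta holds non-centered raw offsets and log scales."""
        th = np.asarray(theta, dtype=float)
        out = th.copy()
        sd = np.exp(th[..., self.sl_sd])
        raw = th[..., self.sl_area].reshape(*th.shape[:-1], 4, self.n_areas)
        out[..., self.sl_area] = (raw * sd[..., :, None]).reshape(
            *th.shape[:-1], 4 * self.n_areas)
        out[..., self.sl_sd] = sd
        return out

    def log_posterior_theta(self, theta: np.ndarray, engine: LikelihoodEngine,
                            priors: PriorSpec) -> float:
        """Unnormalized log posterior density in sampler coordinates."""
        th = np.asarray(theta, dtype=float)
        if not np.all(np.isfinite(th)):
            return -np.inf
        u = th[self.sl_sd]
        sd = np.exp(u)
        fixed = th[:self.n_fixed]
        raw = th[self.sl_area]
        lp = float(priors.log_intercept(fixed[self.intercept_idx]).sum())
        lp += float(priors.log_coef(fixed[self.slope_idx]).sum())
        lp += float(-0.5 * (raw ** 2).sum() - 0.5 * raw.size * _LOG_2PI)
        # half-normal prior on sd plus the log-Jacobian of sd = exp(u)
        lp += float(priors.log_halfnormal_sd(sd).sum() + u.sum())
        params = self.to_parameter_set(self.natural_from_theta(th))
        ll = engine.log_likelihood(params)
        return lp + ll

    def sample_prior_theta(self, rng: np.random.Generator,
                           priors: PriorSpec, size: int) -> np.ndarray:
        """Draw sampler-space vectors from the prior (for initialization)."""
        out = np.empty((size, self.n_params))
        out[:, :self.n_fixed] = rng.normal(0.0, priors.coef_sd,
                                           (size, self.n_fixed))
        out[:, self.intercept_idx] = rng.logistic(
            0.0, priors.intercept_scale, (size, 4))
        out[:, self.sl_area] = rng.normal(0.0, 1.0, (size, 4 * self.n_areas))
        sd = np.abs(rng.normal(0.0, priors.area_sd_scale, (size, 4)))
        out[:, self.sl_sd] = np.log(np.maximum(sd, 1e-6))
        return out


# ---------------------------------------------------------------------------
# Posterior density (natural scale, public contract)
# ---------------------------------------------------------------------------

def log_posterior(spec: ModelSpec, params: ParameterSet, dataset: Dataset,
                  priors: PriorSpec | None = None) -> float:
    """Marginal log-likelihood plus log prior density at ``params``.

    Intercepts carry logistic priors, slopes standard-normal priors, the
    four area random-effect scales half-normal priors, and the offsets are
    normal(0, sd) given their scale.
    """
    priors = priors or PriorSpec()
    lp = float(priors.log_intercept(np.asarray([
        params.psi_coefs[0], params.gamma_coefs[0],
        params.eps_coefs[0], params.p_coefs[0]])).sum())
    slopes = np.concatenate([
        params.psi_coefs[1:], params.gamma_coefs[1:],
        params.eps_coefs[1:], params.p_coefs[1:]])
    lp += float(priors.log_coef(slopes).sum())
    lp += float(priors.log_halfnormal_sd(params.area_sd).sum())
    sd = params.area_sd[:, None]
    lp += float((-0.5 * (params.area_effects / sd) ** 2
                 - np.log(sd) - 0.5 * _LOG_2PI).sum())
    ll = marginal_log_likelihood(spec, params, dataset)
    out = lp + ll
    if np.isnan(out):
        raise NumericalGuardError("log posterior evaluated to NaN")
    return out


# ---------------------------------------------------------------------------
# Posterior samples container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """MCMC draws on the natural scale: (chain, draw, parameter)."""

    draws: np.ndarray
    names: tuple[str, ...]
    spec: ModelSpec
    area_ids: tuple[str, ...]
    config: McmcConfig
    map_estimate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3 or self.draws.shape[2] != len(self.names):
            raise DataValidationError("draws must be (chain, draw, parameter)")
        if not np.all(np.isfinite(self.draws)):
            raise NumericalGuardError("posterior draws contain non-finite values")

    @property
    def n_chains(self) -> int:
        return int(self.draws.shape[0])

    @property
    def n_draws_per_chain(self) -> int:
        return int(self.draws.shape[1])

    @property
    def layout(self) -> ParameterLayout:
        return ParameterLayout(self.spec, self.area_ids)

    def pooled(self, name: str | None = None) -> np.ndarray:
        """Draws flattened over chains; one column per parameter or a single
        parameter's vector."""
        flat = self.draws.reshape(-1, self.draws.shape[2])
        if name is None:
            return flat
        return flat[:, self.names.index(name)]

    def parameter_set(self, flat_index: int) -> ParameterSet:
        return self.layout.to_parameter_set(self.pooled()[flat_index])

    def subsample_indices(self, n: int, rng: np.random.Generator) -> np.ndarray:
        total = self.n_chains * self.n_draws_per_chain
        if n > total:
            raise DataValidationError(
                f"requested {n} draws but only {total} are retained")
        return rng.choice(total, size=n, replace=False)

    # -- persistence ---------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        C, D, P = self.draws.shape
        chain = np.repeat(np.arange(1, C + 1), D * P)
        draw = np.tile(np.repeat(np.arange(1, D + 1), P), C)
        param = np.tile(np.asarray(self.names), C * D)
        return pd.DataFrame({
            "chain": chain, "draw": draw, "parameter": param,
            "value": self.draws.ravel(),
        })

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(d / "draws.csv", index=False)
        meta = {
            "variant": self.spec.variant,
            "area_ids": list(self.area_ids),
            "names": list(self.names),
            "config": {
                "n_chains": self.config.n_chains, "n_iter": self.config.n_iter,
                "n_burnin": self.config.n_burnin, "thin": self.config.thin,
                "seed": self.config.seed,
            },
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "PosteriorSamples":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        df = pd.read_csv(d / "draws.csv")
        names = meta["names"]
        C = int(df["chain"].max())
        D = int(df["draw"].max())
        arr = (df.sort_values(["chain", "draw"])  # parameter order preserved
                 ["value"].to_numpy().reshape(C, D, len(names)))
        return cls(
            draws=arr, names=tuple(names), spec=ModelSpec(meta["variant"]),
            area_ids=tuple(meta["area_ids"]), config=McmcConfig(**meta["config"]),
        )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _find_map(layout: ParameterLayout, engine: LikelihoodEngine,
              priors: PriorSpec) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mode and a curvature-based covariance guess (from the
    L-BFGS inverse-Hessian approximation, regularized to be SPD)."""
    x0 = np.zeros(layout.n_params)
    x0[layout.sl_sd] = np.log(0.3)

    def neg(theta: np.ndarray) -> float:
        v = -layout.log_posterior_theta(theta, engine, priors)
        return v if np.isfinite(v) else 1e12  # keep finite differences clean

    res = optimize.minimize(neg, x0, method="L-BFGS-B",
                            options={"maxiter": 300, "maxfun": 40_000})
    x = res.x if np.all(np.isfinite(res.x)) else x0
    return x, _laplace_covariance(neg, x)


def _laplace_covariance(neg_logp, x: np.ndarray, h: float = 1e-3) -> np.ndarray:
    """Inverse of the numerical Hessian of -log posterior at the mode,
    repaired to be symmetric positive definite (eigenvalue clipping).
    Central second differences: ~2 d^2 function evaluations."""
    d = x.size
    H = np.empty((d, d))
    f0 = neg_logp(x)
    steps = np.full(d, h)
    fp = np.empty(d)
    fm = np.empty(d)
    for i in range(d):
        ei = np.zeros(d); ei[i] = steps[i]
        fp[i] = neg_logp(x + ei)
        fm[i] = neg_logp(x - ei)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / steps[i] ** 2
    for i in range(d):
        ei = np.zeros(d); ei[i] = steps[i]
        for j in range(i + 1, d):
            ej = np.zeros(d); ej[j] = steps[j]
            fpp = neg_logp(x + ei + ej)
            fmm = neg_logp(x - ei - ej)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
            ) / (2 * steps[i] * steps[j])
    H = 0.5 * (H + H.T)
    w, v = np.linalg.eigh(H)
    if not np.all(np.isfinite(w)):
        return np.eye(d) * 0.01
    w = np.clip(w, 1e-2, 1e6)  # curvature floor caps the widest direction
    return (v / w) @ v.T


def _run_am_chain(logp, x0: np.ndarray, cov0: np.ndarray, mcmc: McmcConfig,
                  rng: np.random.Generator, layout: ParameterLayout,
                  priors: PriorSpec) -> np.ndarray:
    """One adaptive random-walk Metropolis chain with interweaving moves.

    The base move is a full-vector Gaussian random walk whose covariance is
    seeded from ``cov0`` and adapted (Haario) during burn-in, with a global
    scale tuned toward 0.234 acceptance; after burn-in the kernel is
    frozen, so retained draws come from an exactly stationary chain.

    Two likelihood-invariant interweaving moves per predictor break the
    slow ridges of the hierarchical block: a *scaling* move changes the
    random-effect scale while holding the actual area offsets fixed
    (raw -> raw * exp(-delta), log sd -> log sd + delta), and a
    *translation* move shifts the intercept against the offset mean
    (b0 -> b0 + c, offsets -> offsets - c).  Both leave the likelihood
    unchanged, so their acceptance ratios involve only the prior.
    """
    d = x0.size
    target_accept = 0.234
    base_scale = 2.38 ** 2 / d
    s_area = priors.area_sd_scale
    A = layout.n_areas
    blocks = []  # (intercept index, raw-offset slice, log-sd index)
    for k in range(4):
        blocks.append((
            int(layout.intercept_idx[k]),
            slice(layout.sl_area.start + k * A, layout.sl_area.start + (k + 1) * A),
            layout.sl_sd.start + k,
        ))

    def log_h(u):  # half-normal prior on exp(u) plus the Jacobian, un-normalized
        return -0.5 * np.exp(2 * u) / s_area ** 2 + u

    def log_int(b):  # logistic prior, un-normalized
        a = -np.abs(b) / priors.intercept_scale
        return a - 2.0 * np.log1p(np.exp(a))

    x = x0.copy()
    lp = logp(x)
    log_lambda = 0.0
    mean = x.copy()
    cov = cov0.copy()
    chol = np.linalg.cholesky(base_scale * cov + 1e-12 * np.eye(d))
    keep = np.empty((mcmc.n_retained_per_chain, d))
    k_out = 0
    refresh = 250
    for it in range(mcmc.n_iter):
        prop = x + np.exp(0.5 * log_lambda) * (chol @ rng.standard_normal(d))
        lp_prop = logp(prop)
        alpha = 1.0 if lp_prop >= lp else np.exp(lp_prop - lp)
        if rng.random() < alpha:
            x = prop
            lp = lp_prop

        for b0_i, raw_sl, u_i in blocks:
            # scaling interweave: offsets fixed, scale resampled
            delta = 0.6 * rng.standard_normal()
            raw = x[raw_sl]
            raw_new = raw * np.exp(-delta)
            u = x[u_i]
            dlp = (-0.5 * (raw_new @ raw_new - raw @ raw)
                   + log_h(u + delta) - log_h(u))
            if np.log(rng.random()) < dlp - A * delta:  # Jacobian exp(-A delta)
                x[raw_sl] = raw_new
                x[u_i] = u + delta
                lp += dlp
            # translation interweave: intercept vs offset mean
            c = 0.6 * rng.standard_normal()
            raw = x[raw_sl]
            raw_new = raw - c * np.exp(-x[u_i])
            b0 = x[b0_i]
            dlp = (log_int(b0 + c) - log_int(b0)
                   - 0.5 * (raw_new @ raw_new - raw @ raw))
            if np.log(rng.random()) < dlp:
                x[b0_i] = b0 + c
                x[raw_sl] = raw_new
                lp += dlp

        if it < mcmc.n_burnin:
            # running mean/covariance of the chain (Haario adaptation)
            n = it + 1
            delta_m = x - mean
            mean += delta_m / (n + 1)
            cov += (np.outer(delta_m, x - mean) - cov) / (n + 1)
            log_lambda += (alpha - target_accept) / (n ** 0.6 + 10.0)
            if (it + 1) % refresh == 0:
                chol = np.linalg.cholesky(
                    base_scale * cov + 1e-9 * np.eye(d))
        else:
            j = it - mcmc.n_burnin
            if j % mcmc.thin == 0 and k_out < keep.shape[0]:
                keep[k_out] = x
                k_out += 1
    if k_out != keep.shape[0]:  # pragma: no cover - arithmetic guard
        raise NumericalGuardError("retained-draw accounting failed")
    return keep


def fit(spec: ModelSpec, dataset: Dataset, priors: PriorSpec | None = None,
        mcmc: McmcConfig | None = None, init: str = "map",
        method: str = "am", n_walkers: int | None = None,
        progress: bool = False) -> PosteriorSamples:
    """Sample the posterior of the marginalized model.

    Parameters
    ----------
    init : {"map", "prior"}
        "map" starts chains from scattered points around the posterior mode
        located with L-BFGS (default); "prior" starts from prior draws,
        the right choice for prior-predictive runs on empty data.
    method : {"am", "ensemble"}
        "am" (default) runs one adaptive random-walk Metropolis chain per
        configured chain, with the proposal covariance seeded from the
        posterior curvature, adapted during burn-in and frozen afterwards.
        "ensemble" runs an emcee walker ensemble per chain; there
        ``n_iter`` counts walker-samples.
    n_walkers : int, optional
        Ensemble size per chain (ensemble method only); defaults to
        ``2 * n_params + 2``.

    Returns draws on the natural scale with exactly
    ``n_chains * (n_iter - n_burnin) // thin`` retained samples.
    """
    priors = priors or PriorSpec()
    mcmc = mcmc or McmcConfig()
    layout = ParameterLayout(spec, dataset.covariates.area_ids)
    engine = LikelihoodEngine(spec, dataset)
    ndim = layout.n_params
    if init not in ("map", "prior"):
        raise DataValidationError("init must be 'map' or 'prior'")
    if method not in ("am", "ensemble"):
        raise DataValidationError("method must be 'am' or 'ensemble'")

    center = cov0 = None
    if init == "map":
        center, cov0 = _find_map(layout, engine, priors)

    def logp(theta: np.ndarray) -> float:
        try:
            return layout.log_posterior_theta(theta, engine, priors)
        except NumericalGuardError:
            return -np.inf

    chains = []
    for c in range(mcmc.n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([int(mcmc.seed), c]))
        if method == "am":
            if center is None:
                x0 = layout.sample_prior_theta(rng, priors, 1)[0]
                c0 = _prior_covariance(layout, priors)
            else:
                # over-dispersed starts within the curvature ball
                x0 = center + np.linalg.cholesky(
                    cov0 + 1e-9 * np.eye(ndim)) @ rng.standard_normal(ndim)
                c0 = cov0
            sel = _run_am_chain(logp, x0, c0, mcmc, rng, layout, priors)
        else:
            sel = _run_ensemble_chain(logp, layout, priors, center, mcmc,
                                      rng, n_walkers, progress)
        chains.append(layout.natural_from_theta(sel))
    draws = np.stack(chains, axis=0)
    return PosteriorSamples(
        draws=draws, names=tuple(layout.names), spec=spec,
        area_ids=layout.area_ids, config=mcmc,
        map_estimate=None if center is None else layout.natural_from_theta(center),
    )


def _prior_covariance(layout: ParameterLayout, priors: PriorSpec) -> np.ndarray:
    """Diagonal covariance matching the prior scales (fallback seed)."""
    var = np.ones(layout.n_params)
    var[:layout.n_fixed] = priors.coef_sd ** 2
    var[layout.intercept_idx] = (np.pi ** 2 / 3) * priors.intercept_scale ** 2
    var[layout.sl_sd] = 0.6  # log half-normal scale, roughly
    return np.diag(var)


def _run_ensemble_chain(logp, layout: ParameterLayout, priors: PriorSpec,
                        center: np.ndarray | None, mcmc: McmcConfig,
                        rng: np.random.Generator, n_walkers: int | None,
                        progress: bool) -> np.ndarray:
    ndim = layout.n_params
    W = n_walkers or (2 * ndim + 2)
    if W < 2 * ndim + 2:
        raise DataValidationError(
            f"need at least {2 * ndim + 2} walkers for {ndim} parameters")
    steps = -(-mcmc.n_iter // W)  # ceil
    if center is None:
        coords = layout.sample_prior_theta(rng, priors, W)
    else:
        coords = center[None, :] + 0.05 * rng.standard_normal((W, ndim))
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(W, ndim, logp, moves=moves)
    rs = np.random.RandomState(rng.integers(2 ** 31 - 1))
    state = emcee.State(coords, random_state=rs.get_state())
    sampler.run_mcmc(state, steps, progress=progress,
                     skip_initial_state_check=True)
    flat = sampler.get_chain().reshape(steps * W, ndim)  # step-major
    keep = mcmc.n_retained_per_chain
    return flat[mcmc.n_burnin: mcmc.n_burnin + keep * mcmc.thin: mcmc.thin]


# ---------------------------------------------------------------------------
# Diagnostics and summaries
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceReport:
    """Split R-hat and effective sample size per parameter."""

    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool
    threshold: float = 1.1

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": list(self.rhat),
            "rhat": list(self.rhat.values()),
            "ess": [self.ess[k] for k in self.rhat],
        })


def diagnose(samples: PosteriorSamples, threshold: float = 1.1) -> ConvergenceReport:
    """Rank-normalized split R-hat and bulk ESS for every parameter.

    Convergence is declared when every R-hat is at or below ``threshold``
    (1.1, the usual rule for this model family).
    """
    import arviz as az

    if samples.n_chains < 2:
        raise DiagnosticError("R-hat requires at least two chains")
    if samples.n_draws_per_chain < 4:
        raise DiagnosticError("R-hat requires at least four draws per chain")
    post = {name: samples.draws[:, :, k]
            for k, name in enumerate(samples.names)}
    idata = az.from_dict(posterior=post)
    rh = az.rhat(idata)
    es = az.ess(idata)
    rhat = {}
    ess = {}
    for name in samples.names:
        r = float(rh[name].values)
        if np.isnan(r):  # constant parameter across all chains
            r = 1.0
        rhat[name] = r
        e = float(es[name].values)
        ess[name] = e if np.isfinite(e) else float(
            samples.n_chains * samples.n_draws_per_chain)
    converged = all(r <= threshold for r in rhat.values())
    return ConvergenceReport(rhat=rhat, ess=ess, converged=converged,
                             threshold=threshold)


def summarize(samples: PosteriorSamples, prob: float = 0.95) -> pd.DataFrame:
    """Posterior mean, sd, equal-tailed interval and a zero-overlap flag.

    ``excludes_zero`` reproduces the usual caterpillar-plot significance
    check: True when the interval does not contain zero.
    """
    if not (0 < prob < 1):
        raise DataValidationError("prob must be in (0, 1)")
    flat = samples.pooled()
    lo_q, hi_q = (1 - prob) / 2, 1 - (1 - prob) / 2
    lo = np.quantile(flat, lo_q, axis=0)
    hi = np.quantile(flat, hi_q, axis=0)
    return pd.DataFrame({
        "parameter": list(samples.names),
        "mean": flat.mean(axis=0),
        "sd": flat.std(axis=0, ddof=1) if flat.shape[0] > 1 else np.zeros(flat.shape[1]),
        "lo": lo,
        "hi": hi,
        "excludes_zero": (lo > 0) | (hi < 0),
    }).set_index("parameter")
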