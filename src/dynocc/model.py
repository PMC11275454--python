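"""Dynamic occupancy model: predictors, latent dynamics and exact likelihood.

The model is a two-level hidden Markov chain per site i.  The ecological
process is the latent seasonal use state z[i, t]:

    z[i, 1] ~ Bernoulli(psi1[i])
    z[i, t] ~ Bernoulli(z[i, t-1] * (1 - eps[i, t-1]) + (1 - z[i, t-1]) * gamma[i, t-1])

with colonization gamma and desertion eps between consecutive primary
periods (seasons).  The observation process is monthly detection given use,
adjusted for trapping effort (camera-active days d):

    y[i, j, t] ~ Bernoulli(z[i, t] * p_star[i, j, t]),   p_star = 1 - (1 - p)^d

All four rates (psi1, gamma, eps, p) are logit-linear in site/season
covariates with a Gaussian random intercept per survey area.  Three fixed
model variants are supported; they differ only in the gamma and eps formulas:

    additive              gamma, eps ~ season + elevation + popden
    interaction_popden    gamma, eps ~ season + popden + season:popden
    interaction_elevation gamma, eps ~ season + elevation + season:elevation

while psi1 ~ habitat * popden and p ~ season * habitat in every variant.
The season covariate of a transition t -> t+1 is the ORIGIN season's label
(seasons alternate, so this encodes winter-to-summer versus summer-to-winter
transitions); "summer" and "broadleaf" are reference levels throughout.

The likelihood is marginalized over z by the forward algorithm, so inference
only ever sees continuous parameters; z is recovered afterwards by
forward-filter backward-sampling (:func:`sample_latent_states`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import expit

from .design import DataValidationError, Dataset, HABITAT_LEVELS

__all__ = [
    "VARIANTS",
    "NumericalGuardError",
    "ModelSpec",
    "ParameterSet",
    "RateSurfaces",
    "LatentStateMatrix",
    "LikelihoodEngine",
    "linear_predictors",
    "transition_probability",
    "effort_adjusted_detection",
    "marginal_log_likelihood",
    "sample_latent_states",
]

VARIANTS = ("additive", "interaction_popden", "interaction_elevation")
Variant = Literal["additive", "interaction_popden", "interaction_elevation"]

#: Row order of the per-predictor random area effects.
PREDICTORS = ("psi", "gamma", "eps", "p")

_HAB = [h for h in HABITAT_LEVELS[1:]]


class NumericalGuardError(ArithmeticError):
    """A likelihood or posterior evaluation produced a non-finite value."""


@dataclass(frozen=True)
class ModelSpec:
    """One of the three fixed model variants.

    The initial-use and detection formulas are shared by all variants
    (``psi1 ~ habitat * popden``, ``p ~ season * habitat``); the variant
    selects the colonization/desertion formula.
    """

    variant: Variant = "additive"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise DataValidationError(
                f"unknown model variant {self.variant!r}; choose from {VARIANTS}"
            )

    # --- coefficient naming -------------------------------------------------
    @property
    def psi_names(self) -> list[str]:
        return (
            ["psi_int"]
            + [f"psi_hab[{h}]" for h in _HAB]
            + ["psi_popden"]
            + [f"psi_hab[{h}]:popden" for h in _HAB]
        )

    def _trans_names(self, prefix: str) -> list[str]:
        base = [f"{prefix}_int", f"{prefix}_season[winter]"]
        if self.variant == "additive":
            return base + [f"{prefix}_elev", f"{prefix}_popden"]
        if self.variant == "interaction_popden":
            return base + [f"{prefix}_popden", f"{prefix}_season:popden"]
        return base + [f"{prefix}_elev", f"{prefix}_season:elev"]

    @property
    def gamma_names(self) -> list[str]:
        return self._trans_names("gamma")

    @property
    def eps_names(self) -> list[str]:
        return self._trans_names("eps")

    @property
    def p_names(self) -> list[str]:
        return (
            ["p_int", "p_season[winter]"]
            + [f"p_hab[{h}]" for h in _HAB]
            + [f"p_season:hab[{h}]" for h in _HAB]
        )

    @property
    def n_psi(self) -> int:
        return len(self.psi_names)

    @property
    def n_gamma(self) -> int:
        return len(self.gamma_names)

    @property
    def n_eps(self) -> int:
        return len(self.eps_names)

    @property
    def n_p(self) -> int:
        return len(self.p_names)


@dataclass
class ParameterSet:
    """All regression coefficients and random effects of one model variant.

    ``area_effects`` has one row per predictor (psi, gamma, eps, p) and one
    column per survey area, holding the realized random intercepts;
    ``area_sd`` holds the four corresponding scale parameters.
    """

    spec: ModelSpec
    psi_coefs: np.ndarray
    gamma_coefs: np.ndarray
    eps_coefs: np.ndarray
    p_coefs: np.ndarray
    area_effects: np.ndarray  # (4, n_areas)
    area_sd: np.ndarray       # (4,)

    def __post_init__(self) -> None:
        self.psi_coefs = np.atleast_1d(np.asarray(self.psi_coefs, dtype=float))
        self.gamma_coefs = np.atleast_1d(np.asarray(self.gamma_coefs, dtype=float))
        self.eps_coefs = np.atleast_1d(np.asarray(self.eps_coefs, dtype=float))
        self.p_coefs = np.atleast_1d(np.asarray(self.p_coefs, dtype=float))
        self.area_effects = np.atleast_2d(np.asarray(self.area_effects, dtype=float))
        self.area_sd = np.atleast_1d(np.asarray(self.area_sd, dtype=float))
        s = self.spec
        checks = {
            "psi_coefs": (self.psi_coefs.size, s.n_psi),
            "gamma_coefs": (self.gamma_coefs.size, s.n_gamma),
            "eps_coefs": (self.eps_coefs.size, s.n_eps),
            "p_coefs": (self.p_coefs.size, s.n_p),
        }
        for name, (got, want) in checks.items():
            if got != want:
                raise DataValidationError(
                    f"{name} has {got} entries; variant {s.variant!r} needs {want}"
                )
        if self.area_effects.shape[0] != len(PREDICTORS):
            raise DataValidationError("area_effects must have one row per predictor")
        if self.area_sd.size != len(PREDICTORS) or np.any(self.area_sd <= 0):
            raise DataValidationError("area_sd must be four positive scales")

    @property
    def n_areas(self) -> int:
        return int(self.area_effects.shape[1])

    @classmethod
    def null(cls, spec: ModelSpec, n_areas: int) -> "ParameterSet":
        """All coefficients and offsets zero (unit random-effect scales)."""
        return cls(
            spec=spec,
            psi_coefs=np.zeros(spec.n_psi),
            gamma_coefs=np.zeros(spec.n_gamma),
            eps_coefs=np.zeros(spec.n_eps),
            p_coefs=np.zeros(spec.n_p),
            area_effects=np.zeros((4, n_areas)),
            area_sd=np.ones(4),
        )


@dataclass
class RateSurfaces:
    """Per-site probability surfaces implied by one parameter set."""

    psi1: np.ndarray   # (n_sites,)
    gamma: np.ndarray  # (n_sites, n_seasons - 1)
    eps: np.ndarray    # (n_sites, n_seasons - 1)
    p: np.ndarray      # (n_sites, n_months) daily detection probability

    def __post_init__(self) -> None:
        for name in ("psi1", "gamma", "eps", "p"):
            a = getattr(self, name)
            if np.any((a < 0) | (a > 1)):
                raise DataValidationError(f"{name} contains values outside [0, 1]")


@dataclass
class LatentStateMatrix:
    """Binary seasonal use states, one column per primary period."""

    z: np.ndarray  # (n_sites, n_seasons) in {0, 1}

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z)
        vals = np.unique(self.z)
        if not np.all(np.isin(vals, (0, 1))):
            raise DataValidationError("latent states must be binary")
        self.z = self.z.astype(np.int8)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def transition_probability(z_prev, gamma, eps):
    """P(z[t+1] = 1 | z[t]) = z*(1-eps) + (1-z)*gamma, elementwise."""
    z = np.asarray(z_prev, dtype=float)
    g = np.asarray(gamma, dtype=float)
    e = np.asarray(eps, dtype=float)
    for name, a in (("gamma", g), ("eps", e)):
        if np.any((a < 0) | (a > 1)):
            raise DataValidationError(f"{name} outside [0, 1]")
    if np.any((z != 0) & (z != 1)):
        raise DataValidationError("z_prev must be 0 or 1")
    out = z * (1.0 - e) + (1.0 - z) * g
    return out if out.ndim else float(out)


def effort_adjusted_detection(p, days):
    """Monthly detection probability from daily p over ``days`` active days.

    p_star = 1 - (1 - p)^days; equals p at one day and 0 at zero days.
    """
    p_arr = np.asarray(p, dtype=float)
    d = np.asarray(days, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise DataValidationError("p outside [0, 1]")
    if np.any(d < 0):
        raise DataValidationError("days must be non-negative")
    # -expm1(d * log1p(-p)) is accurate for small p and large d
    with np.errstate(divide="ignore"):
        log_miss = d * np.log1p(-p_arr)
    out = -np.expm1(log_miss)
    out = np.where(p_arr >= 1.0, np.where(d > 0, 1.0, 0.0), out)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Linear predictors
# ---------------------------------------------------------------------------

def _transition_parts(spec: ModelSpec, coefs: np.ndarray, elev: np.ndarray,
                      pop: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a gamma/eps predictor into a site term A and a winter-origin
    multiplier B so that eta[i, t] = A[i] + B[i] * winter_origin[t]."""
    c0, c_season, c2, c3 = coefs
    if spec.variant == "additive":
        a = c0 + c2 * elev + c3 * pop
        b = np.full_like(a, c_season)
    elif spec.variant == "interaction_popden":
        a = c0 + c2 * pop
        b = c_season + c3 * pop
    else:  # interaction_elevation
        a = c0 + c2 * elev
        b = c_season + c3 * elev
    return a, b


def linear_predictors(spec: ModelSpec, params: ParameterSet,
                      dataset: Dataset) -> RateSurfaces:
    """Evaluate all four probability surfaces for a dataset.

    Each surface is the inverse logit of the corresponding design-matrix
    product plus the site's area random intercept.  The ``p`` surface is the
    daily detection probability (before effort adjustment).
    """
    cov, ss = dataset.covariates, dataset.seasons
    if params.n_areas != len(cov.area_ids):
        raise DataValidationError(
            f"params have {params.n_areas} areas; dataset has {len(cov.area_ids)}"
        )
    ai = cov.area_index()
    hab = cov.habitat_contrasts()           # (n, 3)
    elev = cov.elevation_std
    pop = cov.popden_std

    # psi1 ~ habitat * popden
    b = params.psi_coefs
    eta_psi = (b[0] + hab @ b[1:4] + b[4] * pop + (hab @ b[5:8]) * pop
               + params.area_effects[0, ai])

    # gamma, eps: site part + winter-origin part (origin-season convention)
    w_origin = ss.winter_indicator_seasons()[:-1]  # (T-1,)
    a_g, b_g = _transition_parts(spec, params.gamma_coefs, elev, pop)
    a_e, b_e = _transition_parts(spec, params.eps_coefs, elev, pop)
    off_g = params.area_effects[1, ai]
    off_e = params.area_effects[2, ai]
    eta_gamma = (a_g + off_g)[:, None] + np.outer(b_g, w_origin)
    eta_eps = (a_e + off_e)[:, None] + np.outer(b_e, w_origin)

    # p ~ season * habitat, per month
    d = params.p_coefs
    w_month = ss.winter_indicator_months()  # (M,)
    a_p = d[0] + hab @ d[2:5] + params.area_effects[3, ai]
    b_p = d[1] + hab @ d[5:8]
    eta_p = a_p[:, None] + np.outer(b_p, w_month)

    return RateSurfaces(
        psi1=expit(eta_psi),
        gamma=expit(eta_gamma),
        eps=expit(eta_eps),
        p=expit(eta_p),
    )


# ---------------------------------------------------------------------------
# Likelihood engine (forward algorithm over seasons)
# ---------------------------------------------------------------------------

class LikelihoodEngine:
    """Precomputed per-dataset quantities for fast repeated likelihood work.

    Building the engine once and calling it with many parameter sets (as the
    sampler does) avoids re-deriving masks and design pieces per evaluation.
    """

    def __init__(self, spec: ModelSpec, dataset: Dataset) -> None:
        self.spec = spec
        self.dataset = dataset
        dh, ss = dataset.detection_history, dataset.seasons
        self.n_sites = dh.n_sites
        self.n_seasons = ss.n_seasons
        self.obs = dh.observed_mask()
        self.y = np.where(self.obs, dh.y, 0.0)
        self.effort = np.where(self.obs, dh.effort, 0.0)
        self.season_of_month = ss.season_of_month()
        # months grouped per season for fast segment sums
        self._season_slices = []
        start = 0
        for m in ss.months_per_season:
            self._season_slices.append(slice(start, start + m))
            start += m
        # any observed detection per site-season forces z = 1
        self.det_any = np.zeros((self.n_sites, self.n_seasons), dtype=bool)
        self.n_obs_months = np.zeros((self.n_sites, self.n_seasons))
        for t, sl in enumerate(self._season_slices):
            self.det_any[:, t] = np.any((self.y[:, sl] == 1.0) & self.obs[:, sl], axis=1)
            self.n_obs_months[:, t] = self.obs[:, sl].sum(axis=1)

    # -- emission terms ------------------------------------------------------
    def pstar_logs(self, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """log(1 - p_star) and log(p_star) per site-month (0 where missing)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.log1p(-np.where(self.obs, p, 0.0))
            # effort 0 (or a missing cell) means p_star = 0 exactly
            log_q = np.where(self.effort > 0, self.effort * raw, 0.0)
        # log(p_star) = log(1 - exp(log_q)); guard log(0) at log_q == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            log_pstar = np.where(log_q < 0, np.log(-np.expm1(log_q)), -np.inf)
        return log_q, log_pstar

    def emissions(self, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-site-season log emission probabilities for z=1 and z=0."""
        log_q, log_pstar = self.pstar_logs(p)
        term = np.where(self.obs,
                        np.where(self.y == 1.0, log_pstar, log_q), 0.0)
        e1 = np.empty((self.n_sites, self.n_seasons))
        for t, sl in enumerate(self._season_slices):
            e1[:, t] = term[:, sl].sum(axis=1)
        e0 = np.where(self.det_any, -np.inf, 0.0)
        return e1, e0

    # -- forward recursion ---------------------------------------------------
    def _forward(self, rates: RateSurfaces) -> tuple[np.ndarray, np.ndarray]:
        """Filtered joint log-probabilities alpha1/alpha0, (n_sites, T)."""
        e1, e0 = self.emissions(rates.p)
        n, T = self.n_sites, self.n_seasons
        a1 = np.empty((n, T))
        a0 = np.empty((n, T))
        with np.errstate(divide="ignore"):
            a1[:, 0] = np.log(rates.psi1) + e1[:, 0]
            a0[:, 0] = np.log1p(-rates.psi1) + e0[:, 0]
            lg = np.log(rates.gamma)
            l1mg = np.log1p(-rates.gamma)
            le = np.log(rates.eps)
            l1me = np.log1p(-rates.eps)
        for t in range(1, T):
            a1[:, t] = np.logaddexp(a1[:, t - 1] + l1me[:, t - 1],
                                    a0[:, t - 1] + lg[:, t - 1]) + e1[:, t]
            a0[:, t] = np.logaddexp(a1[:, t - 1] + le[:, t - 1],
                                    a0[:, t - 1] + l1mg[:, t - 1]) + e0[:, t]
        return a1, a0

    def log_likelihood(self, params: ParameterSet) -> float:
        rates = linear_predictors(self.spec, params, self.dataset)
        return self.log_likelihood_from_rates(rates)

    def log_likelihood_from_rates(self, rates: RateSurfaces) -> float:
        a1, a0 = self._forward(rates)
        per_site = np.logaddexp(a1[:, -1], a0[:, -1])
        total = float(per_site.sum())
        if np.isnan(total):
            raise NumericalGuardError("log-likelihood evaluated to NaN")
        return total

    # -- conditional latent-state draw (FFBS) --------------------------------
    def sample_latent(self, rates: RateSurfaces,
                      rng: np.random.Generator) -> np.ndarray:
        """One draw of z | y from the exact conditional (backward sampling)."""
        a1, a0 = self._forward(rates)
        n, T = self.n_sites, self.n_seasons
        z = np.empty((n, T), dtype=np.int8)
        z[:, -1] = _bern_from_logits(a1[:, -1], a0[:, -1], rng)
        with np.errstate(divide="ignore"):
            lg = np.log(rates.gamma)
            l1mg = np.log1p(-rates.gamma)
            le = np.log(rates.eps)
            l1me = np.log1p(-rates.eps)
        for t in range(T - 2, -1, -1):
            nxt = z[:, t + 1]
            # log P(z[t+1] | z[t]=1) and | z[t]=0
            lt1 = np.where(nxt == 1, l1me[:, t], le[:, t])
            lt0 = np.where(nxt == 1, lg[:, t], l1mg[:, t])
            z[:, t] = _bern_from_logits(a1[:, t] + lt1, a0[:, t] + lt0, rng)
        return z


def _bern_from_logits(l1: np.ndarray, l0: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Draw z in {0,1} with P(z=1) proportional to exp(l1) vs exp(l0)."""
    both_ninf = np.isneginf(l1) & np.isneginf(l0)
    if np.any(both_ninf):
        raise NumericalGuardError("impossible latent state: zero total probability")
    p1 = expit(l1 - l0)  # handles -inf correctly (expit(-inf)=0, expit(inf)=1)
    return (rng.random(p1.shape) < p1).astype(np.int8)


# ---------------------------------------------------------------------------
# Public likelihood API
# ---------------------------------------------------------------------------

def marginal_log_likelihood(spec: ModelSpec, params: ParameterSet,
                            dataset: Dataset) -> float:
    """Exact log P(y | params): the latent use states are summed out by a
    forward recursion over seasons.  Missing cells contribute no term; a
    season with no surveyed month is uninformative."""
    return LikelihoodEngine(spec, dataset).log_likelihood(params)


def sample_latent_states(spec: ModelSpec, params: ParameterSet,
                         dataset: Dataset,
                         rng: np.random.Generator) -> LatentStateMatrix:
    """Draw z | y, params exactly via forward-filter backward-sampling.

    Any site-season with an observed detection has z = 1 with probability 1.
    """
    engine = LikelihoodEngine(spec, dataset)
    rates = linear_predictors(spec, params, dataset)
    return LatentStateMatrix(z=engine.sample_latent(rates, rng))
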