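"""Posterior-predictive goodness-of-fit checks.

Two chi-square discrepancies are monitored, one per sub-model:

* closed part (detection): per site-season counts of months with a
  detection, compared with their expectation given the latent state and the
  effort-adjusted detection probabilities;
* open part (habitat-use transitions): per-transition counts of
  colonization and desertion events among the at-risk sites, compared with
  the expected counts under the colonization/desertion rates.

For each posterior draw the latent states are sampled conditional on the
observed data, a replicated dataset is simulated from the same draw (with
the observed missingness and effort pattern), and both discrepancies are
evaluated on the observed and the replicated data.  The Bayesian p-value is
Pr(chi2_replicated > chi2_observed) and the lack-of-fit ratio is
mean(chi2_observed) / mean(chi2_replicated); a p-value near 0.5 and a ratio
near 1 indicate an adequate model.

The exact cell structure of a chi-square discrepancy for this model family
is a design choice, not a canon; the aggregations above are a
reconstruction using the natural sufficient summaries of each sub-model.
Each squared residual is scaled by a binomial-variance denominator with a
small stabilizer c (default 0.5) guarding empty cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .design import DataValidationError, Dataset
from .model import (
    LikelihoodEngine,
    ModelSpec,
    RateSurfaces,
    effort_adjusted_detection,
    linear_predictors,
)
from .inference import PosteriorSamples

__all__ = [
    "GofResult",
    "chi_square_discrepancy_closed",
    "chi_square_discrepancy_open",
    "posterior_predictive_gof",
]

#: Stabilizing constant added to every variance denominator.
STABILIZER = 0.5


@dataclass
class GofResult:
    """Headline Bayesian p-values and lack-of-fit ratios plus per-draw arrays."""

    bpv_closed: float
    bpv_open: float
    lof_closed: float
    lof_open: float
    chi2_obs_closed: np.ndarray
    chi2_rep_closed: np.ndarray
    chi2_obs_open: np.ndarray
    chi2_rep_open: np.ndarray

    def __post_init__(self) -> None:
        for name in ("bpv_closed", "bpv_open"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DataValidationError(f"{name}={v} outside [0, 1]")

    def to_dict(self) -> dict[str, Any]:
        return {
            "bpv_closed": self.bpv_closed,
            "bpv_open": self.bpv_open,
            "lof_closed": self.lof_closed,
            "lof_open": self.lof_open,
            "chi2_obs_closed": self.chi2_obs_closed.tolist(),
            "chi2_rep_closed": self.chi2_rep_closed.tolist(),
            "chi2_obs_open": self.chi2_obs_open.tolist(),
            "chi2_rep_open": self.chi2_rep_open.tolist(),
        }


# ---------------------------------------------------------------------------
# Discrepancy statistics
# ---------------------------------------------------------------------------

def chi_square_discrepancy_closed(observed: np.ndarray, expected: np.ndarray,
                                  n_months: np.ndarray,
                                  c: float = STABILIZER) -> float:
    """Detection-part chi-square over site-season cells.

    Parameters
    ----------
    observed, expected : (n_sites, n_seasons)
        Observed and expected counts of months with at least one detection.
    n_months : (n_sites, n_seasons)
        Number of surveyed months per cell (cells with zero months drop out).

    The denominator is the binomial-style variance expected * (1 -
    expected / n_months) plus the stabilizer c.
    """
    obs = np.asarray(observed, dtype=float)
    exp_ = np.asarray(expected, dtype=float)
    n = np.asarray(n_months, dtype=float)
    if obs.shape != exp_.shape or obs.shape != n.shape:
        raise DataValidationError("observed/expected/n_months shapes differ")
    active = n > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        var = exp_ * (1.0 - np.where(active, exp_ / np.where(active, n, 1.0), 0.0))
    contrib = (obs - exp_) ** 2 / (var + c)
    return float(contrib[active].sum())


def chi_square_discrepancy_open(z: np.ndarray, gamma: np.ndarray,
                                eps: np.ndarray, c: float = STABILIZER) -> float:
    """Transition-part chi-square over per-transition event counts.

    For each transition t -> t+1, colonization events are counted among the
    sites unused at t and compared with the expected count (the sum of their
    gamma); desertion events likewise among the used sites against their
    eps.  Each squared residual is scaled by the summed Bernoulli variance
    plus the stabilizer c.
    """
    z = np.asarray(z)
    g = np.asarray(gamma, dtype=float)
    e = np.asarray(eps, dtype=float)
    n, T = z.shape
    if g.shape != (n, T - 1) or e.shape != (n, T - 1):
        raise DataValidationError("gamma/eps must be (n_sites, n_seasons - 1)")
    total = 0.0
    for t in range(T - 1):
        unused = z[:, t] == 0
        used = ~unused
        o_col = float(np.sum(z[unused, t + 1] == 1))
        e_col = float(g[unused, t].sum())
        v_col = float((g[unused, t] * (1.0 - g[unused, t])).sum())
        total += (o_col - e_col) ** 2 / (v_col + c)
        o_des = float(np.sum(z[used, t + 1] == 0))
        e_des = float(e[used, t].sum())
        v_des = float((e[used, t] * (1.0 - e[used, t])).sum())
        total += (o_des - e_des) ** 2 / (v_des + c)
    return total


# ---------------------------------------------------------------------------
# Posterior-predictive loop
# ---------------------------------------------------------------------------

def _season_counts(engine: LikelihoodEngine, y: np.ndarray) -> np.ndarray:
    """Count months with a detection per site-season (observed cells only)."""
    out = np.empty((engine.n_sites, engine.n_seasons))
    for t, sl in enumerate(engine._season_slices):
        out[:, t] = (np.where(engine.obs[:, sl], y[:, sl], 0.0) == 1.0).sum(axis=1)
    return out


def _expected_counts(engine: LikelihoodEngine, z: np.ndarray,
                     pstar: np.ndarray) -> np.ndarray:
    """Expected detection-month counts per site-season given z and p_star."""
    out = np.empty((engine.n_sites, engine.n_seasons))
    masked = np.where(engine.obs, pstar, 0.0)
    for t, sl in enumerate(engine._season_slices):
        out[:, t] = masked[:, sl].sum(axis=1) * z[:, t]
    return out


def _simulate_z(rates: RateSurfaces, rng: np.random.Generator,
                n_seasons: int) -> np.ndarray:
    """Forward-simulate latent states from a draw's rates (unconditional)."""
    n = rates.psi1.shape[0]
    z = np.empty((n, n_seasons), dtype=np.int8)
    z[:, 0] = rng.random(n) < rates.psi1
    for t in range(1, n_seasons):
        p1 = np.where(z[:, t - 1] == 1, 1.0 - rates.eps[:, t - 1],
                      rates.gamma[:, t - 1])
        z[:, t] = rng.random(n) < p1
    return z


def posterior_predictive_gof(samples: PosteriorSamples, spec: ModelSpec,
                             dataset: Dataset,
                             rng: np.random.Generator | int | None = None,
                             n_draws: int = 500) -> GofResult:
    """Run the posterior-predictive check over ``n_draws`` posterior draws.

    Replicated data inherit the observed missingness pattern and effort, so
    observed and replicated discrepancies are directly comparable.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    engine = LikelihoodEngine(spec, dataset)
    total = samples.n_chains * samples.n_draws_per_chain
    if n_draws > total:
        raise DataValidationError(
            f"n_draws={n_draws} exceeds the {total} retained draws")
    idx = np.sort(samples.subsample_indices(n_draws, rng))
    obs_counts = _season_counts(engine, engine.y)

    co = np.empty(n_draws); cr = np.empty(n_draws)
    oo = np.empty(n_draws); orp = np.empty(n_draws)
    for k, i in enumerate(idx):
        params = samples.parameter_set(int(i))
        rates = linear_predictors(spec, params, dataset)
        pstar = effort_adjusted_detection(rates.p, engine.effort)
        # closed part: condition z on the observed data
        z_cond = engine.sample_latent(rates, rng)
        expected = _expected_counts(engine, z_cond, pstar)
        y_rep = np.where(
            engine.obs,
            (rng.random(engine.y.shape)
             < z_cond[:, engine.season_of_month] * pstar).astype(float),
            np.nan,
        )
        rep_counts = _season_counts(engine, np.nan_to_num(y_rep))
        co[k] = chi_square_discrepancy_closed(obs_counts, expected,
                                              engine.n_obs_months)
        cr[k] = chi_square_discrepancy_closed(rep_counts, expected,
                                              engine.n_obs_months)
        # open part: conditional z versus a fresh unconditional replicate
        z_rep = _simulate_z(rates, rng, engine.n_seasons)
        oo[k] = chi_square_discrepancy_open(z_cond, rates.gamma, rates.eps)
        orp[k] = chi_square_discrepancy_open(z_rep, rates.gamma, rates.eps)

    return GofResult(
        bpv_closed=float(np.mean(cr > co)),
        bpv_open=float(np.mean(orp > oo)),
        lof_closed=float(co.mean() / cr.mean()),
        lof_open=float(oo.mean() / orp.mean()),
        chi2_obs_closed=co, chi2_rep_closed=cr,
        chi2_obs_open=oo, chi2_rep_open=orp,
    )
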