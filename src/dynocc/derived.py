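"""Posterior derived quantities.

Two figure-style summaries are computed from a fitted model:

* the seasonal proportion of sites used — per posterior draw the latent use
  states are sampled conditional on the data and averaged over sites, which
  propagates both parameter and state uncertainty into the series;
* colonization/desertion response curves over a covariate grid for the two
  transition types (winter-to-summer and summer-to-winter), evaluated at
  the "typical area" (random intercept 0) with the other covariates at
  their standardized mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import DataValidationError, Dataset
from .model import LikelihoodEngine, ModelSpec, linear_predictors
from .inference import PosteriorSamples

__all__ = ["UseSeries", "ResponseCurve", "proportion_used", "response_curve"]


@dataclass
class UseSeries:
    """Posterior summary of the proportion of sites used per season."""

    season: np.ndarray       # 1-based season index
    label: tuple[str, ...]   # summer/winter per season
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    draws: np.ndarray        # (n_draws, n_seasons)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "season": self.season, "label": list(self.label),
            "mean": self.mean, "lo95": self.lo, "hi95": self.hi,
        })


@dataclass
class ResponseCurve:
    """Posterior mean and interval of gamma or eps along a covariate grid."""

    target: str                  # "colonization" or "desertion"
    covariate: str               # "popden" or "elevation"
    grid_std: np.ndarray
    grid_raw: np.ndarray
    transition_labels: tuple[str, ...]   # e.g. ("winter_to_summer", ...)
    mean: np.ndarray             # (n_transitions, n_grid)
    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid_std) <= 0):
            raise DataValidationError("covariate grid must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, lab in enumerate(self.transition_labels):
            for j, g in enumerate(self.grid_std):
                rows.append({
                    "transition": lab, "grid_std": g,
                    "grid_raw": self.grid_raw[j],
                    "mean": self.mean[k, j], "lo95": self.lo[k, j],
                    "hi95": self.hi[k, j],
                })
        return pd.DataFrame(rows)


def proportion_used(samples: PosteriorSamples, spec: ModelSpec,
                    dataset: Dataset,
                    rng: np.random.Generator | int | None = None,
                    n_draws: int | None = None, prob: float = 0.95) -> UseSeries:
    """Seasonal proportion of sites used, with parameter and state uncertainty.

    For each posterior draw the seasonal true use states are sampled given
    the observed histories and summed over sites.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    engine = LikelihoodEngine(spec, dataset)
    total = samples.n_chains * samples.n_draws_per_chain
    n_draws = min(n_draws or 1000, total)
    idx = np.sort(samples.subsample_indices(n_draws, rng))
    props = np.empty((n_draws, dataset.n_seasons))
    for k, i in enumerate(idx):
        params = samples.parameter_set(int(i))
        rates = linear_predictors(spec, params, dataset)
        z = engine.sample_latent(rates, rng)
        props[k] = z.mean(axis=0)
    lo_q, hi_q = (1 - prob) / 2, 1 - (1 - prob) / 2
    return UseSeries(
        season=np.arange(1, dataset.n_seasons + 1),
        label=dataset.seasons.labels,
        mean=props.mean(axis=0),
        lo=np.quantile(props, lo_q, axis=0),
        hi=np.quantile(props, hi_q, axis=0),
        draws=props,
    )


_COV_FOR_VARIANT = {"popden": "interaction_popden",
                    "elevation": "interaction_elevation"}


def response_curve(samples: PosteriorSamples, spec: ModelSpec, target: str,
                   covariate: str, grid: np.ndarray | None = None,
                   fixed_values: dict[str, float] | None = None,
                   dataset: Dataset | None = None,
                   prob: float = 0.95) -> ResponseCurve:
    """Colonization or desertion probability along a covariate grid.

    Requires the model variant whose gamma/eps formula interacts season
    with the requested covariate.  The curve conditions on the typical area
    (random intercept 0); ``fixed_values`` may pin the other covariate on
    its standardized scale (default 0).  When a dataset is supplied its
    standardization constants annotate the grid on the raw scale.
    """
    if target not in ("colonization", "desertion"):
        raise DataValidationError("target must be 'colonization' or 'desertion'")
    if covariate not in _COV_FOR_VARIANT:
        raise DataValidationError("covariate must be 'popden' or 'elevation'")
    if spec.variant != _COV_FOR_VARIANT[covariate]:
        raise DataValidationError(
            f"variant {spec.variant!r} has no season:{covariate} interaction; "
            f"use {_COV_FOR_VARIANT[covariate]!r}"
        )
    if samples.spec.variant != spec.variant:
        raise DataValidationError("samples were drawn under a different variant")
    grid = np.asarray(grid if grid is not None else np.linspace(-2, 2, 41),
                      dtype=float)
    coef_block = "gamma" if target == "colonization" else "eps"
    names = spec.gamma_names if coef_block == "gamma" else spec.eps_names
    cols = [samples.names.index(n) for n in names]
    draws = samples.pooled()[:, cols]  # (D, 4): int, season, cov, season:cov
    winter = np.asarray([0.0, 1.0])    # origin-season indicator per transition
    # eta: (D, transition, grid)
    eta = (draws[:, 0, None, None]
           + draws[:, 1, None, None] * winter[None, :, None]
           + draws[:, 2, None, None] * grid[None, None, :]
           + draws[:, 3, None, None] * winter[None, :, None] * grid[None, None, :])
    curves = expit(eta)
    lo_q, hi_q = (1 - prob) / 2, 1 - (1 - prob) / 2
    if dataset is not None:
        cov = dataset.covariates
        mu, sd = ((cov.popden_mean, cov.popden_sd) if covariate == "popden"
                  else (cov.elevation_mean, cov.elevation_sd))
        grid_raw = grid * sd + mu
    else:
        grid_raw = grid.copy()
    return ResponseCurve(
        target=target, covariate=covariate,
        grid_std=grid, grid_raw=grid_raw,
        transition_labels=("summer_to_winter", "winter_to_summer"),
        mean=curves.mean(axis=0),
        lo=np.quantile(curves, lo_q, axis=0),
        hi=np.quantile(curves, hi_q, axis=0),
    )
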