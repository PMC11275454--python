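"""Synthetic camera-trap data from the model's own generative process.

The generator draws clustered site covariates (areas differ in elevation
and human-population level), realizes area random intercepts, simulates the
latent seasonal use states forward through the colonization/desertion
dynamics, and emits monthly detections through the effort-adjusted
observation model.  Missingness (a long survey gap, sporadic camera
malfunction) is applied after generation, jointly to detections and effort.

Scenario presets cover the survey shape of the motivating study (171
stations in 10 areas, 22 alternating seasons over 110 months with a long
contiguous gap) plus small designs used for oracle and power checks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .design import (
    DataValidationError,
    Dataset,
    DetectionHistory,
    HABITAT_LEVELS,
    SeasonStructure,
    SiteCovariates,
    build_season_structure,
)
from .model import (
    LatentStateMatrix,
    ModelSpec,
    ParameterSet,
    RateSurfaces,
    effort_adjusted_detection,
    linear_predictors,
    transition_probability,
)

__all__ = [
    "SimulationScenario",
    "SimulationTruth",
    "simulate",
    "default_scenarios",
]


@dataclass(frozen=True)
class SimulationScenario:
    """Complete description of one synthetic survey.

    Coefficients are on the logit scale in the model's coefficient order
    (see :class:`~dynocc.model.ModelSpec` name lists); ``area_sd`` gives the
    four random-intercept scales from which area offsets are realized.
    """

    variant: str = "additive"
    n_sites: int = 100
    n_areas: int = 10
    n_summer: int = 5
    n_winter: int = 5
    summer_len: int = 6
    winter_len: int = 4
    first_season: str = "summer"
    psi_coefs: tuple[float, ...] = (0.4, 0.4, -0.4, -0.8, -0.5, 0.3, -0.2, 0.3)
    gamma_coefs: tuple[float, ...] = (-1.5, 2.5, -0.5, -0.5)
    eps_coefs: tuple[float, ...] = (-0.5, -1.5, 0.3, 0.5)
    p_coefs: tuple[float, ...] = (-3.0, -0.5, 0.3, -0.3, 0.3, 0.2, -0.2, 0.2)
    area_sd: tuple[float, ...] = (0.3, 0.3, 0.3, 0.3)
    habitat_probs: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)
    elev_area_spread: float = 1.0
    elev_within_sd: float = 0.5
    popden_area_spread: float = 1.0
    popden_within_sd: float = 0.5
    effort_min: int = 20
    effort_max: int = 31
    gap: tuple[int, int] | None = None  # 1-based inclusive month range
    malfunction_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < self.n_areas:
            raise DataValidationError("need at least one site per area")
        if self.n_areas < 1:
            raise DataValidationError("n_areas must be positive")
        probs = np.asarray(self.habitat_probs, dtype=float)
        if probs.size != len(HABITAT_LEVELS) or np.any(probs < 0) or abs(probs.sum() - 1) > 1e-9:
            raise DataValidationError("habitat_probs must be 4 probabilities summing to 1")
        if not (0 <= self.effort_min <= self.effort_max):
            raise DataValidationError("invalid effort range")
        if not (0.0 <= self.malfunction_rate < 1.0):
            raise DataValidationError("malfunction_rate must be in [0, 1)")
        if np.any(np.asarray(self.area_sd) <= 0):
            raise DataValidationError("area_sd entries must be positive")
        if self.gap is not None:
            a, b = self.gap
            if not (1 <= a <= b):
                raise DataValidationError("gap must be a 1-based (start, end) range")

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(self.variant)

    def season_structure(self) -> SeasonStructure:
        return build_season_structure(self.n_summer, self.n_winter,
                                      self.summer_len, self.winter_len,
                                      first=self.first_season)


@dataclass
class SimulationTruth:
    """Generating parameters plus the realized states and rate surfaces."""

    params: ParameterSet
    z: LatentStateMatrix
    rates: RateSurfaces


def _draw_covariates(scn: SimulationScenario,
                     rng: np.random.Generator) -> SiteCovariates:
    n, A = scn.n_sites, scn.n_areas
    area_of_site = np.sort(rng.integers(0, A, size=n))
    # guarantee every area holds at least one site
    area_of_site[:A] = np.arange(A)
    area_of_site = np.sort(area_of_site)
    area_ids = [f"A{k + 1:02d}" for k in range(A)]

    elev_means = rng.normal(0.0, scn.elev_area_spread, A)
    pop_means = rng.normal(0.0, scn.popden_area_spread, A)
    elev_lat = elev_means[area_of_site] + rng.normal(0, scn.elev_within_sd, n)
    pop_lat = pop_means[area_of_site] + rng.normal(0, scn.popden_within_sd, n)
    # raw scales: metres a.s.l. and persons per km^2 (log-normal-ish)
    elevation_raw = 1000.0 + 350.0 * elev_lat
    popden_raw = np.exp(1.0 + 0.8 * pop_lat)
    habitat = rng.choice(HABITAT_LEVELS, size=n, p=scn.habitat_probs)
    return SiteCovariates(
        site_ids=tuple(f"S{i + 1:03d}" for i in range(n)),
        habitat=tuple(habitat.tolist()),
        elevation_raw=elevation_raw,
        popden_raw=popden_raw,
        area=tuple(area_ids[a] for a in area_of_site),
    )


def simulate(scenario: SimulationScenario,
             seed: int | None = None) -> tuple[Dataset, SimulationTruth]:
    """Generate one dataset and its ground truth; deterministic given seed."""
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    spec = scenario.spec
    seasons = scenario.season_structure()
    M, T = seasons.n_months, seasons.n_seasons
    n = scenario.n_sites

    cov = _draw_covariates(scenario, rng)
    A = len(cov.area_ids)
    area_sd = np.asarray(scenario.area_sd, dtype=float)
    area_effects = rng.normal(0.0, area_sd[:, None], (4, A))
    params = ParameterSet(
        spec=spec,
        psi_coefs=np.asarray(scenario.psi_coefs, dtype=float),
        gamma_coefs=np.asarray(scenario.gamma_coefs, dtype=float),
        eps_coefs=np.asarray(scenario.eps_coefs, dtype=float),
        p_coefs=np.asarray(scenario.p_coefs, dtype=float),
        area_effects=area_effects,
        area_sd=area_sd,
    )

    # rate surfaces need a Dataset shell (covariates + season map only)
    effort = rng.integers(scenario.effort_min, scenario.effort_max + 1,
                          size=(n, M)).astype(float)
    shell = Dataset(
        detection_history=DetectionHistory(
            site_ids=cov.site_ids, y=np.zeros((n, M)),
            effort=np.maximum(effort, 1.0)),
        covariates=cov, seasons=seasons,
    )
    rates = linear_predictors(spec, params, shell)

    z = np.empty((n, T), dtype=np.int8)
    z[:, 0] = rng.random(n) < rates.psi1
    for t in range(1, T):
        pr = transition_probability(z[:, t - 1], rates.gamma[:, t - 1],
                                    rates.eps[:, t - 1])
        z[:, t] = rng.random(n) < pr

    pstar = effort_adjusted_detection(rates.p, effort)
    season_of_month = seasons.season_of_month()
    y = (rng.random((n, M)) < z[:, season_of_month] * pstar).astype(float)

    missing = np.zeros((n, M), dtype=bool)
    if scenario.gap is not None:
        a, b = scenario.gap
        if b > M:
            raise DataValidationError(f"gap {scenario.gap} exceeds {M} months")
        missing[:, a - 1:b] = True
    if scenario.malfunction_rate > 0:
        missing |= rng.random((n, M)) < scenario.malfunction_rate
    y = np.where(missing, np.nan, y)
    effort = np.where(missing, np.nan, effort)

    dataset = Dataset(
        detection_history=DetectionHistory(site_ids=cov.site_ids, y=y,
                                           effort=effort),
        covariates=cov, seasons=seasons,
    )
    truth = SimulationTruth(params=params, z=LatentStateMatrix(z=z),
                            rates=rates)
    return dataset, truth


def default_scenarios() -> dict[str, SimulationScenario]:
    """Named scenario presets.

    ``paper_shape``
        The motivating survey's dimensions: 171 stations in 10 areas, 11
        summer (6-month) and 11 winter (4-month) seasons = 110 months, a
        35-month contiguous gap plus sporadic malfunction.
    ``strong_seasonality``
        100 sites, 10 seasons, large season contrasts in colonization and
        desertion (summer colonization high, summer desertion low).
    ``null_seasonality``
        As above with the season effects removed.
    ``human_avoidance``
        Colonization decreasing and desertion increasing with human
        population density.
    ``reduced``
        40 sites in 4 areas over 6 seasons; a desk-scale design for
        replicated fit studies (coverage, calibration).
    ``tiny``
        8 sites and 4 seasons; small enough for exhaustive latent-state
        enumeration.
    """
    strong = SimulationScenario()  # defaults are the strong-seasonality design
    return {
        "strong_seasonality": strong,
        "reduced": replace(
            strong, n_sites=40, n_areas=4, n_summer=3, n_winter=3,
        ),
        "paper_shape": replace(
            strong, n_sites=171, n_areas=10, n_summer=11, n_winter=11,
            summer_len=6, winter_len=4, gap=(35, 69), malfunction_rate=0.02,
        ),
        "null_seasonality": replace(
            strong,
            gamma_coefs=(-0.8, 0.0, -0.5, -0.5),
            eps_coefs=(-0.8, 0.0, 0.3, 0.5),
        ),
        "human_avoidance": replace(
            strong,
            gamma_coefs=(-0.8, 1.0, -0.3, -1.2),
            eps_coefs=(-0.8, -0.5, 0.2, 1.2),
        ),
        "tiny": replace(
            strong, n_sites=8, n_areas=2, n_summer=2, n_winter=2,
            summer_len=2, winter_len=2,
        ),
    }
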