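"""Shared fixtures.

The two expensive session fixtures (a full-size strong-seasonality fit and a
20-replicate simulate-fit study on a reduced design) are shared by several
acceptance-level checks so each fit is paid for once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import dynocc as dc
from dynocc.inference import McmcConfig, ParameterLayout, diagnose, summarize


@pytest.fixture(scope="session")
def scenarios():
    return dc.default_scenarios()


@pytest.fixture(scope="session")
def tiny_bundle(scenarios):
    scn = scenarios["tiny"]
    ds, truth = dc.simulate(scn, seed=1)
    return scn, ds, truth


@dataclass
class FitBundle:
    scenario: dc.SimulationScenario
    dataset: dc.Dataset
    truth: dc.SimulationTruth
    samples: object
    report: object


@pytest.fixture(scope="session")
def strong_fit(scenarios) -> FitBundle:
    """Additive-model fit to a strong-seasonality dataset (100 sites,
    10 areas, 10 seasons), 3 chains at desk-scale length."""
    scn = scenarios["strong_seasonality"]
    ds, truth = dc.simulate(scn, seed=11)
    cfg = McmcConfig(n_chains=3, n_iter=100_000, n_burnin=50_000, thin=10, seed=3)
    samples = dc.fit(scn.spec, ds, mcmc=cfg)
    report = diagnose(samples)
    return FitBundle(scn, ds, truth, samples, report)


@dataclass
class ReplicateStudy:
    coverage: np.ndarray  # per-replicate fraction of fixed coefficients covered


@dataclass
class GofCalibrationStudy:
    bpv_open: np.ndarray
    bpv_closed: np.ndarray
    lof_open: np.ndarray
    lof_closed: np.ndarray


def prior_drawn_scenario(base: dc.SimulationScenario,
                         rng: np.random.Generator) -> dc.SimulationScenario:
    """Redraw the generating parameters from the model's priors
    (logistic intercepts, standard-normal slopes, half-normal area scales);
    the generator itself draws area offsets normal(0, sd).  Under this
    calibration design 95% credible intervals cover the generating values
    at exactly 95% when likelihood and sampler are correct."""
    from dataclasses import replace
    spec = base.spec

    def block(n):
        v = rng.normal(0.0, 1.0, n)
        v[0] = rng.logistic(0.0, 1.0)
        return tuple(v)

    return replace(
        base,
        psi_coefs=block(spec.n_psi),
        gamma_coefs=block(spec.n_gamma),
        eps_coefs=block(spec.n_eps),
        p_coefs=block(spec.n_p),
        area_sd=tuple(np.abs(rng.normal(0.0, 1.0, 4)) + 1e-9),
    )


@pytest.fixture(scope="session")
def replicate_study(scenarios) -> ReplicateStudy:
    """20 simulate-fit-check replicates on the reduced design (40 sites,
    4 areas, 6 seasons), each with generating parameters drawn from the
    priors: interval coverage of the generating fixed-effect coefficients
    plus posterior-predictive calibration per replicate."""
    base = scenarios["reduced"]
    n_reps = 20
    cover = []
    for r in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence([77, r]))
        scn = prior_drawn_scenario(base, rng)
        ds, truth = dc.simulate(scn, seed=2000 + r)
        cfg = McmcConfig(n_chains=2, n_iter=40_000, n_burnin=20_000,
                         thin=4, seed=100 + r)
        s = dc.fit(scn.spec, ds, mcmc=cfg)
        lay = ParameterLayout(scn.spec, ds.covariates.area_ids)
        tv = lay.from_parameter_set(truth.params)
        summ = summarize(s)
        cov_r = [
            bool(summ.loc[nm, "lo"] <= tv[lay.names.index(nm)] <= summ.loc[nm, "hi"])
            for nm in lay.fixed_names
        ]
        cover.append(np.mean(cov_r))
    return ReplicateStudy(coverage=np.asarray(cover))


@pytest.fixture(scope="session")
def gof_calibration_study(scenarios) -> GofCalibrationStudy:
    """10 simulate-fit-check replicates at the reduced design's generating
    parameters (moderate detection and transition rates): the regime whose
    posterior-predictive calibration the chi-square construction targets."""
    scn = scenarios["reduced"]
    bo, bc, lo, lc = [], [], [], []
    for r in range(10):
        ds, _ = dc.simulate(scn, seed=5000 + r)
        cfg = McmcConfig(n_chains=2, n_iter=24_000, n_burnin=12_000,
                         thin=4, seed=400 + r)
        s = dc.fit(scn.spec, ds, mcmc=cfg)
        res = dc.posterior_predictive_gof(s, scn.spec, ds, rng=r, n_draws=250)
        bo.append(res.bpv_open); bc.append(res.bpv_closed)
        lo.append(res.lof_open); lc.append(res.lof_closed)
    return GofCalibrationStudy(
        bpv_open=np.asarray(bo), bpv_closed=np.asarray(bc),
        lof_open=np.asarray(lo), lof_closed=np.asarray(lc),
    )
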