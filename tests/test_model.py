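"""Model core: predictors, dynamics, detection, likelihood and latent draws.

The central oracle is exhaustive enumeration of all 2^T latent-state
sequences per site, implemented here independently of the package's forward
recursion.
"""

from dataclasses import replace
from itertools import product

import numpy as np
import pytest
from scipy.special import expit, logit

import dynocc as dc
from dynocc.design import DataValidationError, Dataset, DetectionHistory, SiteCovariates
from dynocc.model import (
    LikelihoodEngine,
    ModelSpec,
    ParameterSet,
    RateSurfaces,
    effort_adjusted_detection,
    linear_predictors,
    marginal_log_likelihood,
    sample_latent_states,
    transition_probability,
)


# ---------------------------------------------------------------------------
# Helpers and oracles
# ---------------------------------------------------------------------------

def single_site_dataset(n_months=1, months_per_season=(1,), y=None, effort=None):
    """One-site dataset with explicit observations."""
    labels = tuple("summer" if i % 2 == 0 else "winter"
                   for i in range(len(months_per_season)))
    seasons = dc.SeasonStructure(labels=labels,
                                 months_per_season=tuple(months_per_season))
    y = np.asarray([[0.0] * n_months] if y is None else y, dtype=float)
    effort = np.asarray([[1.0] * n_months] if effort is None else effort,
                        dtype=float)
    cov = SiteCovariates(site_ids=("S1",), habitat=("broadleaf",),
                         elevation_raw=np.array([100.0]),
                         popden_raw=np.array([5.0]), area=("A1",))
    dh = DetectionHistory(site_ids=("S1",), y=y, effort=effort)
    return Dataset(detection_history=dh, covariates=cov, seasons=seasons)


def params_with(spec, n_areas=1, **kwargs) -> ParameterSet:
    p = ParameterSet.null(spec, n_areas)
    for key, val in kwargs.items():
        arr = getattr(p, key).copy()
        if isinstance(val, dict):
            for idx, v in val.items():
                arr[idx] = v
        else:
            arr[...] = val
        setattr(p, key, arr)
    return p


def enumeration_log_likelihood(spec, params, dataset):
    """Brute-force sum over all latent sequences (independent oracle)."""
    eng = LikelihoodEngine(spec, dataset)
    rates = linear_predictors(spec, params, dataset)
    e1, e0 = eng.emissions(rates.p)
    T = dataset.n_seasons
    total = 0.0
    for i in range(dataset.n_sites):
        s = 0.0
        for zs in product([0, 1], repeat=T):
            lp = np.log(rates.psi1[i]) if zs[0] else np.log1p(-rates.psi1[i])
            for t in range(1, T):
                pr = (zs[t - 1] * (1 - rates.eps[i, t - 1])
                      + (1 - zs[t - 1]) * rates.gamma[i, t - 1])
                lp += np.log(pr) if zs[t] else np.log1p(-pr)
            for t in range(T):
                lp += e1[i, t] if zs[t] else e0[i, t]
            s += np.exp(lp)
        total += np.log(s)
    return total


def enumeration_latent_marginals(spec, params, dataset):
    """Exact P(z[i, t] = 1 | y) by enumeration (independent oracle)."""
    eng = LikelihoodEngine(spec, dataset)
    rates = linear_predictors(spec, params, dataset)
    e1, e0 = eng.emissions(rates.p)
    T = dataset.n_seasons
    marg = np.zeros((dataset.n_sites, T))
    for i in range(dataset.n_sites):
        weights = {}
        for zs in product([0, 1], repeat=T):
            lp = np.log(rates.psi1[i]) if zs[0] else np.log1p(-rates.psi1[i])
            for t in range(1, T):
                pr = (zs[t - 1] * (1 - rates.eps[i, t - 1])
                      + (1 - zs[t - 1]) * rates.gamma[i, t - 1])
                lp += np.log(pr) if zs[t] else np.log1p(-pr)
            for t in range(T):
                lp += e1[i, t] if zs[t] else e0[i, t]
            weights[zs] = np.exp(lp)
        tot = sum(weights.values())
        for t in range(T):
            marg[i, t] = sum(w for zs, w in weights.items() if zs[t]) / tot
    return marg


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

class TestTransitionProbability:
    @pytest.mark.parametrize("z,g,e,expect", [
        (1, 0.3, 0.0, 1.0),
        (0, 0.3, 0.9, 0.3),
        (1, 0.2, 0.4, 0.6),
    ])
    def test_values(self, z, g, e, expect):
        assert transition_probability(z, g, e) == pytest.approx(expect)

    def test_long_run_occupancy_matches_closed_form(self):
        """Iterating the two-state recursion converges to gamma/(gamma+eps)."""
        g, e = 0.23, 0.41
        p1 = 0.9
        for _ in range(300):
            p1 = p1 * (1 - e) + (1 - p1) * g
        assert p1 == pytest.approx(g / (g + e), abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(DataValidationError):
            transition_probability(1, 1.2, 0.1)


class TestEffortAdjustedDetection:
    @pytest.mark.parametrize("p,d,expect", [
        (0.5, 2, 0.75),
        (0.37, 1, 0.37),
        (0.1, 30, 1 - 0.9 ** 30),
        (0.8, 0, 0.0),
    ])
    def test_values(self, p, d, expect):
        assert effort_adjusted_detection(p, d) == pytest.approx(expect, rel=1e-12)

    def test_monotone_in_days_and_p(self):
        days = np.arange(0, 32)
        ps = effort_adjusted_detection(0.13, days)
        assert np.all(np.diff(ps) >= 0)
        grid = np.linspace(0, 1, 101)
        out = effort_adjusted_detection(grid, 7)
        assert np.all(np.diff(out) >= 0)

    def test_rejects_negative_days(self):
        with pytest.raises(DataValidationError):
            effort_adjusted_detection(0.5, -1)


class TestLinearPredictors:
    def test_all_zero_gives_half(self, tiny_bundle):
        scn, ds, _ = tiny_bundle
        params = ParameterSet.null(scn.spec, len(ds.covariates.area_ids))
        rates = linear_predictors(scn.spec, params, ds)
        for surf in (rates.psi1, rates.gamma, rates.eps, rates.p):
            assert np.allclose(surf, 0.5)

    def test_psi_intercept_only(self):
        ds = single_site_dataset()
        spec = ModelSpec("additive")
        params = params_with(spec, psi_coefs={0: logit(0.8)})
        rates = linear_predictors(spec, params, ds)
        assert rates.psi1[0] == pytest.approx(0.8)

    def test_handpicked_dot_product(self):
        """One site with conifer habitat: probabilities equal hand-computed
        inverse logits of the design products."""
        ds = single_site_dataset(n_months=2, months_per_season=(1, 1))
        cov = SiteCovariates(site_ids=("S1",), habitat=("conifer",),
                             elevation_raw=np.array([100.0]),
                             popden_raw=np.array([5.0]), area=("A1",))
        ds = Dataset(detection_history=ds.detection_history, covariates=cov,
                     seasons=ds.seasons)
        elev = float(cov.elevation_std[0])   # 0 for a single site
        pop = float(cov.popden_std[0])
        spec = ModelSpec("additive")
        params = params_with(
            spec,
            psi_coefs={0: 0.3, 1: -0.7, 4: 0.5, 5: 0.25},
            gamma_coefs={0: -0.2, 1: 1.1, 2: 0.4, 3: -0.6},
            p_coefs={0: -1.0, 1: 0.5, 2: 0.9, 5: -0.3},
        )
        params.area_effects[:] = [[0.11], [0.22], [0.33], [0.44]]
        rates = linear_predictors(spec, params, ds)
        assert rates.psi1[0] == pytest.approx(
            expit(0.3 - 0.7 + 0.5 * pop + 0.25 * pop + 0.11))
        # transition 1 originates in season 1 (summer): no season term
        assert rates.gamma[0, 0] == pytest.approx(
            expit(-0.2 + 0.4 * elev - 0.6 * pop + 0.22))
        # month 2 is winter: season effect and its habitat interaction apply
        assert rates.p[0, 0] == pytest.approx(expit(-1.0 + 0.9 + 0.44))
        assert rates.p[0, 1] == pytest.approx(expit(-1.0 + 0.5 + 0.9 - 0.3 + 0.44))

    def test_origin_season_convention(self):
        """gamma for a transition uses the label of the season it starts in."""
        ds = single_site_dataset(n_months=4, months_per_season=(1, 1, 1, 1))
        spec = ModelSpec("additive")
        params = params_with(spec, gamma_coefs={0: 0.0, 1: 2.0})
        rates = linear_predictors(spec, params, ds)
        # seasons: summer, winter, summer, winter -> origins s, w, s
        assert np.allclose(rates.gamma[0], expit(np.array([0.0, 2.0, 0.0])))

    def test_dimension_mismatch_rejected(self, tiny_bundle):
        scn, ds, truth = tiny_bundle
        with pytest.raises(DataValidationError):
            ParameterSet(spec=scn.spec, psi_coefs=np.zeros(3),
                         gamma_coefs=np.zeros(4), eps_coefs=np.zeros(4),
                         p_coefs=np.zeros(8), area_effects=np.zeros((4, 2)),
                         area_sd=np.ones(4))


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

class TestMarginalLogLikelihood:
    def test_one_cell_detected(self):
        """psi = p* = 1/2 and a detection: both use and detection required."""
        ds = single_site_dataset(y=[[1.0]])
        spec = ModelSpec("additive")
        params = ParameterSet.null(spec, 1)
        assert marginal_log_likelihood(spec, params, ds) == pytest.approx(
            np.log(0.25), abs=1e-12)

    def test_one_cell_undetected(self):
        ds = single_site_dataset(y=[[0.0]])
        spec = ModelSpec("additive")
        params = ParameterSet.null(spec, 1)
        assert marginal_log_likelihood(spec, params, ds) == pytest.approx(
            np.log(0.75), abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_on_random_instances(self, seed):
        """Forward recursion equals exhaustive 2^T enumeration, including
        datasets with missing cells."""
        scn = dc.default_scenarios()["tiny"]
        scn = replace(scn, malfunction_rate=0.2, seed=seed)
        ds, truth = dc.simulate(scn)
        got = marginal_log_likelihood(scn.spec, truth.params, ds)
        want = enumeration_log_likelihood(scn.spec, truth.params, ds)
        assert got == pytest.approx(want, abs=1e-10)

    def test_all_missing_is_zero(self, tiny_bundle):
        scn, ds, truth = tiny_bundle
        n, M = ds.n_sites, ds.n_months
        empty = Dataset(
            detection_history=DetectionHistory(
                site_ids=ds.detection_history.site_ids,
                y=np.full((n, M), np.nan), effort=np.full((n, M), np.nan)),
            covariates=ds.covariates, seasons=ds.seasons)
        assert marginal_log_likelihood(scn.spec, truth.params, empty) == pytest.approx(0.0, abs=1e-10)

    def test_monotone_in_detection_at_detected_cell(self, tiny_bundle):
        """Raising p at a cell holding a detection cannot lower the
        likelihood."""
        scn, ds, truth = tiny_bundle
        eng = LikelihoodEngine(scn.spec, ds)
        rates = linear_predictors(scn.spec, truth.params, ds)
        cell = np.argwhere((ds.detection_history.y == 1.0))[0]
        base = eng.log_likelihood_from_rates(rates)
        lls = [base]
        p = rates.p.copy()
        for bump in (0.05, 0.15, 0.3):
            p2 = p.copy()
            p2[cell[0], cell[1]] = min(0.999, p[cell[0], cell[1]] + bump)
            r2 = RateSurfaces(psi1=rates.psi1, gamma=rates.gamma,
                              eps=rates.eps, p=p2)
            lls.append(eng.log_likelihood_from_rates(r2))
        assert np.all(np.diff(lls) >= -1e-12)


# ---------------------------------------------------------------------------
# Conditional latent-state draws
# ---------------------------------------------------------------------------

class TestSampleLatentStates:
    def test_detection_forces_use(self):
        y = [[1.0, 0.0, 1.0, 1.0]]
        ds = single_site_dataset(n_months=4, months_per_season=(1, 1, 1, 1), y=y)
        spec = ModelSpec("additive")
        params = ParameterSet.null(spec, 1)
        rng = np.random.default_rng(0)
        for _ in range(50):
            z = sample_latent_states(spec, params, ds, rng).z
            assert z[0, 0] == 1 and z[0, 2] == 1 and z[0, 3] == 1

    def test_single_cell_bayes_rule(self):
        """P(z=1 | no detection) = (1/2 * 1/2) / (1/2 * 1/2 + 1/2) = 1/3."""
        ds = single_site_dataset(y=[[0.0]])
        spec = ModelSpec("additive")
        params = ParameterSet.null(spec, 1)
        eng = LikelihoodEngine(spec, ds)
        rates = linear_predictors(spec, params, ds)
        rng = np.random.default_rng(7)
        n = 20_000
        hits = sum(int(eng.sample_latent(rates, rng)[0, 0]) for _ in range(n))
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(hits / n - 1 / 3) < 3 * se

    def test_no_detection_power_recovers_prior_chain(self):
        """With p* = 0 the conditional draw is the unconditional Markov
        chain; frequencies match the analytic marginals."""
        T = 4
        ds = single_site_dataset(n_months=T, months_per_season=(1,) * T)
        spec = ModelSpec("additive")
        eng = LikelihoodEngine(spec, ds)
        psi, g, e = 0.35, 0.25, 0.45
        rates = RateSurfaces(
            psi1=np.array([psi]),
            gamma=np.full((1, T - 1), g), eps=np.full((1, T - 1), e),
            p=np.zeros((1, T)))
        # analytic chain marginals
        marg = [psi]
        for _ in range(T - 1):
            marg.append(marg[-1] * (1 - e) + (1 - marg[-1]) * g)
        rng = np.random.default_rng(11)
        n = 10_000
        freq = np.zeros(T)
        for _ in range(n):
            freq += eng.sample_latent(rates, rng)[0]
        freq /= n
        for t in range(T):
            se = np.sqrt(marg[t] * (1 - marg[t]) / n)
            assert abs(freq[t] - marg[t]) < 3 * se

    def test_conditional_marginals_match_enumeration(self):
        """FFBS frequencies agree with exact enumeration posteriors within
        Monte-Carlo error on a detected/undetected mixed history."""
        scn = dc.default_scenarios()["tiny"]
        ds, truth = dc.simulate(scn, seed=5)
        spec = scn.spec
        want = enumeration_latent_marginals(spec, truth.params, ds)
        eng = LikelihoodEngine(spec, ds)
        rates = linear_predictors(spec, truth.params, ds)
        rng = np.random.default_rng(3)
        n = 10_000
        freq = np.zeros_like(want)
        for _ in range(n):
            freq += eng.sample_latent(rates, rng)
        freq /= n
        se = np.sqrt(np.maximum(want * (1 - want), 1e-12) / n)
        assert np.all(np.abs(freq - want) <= 3 * se + 1e-9)
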