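"""Parametric survival fitting: closed forms, oracles, sampling, ranking."""
import numpy as np
import pytest
from scipy import stats

from psmcea import survfit
from psmcea.ipd import sample_survival_times
from psmcea.survfit import (
    FAMILIES, EstimationError, fit_parametric, loglikelihood, rank_fits,
    sample_parameters, survival_at, cumulative_hazard_at, hazard_at,
)

GENERATING = {
    "exponential": (0.15,),
    "weibull": (1.3, 8.0),
    "lognormal": (1.7, 0.8),
    "loglogistic": (1.5, 6.0),
    "gompertz": (0.08, 0.05),
    "generalized_gamma": (1.5, 0.9, 6.0),
}


def _censored_sample(family, params, n, seed, censor_q=0.8):
    rng = np.random.default_rng(seed)
    t = sample_survival_times(family, params, n, rng)
    c = np.quantile(t, censor_q)
    return np.minimum(t, c), (t <= c).astype(int)


def test_exponential_rate_closed_form():
    # d / sum(t) = 3 / 12
    fit = fit_parametric([2.0, 4.0, 6.0], [1, 1, 1], "exponential")
    assert fit.params[0] == pytest.approx(0.25, rel=1e-6)


def test_weibull_nests_exponential_loglik():
    times, events = [2.0, 4.0, 6.0, 5.0], [1, 1, 1, 0]
    exp_fit = fit_parametric(times, events, "exponential")
    rate = exp_fit.params[0]
    ll_weibull = loglikelihood("weibull", (1.0, 1.0 / rate), times, events)
    assert ll_weibull == pytest.approx(exp_fit.loglik, abs=1e-9)


def test_lognormal_mle_matches_grid_search_oracle():
    times, events = _censored_sample("lognormal", (1.7, 0.8), 500, seed=21)
    fit = fit_parametric(times, events, "lognormal")

    # independent brute-force likelihood oracle on a grid, scipy formulas
    def oracle_ll(mu, sigma):
        z = (np.log(times) - mu) / sigma
        ll = np.where(events == 1,
                      stats.norm.logpdf(z) - np.log(sigma * times),
                      stats.norm.logsf(z))
        return ll.sum()

    mus = np.linspace(1.2, 2.2, 201)
    sigmas = np.linspace(0.4, 1.2, 161)
    grid = np.array([[oracle_ll(m, s) for s in sigmas] for m in mus])
    i, j = np.unravel_index(np.argmax(grid), grid.shape)
    assert fit.loglik >= grid[i, j] - 1e-6
    assert fit.params[0] == pytest.approx(mus[i], abs=0.006)
    assert fit.params[1] == pytest.approx(sigmas[j], abs=0.006)
    # recovery within 3 SE of the generating values (transformed scale)
    se = np.sqrt(np.diag(fit.vcov))
    assert abs(fit.params[0] - 1.7) < 3 * se[0]
    assert abs(np.log(fit.params[1]) - np.log(0.8)) < 3 * se[1]


def test_information_criteria_identities(trial_ipd):
    act = trial_ipd[trial_ipd["arm"] == "active"]
    fit = fit_parametric(act["pfs_time"], act["pfs_event"], "weibull")
    assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik)
    assert fit.bic == pytest.approx(2 * np.log(fit.n) - 2 * fit.loglik)


def test_rank_fits_orders_by_aic_and_validates_n():
    times, events = _censored_sample("exponential", (0.2,), 2000, seed=3)
    fits = {f: fit_parametric(times, events, f)
            for f in ("exponential", "generalized_gamma")}
    table = rank_fits(fits.values())
    # on exponential data the BIC parsimony penalty favors the 1-parameter family
    by = {r["family"]: r for _, r in table.iterrows()}
    assert by["exponential"]["bic"] < by["generalized_gamma"]["bic"]
    single = rank_fits([fits["exponential"]])
    assert len(single) == 1 and single.loc[0, "family"] == "exponential"
    other = fit_parametric(times[:500], events[:500], "weibull")
    with pytest.raises(ValueError):
        rank_fits([fits["exponential"], other])


def test_survival_at_identities():
    exp_fit = survfit.ParametricSurvival("exponential", [0.25], 0.0, 10, np.zeros((1, 1)))
    assert survival_at(exp_fit, 0.0) == pytest.approx(1.0)
    assert survival_at(exp_fit, np.log(2) / 0.25) == pytest.approx(0.5)
    ln_fit = survfit.ParametricSurvival("lognormal", [1.7, 0.8], 0.0, 10, np.zeros((2, 2)))
    assert survival_at(ln_fit, np.exp(1.7)) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        survival_at(exp_fit, -1.0)


@pytest.mark.parametrize("family", sorted(FAMILIES))
def test_hazard_integrates_to_cumulative_hazard(family):
    """S(t) = exp(-integral of h) for every family, to 1e-6 on a grid."""
    fit = survfit.ParametricSurvival(family, GENERATING[family], 0.0, 100,
                                     np.zeros((len(GENERATING[family]),) * 2))
    grid = np.linspace(0.05, 30.0, 4000)
    h = hazard_at(fit, grid)
    H_num = np.concatenate([[0.0], np.cumsum(0.5 * (h[1:] + h[:-1]) * np.diff(grid))])
    H_ref = cumulative_hazard_at(fit, grid) - cumulative_hazard_at(fit, grid[0])
    s_num = np.exp(-H_num)
    s_ref = np.exp(-H_ref)
    assert np.max(np.abs(s_num - s_ref)) < 1e-5
    # survival is non-increasing with S(0) = 1
    s = survival_at(fit, np.linspace(0, 200, 500))
    assert s[0] == pytest.approx(1.0)
    assert np.all(np.diff(s) <= 1e-12)


def test_all_censored_raises():
    with pytest.raises(EstimationError):
        fit_parametric([1.0, 2.0, 3.0], [0, 0, 0], "weibull")


def test_fit_agrees_with_lifelines_oracle(trial_ipd):
    from lifelines import LogNormalFitter, WeibullFitter

    act = trial_ipd[trial_ipd["arm"] == "active"]
    t, e = act["pfs_time"], act["pfs_event"]
    wf = WeibullFitter().fit(np.maximum(t, 1e-9), e)
    ours = fit_parametric(t, e, "weibull")
    assert ours.params[0] == pytest.approx(wf.rho_, rel=1e-3)
    assert ours.params[1] == pytest.approx(wf.lambda_, rel=1e-3)
    lnf = LogNormalFitter().fit(np.maximum(t, 1e-9), e)
    ours = fit_parametric(t, e, "lognormal")
    assert ours.params[0] == pytest.approx(lnf.mu_, abs=1e-3)
    assert ours.params[1] == pytest.approx(lnf.sigma_, rel=1e-3)


def test_sample_parameters_degenerate_and_deterministic():
    fit = survfit.ParametricSurvival("weibull", [1.3, 8.0], 0.0, 100, np.zeros((2, 2)))
    draws = sample_parameters(fit, 7, seed=1)
    assert np.allclose(draws, fit.params)
    fit2 = survfit.ParametricSurvival("weibull", [1.3, 8.0], 0.0, 100,
                                      np.diag([0.01, 0.02]))
    a = sample_parameters(fit2, 50, seed=9)
    b = sample_parameters(fit2, 50, seed=9)
    np.testing.assert_array_equal(a, b)
    assert np.all(a > 0)  # log-scale sampling keeps positives positive


def test_sample_parameters_marginal_variances():
    vcov = np.diag([0.02, 0.005])
    fit = survfit.ParametricSurvival("lognormal", [1.7, 0.8], 0.0, 100, vcov)
    draws = sample_parameters(fit, 100_000, seed=4)
    transformed = np.column_stack([draws[:, 0], np.log(draws[:, 1])])
    var = transformed.var(axis=0)
    assert np.allclose(var, np.diag(vcov), rtol=0.05)


def test_serialization_round_trip(tmp_path):
    times, events = _censored_sample("weibull", (1.3, 8.0), 300, seed=8)
    fit = fit_parametric(times, events, "weibull")
    path = tmp_path / "fits.json"
    survfit.save_fits({"pfs_active": fit}, path)
    back = survfit.load_fits(path)["pfs_active"]
    np.testing.assert_allclose(back.params, fit.params)
    np.testing.assert_allclose(back.vcov, fit.vcov)
    assert back.aic == pytest.approx(fit.aic)
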