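"""Likelihood construction, ML fitting, nesting and model comparison.

The independent oracle for the likelihood is the K = 2 / zero-background
reduction: with a pure linear baseline on log time and no expected
mortality, the flexible model is exactly a Weibull all-cause model, which
lifelines fits by its own independent route.
"""

import numpy as np
import pandas as pd
import pytest

import flexcure as fc
from flexcure.models import CovariateDesign, information_criteria, lrt_cure


def _y(df):
    return df["time"].to_numpy(), df["event"].to_numpy()


def test_k2_zero_background_reduces_to_weibull(zero_ratetable, rng):
    """MLE of the K=2 flexible model on censoring-free-background data
    matches an independent Weibull fit (lifelines) to high accuracy."""
    lifelines = pytest.importorskip("lifelines")
    n = 4000
    t = rng.weibull(1.4, size=n) * 1.8
    cens = 3.0
    event = (t <= cens).astype(int)
    tobs = np.minimum(t, cens)
    df = pd.DataFrame({"time": tobs, "event": event, "age": 60.0,
                       "sex": "male", "year": 1990.0})
    m = fc.FlexibleParametricModel(knots=[0.05, 5.0], cure=False,
                                   orthogonalize=False,
                                   ratetable=zero_ratetable).fit(df, _y(df))
    wf = lifelines.WeibullFitter().fit(tobs, event)
    # ln Lambda = gamma00 + gamma01 (x - kK)  <=>  Lambda = (t/lambda)^rho,
    # the basis being centered at the last knot kK = ln 5
    rho, lam = wf.rho_, wf.lambda_
    assert m.params_[1] == pytest.approx(rho, rel=1e-5)
    assert m.params_[0] == pytest.approx(rho * (np.log(5.0) - np.log(lam)), rel=1e-5)
    assert m.loglik_ == pytest.approx(wf.log_likelihood_, rel=1e-6)


def test_cure_model_nested_within_unrestricted(fitted_cure, fitted_unrestricted):
    assert fitted_cure.loglik_ <= fitted_unrestricted.loglik_ + 1e-9
    assert len(fitted_unrestricted.params_) == len(fitted_cure.params_) + 1


def test_standard_and_backward_bases_are_reparameterisations(twogroup_sim):
    """Unrestricted fits with either basis agree in loglik, fitted relative
    survival and excess hazard ratios: the bases span the same space."""
    d = twogroup_sim.data
    kw = dict(covariates=["age_group"], ratetable=twogroup_sim.ratetable)
    ms = fc.FlexibleParametricModel(direction="standard", **kw).fit(d, _y(d))
    mb = fc.FlexibleParametricModel(direction="backward", **kw).fit(d, _y(d))
    assert ms.loglik_ == pytest.approx(mb.loglik_, abs=1e-6)
    tg = np.linspace(0.1, 10.0, 60)
    for pat in ({}, {"age_group": "B"}):
        np.testing.assert_allclose(ms.relative_survival(tg, pat),
                                   mb.relative_survival(tg, pat), atol=1e-6)
    ehr_s = ms.params_[ms.param_names_.index("age_group[B]")]
    ehr_b = mb.params_[mb.param_names_.index("age_group[B]")]
    assert ehr_s == pytest.approx(ehr_b, abs=1e-6)


def test_excess_hazard_ratio_recovers_simulated_contrast(twogroup_sim):
    """Under proportional-excess-hazard truth the fitted exp(beta) is the
    true excess hazard ratio, within its CI."""
    d = twogroup_sim.data
    m = fc.FlexibleParametricModel(cure=True, covariates=["age_group"],
                                   ratetable=twogroup_sim.ratetable).fit(d, _y(d))
    i = m.param_names_.index("age_group[B]")
    beta, se = m.params_[i], m.se_[i]
    assert abs(beta - 0.5) < 1.96 * se


def test_doubling_true_contrast_doubles_log_ehr():
    betas = {}
    for b in (0.4, 0.8):
        spec = fc.ScenarioSpec(
            n=8000, family="nonmixture", pi=0.5,
            uncured={"dist": "weibull", "scale": 1.1, "shape": 1.2},
            age_groups=(("A", 55.0, 65.0, 0.5), ("B", 65.0, 75.0, 0.5)),
            pi_age_effects={"B": b}, seed=99)
        res = fc.simulate_cohort(spec)
        m = fc.FlexibleParametricModel(cure=True, covariates=["age_group"],
                                       ratetable=res.ratetable
                                       ).fit(res.data, _y(res.data))
        i = m.param_names_.index("age_group[B]")
        betas[b] = (m.params_[i], m.se_[i])
    assert abs(betas[0.8][0] - 2 * betas[0.4][0]) < 2 * (
        betas[0.8][1] + 2 * betas[0.4][1])


def test_time_dependent_effects_fit_and_nest(twogroup_sim):
    d = twogroup_sim.data
    kw = dict(covariates=["age_group"], ratetable=twogroup_sim.ratetable)
    m0 = fc.FlexibleParametricModel(cure=True, **kw).fit(d, _y(d))
    m1 = fc.FlexibleParametricModel(cure=True, td_effects=["age_group"],
                                    **kw).fit(d, _y(d))
    assert m1.loglik_ >= m0.loglik_ - 1e-6
    assert len(m1.params_) > len(m0.params_)
    # cure prediction still uses only the constant parameters
    pc = fc.predict_cure(m1, {"age_group": "B"})
    assert 0.0 < pc["estimate"] < 1.0


def test_weibull_mixture_pi_zero_is_plain_weibull(recovery_sim):
    """With the cure link sent to pi ~ 0 the mixture likelihood equals the
    plain Weibull relative-survival likelihood computed directly."""
    d = recovery_sim.data
    m = fc.WeibullCureModel(kind="mixture", ratetable=recovery_sim.ratetable)
    m.fit(d, _y(d))
    sc, sh = 1.3, 1.1
    theta = np.array([5.0, np.log(sc), np.log(sh)])  # pi = exp(-e^5) ~ 1e-65
    got = -m._nll_mean(theta) * m.n_
    t, ev = d["time"].to_numpy(), d["event"].to_numpy().astype(float)
    hstar = m._fit_data[-1]
    lam = sc * sh * t ** (sh - 1.0)
    want = (ev * np.log(hstar + lam) - sc * t ** sh).sum()
    assert got == pytest.approx(want, rel=1e-10)


def test_nonmixture_recovers_its_own_parameters():
    spec = fc.ScenarioSpec(n=5000, family="nonmixture", pi=0.4,
                           uncured={"dist": "weibull", "scale": 0.9 ** -1.2,
                                    "shape": 1.2}, seed=7)
    res = fc.simulate_cohort(spec)
    m = fc.WeibullCureModel(kind="nonmixture",
                            ratetable=res.ratetable).fit(res.data, _y(res.data))
    assert fc.predict_cure(m)["estimate"] == pytest.approx(0.4, abs=0.03)
    sh = np.exp(m.params_[m.param_names_.index("lnshape:Intercept")])
    assert sh == pytest.approx(1.2, abs=0.15)


def test_lrt_statistic_and_refusals(fitted_cure, fitted_unrestricted):
    stat, df, p = lrt_cure(fitted_cure, fitted_unrestricted)
    assert stat == pytest.approx(
        2 * (fitted_unrestricted.loglik_ - fitted_cure.loglik_), abs=1e-9)
    assert stat >= 0 and df == 1 and 0 <= p <= 1
    with pytest.raises(ValueError, match="restricted"):
        lrt_cure(fitted_unrestricted, fitted_cure)
    other = fc.FlexibleParametricModel(knots=[0.1, 1.0, 11.0], cure=False,
                                       direction="backward")
    # different data / knots refused
    with pytest.raises(ValueError):
        lrt_cure(fitted_cure, other)


def test_information_criteria_formulas(fitted_cure, fitted_unrestricted):
    aic, bic = information_criteria(fitted_cure)
    p, n = len(fitted_cure.params_), fitted_cure.n_
    assert aic == pytest.approx(-2 * fitted_cure.loglik_ + 2 * p)
    assert bic == pytest.approx(-2 * fitted_cure.loglik_ + p * np.log(n))
    _, bic_ev = information_criteria(fitted_cure, n_convention="events")
    assert bic_ev == pytest.approx(
        -2 * fitted_cure.loglik_ + p * np.log(fitted_cure.n_events_))
    # restricted model has exactly one fewer parameter here
    aic_u, _ = information_criteria(fitted_unrestricted)
    dll = fitted_unrestricted.loglik_ - fitted_cure.loglik_
    assert (aic - aic_u) == pytest.approx(2 * dll - 2, abs=1e-9)


def test_parameter_count_cure_model(twogroup_sim):
    """flexible_cure with K knots and a 2-level covariate: (K-2) spline
    terms + intercept + 1 dummy."""
    d = twogroup_sim.data
    m = fc.FlexibleParametricModel(cure=True, knots="centiles 0 25 50 75 95 + fixed 12",
                                   covariates=["age_group"],
                                   ratetable=twogroup_sim.ratetable).fit(d, _y(d))
    K = len(m.knots_)
    assert len(m.params_) == (K - 2) + 1 + 1


def test_covariate_design_levels_and_patterns(twogroup_sim):
    des = CovariateDesign(["age_group", "age"]).fit(twogroup_sim.data)
    Z = des.transform(twogroup_sim.data)
    assert Z.shape[1] == 2  # 1 dummy + 1 numeric
    row = des.pattern_row({"age_group": "B", "age": 70.0})
    np.testing.assert_array_equal(row, [1.0, 70.0])
    np.testing.assert_array_equal(des.pattern_row(), [0.0, 0.0])
    with pytest.raises(KeyError):
        des.pattern_row({"age_group": "Z"})
    with pytest.raises(KeyError):
        des.pattern_row({"nope": 1})


def test_fit_input_validation(recovery_sim, zero_ratetable):
    d = recovery_sim.data
    with pytest.raises(ValueError, match="backward"):
        fc.FlexibleParametricModel(cure=True, direction="standard").fit(d, _y(d))
    with pytest.raises(ValueError, match="K >= 3"):
        fc.FlexibleParametricModel(cure=True, knots=[0.5, 11.0]).fit(d, _y(d))
    nodeath = d.assign(event=0)
    with pytest.raises(ValueError, match="event"):
        fc.FlexibleParametricModel().fit(nodeath, _y(nodeath))
    with pytest.raises(ValueError, match="kind"):
        fc.WeibullCureModel(kind="nope").fit(d, _y(d))


def test_zero_time_records_are_shifted(zero_ratetable, rng):
    t = np.concatenate([[0.0, 0.0], rng.weibull(1.2, 200)])
    df = pd.DataFrame({"time": t, "event": 1, "age": 60.0, "sex": "male",
                       "year": 1990.0})
    with pytest.warns(UserWarning, match="shifted"):
        m = fc.FlexibleParametricModel(knots=[0.01, 3.0],
                                       ratetable=zero_ratetable).fit(df, _y(df))
    assert m.zero_time_shifted_ == 2


def test_analytic_gradient_matches_finite_differences(fitted_cure):
    from flexcure.models import _fd_grad

    theta = fitted_cure.params_ + 0.05
    g_an = fitted_cure._grad_mean(theta)
    g_fd = _fd_grad(fitted_cure._nll_mean, theta)
    np.testing.assert_allclose(g_an, g_fd, atol=1e-6)


def test_loglik_wrappers(fitted_cure, fitted_nonmixture):
    from flexcure.models import loglik_flexible, loglik_weibull_cure

    assert loglik_flexible(fitted_cure.params_, None, None, fitted_cure) == \
        pytest.approx(fitted_cure.loglik_)
    assert loglik_weibull_cure(fitted_nonmixture.params_, None, None,
                               fitted_nonmixture) == \
        pytest.approx(fitted_nonmixture.loglik_)
    # perturbing the MLE can only lower the likelihood
    worse = fitted_cure.loglikelihood(fitted_cure.params_ + 0.1)
    assert worse < fitted_cure.loglik_


def test_fit_function_dispatch(recovery_sim):
    m = fc.fit({"family": "flexible_cure"}, recovery_sim.data,
               recovery_sim.ratetable)
    assert m.family == "flexible_cure"
    with pytest.raises(ValueError, match="family"):
        fc.fit({"family": "gamma"}, recovery_sim.data, None)
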