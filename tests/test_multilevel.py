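"""Mixed-model estimation: quadrature accuracy, identities, recovery."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from egosmoke import (
    ModelFit,
    ModelSpec,
    SyntheticConfig,
    fit_glm_logistic,
    fit_random_intercept_logistic,
    generate_regression_population,
    icc,
    marginal_loglik,
    nakagawa_r2,
)

from conftest import grid_loglik


def test_agq_matches_dense_grid_oracle(glmm_fixture):
    """Adaptive Gauss–Hermite (15 nodes) agrees with trapezoid integration
    over the random intercept to 1e-6 on the fixed 3-ego fixture."""
    beta, sigma = np.array([0.3, 0.8]), 1.3
    spec = ModelSpec(outcome="y", terms=("x",), n_quad=15)
    agq = marginal_loglik(glmm_fixture, spec, beta, sigma)
    grid = grid_loglik(glmm_fixture, beta, sigma)
    assert agq == pytest.approx(grid, abs=1e-6)


@pytest.mark.parametrize("beta0, beta1, sigma", [
    (0.0, 0.0, 0.5), (-1.0, 2.0, 0.2), (0.5, -1.5, 2.5),
])
def test_agq_matches_grid_across_parameter_values(glmm_fixture, beta0, beta1, sigma):
    spec = ModelSpec(outcome="y", terms=("x",), n_quad=15)
    agq = marginal_loglik(glmm_fixture, spec, [beta0, beta1], sigma)
    grid = grid_loglik(glmm_fixture, [beta0, beta1], sigma)
    assert agq == pytest.approx(grid, abs=1e-6)


def test_quadrature_converged_by_seven_nodes(glmm_fixture):
    """logLik at 7, 15 and 25 nodes agrees to < 1e-4 (adaptive centring)."""
    vals = [marginal_loglik(glmm_fixture,
                            ModelSpec(outcome="y", terms=("x",), n_quad=q),
                            [0.3, 0.8], 1.3) for q in (7, 15, 25)]
    assert max(vals) - min(vals) < 1e-4


def test_icc_formula_and_limits():
    assert icc(0.0) == 0.0
    assert icc(math.pi**2 / 3) == pytest.approx(0.5)
    assert icc(1e6) == pytest.approx(1.0, abs=1e-5)
    with pytest.raises(ValueError):
        icc(-0.1)


def test_fit_statistic_identities_from_published_model():
    """k=2, n=1622, logLik −916.082 imply AIC 1836.164, BIC 1846.947 and
    deviance 1832.164 under deviance + 2k / deviance + k·ln(n)."""
    fit = ModelFit(model_id="M0", outcome="y_smoker", terms=(),
                   beta=np.array([-1.08]), se=np.array([0.1]),
                   sigma2_u=0.5, loglik=-916.082, n_obs=1622, n_groups=76,
                   converged=True)
    assert fit.k_params == 2
    assert fit.deviance == pytest.approx(1832.164)
    assert fit.aic == pytest.approx(1836.164)
    assert fit.bic == pytest.approx(1846.947, abs=5e-4)


def test_sigma_zero_recovery_and_glm_agreement():
    """Data simulated with sigma_u = 0 and beta0 = 0 at n = 2000: the GLMM
    estimates a near-zero variance and intercept, and agrees with both our
    plain GLM and a statsmodels Logit cross-check."""
    rng = np.random.default_rng(17)
    frame = pd.DataFrame({
        "ego_id": np.repeat([f"e{i}" for i in range(50)], 40),
        "x": rng.normal(size=2000),
    })
    eta = 0.0 + 0.8 * frame["x"].to_numpy()
    frame["y"] = (rng.random(2000) < 1 / (1 + np.exp(-eta))).astype(int)

    spec = ModelSpec(outcome="y", terms=("x",), model_id="sim")
    mixed = fit_random_intercept_logistic(frame, spec)
    assert mixed.converged
    assert mixed.sigma2_u < 0.05
    assert abs(mixed.beta[0]) < 0.1

    glm = fit_glm_logistic(frame, spec)
    X = sm.add_constant(frame["x"].to_numpy())
    logit = sm.Logit(frame["y"].to_numpy(), X).fit(disp=0)
    np.testing.assert_allclose(glm.beta, logit.params, atol=1e-6)
    joint_se = np.sqrt(mixed.se**2 + glm.se**2)
    assert np.all(np.abs(mixed.beta - glm.beta) < 2 * joint_se)
    assert mixed.loglik == pytest.approx(glm.loglik, abs=0.05)


def test_glm_recovers_two_by_two_odds_ratio_exactly():
    """Counts (20,10;10,20) give a cross-product odds ratio of exactly 4."""
    rows = ([{"x": 1, "y": 1}] * 20 + [{"x": 1, "y": 0}] * 10
            + [{"x": 0, "y": 1}] * 10 + [{"x": 0, "y": 0}] * 20)
    frame = pd.DataFrame(rows)
    frame["ego_id"] = "e0"
    fit = fit_glm_logistic(frame, ModelSpec(outcome="y", terms=("x",)))
    assert math.exp(fit.beta[1]) == pytest.approx(4.0, abs=1e-6)


def test_balanced_null_table_gives_zero_coefficient():
    rows = [{"x": x, "y": y} for x in (0, 1) for y in (0, 1) for _ in range(25)]
    frame = pd.DataFrame(rows)
    frame["ego_id"] = "e0"
    fit = fit_glm_logistic(frame, ModelSpec(outcome="y", terms=("x",)))
    assert fit.beta[1] == pytest.approx(0.0, abs=1e-8)


def test_complete_separation_raises_naming_term():
    frame = pd.DataFrame({
        "ego_id": ["e1", "e1", "e2", "e2"] * 10,
        "sep": [0, 0, 1, 1] * 10,
        "y": [0, 0, 1, 1] * 10,
    })
    with pytest.raises(ValueError, match="sep"):
        fit_glm_logistic(frame, ModelSpec(outcome="y", terms=("sep",)))


def test_nakagawa_r2_identities():
    frame, _ = generate_regression_population(SyntheticConfig(n_egos=40), seed=6)
    fit = fit_random_intercept_logistic(
        frame, ModelSpec(outcome="y", terms=("assort",)))
    marg, cond = nakagawa_r2(fit, frame)
    assert 0 <= marg <= cond < 1
    assert fit.r2_marginal == pytest.approx(marg)
    # intercept-only: marginal exactly 0, conditional equals the ICC
    m0 = fit_random_intercept_logistic(frame, ModelSpec(outcome="y"))
    assert m0.r2_marginal == 0.0
    assert m0.r2_conditional == pytest.approx(m0.icc)


def test_parameter_recovery_of_planted_assortativity_effect():
    """Mean estimate over 8 seeds at 120 egos sits near the planted ln 3
    (within 3 Monte-Carlo SEs; the deeper 30-seed run lives in the
    acceptance suite)."""
    est = []
    for seed in range(8):
        frame, truth = generate_regression_population(
            SyntheticConfig(n_egos=120), seed=seed)
        fit = fit_random_intercept_logistic(
            frame, ModelSpec(outcome="y", terms=("assort",)))
        est.append(fit.beta[1])
    se = np.std(est, ddof=1) / np.sqrt(len(est))
    assert abs(np.mean(est) - math.log(3.0)) < 3 * se + 0.05


def test_errors_on_bad_input():
    frame = pd.DataFrame({"ego_id": ["e1", "e2"], "y": [0, 2]})
    with pytest.raises(ValueError, match="binary"):
        fit_random_intercept_logistic(frame, ModelSpec(outcome="y"))
    one_group = pd.DataFrame({"ego_id": ["e1"] * 4, "y": [0, 1, 0, 1]})
    with pytest.raises(ValueError, match="groups"):
        fit_random_intercept_logistic(one_group, ModelSpec(outcome="y"))
    nan_frame = pd.DataFrame({"ego_id": ["e1", "e2"], "y": [0.0, np.nan]})
    with pytest.raises(ValueError, match="missing"):
        fit_random_intercept_logistic(nan_frame, ModelSpec(outcome="y"))
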