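"""Two-level random-intercept logistic regression for alters nested in egos.

The model for alter i of ego j with covariate row x_ij is

    y_ij | u_j ~ Bernoulli( logit^-1( x_ij' beta + u_j ) ),
    u_j ~ Normal(0, sigma_u^2),

fitted by maximum marginal likelihood.  The per-ego integral over u_j has
no closed form and is evaluated by *adaptive* Gauss–Hermite quadrature:
for each ego the integrand is re-centred at its mode and re-scaled by the
curvature there before applying the Hermite rule, so a modest number of
nodes (default 15; 1 node equals the Laplace approximation) is accurate
even when an ego's likelihood is far from the prior's scale.

Reported alongside the odds ratios: the random-intercept variance
sigma_u^2; the intraclass correlation sigma_u^2 / (sigma_u^2 + pi^2/3)
using the latent logistic residual variance; AIC/BIC/deviance with
k = (fixed effects) + 1 for sigma_u; and latent-scale marginal/conditional
R^2 (fixed-effect variance over total; fixed-plus-random over total).

The plain logistic robustness models (no random intercept, with an
ego-level leave-one-out composition covariate instead) are delegated to
statsmodels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, logsumexp
from scipy.stats import norm

__all__ = [
    "ModelSpec",
    "ModelFit",
    "marginal_loglik",
    "fit_random_intercept_logistic",
    "fit_glm_logistic",
    "icc",
    "nakagawa_r2",
]

LOGISTIC_RESIDUAL_VAR = math.pi**2 / 3  # latent-scale residual variance

#: Past this magnitude a logit coefficient is treated as diverging
#: (complete separation), since exp(12) ~ 1.6e5 already dwarfs any OR a
#: social-network covariate could earn.
_SEPARATION_BOUND = 12.0


@dataclass(frozen=True)
class ModelSpec:
    """Which outcome and fixed effects to fit; grouping is always ego_id."""

    outcome: str
    terms: tuple[str, ...] = ()
    model_id: str = "custom"
    n_quad: int = 15
    group: str = "ego_id"

    def __post_init__(self) -> None:
        if self.n_quad < 1:
            raise ValueError("n_quad must be >= 1")


@dataclass
class ModelFit:
    """Estimates and fit statistics for one fitted model."""

    model_id: str
    outcome: str
    terms: tuple[str, ...]
    beta: np.ndarray  # includes leading intercept
    se: np.ndarray
    sigma2_u: float | None  # None for plain GLMs
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    r2_marginal: float | None = None
    r2_conditional: float | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def k_params(self) -> int:
        return len(self.beta) + (1 if self.sigma2_u is not None else 0)

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    @property
    def aic(self) -> float:
        return self.deviance + 2 * self.k_params

    @property
    def bic(self) -> float:
        return self.deviance + self.k_params * math.log(self.n_obs)

    @property
    def icc(self) -> float | None:
        return None if self.sigma2_u is None else icc(self.sigma2_u)

    def table(self) -> pd.DataFrame:
        """Coefficient table: OR, 95% Wald CI, p, per term."""
        names = ["intercept", *self.terms]
        z = np.divide(self.beta, self.se, out=np.full_like(self.beta, np.nan),
                      where=self.se > 0)
        p = 2 * norm.sf(np.abs(z))
        return pd.DataFrame({
            "term": names,
            "OR": np.exp(self.beta),
            "ci_low": np.exp(self.beta - 1.96 * self.se),
            "ci_high": np.exp(self.beta + 1.96 * self.se),
            "p": p,
        })


def icc(sigma2_u: float) -> float:
    """Intraclass correlation on the latent scale: s2 / (s2 + pi^2/3)."""
    if sigma2_u < 0:
        raise ValueError(f"variance must be non-negative, got {sigma2_u}")
    return sigma2_u / (sigma2_u + LOGISTIC_RESIDUAL_VAR)


def _design(records: pd.DataFrame, spec: ModelSpec):
    cols = [spec.outcome, *spec.terms, spec.group]
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise KeyError(f"records lack columns {missing}")
    sub = records[cols]
    if sub.isna().any().any():
        raise ValueError(
            "records contain missing values in modelled columns; apply "
            "listwise deletion upstream"
        )
    y = sub[spec.outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"outcome {spec.outcome} must be binary 0/1")
    X = np.column_stack([np.ones(len(sub))] +
                        [sub[t].to_numpy(dtype=float) for t in spec.terms])
    codes, uniques = pd.factorize(sub[spec.group], sort=True)
    return y, X, codes, len(uniques)


def _group_loglik_agq(y, eta0, codes, n_groups, sigma_u, n_quad):
    """Per-group marginal log-likelihood by adaptive Gauss–Hermite."""
    s2 = sigma_u * sigma_u
    if sigma_u < 1e-8:
        ll = y * eta0 - np.logaddexp(0.0, eta0)
        return np.bincount(codes, ll, minlength=n_groups)

    # Mode of the joint log-density in u, per group (Newton, vectorized).
    u = np.zeros(n_groups)
    for _ in range(100):
        mu = expit(eta0 + u[codes])
        score = np.bincount(codes, y - mu, minlength=n_groups) - u / s2
        info = np.bincount(codes, mu * (1 - mu), minlength=n_groups) + 1 / s2
        step = score / info
        np.clip(step, -5.0, 5.0, out=step)
        u += step
        if np.max(np.abs(step)) < 1e-12:
            break
    tau = 1.0 / np.sqrt(info)  # curvature scale at the mode

    z, w = hermgauss(n_quad)
    # integral = sqrt(2)*tau * sum_k w_k exp(z_k^2) g(u + sqrt(2)*tau*z_k)
    # with g the joint density; evaluated in logs for stability.
    log_terms = np.empty((n_quad, n_groups))
    for k in range(n_quad):
        uk = u + math.sqrt(2.0) * tau * z[k]
        eta = eta0 + uk[codes]
        ll_obs = y * eta - np.logaddexp(0.0, eta)
        log_g = (np.bincount(codes, ll_obs, minlength=n_groups)
                 - uk * uk / (2 * s2)
                 - math.log(sigma_u) - 0.5 * math.log(2 * math.pi))
        log_terms[k] = math.log(w[k]) + z[k] ** 2 + log_g
    return logsumexp(log_terms, axis=0) + 0.5 * math.log(2.0) + np.log(tau)


def marginal_loglik(
    records: pd.DataFrame, spec: ModelSpec, beta, sigma_u: float
) -> float:
    """Marginal log-likelihood at fixed parameters (quadrature from spec)."""
    y, X, codes, n_groups = _design(records, spec)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (X.shape[1],):
        raise ValueError(f"beta must have length {X.shape[1]} (incl. intercept)")
    return float(_group_loglik_agq(y, X @ beta, codes, n_groups,
                                   float(sigma_u), spec.n_quad).sum())


def _neg_loglik_factory(y, X, codes, n_groups, n_quad):
    def nll(params):
        beta, log_sigma = params[:-1], params[-1]
        sigma = math.exp(log_sigma)
        return -float(_group_loglik_agq(y, X @ beta, codes, n_groups,
                                        sigma, n_quad).sum())
    return nll


def _num_hessian(f, x, eps=1e-4):
    p = len(x)
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = eps
            ej = np.zeros(p); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return H


def fit_random_intercept_logistic(
    records: pd.DataFrame, spec: ModelSpec
) -> ModelFit:
    """Fit the two-level random-intercept logistic model by ML with AGQ.

    Records must be complete (listwise deletion upstream) with a binary
    outcome and at least two groups.  sigma_u is optimized on the log scale
    so the boundary sigma_u -> 0 stays reachable; a variance estimated at
    the boundary is reported as 0.  Complete separation (a diverging
    coefficient) raises ``ValueError`` naming the term.
    """
    y, X, codes, n_groups = _design(records, spec)
    if n_groups < 2:
        raise ValueError("need >= 2 groups (egos) for a random intercept")

    nll = _neg_loglik_factory(y, X, codes, n_groups, spec.n_quad)
    p = X.shape[1]
    x0 = np.zeros(p + 1)  # beta = 0, log sigma_u = 0 (sigma_u = 1)
    bounds = [(None, None)] * p + [(-7.0, 3.0)]
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"ftol": 1e-13, "gtol": 1e-6, "maxiter": 500, "maxfun": 20000},
    )
    beta_hat, log_sigma = res.x[:-1], res.x[-1]
    sigma_hat = math.exp(log_sigma)
    boundary = log_sigma <= bounds[-1][0] + 1e-6

    names = ["intercept", *spec.terms]
    big = np.abs(beta_hat) > _SEPARATION_BOUND
    if big.any():
        bad = [names[i] for i in np.flatnonzero(big)]
        raise ValueError(f"complete separation suspected: diverging "
                         f"coefficient(s) for {bad}")

    # Wald SEs from the observed information; at a variance boundary the
    # sigma block is degenerate, so fall back to the beta block alone.
    H = _num_hessian(nll, res.x)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
        if not np.isfinite(se).all():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov_b = np.linalg.pinv(H[:p, :p])
        se = np.sqrt(np.clip(np.diag(cov_b), 0, None))

    sigma2 = 0.0 if boundary else sigma_hat**2
    fit = ModelFit(
        model_id=spec.model_id,
        outcome=spec.outcome,
        terms=spec.terms,
        beta=beta_hat,
        se=se,
        sigma2_u=sigma2,
        loglik=-res.fun,
        n_obs=len(y),
        n_groups=n_groups,
        converged=bool(res.success),
        diagnostics={"n_quad": spec.n_quad, "optimizer_message": str(res.message),
                     "sigma_boundary": bool(boundary)},
    )
    fit.r2_marginal, fit.r2_conditional = nakagawa_r2(fit, records)
    return fit


def nakagawa_r2(fit: ModelFit, records: pd.DataFrame) -> tuple[float, float]:
    """Latent-scale marginal and conditional R^2 for a binary mixed model.

    marginal    = var(X beta) / (var(X beta) + sigma_u^2 + pi^2/3)
    conditional = (var(X beta) + sigma_u^2) / (same denominator)

    For an intercept-only model var(X beta) = 0, so marginal R^2 is exactly
    0 while conditional R^2 equals the ICC.
    """
    if not fit.terms:
        var_f = 0.0
    else:
        X = np.column_stack(
            [np.ones(len(records))]
            + [records[t].to_numpy(dtype=float) for t in fit.terms])
        var_f = float(np.var(X @ fit.beta))
    s2 = fit.sigma2_u or 0.0
    denom = var_f + s2 + LOGISTIC_RESIDUAL_VAR
    return var_f / denom, (var_f + s2) / denom


def fit_glm_logistic(records: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Plain (single-level) ML logistic fit of the same design.

    Used for the robustness models, where the random intercept is replaced
    by an ego-level leave-one-out composition covariate included among the
    terms.  Delegates the fit to statsmodels; separation raises
    ``ValueError`` naming the diverging term.
    """
    y, X, codes, n_groups = _design(records, spec)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=200)
    names = ["intercept", *spec.terms]
    big = np.abs(res.params) > _SEPARATION_BOUND
    if big.any():
        bad = [names[i] for i in np.flatnonzero(big)]
        raise ValueError(f"complete separation suspected: diverging "
                         f"coefficient(s) for {bad}")
    return ModelFit(
        model_id=spec.model_id,
        outcome=spec.outcome,
        terms=spec.terms,
        beta=np.asarray(res.params),
        se=np.asarray(res.bse),
        sigma2_u=None,
        loglik=float(res.llf),
        n_obs=len(y),
        n_groups=n_groups,
        converged=bool(res.converged),
        diagnostics={"engine": "statsmodels.GLM(Binomial)"},
    )
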