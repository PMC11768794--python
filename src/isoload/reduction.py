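"""Feature standardization, PCA compression and model-based evaluation.

Training-load indexes and training parameters are standardized, compressed
with principal component analysis, and evaluated against physiological
responses: one simple regression per (index, response) pair, plus the
first-component score ("Dim.1") and a meta-regression on the first k
components ("Stacked.Dim"). A random-intercept/random-slope hierarchical
model with weakly informative priors (Gaussian on fixed effects, Student-t
on random-effect standard deviations) is fitted by penalized marginal
likelihood with Laplace (curvature-based) intervals; an MCMC sampler is
available as an alternative engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.decomposition import PCA

from .exceptions import DataError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "ReductionModel",
    "HierarchicalModelSpec",
    "HierarchicalFit",
    "standardize",
    "pca_compress",
    "stacked_dim",
    "evaluate_tl_methods",
    "fit_hierarchical",
]


@dataclass
class FeatureTable:
    """A standardized feature matrix with the transform stored for inversion."""

    data: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    standardized: bool = True
    dropped: list[str] = field(default_factory=list)

    def inverse_transform(self) -> pd.DataFrame:
        return self.data * self.sds + self.means


@dataclass
class ReductionModel:
    loadings: pd.DataFrame       # feature x component
    explained_var: np.ndarray    # fraction per component
    scores: pd.DataFrame         # row x component
    k: int
    stacked_coefs: np.ndarray | None = None


@dataclass
class HierarchicalModelSpec:
    """Random-intercept (+ optional random-slope) linear mixed model.

    Priors: fixed effects ~ N(0, (10 k_scale)^2); random-effect SDs ~
    half-Student-t(1, 0, 2.5) for the intercept and half-Student-t(1, 0, 5)
    for the slope; these act as penalties on the marginal likelihood.
    """

    response: str
    fixed: list[str]
    group: str
    slope_on: str | None = None   # column carrying the random slope
    k_scale: float = 1.0
    beta_prior_sd: float = 10.0
    sd_intercept_prior_scale: float = 2.5
    sd_slope_prior_scale: float = 5.0
    engine: str = "laplace"       # or "mcmc"
    chains: int = 4
    iterations: int = 4000
    warmup: int = 1000

    def __post_init__(self):
        if self.beta_prior_sd <= 0 or self.k_scale <= 0:
            raise ParameterError("prior scales must be positive")


@dataclass
class HierarchicalFit:
    beta: pd.Series
    beta_se: pd.Series
    beta_ci: pd.DataFrame       # columns lo, hi (95%)
    sd_intercept: float
    sd_slope: float | None
    sd_residual: float
    icc: float
    pve_intercept: float
    pve_slope: float
    r2_conditional: float
    singular: bool = False
    loglik: float = np.nan
    aic: float = np.nan


# ---------------------------------------------------------------------------
# Standardization and PCA
# ---------------------------------------------------------------------------

def standardize(table: pd.DataFrame) -> FeatureTable:
    """Column-wise z-scores (sample SD); constant columns are dropped."""
    num = table.select_dtypes(include=[np.number])
    if num.shape[1] == 0:
        raise DataError("no numeric columns to standardize")
    if num.isna().any().any():
        raise DataError("missing values present; apply an imputation policy first")
    sds = num.std(ddof=1)
    constant = sds[(sds == 0) | sds.isna()].index.tolist()
    if constant:
        logger.warning("dropping constant columns: %s", constant)
        num = num.drop(columns=constant)
        sds = sds.drop(index=constant)
    if num.shape[1] == 0:
        raise DataError("all columns constant; nothing to standardize")
    means = num.mean()
    z = (num - means) / sds
    return FeatureTable(data=z, means=means, sds=sds, dropped=constant)


def pca_compress(ft: FeatureTable, k: int = 2) -> ReductionModel:
    """PCA of the standardized table with a deterministic sign convention.

    All components are kept (so explained variances sum to one); each
    loading vector is flipped so its largest-magnitude element is positive.
    ``k`` only records how many components downstream consumers use.
    """
    if not ft.standardized:
        raise ParameterError("standardize the table before PCA")
    X = ft.data.to_numpy(float)
    if X.shape[0] < 2:
        raise DataError("PCA needs at least two rows")
    n_comp = min(X.shape)
    if k > n_comp:
        raise ParameterError(f"k={k} exceeds the {n_comp} available components")
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # feature x component
    for j in range(loadings.shape[1]):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"Dim{j + 1}" for j in range(n_comp)]
    return ReductionModel(
        loadings=pd.DataFrame(loadings, index=ft.data.columns, columns=comp_names),
        explained_var=pca.explained_variance_ratio_,
        scores=pd.DataFrame(scores, index=ft.data.index, columns=comp_names),
        k=k,
    )


def _ols_r2(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    design = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise DataError("degenerate (constant) response")
    return coef, 1.0 - float(resid @ resid) / ss_tot


def stacked_dim(
    model: ReductionModel,
    response: np.ndarray,
    k: int | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Meta-regression of a response on the first k principal components.

    Returns the coefficients, R^2 and a seeded bootstrap 95% interval on
    R^2.
    """
    k = k if k is not None else model.k
    if k > model.scores.shape[1]:
        raise ParameterError(f"k={k} exceeds available components")
    y = np.asarray(response, dtype=float)
    X = model.scores.to_numpy(float)[:, :k]
    if y.size != X.shape[0]:
        raise ParameterError("response length must match the score rows")
    coef, r2 = _ols_r2(X, y)
    rng = np.random.default_rng(seed)
    n = y.size
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            _, boots[b] = _ols_r2(X[idx], y[idx])
        except DataError:
            boots[b] = np.nan
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return {"coefs": coef, "r2": r2, "r2_ci": (float(lo), float(hi)), "k": k}


def evaluate_tl_methods(
    ft: FeatureTable,
    responses: pd.DataFrame,
    tl_columns: list[str] | None = None,
    k: int = 2,
    seed: int = 0,
    n_boot: int = 500,
) -> pd.DataFrame:
    """Variance in each response explained by each training-load method.

    One simple regression per (index, response) pair plus the Dim.1 and
    Stacked.Dim rows from a PCA of the feature table. Long-format output:
    columns (method, response, estimate, r2, r2_lo, r2_hi).
    """
    tl_columns = tl_columns or list(ft.data.columns)
    model = pca_compress(ft, k=k)
    rows = []
    rng = np.random.default_rng(seed)
    for resp_name in responses.columns:
        y = responses[resp_name].to_numpy(float)
        if np.ptp(y[np.isfinite(y)]) == 0 or not np.isfinite(y).all():
            logger.warning("response %s degenerate or incomplete; skipped", resp_name)
            continue
        for col in tl_columns:
            x = ft.data[col].to_numpy(float)
            coef, r2 = _ols_r2(x[:, None], y)
            rows.append({"method": col, "response": resp_name,
                         "estimate": coef[1], "r2": r2})
        d1 = stacked_dim(model, y, k=1, n_boot=n_boot, seed=int(rng.integers(2**31)))
        rows.append({"method": "Dim.1", "response": resp_name,
                     "estimate": d1["coefs"][1], "r2": d1["r2"],
                     "r2_lo": d1["r2_ci"][0], "r2_hi": d1["r2_ci"][1]})
        sk = stacked_dim(model, y, k=k, n_boot=n_boot, seed=int(rng.integers(2**31)))
        rows.append({"method": "Stacked.Dim", "response": resp_name,
                     "estimate": np.nan, "r2": sk["r2"],
                     "r2_lo": sk["r2_ci"][0], "r2_hi": sk["r2_ci"][1]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hierarchical model (penalized marginal likelihood)
# ---------------------------------------------------------------------------

def _group_matrices(data: pd.DataFrame, spec: HierarchicalModelSpec):
    y_all, X_all, Z_all = [], [], []
    for _, g in data.groupby(spec.group, sort=True):
        y_all.append(g[spec.response].to_numpy(float))
        X_all.append(np.column_stack(
            [np.ones(len(g))] + [g[c].to_numpy(float) for c in spec.fixed]))
        if spec.slope_on is not None:
            Z_all.append(np.column_stack(
                [np.ones(len(g)), g[spec.slope_on].to_numpy(float)]))
        else:
            Z_all.append(np.ones((len(g), 1)))
    return y_all, X_all, Z_all


def _neg_penalized_profile(log_sd, y_all, X_all, Z_all, spec):
    """Negative penalized marginal log-likelihood, beta profiled out by GLS."""
    sds = np.exp(log_sd)
    sd_re = sds[:-1]
    sd_e = sds[-1]
    G = np.diag(sd_re**2)
    p = X_all[0].shape[1]
    prior_prec = np.eye(p) / (spec.beta_prior_sd * spec.k_scale) ** 2
    A = prior_prec.copy()
    rhs = np.zeros(p)
    logdet = 0.0
    quad_parts = []
    Vinv_list = []
    for y, X, Z in zip(y_all, X_all, Z_all):
        V = Z @ G @ Z.T + sd_e**2 * np.eye(len(y))
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        logdet += 2.0 * float(np.sum(np.log(np.diag(L))))
        Vinv_y = np.linalg.solve(V, y)
        Vinv_X = np.linalg.solve(V, X)
        A += X.T @ Vinv_X
        rhs += X.T @ Vinv_y
        quad_parts.append((y, Vinv_y))
        Vinv_list.append((X, Vinv_X, Vinv_y))
    beta = np.linalg.solve(A, rhs)
    quad = sum(float(y @ Vy) for y, Vy in quad_parts) - float(beta @ rhs)
    n_total = sum(len(y) for y in y_all)
    nll = 0.5 * (logdet + quad + n_total * np.log(2 * np.pi))
    # prior penalties
    nll += 0.5 * float(beta @ prior_prec @ beta)
    nll -= stats.t.logpdf(sd_re[0], df=1, scale=spec.sd_intercept_prior_scale)
    if sd_re.size > 1:
        nll -= stats.t.logpdf(sd_re[1], df=1, scale=spec.sd_slope_prior_scale)
    # half-t on a log scale needs the Jacobian sd = exp(log_sd)
    nll -= float(np.sum(np.log(sds)))
    return nll, beta, A


def _neg_penalized_joint(beta, log_sd, y_all, X_all, Z_all, spec):
    """Joint (beta not profiled) negative penalized marginal log-likelihood."""
    sds = np.exp(log_sd)
    sd_re, sd_e = sds[:-1], sds[-1]
    G = np.diag(sd_re**2)
    nll = 0.0
    for y, X, Z in zip(y_all, X_all, Z_all):
        V = Z @ G @ Z.T + sd_e**2 * np.eye(len(y))
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf
        r = y - X @ beta
        u = np.linalg.solve(L, r)
        nll += 0.5 * (2.0 * float(np.sum(np.log(np.diag(L))))
                      + float(u @ u) + len(y) * np.log(2 * np.pi))
    prior_sd = spec.beta_prior_sd * spec.k_scale
    nll += 0.5 * float(beta @ beta) / prior_sd**2
    nll -= stats.t.logpdf(sd_re[0], df=1, scale=spec.sd_intercept_prior_scale)
    if sd_re.size > 1:
        nll -= stats.t.logpdf(sd_re[1], df=1, scale=spec.sd_slope_prior_scale)
    nll -= float(np.sum(np.log(sds)))
    return nll


def _sample_posterior(beta0, log_sd0, cov_beta, y_all, X_all, Z_all, spec,
                      seed: int = 0):
    """Random-walk Metropolis over (beta, log-SDs), one chain per seed.

    Proposals are Gaussian, scaled from the Laplace covariance of the fixed
    effects and a fixed step on the log-variance scale.
    """
    rng = np.random.default_rng(seed)
    p = beta0.size
    q = log_sd0.size
    theta = np.concatenate([beta0, log_sd0])
    step_beta = 2.4 / np.sqrt(p + q) * np.linalg.cholesky(cov_beta + 1e-12 * np.eye(p))
    step_sd = 0.15

    def logpost(th):
        return -_neg_penalized_joint(th[:p], th[p:], y_all, X_all, Z_all, spec)

    lp = logpost(theta)
    draws = np.empty((spec.iterations - spec.warmup, p + q))
    kept = 0
    for it in range(spec.iterations):
        prop = theta.copy()
        prop[:p] = theta[:p] + step_beta @ rng.standard_normal(p)
        prop[p:] = theta[p:] + step_sd * rng.standard_normal(q)
        lp_prop = logpost(prop)
        if np.log(rng.uniform()) < lp_prop - lp:
            theta, lp = prop, lp_prop
        if it >= spec.warmup:
            draws[kept] = theta
            kept += 1
    return draws


def fit_hierarchical(spec: HierarchicalModelSpec,
                     data: pd.DataFrame) -> HierarchicalFit:
    """Fit the mixed model by penalized marginal likelihood.

    Random effects are integrated out analytically (Gaussian marginal per
    participant); variance parameters are optimized on the log scale with
    the prior penalties, and the fixed effects are profiled out by
    penalized GLS. Intervals on the fixed effects come from the curvature
    of the penalized GLS problem at the optimum. A random-slope variance
    collapsing to zero triggers an intercept-only refit, flagged via
    ``singular``.
    """
    groups = data[spec.group].unique()
    if len(groups) < 2:
        raise DataError("need at least two participants")
    counts = data.groupby(spec.group).size()
    if (counts < 2).any():
        raise DataError("each participant needs at least two observations")
    if spec.engine not in ("laplace", "mcmc"):
        raise ParameterError("engine must be 'laplace' or 'mcmc'")

    y_all, X_all, Z_all = _group_matrices(data, spec)
    # the priors are scaled for a standardized response: fit on z-scores
    # and map the estimates back, which also makes ICC and the variance
    # shares invariant to affine rescaling of the response
    y_concat = np.concatenate(y_all)
    y_mean = float(np.mean(y_concat))
    y_scale = float(np.std(y_concat, ddof=1))
    if y_scale == 0:
        y_scale = 1.0
    y_all = [(y - y_mean) / y_scale for y in y_all]
    y_sd = 1.0
    n_re = Z_all[0].shape[1]
    x0 = np.log(np.full(n_re + 1, 0.5))

    def obj(log_sd):
        return _neg_penalized_profile(log_sd, y_all, X_all, Z_all, spec)[0]

    res = optimize.minimize(obj, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-9,
                                     "maxiter": 4000})
    nll, beta, A = _neg_penalized_profile(res.x, y_all, X_all, Z_all, spec)
    sds = np.exp(res.x)
    singular = False
    if n_re == 2 and sds[1] < 1e-4 * max(y_sd, 1e-6):
        logger.warning("random-slope variance collapsed; refitting intercept-only")
        singular = True
        intercept_spec = HierarchicalModelSpec(
            response=spec.response, fixed=spec.fixed, group=spec.group,
            slope_on=None, k_scale=spec.k_scale,
            beta_prior_sd=spec.beta_prior_sd,
            sd_intercept_prior_scale=spec.sd_intercept_prior_scale,
            sd_slope_prior_scale=spec.sd_slope_prior_scale,
            engine=spec.engine)
        fit = fit_hierarchical(intercept_spec, data)
        fit.singular = True
        return fit

    cov_beta = np.linalg.inv(A)
    se = np.sqrt(np.diag(cov_beta))
    names = ["intercept"] + list(spec.fixed)
    zcrit = stats.norm.ppf(0.975)
    ci = pd.DataFrame({"lo": beta - zcrit * se, "hi": beta + zcrit * se},
                      index=names)

    if spec.engine == "mcmc":
        p = beta.size
        chains = [_sample_posterior(beta, res.x, cov_beta, y_all, X_all,
                                    Z_all, spec, seed=c)
                  for c in range(spec.chains)]
        draws = np.vstack(chains)
        beta = draws[:, :p].mean(axis=0)
        se = draws[:, :p].std(axis=0, ddof=1)
        lo, hi = np.percentile(draws[:, :p], [2.5, 97.5], axis=0)
        ci = pd.DataFrame({"lo": lo, "hi": hi}, index=names)
        sds = np.exp(draws[:, p:].mean(axis=0))

    # map estimates back to the original response scale
    beta = beta * y_scale
    se = se * y_scale
    ci = ci * y_scale
    beta[0] += y_mean
    ci.iloc[0] += y_mean
    sds = sds * y_scale
    sd_b0 = float(sds[0])
    sd_b1 = float(sds[1]) if n_re == 2 else None
    sd_e = float(sds[-1])

    # variance decomposition (convention: variance shares of the total)
    yhat_fixed = np.concatenate([X @ beta for X in X_all])
    var_fixed = float(np.var(yhat_fixed, ddof=1)) if yhat_fixed.size > 1 else 0.0
    var_slope = 0.0
    if sd_b1 is not None:
        z2 = np.concatenate([Z[:, 1] for Z in Z_all])
        var_slope = sd_b1**2 * float(np.mean(z2**2))
    total = var_fixed + sd_b0**2 + var_slope + sd_e**2
    icc = sd_b0**2 / (sd_b0**2 + sd_e**2)
    r2_cond = (var_fixed + sd_b0**2 + var_slope) / total

    n_params = len(beta) + n_re + 1
    return HierarchicalFit(
        beta=pd.Series(beta, index=names),
        beta_se=pd.Series(se, index=names),
        beta_ci=ci,
        sd_intercept=sd_b0, sd_slope=sd_b1, sd_residual=sd_e,
        icc=float(icc),
        pve_intercept=float(sd_b0**2 / total),
        pve_slope=float(var_slope / total),
        r2_conditional=float(r2_cond),
        singular=singular,
        loglik=-float(nll),
        aic=2.0 * n_params + 2.0 * float(nll),
    )
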