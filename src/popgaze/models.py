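"""Mixed-model inference for trial-level outcomes.

Gaussian outcomes (pupil dilation, first-look latency) are fitted as linear
mixed models with a random intercept per infant, by maximum likelihood
(statsmodels MixedLM, ``reml=False`` so nested models are LRT-comparable).
Binary outcomes (first look to the face) are fitted as random-intercept
logistic models whose marginal likelihood is integrated by adaptive
Gauss-Hermite quadrature; the quadrature is mode-centred per cluster, so a
moderate number of nodes is accurate enough for likelihood-ratio testing.

Fixed-effect significance is assessed by single-term-deletion LRTs: the
reduced model is refitted on exactly the rows the full model used and
chi-square = 2 * (llf_full - llf_reduced) with df equal to the number of
parameters dropped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import scipy.optimize
import scipy.special
import scipy.stats
import statsmodels.api as sm
from statsmodels.tools.numdiff import approx_hess

__all__ = [
    "ModelSpec", "ModelFit", "fit_mixed", "lrt_single_term",
    "quadratic_test", "marginal_contrasts", "critical_f",
]


@dataclass
class ModelSpec:
    """Outcome, fixed-effect terms, family, and grouping column.

    ``terms`` are patsy term strings (e.g. ``"C(volume, Sum)"``,
    ``"age10"``, ``"center(isi_s)"``, ``"I(baseline_c**2)"``); the random
    part is always an intercept per ``groups``.
    """

    outcome: str
    terms: tuple[str, ...] | list[str]
    family: str = "gaussian"           # 'gaussian' | 'binomial'
    groups: str = "infant_id"

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        self.terms = tuple(self.terms)

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"{self.outcome} ~ {rhs}"

    def drop_term(self, term: str) -> "ModelSpec":
        if term not in self.terms:
            raise ValueError(f"term {term!r} not in model")
        for other in self.terms:
            if other != term and term in _interaction_parts(other):
                raise ValueError(
                    f"cannot drop {term!r}: it participates in the retained "
                    f"interaction {other!r}")
        return ModelSpec(self.outcome,
                         tuple(t for t in self.terms if t != term),
                         self.family, self.groups)


def _interaction_parts(term: str) -> list[str]:
    return [p.strip() for p in term.split(":")] if ":" in term else []


@dataclass
class ModelFit:
    """Fitted fixed effects, random-intercept variance, and log-likelihood."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    llf: float
    re_var: float
    n_obs: int
    n_groups: int
    converged: bool
    scale: float = float("nan")        # residual variance (gaussian only)
    design_info: object = None
    data: pd.DataFrame | None = field(default=None, repr=False)
    row_index: pd.Index | None = field(default=None, repr=False)

    @property
    def n_params(self) -> int:
        return len(self.params)


def _design(spec: ModelSpec, table: pd.DataFrame):
    """Build the outcome/design matrices, dropping rows with missing values
    in any referenced column (patsy's NA action), and keep the surviving
    row index so nested models can be fitted on identical rows."""
    y, X = patsy.dmatrices(spec.formula, table, return_type="dataframe")
    groups = table.loc[X.index, spec.groups]
    return np.asarray(y).ravel(), X, groups


def fit_mixed(spec: ModelSpec, table: pd.DataFrame,
              n_quad: int = 15, re_var_zero: bool = False) -> ModelFit:
    """Fit a random-intercept mixed model by maximum likelihood.

    ``re_var_zero`` fixes the random-intercept variance at zero, in which
    case the gaussian ML fit is exactly ordinary least squares.
    Non-convergence is reported through ``converged``, not raised.
    """
    y, X, groups = _design(spec, table)
    if groups.nunique() < 2:
        raise ValueError("need at least 2 groups for a mixed model")
    if spec.family == "gaussian":
        if re_var_zero:
            return _fit_lm(spec, y, X, groups, table)
        return _fit_lmm(spec, y, X, groups, table)
    return _fit_logit_glmm(spec, y, X, groups, table, n_quad=n_quad)


def _fit_lm(spec, y, X, groups, table) -> ModelFit:
    res = sm.OLS(y, np.asarray(X)).fit()
    names = list(X.columns)
    return ModelFit(
        spec=spec,
        params=pd.Series(np.asarray(res.params), index=names),
        bse=pd.Series(np.asarray(res.bse), index=names),
        cov_params=pd.DataFrame(np.asarray(res.cov_params()),
                                index=names, columns=names),
        llf=float(res.llf), re_var=0.0, n_obs=int(len(y)),
        n_groups=int(groups.nunique()), converged=True,
        scale=float(res.scale), design_info=X.design_info,
        data=table.loc[X.index], row_index=X.index,
    )


def _lmm_suffstats(y, X, groups):
    """Per-cluster sufficient statistics for the profiled random-intercept
    likelihood."""
    codes, _ = pd.factorize(np.asarray(groups))
    Xa = np.asarray(X, float)
    ya = np.asarray(y, float)
    ng = codes.max() + 1
    p = Xa.shape[1]
    xtx = Xa.T @ Xa
    xty = Xa.T @ ya
    yty = float(ya @ ya)
    a = np.zeros((ng, p))      # X_j' 1
    b = np.zeros(ng)           # 1' y_j
    np.add.at(a, codes, Xa)
    np.add.at(b, codes, ya)
    n_j = np.bincount(codes, minlength=ng).astype(float)
    return xtx, xty, yty, a, b, n_j


def _lmm_profile(lam, stats):
    """Profiled ML log-likelihood and GLS quantities at variance ratio
    ``lam`` = sigma_u^2 / sigma_e^2 (Woodbury closed forms per cluster)."""
    xtx, xty, yty, a, b, n_j, N = stats
    c = lam / (1.0 + lam * n_j)
    xwx = xtx - (a * c[:, None]).T @ a
    xwy = xty - a.T @ (c * b)
    ywy = yty - float(c @ b ** 2)
    beta = np.linalg.solve(xwx, xwy)
    rss = ywy - 2.0 * beta @ xwy + beta @ xwx @ beta
    sigma2 = max(rss / N, 1e-300)
    llf = (-0.5 * N * (math.log(2.0 * math.pi * sigma2) + 1.0)
           - 0.5 * float(np.sum(np.log1p(lam * n_j))))
    return llf, beta, sigma2, xwx


def _fit_lmm(spec, y, X, groups, table) -> ModelFit:
    """Exact ML for the random-intercept gaussian model.

    beta and the residual variance have closed forms given the variance
    ratio lambda = sigma_u^2/sigma_e^2, so the likelihood is maximized by a
    1-D search over log(lambda), with the lambda = 0 boundary checked
    explicitly.  Deterministic and accurate to optimizer tolerance, which
    single-term-deletion LRTs require.
    """
    N = len(y)
    base = _lmm_suffstats(y, X, groups)
    stats = (*base, N)

    def neg(u):
        return -_lmm_profile(math.exp(u), stats)[0]

    opt = scipy.optimize.minimize_scalar(neg, bounds=(-14.0, 10.0),
                                         method="bounded",
                                         options={"xatol": 1e-10})
    cand = [(_lmm_profile(0.0, stats)[0], 0.0)]
    cand.append((-opt.fun, math.exp(opt.x)))
    llf, lam = max(cand)
    _, beta, sigma2, xwx = _lmm_profile(lam, stats)
    names = list(X.columns)
    cov = sigma2 * np.linalg.inv(xwx)
    return ModelFit(
        spec=spec,
        params=pd.Series(beta, index=names),
        bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        llf=float(llf),
        re_var=float(lam * sigma2),
        n_obs=int(N),
        n_groups=int(groups.nunique()),
        converged=True,
        scale=float(sigma2),
        design_info=X.design_info,
        data=table.loc[X.index],
        row_index=X.index,
    )


# ---------------------------------------------------------------------------
# Random-intercept logistic GLMM via adaptive Gauss-Hermite quadrature

def _glmm_parts(y, X, groups):
    codes, _ = pd.factorize(np.asarray(groups))
    return np.asarray(y, float), np.asarray(X, float), codes, codes.max() + 1


def _cluster_modes(eta0, y, gidx, ng, sigma2, u0=None):
    """Newton maximization of the per-cluster integrand exponent."""
    u = np.zeros(ng) if u0 is None else u0.copy()
    for _ in range(100):
        eta = eta0 + u[gidx]
        mu = scipy.special.expit(eta)
        grad = np.bincount(gidx, weights=y - mu, minlength=ng) - u / sigma2
        curv = np.bincount(gidx, weights=mu * (1 - mu), minlength=ng) + 1.0 / sigma2
        step = grad / curv
        u += step
        if np.max(np.abs(step)) < 1e-10:
            break
    return u, curv


def _glmm_loglik(theta, y, X, gidx, ng, z_nodes, logw_nodes):
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = math.exp(min(log_sigma, 10.0))
    sigma2 = max(sigma * sigma, 1e-12)
    eta0 = X @ beta
    u_hat, curv = _cluster_modes(eta0, y, gidx, ng, sigma2)
    scale = 1.0 / np.sqrt(curv)
    # log integrand at shifted nodes, per node x cluster
    K = z_nodes.size
    log_terms = np.empty((K, ng))
    const = -0.5 * math.log(2.0 * math.pi) - math.log(sigma)
    for k in range(K):
        u_k = u_hat + math.sqrt(2.0) * scale * z_nodes[k]
        eta = eta0 + u_k[gidx]
        li = y * eta - np.logaddexp(0.0, eta)
        s = np.bincount(gidx, weights=li, minlength=ng)
        log_terms[k] = (logw_nodes[k] + z_nodes[k] ** 2 + s
                        + const - 0.5 * u_k ** 2 / sigma2)
    ll = scipy.special.logsumexp(log_terms, axis=0)
    ll += 0.5 * math.log(2.0) + np.log(scale)
    return float(np.sum(ll))


def _fit_logit_glmm(spec, y, X, groups, table, n_quad: int = 15) -> ModelFit:
    yv, Xv, gidx, ng = _glmm_parts(y, X, groups)
    z, w = np.polynomial.hermite.hermgauss(n_quad)
    logw = np.log(w)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        start_glm = sm.GLM(yv, Xv, family=sm.families.Binomial()).fit()
    theta0 = np.concatenate([start_glm.params, [math.log(0.3)]])

    def nll(theta):
        return -_glmm_loglik(theta, yv, Xv, gidx, ng, z, logw)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        opt = scipy.optimize.minimize(
            nll, theta0, method="L-BFGS-B",
            bounds=[(None, None)] * Xv.shape[1] + [(-8.0, 5.0)],
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
        hess = approx_hess(opt.x, nll)
    names = list(X.columns)
    k = len(names)
    try:
        cov_all = np.linalg.inv(hess)
        bse_all = np.sqrt(np.clip(np.diag(cov_all), 0.0, None))
    except np.linalg.LinAlgError:
        cov_all = np.full((k + 1, k + 1), np.nan)
        bse_all = np.full(k + 1, np.nan)
    sigma = math.exp(opt.x[-1])
    return ModelFit(
        spec=spec,
        params=pd.Series(opt.x[:k], index=names),
        bse=pd.Series(bse_all[:k], index=names),
        cov_params=pd.DataFrame(cov_all[:k, :k], index=names, columns=names),
        llf=-float(opt.fun),
        re_var=sigma * sigma,
        n_obs=int(len(yv)),
        n_groups=int(ng),
        converged=bool(opt.success),
        design_info=X.design_info,
        data=table.loc[X.index],
        row_index=X.index,
    )


# ---------------------------------------------------------------------------
# Likelihood-ratio tests

@dataclass
class LRTResult:
    term: str
    chi2: float
    df: int
    p: float
    full: ModelFit
    reduced: ModelFit


def lrt_single_term(spec: ModelSpec, term: str, table: pd.DataFrame,
                    n_quad: int = 15) -> LRTResult:
    """Single-term-deletion likelihood-ratio test.

    Both models are fitted by ML on exactly the rows the full model uses;
    the statistic is clipped at zero (boundary/optimizer noise can produce
    tiny negative values on truly-null terms).
    """
    full = fit_mixed(spec, table, n_quad=n_quad)
    reduced_spec = spec.drop_term(term)
    reduced = fit_mixed(reduced_spec, table.loc[full.row_index],
                        n_quad=n_quad)
    df = full.n_params - reduced.n_params
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(scipy.stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return LRTResult(term=term, chi2=chi2, df=df, p=p,
                     full=full, reduced=reduced)


def quadratic_test(table: pd.DataFrame, outcome: str, predictor: str,
                   family: str = "gaussian", groups: str = "infant_id",
                   extra_terms: tuple[str, ...] = (),
                   trim: tuple[float, float] = (1.0, 99.0),
                   n_quad: int = 15) -> dict:
    """Linear-vs-quadratic LRT within a robust predictor range.

    Rows outside the [trim] percentile range of ``predictor`` are removed
    before *both* fits (minimizes edge leverage on the quadratic term); the
    predictor is mean-centred so the linear coefficient stays interpretable.
    Returns the 1-df LRT plus the quadratic coefficient and its SE.
    """
    lo_p, hi_p = trim
    x = table[predictor]
    if x.notna().sum() == 0:
        raise ValueError("no usable rows for the quadratic test")
    lo, hi = np.nanpercentile(x.to_numpy(float), [lo_p, hi_p])
    sub = table[(x >= lo) & (x <= hi)].copy()
    if len(sub) == 0:
        raise ValueError("trimming removed every row")
    sub["_xc"] = sub[predictor] - sub[predictor].mean()
    spec = ModelSpec(outcome, tuple(extra_terms) + ("_xc", "I(_xc**2)"),
                     family=family, groups=groups)
    res = lrt_single_term(spec, "I(_xc**2)", sub, n_quad=n_quad)
    quad_name = [c for c in res.full.params.index if "_xc ** 2" in c][0]
    return {
        "chi2": res.chi2, "df": res.df, "p": res.p,
        "quad_coef": float(res.full.params[quad_name]),
        "quad_se": float(res.full.bse[quad_name]),
        "linear_fit": res.reduced, "quadratic_fit": res.full,
        "trim_range": (float(lo), float(hi)), "n": res.full.n_obs,
    }


# ---------------------------------------------------------------------------
# Marginal contrasts

def _representative_row(data: pd.DataFrame) -> dict:
    rep = {}
    for col in data.columns:
        s = data[col]
        if pd.api.types.is_numeric_dtype(s) and s.nunique() > 2:
            rep[col] = float(s.mean())
        elif pd.api.types.is_numeric_dtype(s):
            rep[col] = float(s.mean())   # binary covariate held at its mean
        else:
            rep[col] = s.mode().iloc[0]
    return rep


def marginal_contrasts(fit: ModelFit, factor: str,
                       level_a, level_b,
                       at: dict | None = None) -> dict:
    """Delta-method contrast between two factor levels.

    Builds two design rows differing only in ``factor`` (``level_a`` vs
    ``level_b``), with covariates from ``at`` and everything else held at
    sample means (categoricals at their mode), and returns the linear
    combination ``c'beta`` with its standard error.
    """
    if fit.design_info is None or fit.data is None:
        raise ValueError("fit does not carry design information")
    base = _representative_row(fit.data)
    base.update(at or {})
    if factor in fit.data.columns:
        observed = set(fit.data[factor].unique())
        for lev in (level_a, level_b):
            if lev not in observed:
                raise ValueError(f"level {lev!r} absent from the design "
                                 f"column {factor!r}")
    rows = pd.DataFrame([dict(base, **{factor: level_a}),
                         dict(base, **{factor: level_b})])
    (mat,) = patsy.build_design_matrices([fit.design_info], rows)
    c = np.asarray(mat)[0] - np.asarray(mat)[1]
    est = float(c @ fit.params.to_numpy())
    var = float(c @ fit.cov_params.to_numpy() @ c)
    se = math.sqrt(max(var, 0.0))
    z = est / se if se > 0 else math.nan
    p = 2.0 * scipy.stats.norm.sf(abs(z)) if se > 0 else math.nan
    return {"contrast": est, "se": se, "z": z, "p": p,
            "levels": (level_a, level_b), "at": dict(at or {})}


# ---------------------------------------------------------------------------
# Power-analysis utility

def critical_f(alpha: float, df1: float, df2: float) -> float:
    """Upper-tail critical value of the central F distribution."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degrees of freedom must be positive")
    return float(scipy.stats.f.isf(alpha, df1, df2))
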