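"""Random-intercept effect models.

Two questions drive the analysis: does training-data complexity raise the
hallucination rate, and does the hallucination rate depress downstream TSTR
utility?  Both are answered per generator family with mixed-effects models
in which the reference population is a random intercept — each population
carries its own distribution, core variables and task, so observations from
the same population share an offset.

* HR ~ complexity: a binomial-logit random-intercept GLMM on the aggregated
  hallucinated-record counts (successes out of k x |S| trials per trained
  generator).  The fixed effect is reported as an odds ratio per complexity
  unit.  The marginal likelihood is evaluated by adaptive Gauss-Hermite
  quadrature (the random intercepts are independent across populations, so
  it factorizes into one-dimensional integrals); confidence intervals are
  Wald, from the numerical Hessian at the optimum.

* TSTR ~ HR: a linear random-intercept model (REML) with HR in percentage
  points, so the slope reads as AUROC change per percentage point of HR.
  Only populations with sufficient HR spread across their variants
  (P90 - P10 >= 0.25 by default) enter this model; with a single retained
  population the random effect is dropped and ordinary least squares is used.

Model fit is summarized by marginal and conditional R2 (variance explained
by the fixed effect alone, and by fixed plus random together); on the
logit scale the residual variance is pi^2/3.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logsumexp
import statsmodels.api as sm

from .errors import FitError, ValidationError

__all__ = [
    "EffectEstimate",
    "hr_spread_filter",
    "retention_percentage",
    "fit_binomial_glmm",
    "fit_glmm_hr_on_complexity",
    "fit_lmm_tstr_on_hr",
    "nakagawa_r2",
    "subset_sensitivity",
]

logger = logging.getLogger("tabhallu.effects")

ALPHA = 0.05  # significance level
_Z = stats.norm.ppf(1 - ALPHA / 2)
_LOGIT_RESID_VAR = np.pi ** 2 / 3


@dataclass
class EffectEstimate:
    effect_scale: str  # "odds-ratio" | "slope"
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_groups: int
    method: str
    converged: bool = True

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def nakagawa_r2(var_fixed: float, var_random: float,
                var_residual: float) -> tuple[float, float]:
    """Marginal and conditional R2 from a variance decomposition:
    fixed/(total) and (fixed+random)/(total)."""
    total = var_fixed + var_random + var_residual
    if total <= 0:
        raise FitError("variance components missing or non-positive")
    return var_fixed / total, (var_fixed + var_random) / total


# ---------------------------------------------------------------------------
# HR-spread inclusion filter

def hr_spread_filter(table: pd.DataFrame, low_pct: float = 10,
                     high_pct: float = 90, min_spread: float = 0.25,
                     hr_col: str = "hr_mean", generator_col: str = "generator",
                     population_col: str = "population"
                     ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Keep, per generator, the populations whose HR spread across variants
    (P90 - P10, linear-interpolation percentiles) is at least ``min_spread``.

    Returns the filtered table and the retained populations per generator.
    An empty result is returned with a warning, not an error.
    """
    retained: dict[str, list[str]] = {}
    keep = np.zeros(len(table), dtype=bool)
    for (gen, pop), idx in table.groupby([generator_col, population_col]).groups.items():
        hr = table.loc[idx, hr_col].to_numpy(dtype=float)
        spread = np.percentile(hr, high_pct) - np.percentile(hr, low_pct)
        if spread >= min_spread:
            retained.setdefault(gen, []).append(pop)
            keep[table.index.get_indexer(idx)] = True
    out = table.loc[keep]
    if out.empty:
        logger.warning("hr_spread_filter retained no observations "
                       "(min_spread=%.2f)", min_spread)
    return out, retained


def retention_percentage(n_retained: int, n_total: int) -> float:
    """Share of trained generators surviving the spread filter, in percent."""
    if n_total <= 0 or not 0 <= n_retained <= n_total:
        raise ValidationError("need 0 <= n_retained <= n_total, n_total > 0")
    return 100.0 * n_retained / n_total


# ---------------------------------------------------------------------------
# binomial-logit random-intercept GLMM (adaptive Gauss-Hermite quadrature)

def _glmm_loglik(theta: np.ndarray, y: np.ndarray, n: np.ndarray,
                 x: np.ndarray, gidx: np.ndarray, n_groups: int,
                 nodes: np.ndarray, wts: np.ndarray) -> float:
    """Marginal log-likelihood (up to constants) of successes y out of n with
    logit p = b0 + b1 x + u_g, u_g ~ N(0, sigma^2)."""
    b0, b1, log_sigma = theta
    sigma2 = np.exp(2 * log_sigma)
    eta_fix = b0 + b1 * x

    # inner Newton for the per-group posterior mode of u (concave problem)
    u = np.zeros(n_groups)
    for _ in range(50):
        p = expit(eta_fix + u[gidx])
        grad = -u / sigma2 + np.bincount(gidx, weights=y - n * p,
                                         minlength=n_groups)
        hess = -1.0 / sigma2 - np.bincount(gidx, weights=n * p * (1 - p),
                                           minlength=n_groups)
        step = grad / hess
        u_new = u - step
        if np.max(np.abs(step)) < 1e-10:
            u = u_new
            break
        u = u_new
    p = expit(eta_fix + u[gidx])
    curv = 1.0 / sigma2 + np.bincount(gidx, weights=n * p * (1 - p),
                                      minlength=n_groups)
    s_hat = 1.0 / np.sqrt(curv)

    # adaptive GH: integrate exp(h) with nodes centered at the mode
    log_terms = np.empty((len(nodes), n_groups))
    for qi, (t, w) in enumerate(zip(nodes, wts)):
        uq = u + np.sqrt(2.0) * s_hat * t
        eta = eta_fix + uq[gidx]
        ll = y * eta - n * np.logaddexp(0.0, eta)
        h = (np.bincount(gidx, weights=ll, minlength=n_groups)
             - uq ** 2 / (2 * sigma2) - log_sigma)
        log_terms[qi] = np.log(w) + t ** 2 + h
    group_ll = logsumexp(log_terms, axis=0) + 0.5 * np.log(2.0) + np.log(s_hat)
    return float(group_ll.sum())


def fit_binomial_glmm(successes, trials, x, groups, n_quad: int = 15
                      ) -> dict:
    """Fit ``logit P = b0 + b1 x + u_group`` to binomial counts.

    Returns the coefficient vector, Wald standard errors, the random-intercept
    SD, and the maximized marginal log-likelihood.
    """
    y = np.asarray(successes, dtype=float)
    n = np.asarray(trials, dtype=float)
    x = np.asarray(x, dtype=float)
    labels, gidx = np.unique(np.asarray(groups), return_inverse=True)
    G = len(labels)
    if G < 2:
        raise FitError("random intercept unidentifiable with a single group")
    if np.any(n <= 0) or np.any(y < 0) or np.any(y > n):
        raise ValidationError("need 0 <= successes <= trials, trials > 0")

    nodes, wts = np.polynomial.hermite.hermgauss(n_quad)

    # starting values from the pooled GLM
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(np.column_stack([y, n - y]),
                     sm.add_constant(x), family=sm.families.Binomial()).fit()
    x0 = np.array([glm.params[0], glm.params[1], np.log(0.5)])

    def neg(theta):
        if theta[2] > 5 or theta[2] < -8:  # keep sigma in a sane range
            return 1e12
        return -_glmm_loglik(theta, y, n, x, gidx, G, nodes, wts)

    res = optimize.minimize(neg, x0, method="Nelder-Mead",
                            options={"maxiter": 2000, "xatol": 1e-7,
                                     "fatol": 1e-9})
    res2 = optimize.minimize(neg, res.x, method="Nelder-Mead",
                             options={"maxiter": 2000, "xatol": 1e-8,
                                      "fatol": 1e-10})
    theta = res2.x
    if not (res.success or res2.success):
        grad = optimize.approx_fprime(theta, neg, 1e-6)
        raise FitError(
            f"GLMM did not converge (|grad|={np.linalg.norm(grad):.3g}); "
            "try looser tolerance or rescaled covariate")

    hess = _numerical_hessian(neg, theta)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular Hessian at the optimum: {exc}") from exc
    se = np.sqrt(np.maximum(np.diag(cov), 0))
    return {
        "beta": theta[:2], "se": se[:2], "sigma_u": float(np.exp(theta[2])),
        "loglik": -res2.fun, "n_obs": len(y), "n_groups": G,
        "x": x, "converged": True,
    }


def _numerical_hessian(f, theta: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    k = len(theta)
    h = rel_step * np.maximum(np.abs(theta), 1.0)
    H = np.zeros((k, k))
    f0 = f(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def _glmm_estimate(fit: dict) -> EffectEstimate:
    b1, se1 = float(fit["beta"][1]), float(fit["se"][1])
    var_f = float(np.var(fit["beta"][1] * fit["x"]))
    r2m, r2c = nakagawa_r2(var_f, fit["sigma_u"] ** 2, _LOGIT_RESID_VAR)
    z = b1 / se1 if se1 > 0 else np.inf
    return EffectEstimate(
        effect_scale="odds-ratio",
        estimate=float(np.exp(b1)),
        ci_low=float(np.exp(b1 - _Z * se1)),
        ci_high=float(np.exp(b1 + _Z * se1)),
        p_value=float(min(1.0, 2 * stats.norm.sf(abs(z)))) or np.finfo(float).tiny,
        r2_marginal=r2m, r2_conditional=r2c,
        n_obs=fit["n_obs"], n_groups=fit["n_groups"],
        method="binomial-logit GLMM, adaptive Gauss-Hermite (Laplace-centered), Wald CI",
        converged=fit["converged"],
    )


def fit_glmm_hr_on_complexity(table: pd.DataFrame,
                              generator_col: str = "generator",
                              population_col: str = "population",
                              complexity_col: str = "complexity",
                              successes_col: str = "hallucinated_total",
                              trials_col: str = "trials_total",
                              min_obs: int = 10) -> dict[str, EffectEstimate]:
    """Per generator family: OR of hallucination per complexity unit, from the
    binomial random-intercept GLMM on aggregated hallucinated counts."""
    out: dict[str, EffectEstimate] = {}
    for gen, sub in table.groupby(generator_col):
        if sub[population_col].nunique() < 2:
            raise FitError(
                f"{gen}: random effect unidentifiable with a single population")
        if len(sub) < min_obs:
            raise ValidationError(f"{gen}: fewer than {min_obs} observations")
        fit = fit_binomial_glmm(sub[successes_col], sub[trials_col],
                                sub[complexity_col], sub[population_col])
        out[gen] = _glmm_estimate(fit)
    return out


# ---------------------------------------------------------------------------
# linear mixed model: TSTR ~ HR (percentage points)

def fit_lmm_tstr_on_hr(table: pd.DataFrame, learner: str = "gbm",
                       response_col: str | None = None,
                       hr_col: str = "hr_mean",
                       generator_col: str = "generator",
                       population_col: str = "population",
                       reml: bool = True) -> dict[str, EffectEstimate]:
    """Per generator family: AUROC change per percentage point of HR, from a
    random-intercept LMM (REML); plain OLS when only one population remains
    after filtering (no random effect to estimate)."""
    response_col = response_col or f"tstr_{learner}_mean"
    out: dict[str, EffectEstimate] = {}
    for gen, sub in table.groupby(generator_col):
        sub = sub.dropna(subset=[response_col, hr_col])
        if len(sub) < 3:
            raise ValidationError(f"{gen}: fewer than 3 observations")
        hr_pct = sub[hr_col].to_numpy(dtype=float) * 100.0
        y = sub[response_col].to_numpy(dtype=float)
        n_pops = sub[population_col].nunique()
        if n_pops < 2:
            X = sm.add_constant(hr_pct)
            ols = sm.OLS(y, X).fit()
            slope, se1 = float(ols.params[1]), float(ols.bse[1])
            var_f = float(np.var(slope * hr_pct))
            resid = float(ols.mse_resid)
            r2m, _ = nakagawa_r2(var_f, 0.0, resid)
            out[gen] = EffectEstimate(
                effect_scale="slope", estimate=slope,
                ci_low=slope - _Z * se1, ci_high=slope + _Z * se1,
                p_value=float(ols.pvalues[1]),
                r2_marginal=r2m, r2_conditional=r2m,
                n_obs=len(sub), n_groups=1,
                method="OLS (single population: no random effect)")
            continue
        X = sm.add_constant(hr_pct)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = sm.MixedLM(y, X, groups=sub[population_col].to_numpy())
            res = md.fit(reml=reml, method=["lbfgs", "powell"])
        slope, se1 = float(res.fe_params[1]), float(res.bse_fe[1])
        var_f = float(np.var(slope * hr_pct))
        var_re = float(np.asarray(res.cov_re)[0, 0])
        r2m, r2c = nakagawa_r2(var_f, var_re, float(res.scale))
        out[gen] = EffectEstimate(
            effect_scale="slope", estimate=slope,
            ci_low=slope - _Z * se1, ci_high=slope + _Z * se1,
            p_value=float(res.pvalues[1]),
            r2_marginal=r2m, r2_conditional=r2c,
            n_obs=len(sub), n_groups=int(n_pops),
            method=f"linear mixed model ({'REML' if reml else 'ML'}), Wald CI",
            converged=bool(res.converged))
    return out


# ---------------------------------------------------------------------------
# subset sensitivity

def subset_sensitivity(table: pd.DataFrame, fractions=(0.5, 0.25),
                       seed: int = 0, learner: str = "gbm",
                       apply_filter: bool = True,
                       population_col: str = "population"
                       ) -> dict[float, dict[str, dict[str, EffectEstimate]]]:
    """Refit both effect models on random per-population subsets of the
    variants (e.g. 50% and 25%), mirroring a smaller-scale study design.
    Cells whose subset is too small for a fit are recorded as missing."""
    rng = np.random.default_rng(seed)
    results: dict[float, dict] = {}
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValidationError("fractions must be in (0, 1]")
        parts = []
        for _pop, sub in table.groupby(population_col):
            take = max(1, int(round(frac * len(sub))))
            parts.append(sub.sample(n=take, random_state=rng.integers(2**31 - 1))
                         if take < len(sub) else sub)
        sub_table = pd.concat(parts)
        cell: dict[str, dict] = {"hr_on_complexity": {}, "tstr_on_hr": {}}
        try:
            cell["hr_on_complexity"] = fit_glmm_hr_on_complexity(sub_table)
        except (FitError, ValidationError) as exc:
            logger.warning("fraction %.2f: GLMM missing (%s)", frac, exc)
        try:
            filtered = (hr_spread_filter(sub_table)[0] if apply_filter
                        else sub_table)
            if not filtered.empty:
                cell["tstr_on_hr"] = fit_lmm_tstr_on_hr(filtered, learner=learner)
        except (FitError, ValidationError) as exc:
            logger.warning("fraction %.2f: LMM missing (%s — sparse coverage "
                           "in the random effect)", frac, exc)
        results[frac] = cell
    return results
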