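"""Survival modelling: ridge Cox regression, the signed-average prognostic
index with leave-one-out cross-validation, and Kaplan-Meier / log-rank
comparisons.

The prognostic index deliberately avoids fitted weights: each profile feature
contributes only the sign (+1/-1) of its univariate Cox hazard-ratio
direction, and the per-sample score is the mean of sign-weighted expression
values. Under LOOCV the signs for sample i are re-estimated on the other n-1
samples, so a sample's outcome never touches its own score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .containers import ExpressionMatrix, SurvivalTable

__all__ = [
    "CoxFit",
    "SignedProfile",
    "fit_cox",
    "signed_average_scores",
    "loocv_risk_scores",
    "km_logrank",
    "cox_sign",
]


@dataclass
class SignedProfile:
    """A set of features with +-1 weights (hazard-ratio directions)."""

    feature_ids: list
    signs: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = list(self.feature_ids)
        self.signs = np.asarray(self.signs, dtype=float)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("profile features must be unique")
        if len(self.feature_ids) != len(self.signs):
            raise ValueError("one sign per feature required")
        if not np.isin(self.signs, (-1.0, 1.0)).all():
            raise ValueError("signs must be +1 or -1")


@dataclass
class CoxFit:
    """Result of a (possibly ridge-penalized) Breslow-ties Cox fit."""

    coefficients: pd.Series
    standard_errors: pd.Series
    p_values: pd.Series
    penalty: float
    log_partial_likelihood: float
    n_iterations: int
    converged: bool

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coefficients).rename("hazard_ratio")


def _cox_loglik_grad_hess(beta, x, time, event):
    """Breslow partial log-likelihood with gradient and Hessian.

    x is n x p, pre-sorted not required. Risk set of an event at t is
    {j : t_j >= t}; tied events share the same risk set, each contributing its
    own term (Breslow).
    """
    order = np.argsort(-time, kind="stable")  # descending time
    xs = x[order]
    ts = time[order]
    es = event[order]
    eta = xs @ beta
    # guard against overflow in exp for extreme steps
    w = np.exp(np.clip(eta, -500, 500))
    s0 = np.cumsum(w)  # running sum over risk set (t_j >= current t)
    s1 = np.cumsum(w[:, None] * xs, axis=0)
    s2 = np.cumsum(w[:, None, None] * xs[:, :, None] * xs[:, None, :], axis=0)
    # For tied times, all tied subjects belong to the risk set of each tied
    # event: use the cumulative sums at the *last* index of each tie block.
    n = len(ts)
    last_of_block = n - 1 - np.searchsorted(ts[::-1], ts, side="left")
    ev = np.nonzero(es == 1)[0]
    k = last_of_block[ev]
    S0 = s0[k]
    mu = s1[k] / S0[:, None]
    ll = float(np.sum(eta[ev] - np.log(S0)))
    grad = (xs[ev] - mu).sum(axis=0)
    hess = -(s2[k] / S0[:, None, None]).sum(axis=0) + mu.T @ mu
    return ll, grad, hess


def fit_cox(
    x,
    surv: SurvivalTable,
    penalty: float = 0.0,
    max_iter: int = 100,
    grad_tol: float = 1e-8,
) -> CoxFit:
    """Fit a Cox proportional-hazards model with Breslow ties and an optional
    L2 (ridge) penalty (lambda/2)*||beta||^2 on the partial log-likelihood.

    Parameters
    ----------
    x
        Covariates, DataFrame or array of shape (n_samples, n_covariates),
        rows aligned to ``surv``.
    surv
        Survival table providing time and event.
    penalty
        Ridge lambda >= 0; 0 gives the maximum partial likelihood estimate.
    """
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    xdf = pd.DataFrame(x)
    cov_names = [str(c) for c in xdf.columns]
    xa = xdf.to_numpy(dtype=float)
    if xa.ndim != 2:
        raise ValueError("covariate matrix must be 2-D")
    if not np.all(np.isfinite(xa)):
        raise ValueError("covariates must be finite")
    time = surv.time
    event = surv.event
    if len(time) != xa.shape[0]:
        raise ValueError("covariate rows must match survival samples")
    if event.sum() < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    const = np.ptp(xa, axis=0) == 0
    if const.any() and penalty == 0:
        bad = [cov_names[i] for i in np.nonzero(const)[0]]
        raise ValueError(f"constant covariates are non-identifiable at lambda=0: {bad}")

    p = xa.shape[1]
    beta = np.zeros(p)
    converged = False
    it = 0
    ll, grad, hess = _cox_loglik_grad_hess(beta, xa, time, event)
    pen_ll = ll - 0.5 * penalty * beta @ beta
    for it in range(1, max_iter + 1):
        g = grad - penalty * beta
        h = hess - penalty * np.eye(p)
        if np.linalg.norm(g) < grad_tol:
            converged = True
            break
        step = np.linalg.solve(h, -g)
        # step-halving to ensure the penalized objective does not decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            llc, gc, hc = _cox_loglik_grad_hess(cand, xa, time, event)
            pen_c = llc - 0.5 * penalty * cand @ cand
            if pen_c >= pen_ll - 1e-12:
                beta, ll, grad, hess, pen_ll = cand, llc, gc, hc, pen_c
                break
            scale *= 0.5
        else:  # pragma: no cover - pathological
            break
    else:
        g = grad - penalty * beta
        converged = bool(np.linalg.norm(g) < grad_tol)
    if not converged:
        warnings.warn("fit_cox: Newton iterations did not reach gradient tolerance")

    info = -(hess - penalty * np.eye(p))
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    return CoxFit(
        coefficients=pd.Series(beta, index=cov_names, name="coef"),
        standard_errors=pd.Series(se, index=cov_names, name="se"),
        p_values=pd.Series(pvals, index=cov_names, name="p"),
        penalty=float(penalty),
        log_partial_likelihood=float(ll),
        n_iterations=it,
        converged=converged,
    )


def _univariate_cox_coef(
    values: np.ndarray, time: np.ndarray, event: np.ndarray,
    max_iter: int = 50, grad_tol: float = 1e-8,
) -> float:
    """Unpenalized univariate Breslow Cox coefficient (fast numpy path).

    Same Newton iteration as :func:`fit_cox` without the container overhead;
    used in the hot loops (LOOCV, random baselines).
    """
    x = np.asarray(values, dtype=float)[:, None]
    beta = np.zeros(1)
    ll, grad, hess = _cox_loglik_grad_hess(beta, x, time, event)
    for _ in range(max_iter):
        if abs(grad[0]) < grad_tol:
            break
        step = -grad / hess[0, 0] if hess[0, 0] < 0 else np.array([np.sign(grad[0])])
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            llc, gc, hc = _cox_loglik_grad_hess(cand, x, time, event)
            if llc >= ll - 1e-12:
                beta, ll, grad, hess = cand, llc, gc, hc
                break
            scale *= 0.5
        else:
            break
    return float(beta[0])


def cox_sign(values: np.ndarray, surv: SurvivalTable) -> float:
    """Sign of the univariate Cox coefficient for one feature.

    A zero coefficient (measure-zero event) is treated as +1 with a warning.
    """
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        raise ValueError("constant feature has no Cox direction")
    coef = _univariate_cox_coef(values, surv.time, surv.event)
    if coef == 0:
        warnings.warn("cox_sign: exactly-zero coefficient treated as +1")
        return 1.0
    return float(np.sign(coef))


def signed_average_scores(x: ExpressionMatrix, profile: SignedProfile) -> pd.Series:
    """Per-sample signed-average prognostic index.

    score_j = (1/k) * sum_i sign_i * x_ij over the k profile features.
    """
    missing = [f for f in profile.feature_ids if f not in x.values.index]
    if missing:
        raise KeyError(f"profile features missing from expression matrix: {missing}")
    sub = x.values.loc[profile.feature_ids].to_numpy(dtype=float)
    scores = profile.signs @ sub / len(profile.feature_ids)
    return pd.Series(scores, index=x.sample_ids, name="signed_average")


def loocv_risk_scores(x: ExpressionMatrix, surv: SurvivalTable):
    """Out-of-fold signed-average scores by leave-one-out cross-validation.

    Every row of ``x`` is treated as a profile feature. For each sample i the
    feature signs are estimated by univariate Cox regression on the remaining
    n-1 samples, then sample i is scored with those signs only.

    Returns
    -------
    scores : pd.Series
        Out-of-fold prognostic index per sample.
    fold_signs : pd.DataFrame
        features x samples matrix of the signs used in each fold.
    """
    surv = surv.align_to(x)
    n = x.shape[1]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    values = x.values.to_numpy(dtype=float)
    time = surv.time
    event = surv.event
    scores = np.empty(n)
    signs = np.empty((x.shape[0], n))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if event[mask].sum() < 2:
            raise ValueError("LOOCV fold with fewer than 2 events")
        t_f, e_f = time[mask], event[mask]
        for r in range(x.shape[0]):
            coef = _univariate_cox_coef(values[r, mask], t_f, e_f)
            signs[r, i] = 1.0 if coef == 0 else np.sign(coef)
        scores[i] = signs[:, i] @ values[:, i] / x.shape[0]
    return (
        pd.Series(scores, index=x.sample_ids, name="loocv_score"),
        pd.DataFrame(signs, index=x.feature_ids, columns=x.sample_ids),
    )


def km_logrank(groups, surv: SurvivalTable) -> dict:
    """Kaplan-Meier curves per group plus the two-sided log-rank test.

    Returns a dict with per-group KM survival curves (with Greenwood-based
    confidence intervals), median survival (the string ``"not reached"`` when
    the curve never drops to 0.5), the log-rank chi-square and its p-value.
    """
    groups = pd.Series(groups, index=surv.sample_ids if len(groups) == len(surv.data) else None)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 groups")
    if (counts == 0).any():
        raise ValueError("empty group")
    if surv.n_events == 0:
        raise ValueError("log-rank test undefined: all samples censored")

    curves = {}
    medians = {}
    for g in counts.index:
        mask = (groups == g).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(surv.time[mask], surv.event[mask], label=str(g))
        curve = kmf.survival_function_.copy()
        curve[["ci_lower", "ci_upper"]] = kmf.confidence_interval_.to_numpy()
        curves[g] = curve
        med = kmf.median_survival_time_
        medians[g] = "not reached" if np.isinf(med) else float(med)

    res = multivariate_logrank_test(surv.time, groups.to_numpy(), surv.event)
    return {
        "curves": curves,
        "medians": medians,
        "statistic": float(res.test_statistic),
        "p_value": float(res.p_value),
    }
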