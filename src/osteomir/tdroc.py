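"""Time-dependent ROC analysis for censored survival markers.

Implements the cumulative/dynamic definition at a fixed horizon t: cases are
samples with an event by t, controls are samples still event-free past t.
Sensitivity and specificity are estimated with the Kaplan-Meier-weighted
(marker-stratified) estimator

    Sens(c, t) = [1 - S(t | M > c)] * P(M > c) / [1 - S(t)]
    Spec(c, t) = S(t | M <= c) * P(M <= c) / S(t)

where S(t | .) is the Kaplan-Meier survival estimate within the marker
stratum. With no censoring this reduces exactly to the empirical binary ROC,
so the AUC equals the Mann-Whitney statistic of scores versus event-by-t.
Possible non-monotonicity of the estimated curve under censoring is resolved
by sorting the curve points before trapezoid integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SurvivalTable
from .prognosis import SignedProfile, cox_sign, signed_average_scores

__all__ = [
    "TdROCResult",
    "PermutationTest",
    "tdroc_curve",
    "auc_permutation_pvalue",
    "random_profile_baseline",
]


@dataclass
class TdROCResult:
    horizon: float
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_cases: int
    n_controls: int


@dataclass
class PermutationTest:
    observed: float
    n_permutations: int
    permuted: np.ndarray
    p_value: float
    seed: int
    n_resampled: int = 0


def _km_at(time: np.ndarray, event: np.ndarray, t: float) -> float:
    """Kaplan-Meier survival probability at time t (product-limit)."""
    n = len(time)
    if n == 0:
        return 1.0
    order = np.argsort(time, kind="stable")
    ts = time[order]
    es = event[order]
    uniq, start, _ = np.unique(ts, return_index=True, return_counts=True)
    deaths = np.add.reduceat(es, start)
    at_risk = n - start
    mask = (uniq <= t) & (deaths > 0)
    return float(np.prod(1.0 - deaths[mask] / at_risk[mask]))


def tdroc_curve(scores, surv: SurvivalTable, horizon: float) -> TdROCResult:
    """Time-dependent ROC curve and AUC at a fixed horizon (months)."""
    scores = np.asarray(pd.Series(scores), dtype=float)
    time = surv.time
    event = surv.event
    if len(scores) != len(time):
        raise ValueError("scores and survival table must have the same samples")
    if horizon > time.max():
        raise ValueError("horizon lies beyond the last observed time")
    n_cases = int(np.sum((time <= horizon) & (event == 1)))
    n_controls = int(np.sum(time > horizon))
    if n_cases == 0:
        raise ValueError("no cases (events by the horizon)")
    if n_controls == 0:
        raise ValueError("no controls (samples beyond the horizon)")

    s_all = _km_at(time, event, horizon)
    if s_all <= 0 or s_all >= 1:
        raise ValueError("marginal survival at the horizon is degenerate")

    thresholds = np.unique(scores)
    n = len(scores)
    tpr = [0.0]
    fpr = [0.0]
    for c in thresholds:
        above = scores > c
        p_above = above.mean()
        if p_above > 0:
            s_above = _km_at(time[above], event[above], horizon)
            sens = (1.0 - s_above) * p_above / (1.0 - s_all)
        else:
            sens = 0.0
        below = ~above
        p_below = below.mean()
        if p_below > 0:
            s_below = _km_at(time[below], event[below], horizon)
            spec = s_below * p_below / s_all
        else:
            spec = 0.0
        tpr.append(float(np.clip(sens, 0.0, 1.0)))
        fpr.append(float(np.clip(1.0 - spec, 0.0, 1.0)))
    tpr.append(1.0)
    fpr.append(1.0)
    fpr_a = np.asarray(fpr)
    tpr_a = np.asarray(tpr)
    # sort resolves KM non-monotonicity; the sort key is rounded so that
    # float eps noise in the KM ratios cannot split tie groups and distort
    # the staircase (exact coordinates are kept for integration)
    order = np.lexsort((np.round(tpr_a, 10), np.round(fpr_a, 10)))
    pts = np.column_stack([fpr_a[order], tpr_a[order]])
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return TdROCResult(
        horizon=float(horizon),
        thresholds=thresholds,
        fpr=pts[:, 0],
        tpr=pts[:, 1],
        auc=auc,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def auc_permutation_pvalue(
    scores, surv: SurvivalTable, horizon: float, n_permutations: int = 1000, seed: int = 0
) -> PermutationTest:
    """Label-permutation p-value for the tdROC AUC.

    The (time, event) rows are jointly permuted against the scores
    ``n_permutations`` times; p = (1 + #{perm AUC >= observed}) / (B + 1).
    """
    if n_permutations < 19:
        raise ValueError("need at least 19 permutations")
    scores = np.asarray(pd.Series(scores), dtype=float)
    observed = tdroc_curve(scores, surv, horizon).auc
    rng = np.random.default_rng(seed)
    time = surv.time
    event = surv.event
    ids = surv.sample_ids
    permuted = np.empty(n_permutations)
    n_resampled = 0
    b = 0
    while b < n_permutations:
        perm = rng.permutation(len(scores))
        try:
            ptab = SurvivalTable(
                pd.DataFrame({"time": time[perm], "event": event[perm]}, index=ids)
            )
            permuted[b] = tdroc_curve(scores, ptab, horizon).auc
            b += 1
        except ValueError:  # pragma: no cover - cannot occur under joint permutation
            n_resampled += 1
            if n_resampled > 10 * n_permutations:
                raise
    p = (1.0 + np.sum(permuted >= observed)) / (n_permutations + 1.0)
    return PermutationTest(
        observed=observed,
        n_permutations=n_permutations,
        permuted=permuted,
        p_value=float(p),
        seed=seed,
        n_resampled=n_resampled,
    )


def random_profile_baseline(
    x: ExpressionMatrix,
    surv: SurvivalTable,
    k: int,
    n_lists: int,
    horizon: float,
    seed: int = 0,
    candidate_auc: float | None = None,
    scoring: str = "loocv",
):
    """AUC distribution of random k-feature signed-average profiles.

    Samples ``n_lists`` feature sets of size k without replacement and fits
    each with the same model used for any candidate profile: the
    signed-average prognostic index, with signs estimated under leave-one-out
    cross-validation (``scoring="loocv"``, the default, matching the use of
    LOOCV in all survival analyses) or on the full cohort
    (``scoring="in_sample"``), then evaluates the tdROC AUC at the horizon.

    Returns
    -------
    aucs : np.ndarray of length n_lists
    exceedance : int or None
        Count of random-profile AUCs >= ``candidate_auc`` when given.
    """
    if k > x.shape[0]:
        raise ValueError("k exceeds the number of features")
    if n_lists < 1:
        raise ValueError("n_lists must be >= 1")
    if scoring not in ("loocv", "in_sample"):
        raise ValueError("scoring must be 'loocv' or 'in_sample'")
    from .prognosis import loocv_risk_scores

    rng = np.random.default_rng(seed)
    surv = surv.align_to(x)
    aucs = np.empty(n_lists)
    values = x.values.to_numpy(dtype=float)
    for i in range(n_lists):
        rows = rng.choice(x.shape[0], size=k, replace=False)
        feats = [x.feature_ids[r] for r in rows]
        if scoring == "loocv":
            scores, _ = loocv_risk_scores(x.subset_features(feats), surv)
        else:
            signs = np.array([cox_sign(values[r], surv) for r in rows])
            scores = signed_average_scores(x, SignedProfile(feats, signs))
        aucs[i] = tdroc_curve(scores, surv, horizon).auc
    exceedance = None
    if candidate_auc is not None:
        exceedance = int(np.sum(aucs >= candidate_auc))
    return aucs, exceedance
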