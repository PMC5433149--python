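"""Molecular subtype discovery and characterization.

Unsupervised tooling (average-linkage hierarchical clustering, classical MDS)
plus the supervised statistics used to establish that proposed subtypes are
real: per-feature two-group tests with Benjamini-Hochberg FDR, a
random-splits null for the global count of differential features, exact
concordance/overlap tests, and KS/LS functional class scoring for gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

__all__ = [
    "ClusterAssignment",
    "GeneSet",
    "hierarchical_cluster",
    "classical_mds",
    "two_group_test",
    "random_split_null",
    "fisher_concordance",
    "hypergeometric_overlap",
    "gene_set_ks_ls",
]


@dataclass
class ClusterAssignment:
    labels: pd.Series  # sample -> integer label 1..k
    linkage: np.ndarray
    method: str

    @property
    def k(self) -> int:
        return int(self.labels.max())


@dataclass
class GeneSet:
    name: str
    members: list

    def __post_init__(self) -> None:
        self.members = list(dict.fromkeys(self.members))
        if not self.members:
            raise ValueError("gene set must be non-empty")


def hierarchical_cluster(
    x: ExpressionMatrix, k: int = 2, distance: str = "correlation"
) -> ClusterAssignment:
    """Average-linkage hierarchical clustering of samples, cut to k clusters.

    ``distance`` is ``"correlation"`` (1 - Pearson between sample profiles,
    the convention for expression subtype work) or ``"euclidean"``. Labels
    are renumbered 1..k by order of first appearance, so the assignment is
    deterministic for a fixed sample ordering.
    """
    if distance not in ("correlation", "euclidean"):
        raise ValueError("distance must be 'correlation' or 'euclidean'")
    n = x.shape[1]
    if k > n:
        raise ValueError("k exceeds the number of samples")
    d = pdist(x.values.to_numpy(dtype=float).T, metric=distance)
    link = hierarchy.linkage(d, method="average")
    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        labels[i] = relabel[lab]
    return ClusterAssignment(
        labels=pd.Series(labels, index=x.sample_ids, name="cluster"),
        linkage=link,
        method=f"average/{distance}",
    )


def classical_mds(x: ExpressionMatrix, dims: int = 3) -> pd.DataFrame:
    """Classical (Torgerson) multidimensional scaling of samples.

    Double-centers the squared Euclidean sample-distance matrix and
    eigendecomposes it; coordinates equal centered-data principal-component
    scores up to sign. Distances are reproduced exactly when the Gram matrix
    has rank <= dims.
    """
    if dims < 1:
        raise ValueError("dims must be >= 1")
    n = x.shape[1]
    if dims > n - 1:
        raise ValueError("dims must be <= n_samples - 1")
    d2 = squareform(pdist(x.values.to_numpy(dtype=float).T, metric="euclidean")) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    idx = np.argsort(evals)[::-1][:dims]
    lam = np.clip(evals[idx], 0.0, None)
    coords = evecs[:, idx] * np.sqrt(lam)
    return pd.DataFrame(
        coords, index=x.sample_ids, columns=[f"dim{i + 1}" for i in range(dims)]
    )


def _binary_groups(labels, sample_ids=None):
    labels = pd.Series(labels)
    uniq = sorted(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, got {uniq}")
    return labels, uniq


def two_group_test(
    x: ExpressionMatrix, labels, method: str = "t"
) -> pd.DataFrame:
    """Per-feature two-group differential test with BH FDR.

    ``method`` is ``"t"`` (Welch two-sided t-test) or ``"mann_whitney"``.
    Returns a DataFrame indexed by feature with columns ``statistic``, ``p``,
    ``q`` (Benjamini-Hochberg) and ``direction`` ("up"/"down" in group 2,
    groups taken in sorted label order).
    """
    labels, uniq = _binary_groups(labels)
    mask2 = (labels == uniq[1]).to_numpy()
    a = x.values.to_numpy(dtype=float)[:, ~mask2]
    b = x.values.to_numpy(dtype=float)[:, mask2]
    if method == "t":
        if a.shape[1] < 2 or b.shape[1] < 2:
            raise ValueError("t-test needs >= 2 samples per group")
        with np.errstate(all="ignore"):
            res = stats.ttest_ind(b, a, axis=1, equal_var=False)
        stat = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
        bad = ~np.isfinite(stat)
        if bad.any():
            warnings.warn(f"two_group_test: {bad.sum()} constant features set to p=1")
            stat[bad] = 0.0
            p[bad] = 1.0
    elif method == "mann_whitney":
        if a.shape[1] < 1 or b.shape[1] < 1:
            raise ValueError("Mann-Whitney needs >= 1 sample per group")
        res = stats.mannwhitneyu(b, a, axis=1, alternative="two-sided")
        stat = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
    else:
        raise ValueError("method must be 't' or 'mann_whitney'")
    q = multipletests(p, method="fdr_bh")[1]
    direction = np.where(b.mean(axis=1) >= a.mean(axis=1), "up", "down")
    return pd.DataFrame(
        {"statistic": stat, "p": p, "q": q, "direction": direction},
        index=x.feature_ids,
    )


@dataclass
class RandomSplitNull:
    observed_count: int
    null_counts: np.ndarray
    p_value: float
    alpha: float


def random_split_null(
    x: ExpressionMatrix,
    observed_labels,
    n_splits: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    method: str = "t",
) -> RandomSplitNull:
    """Empirical p-value for the observed number of differential features.

    The statistic is the count of features with raw p < alpha. Each random
    split permutes the sample labels preserving the observed group sizes; the
    empirical p is the fraction of splits whose count reaches the observed
    count.
    """
    if n_splits < 20:
        raise ValueError("need at least 20 random splits")
    labels, uniq = _binary_groups(observed_labels)
    lab_arr = labels.to_numpy()
    if min((lab_arr == uniq[0]).sum(), (lab_arr == uniq[1]).sum()) < 2:
        raise ValueError("each group needs at least 2 samples")
    observed = int((two_group_test(x, lab_arr, method=method)["p"] < alpha).sum())
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_splits, dtype=int)
    for s in range(n_splits):
        perm = rng.permutation(lab_arr)
        null_counts[s] = int((two_group_test(x, perm, method=method)["p"] < alpha).sum())
    p = float(np.mean(null_counts >= observed))
    return RandomSplitNull(observed, null_counts, p, alpha)


def fisher_concordance(labels_a, labels_b) -> dict:
    """2x2 concordance table between two binary labelings plus the exact
    two-sided Fisher p-value."""
    la, ua = _binary_groups(labels_a)
    lb, ub = _binary_groups(labels_b)
    if len(la) != len(lb):
        raise ValueError("labelings must cover the same samples")
    table = np.zeros((2, 2), dtype=int)
    for i, va in enumerate(ua):
        for j, vb in enumerate(ub):
            table[i, j] = int(np.sum((la.to_numpy() == va) & (lb.to_numpy() == vb)))
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return {"table": table, "odds_ratio": float(odds), "p_value": float(p)}


def hypergeometric_overlap(list_a, list_b, universe_size: int) -> dict:
    """Right-tail hypergeometric test for the overlap of two feature lists.

    p = P(X >= observed) for X ~ Hypergeometric(N, |a|, |b|).
    """
    a = set(list_a)
    b = set(list_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("list larger than universe")
    overlap = len(a & b)
    p = float(stats.hypergeom.sf(overlap - 1, universe_size, len(a), len(b)))
    return {"overlap": overlap, "p_value": min(p, 1.0)}


def gene_set_ks_ls(
    feature_pvalues: pd.Series,
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """KS/LS functional class scoring of a gene set.

    LS = mean over the set of -ln(p); KS = two-sided one-sample
    Kolmogorov-Smirnov statistic of the set's p-values against Uniform(0,1).
    Significance for both is assessed by permuting which features form the
    set, with the add-one p-value formula.
    """
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    feature_pvalues = pd.Series(feature_pvalues)
    members = [m for m in gene_set.members if m in feature_pvalues.index]
    if not members:
        raise ValueError("gene set has no members among the tested features")
    pv = feature_pvalues.to_numpy(dtype=float)

    def _stats(p_set: np.ndarray) -> tuple[float, float]:
        ls = float(np.mean(-np.log(p_set)))
        ks = float(stats.kstest(p_set, "uniform").statistic)
        return ls, ks

    set_p = feature_pvalues.loc[members].to_numpy(dtype=float)
    ls_obs, ks_obs = _stats(set_p)
    rng = np.random.default_rng(seed)
    m = len(members)
    ls_null = np.empty(n_perm)
    ks_null = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(len(pv), size=m, replace=False)
        ls_null[i], ks_null[i] = _stats(pv[idx])
    ls_p = (1.0 + np.sum(ls_null >= ls_obs)) / (n_perm + 1.0)
    ks_p = (1.0 + np.sum(ks_null >= ks_obs)) / (n_perm + 1.0)
    return {
        "ls": ls_obs,
        "ks": ks_obs,
        "ls_p": float(ls_p),
        "ks_p": float(ks_p),
        "n_members": m,
    }
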