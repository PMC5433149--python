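"""PUMA message-passing gene-regulatory-network inference.

PANDA-style message passing integrates three evidence channels: a
regulator-gene target prior W0 (sequence motifs / miRNA target predictions),
a regulator-regulator cooperativity prior P0 (protein-protein interactions)
and gene-gene coexpression C0. Each iteration exchanges "responsibility"
(R = T(P, W)) and "availability" (A = T(W, C^T)) messages through a
continuous Tanimoto similarity kernel and relaxes W toward their average;
P and C are then relaxed toward similarities of the updated W.

PUMA is the miRNA-aware variant: miRNAs act through RISC rather than
protein complexes, so after every cooperativity update the P rows and
columns of miRNA regulators are reset to their prior values - miRNAs never
gain cooperativity edges, only regulator-gene edges.

Downstream utilities implement per-edge significance against permuted
backgrounds (an edge is significant when its between-group difference lies
outside four standard deviations of its permuted-background differences),
differential targeting, module extraction, and a gene-drug interaction join.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import RegulatoryPriors

__all__ = [
    "InferredNetwork",
    "normalize_matrix_zscores",
    "tanimoto_similarity",
    "puma_infer",
    "edge_significance",
    "differential_targeting",
    "extract_module",
    "drug_interaction_screen",
]

SIGNIFICANCE_SD_FACTOR = 4.0  # |difference| must exceed 4 background SDs
_DENOM_EPS = 1e-10


@dataclass
class InferredNetwork:
    """Final regulator x gene edge scores (z-score scale) plus run metadata."""

    scores: pd.DataFrame
    alpha: float
    n_iterations: int
    convergence_gap: float
    converged: bool
    final_cooperativity: pd.DataFrame | None = None


def normalize_matrix_zscores(x) -> np.ndarray:
    """Combined row/column z-score normalization used on all three priors.

    Z_ij = [(x_ij - rowmean_i)/rowsd_i + (x_ij - colmean_j)/colsd_j] / sqrt(2)

    Zero-variance rows or columns fall back to the overall standard
    deviation (with a warning) so no NaN can leak into the message passing.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("matrix must be finite")
    overall_sd = arr.std()
    if overall_sd == 0:
        raise ValueError("cannot normalize an all-constant matrix")
    rm = arr.mean(axis=1, keepdims=True)
    rs = arr.std(axis=1, keepdims=True)
    cm = arr.mean(axis=0, keepdims=True)
    cs = arr.std(axis=0, keepdims=True)
    n_degenerate = int((rs == 0).sum() + (cs == 0).sum())
    if n_degenerate:
        warnings.warn(
            f"normalize_matrix_zscores: {n_degenerate} zero-variance rows/cols "
            "use the overall sd"
        )
        rs = np.where(rs == 0, overall_sd, rs)
        cs = np.where(cs == 0, overall_sd, cs)
    return ((arr - rm) / rs + (arr - cm) / cs) / np.sqrt(2.0)


def tanimoto_similarity(a, b) -> np.ndarray:
    """Continuous Tanimoto kernel between rows of ``a`` and columns of ``b``.

    T_ij = (a_i . b_j) / sqrt(||a_i||^2 + ||b_j||^2 - |a_i . b_j|)

    A zero denominator (both vectors zero) is guarded with a small epsilon.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[1] != b.shape[0]:
        raise ValueError("inner dimensions must agree")
    num = a @ b
    denom2 = (a * a).sum(axis=1)[:, None] + (b * b).sum(axis=0)[None, :] - np.abs(num)
    if np.any(denom2 <= 0):
        denom2 = np.maximum(denom2, _DENOM_EPS)
    return num / np.sqrt(denom2)


def _update_diagonal(sim: np.ndarray, alpha: float, step: int) -> np.ndarray:
    """Replace the diagonal of a self-similarity matrix.

    Self-similarity is identically high and would blow up over iterations;
    the diagonal is replaced by (off-diagonal row std) * sqrt(dim) *
    exp(2 * alpha * step).
    """
    dim = sim.shape[0]
    tmp = sim.copy()
    np.fill_diagonal(tmp, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_sd = np.nanstd(tmp, axis=1)
    fill = row_sd * np.sqrt(dim) * np.exp(2.0 * alpha * step)
    out = sim.copy()
    np.fill_diagonal(out, fill)
    return out


def _coexpression(expression: pd.DataFrame) -> np.ndarray:
    """Gene-gene Pearson coexpression with unit diagonal; constant genes get
    zero off-diagonal correlation."""
    arr = expression.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(arr)
    bad = ~np.isfinite(c)
    if bad.any():
        warnings.warn("coexpression: constant genes set to zero correlation")
        c[bad] = 0.0
    np.fill_diagonal(c, 1.0)
    return c


def puma_infer(
    priors: RegulatoryPriors,
    alpha: float = 0.1,
    tol: float = 1e-3,
    max_iter: int = 200,
    debug_assert: bool = False,
) -> InferredNetwork:
    """Run PUMA message passing until the mean |dW| per entry drops below tol.

    Parameters
    ----------
    priors
        Motif prior W0, cooperativity prior P0, expression for coexpression
        C0 and the miRNA regulator subset.
    alpha
        Update (relaxation) rate in (0, 1).
    tol
        Convergence threshold on the mean absolute W change per iteration.
    debug_assert
        When True, assert at every iteration that miRNA cooperativity rows
        and columns still equal their prior.

    Notes
    -----
    With no miRNA regulators this is exactly PANDA. The run is fully
    deterministic: no internal randomness.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    w = normalize_matrix_zscores(priors.motif.to_numpy(dtype=float))
    p = normalize_matrix_zscores(priors.ppi.to_numpy(dtype=float))
    c = normalize_matrix_zscores(_coexpression(priors.expression))
    mi = priors.mirna_indices
    p_prior = p.copy()

    gap = np.inf
    converged = False
    step = 0
    for step in range(max_iter):
        responsibility = tanimoto_similarity(p, w)
        availability = tanimoto_similarity(w, c.T)
        w_new = (1 - alpha) * w + alpha * (responsibility + availability) / 2.0
        gap = float(np.mean(np.abs(w_new - w)))
        w = w_new
        if gap < tol:
            converged = True
            break
        p_new = _update_diagonal(tanimoto_similarity(w, w.T), alpha, step)
        p = (1 - alpha) * p + alpha * p_new
        if len(mi):
            p[mi, :] = p_prior[mi, :]
            p[:, mi] = p_prior[:, mi]
        if debug_assert and len(mi):
            assert np.array_equal(p[mi, :], p_prior[mi, :])
            assert np.array_equal(p[:, mi], p_prior[:, mi])
        c_new = _update_diagonal(tanimoto_similarity(w.T, w), alpha, step)
        c = (1 - alpha) * c + alpha * c_new
    if not converged:
        warnings.warn(f"puma_infer: not converged after {max_iter} iterations (gap={gap:.3g})")
    return InferredNetwork(
        scores=pd.DataFrame(w, index=priors.regulators, columns=priors.genes),
        alpha=alpha,
        n_iterations=step + 1,
        convergence_gap=gap,
        converged=converged,
        final_cooperativity=pd.DataFrame(
            p, index=priors.regulators, columns=priors.regulators
        ),
    )


def _with_expression(priors: RegulatoryPriors, expression: pd.DataFrame) -> RegulatoryPriors:
    return RegulatoryPriors(
        motif=priors.motif,
        ppi=priors.ppi,
        expression=expression,
        mirna_regulators=priors.mirna_regulators,
    )


def edge_significance(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    priors: RegulatoryPriors,
    n_perm: int = 20,
    seed: int = 0,
    alpha: float = 0.1,
    tol: float = 1e-3,
    max_iter: int = 200,
) -> pd.DataFrame:
    """Per-edge differential significance by the 4-SD permuted-background rule.

    Group networks are inferred separately for the two expression matrices
    (shared priors, group-specific coexpression); the observed per-edge
    difference is score_A - score_B. The background permutes the
    sample-to-group assignment ``n_perm`` times preserving group sizes and
    re-infers both networks; an edge is significant when its observed
    |difference| exceeds ``4 * sd`` of its own background differences.
    """
    if n_perm < 10:
        raise ValueError("need at least 10 permutations")
    expr_a = pd.DataFrame(expr_a)
    expr_b = pd.DataFrame(expr_b)
    if expr_a.shape[1] < 3 or expr_b.shape[1] < 3:
        raise ValueError("each group needs >= 3 samples for coexpression")

    def _scores(e: pd.DataFrame) -> np.ndarray:
        return puma_infer(
            _with_expression(priors, e), alpha=alpha, tol=tol, max_iter=max_iter
        ).scores.to_numpy()

    scores_a = _scores(expr_a)
    scores_b = _scores(expr_b)
    obs_diff = scores_a - scores_b
    pooled = pd.concat([expr_a, expr_b], axis=1)
    n_a = expr_a.shape[1]
    n_tot = pooled.shape[1]
    rng = np.random.default_rng(seed)
    bg = np.empty((n_perm,) + obs_diff.shape)
    for i in range(n_perm):
        perm = rng.permutation(n_tot)
        pa = pooled.iloc[:, perm[:n_a]]
        pb = pooled.iloc[:, perm[n_a:]]
        bg[i] = _scores(pa) - _scores(pb)
    sd = bg.std(axis=0, ddof=1)
    significant = np.abs(obs_diff) > SIGNIFICANCE_SD_FACTOR * sd

    regs = priors.regulators
    genes = priors.genes
    ri, gi = np.meshgrid(np.arange(len(regs)), np.arange(len(genes)), indexing="ij")
    return pd.DataFrame(
        {
            "regulator": regs[ri.ravel()],
            "gene": genes[gi.ravel()],
            "score_a": scores_a.ravel(),
            "score_b": scores_b.ravel(),
            "difference": obs_diff.ravel(),
            "background_sd": sd.ravel(),
            "significant": significant.ravel(),
        }
    )


def differential_targeting(net_a: InferredNetwork, net_b: InferredNetwork) -> pd.DataFrame:
    """Per-regulator targeting score (sum of edge scores over genes) and the
    between-group difference."""
    sa = net_a.scores
    sb = net_b.scores
    if sa.shape != sb.shape:
        raise ValueError("networks must have the same dimensions")
    ta = sa.sum(axis=1)
    tb = sb.sum(axis=1)
    return pd.DataFrame(
        {"targeting_a": ta, "targeting_b": tb, "difference": ta - tb}
    )


def extract_module(edges: pd.DataFrame, seed_regulators, top_k: int = 20):
    """Sub-network of the most differential significant edges per seed
    regulator.

    For each seed regulator the significant edges are ranked by |difference|
    (ties broken by gene id) and the top ``top_k`` retained. Returns the edge
    table plus per-node edge counts (node size metadata for graph viewers).
    """
    required = {"regulator", "gene", "difference", "significant"}
    if not required <= set(edges.columns):
        raise ValueError(f"edge table needs columns {sorted(required)}")
    known = set(edges["regulator"])
    unknown = [r for r in seed_regulators if r not in known]
    if unknown:
        raise KeyError(f"unknown regulators: {unknown}")
    parts = []
    for reg in seed_regulators:
        sub = edges[(edges["regulator"] == reg) & edges["significant"]].copy()
        sub["_absdiff"] = sub["difference"].abs()
        sub = sub.sort_values(["_absdiff", "gene"], ascending=[False, True]).head(top_k)
        parts.append(sub.drop(columns="_absdiff"))
    module = pd.concat(parts, axis=0, ignore_index=True) if parts else edges.iloc[0:0]
    node_sizes = (
        pd.concat([module["regulator"], module["gene"]])
        .value_counts()
        .rename("n_edges")
    )
    return module, node_sizes


def drug_interaction_screen(gene_ids, interaction_table: pd.DataFrame) -> pd.DataFrame:
    """Join a gene list against a gene-drug interaction table.

    Matching is case-insensitive on the gene symbol; duplicate
    (gene, drug, source) rows are returned once.
    """
    table = pd.DataFrame(interaction_table)
    required = {"gene", "drug", "source"}
    if not required <= set(table.columns):
        raise ValueError(f"interaction table needs columns {sorted(required)}")
    wanted = {str(g).upper() for g in gene_ids}
    hit = table[table["gene"].astype(str).str.upper().isin(wanted)]
    return hit.drop_duplicates(subset=["gene", "drug", "source"]).reset_index(drop=True)
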