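"""Genomic context annotation and methylation-expression-phenotype analysis
for the imprinted 14q32 non-coding cluster.

CTCF binds unmethylated insulator DNA, so methylation of a probe inside a
CTCF binding site is expected to correlate *positively* with expression of
the downstream non-coding cluster (the enhancer block is relieved), while
conventional promoter/gene-body methylation outside CTCF sites correlates
negatively. The functions here classify probes by CTCF context, compute
Spearman correlation tables with the field's strength bins, and score the
three-way methylation / expression / aggressiveness corner pattern.

Coordinates are 0-based half-open internally; BED files are read natively
and 1-based position tables are converted on ingest.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "REGION_14Q32",
    "annotate_ctcf_overlap",
    "cpg_upstream_count",
    "spearman_correlation_table",
    "classify_correlation_strength",
    "threeway_pattern_assignment",
]

#: chr14 band q32 (hg19): the 19.2 Mb region harboring the DLK1-DIO3 cluster
REGION_14Q32 = ("chr14", 89_800_000, 109_000_000)

DEFAULT_NEAR_WINDOW_BP = 1000

STRENGTH_BINS = (
    (0.5, "strong"),
    (0.3, "moderately_strong"),
    (0.15, "moderate"),
)


def _check_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    df = pd.DataFrame(intervals)
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"interval table needs a '{col}' column")
    if ((df["start"] < 0) | (df["start"] >= df["end"])).any():
        raise ValueError("malformed intervals: require 0 <= start < end")
    return df


def annotate_ctcf_overlap(
    probes: pd.DataFrame,
    ctcf_sites: pd.DataFrame,
    near_window_bp: int = DEFAULT_NEAR_WINDOW_BP,
) -> pd.DataFrame:
    """Classify each probe position relative to CTCF binding-site intervals.

    ``in_site`` when start <= pos < end for any site; ``near_site`` when the
    position falls within ``near_window_bp`` of a site boundary but not
    inside any site (both window boundaries inclusive: a probe exactly at
    ``end + near_window_bp`` or ``start - near_window_bp`` is near);
    otherwise ``not_in_site``. Classes are mutually exclusive and exhaustive.

    ``probes`` needs columns ``probe``, ``chrom``, ``pos`` (0-based).
    """
    sites = _check_intervals(ctcf_sites)
    probes = pd.DataFrame(probes)
    out = []
    by_chrom = {c: g for c, g in sites.groupby("chrom")}
    for _, row in probes.iterrows():
        g = by_chrom.get(row["chrom"])
        cls = "not_in_site"
        if g is not None:
            pos = int(row["pos"])
            start = g["start"].to_numpy()
            end = g["end"].to_numpy()
            if np.any((start <= pos) & (pos < end)):
                cls = "in_site"
            elif np.any(
                ((start - near_window_bp <= pos) & (pos < start))
                | ((end <= pos) & (pos <= end + near_window_bp))
            ):
                cls = "near_site"
        out.append(cls)
    res = probes.copy()
    res["ctcf_class"] = out
    return res


def cpg_upstream_count(position: int, islands: pd.DataFrame, window: int = 100_000) -> int:
    """Number of CpG islands intersecting the window upstream of a position.

    Upstream is taken as decreasing coordinates (+ strand assumption): an
    island counts when its interval intersects ``[position - window,
    position)``.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    isl = _check_intervals(islands)
    lo = position - window
    hit = (isl["start"] < position) & (isl["end"] > lo)
    return int(hit.sum())


def classify_correlation_strength(rho: float) -> str:
    """Bin |rho| into strength categories: >=0.5 strong, [0.3, 0.5)
    moderately_strong, [0.15, 0.3) moderate, else weak."""
    if not np.isfinite(rho) or abs(rho) > 1:
        raise ValueError("rho must be finite with |rho| <= 1")
    for cut, name in STRENGTH_BINS:
        if abs(rho) >= cut:
            return name
    return "weak"


def spearman_correlation_table(a: pd.DataFrame, b: pd.DataFrame, pairs) -> pd.DataFrame:
    """Spearman rank correlations for named (row-of-a, row-of-b) pairs.

    Returns a DataFrame with columns ``probe_id``, ``feature_id``, ``rho``,
    ``p``, ``strength_bin`` and ``undefined`` (True when either vector is
    constant, in which case rho/p are NaN by construction rather than
    leaking silently).
    """
    a = pd.DataFrame(a)
    b = pd.DataFrame(b)
    if not a.columns.equals(b.columns):
        raise ValueError("matrices must share sample columns")
    records = []
    for ra, rb in pairs:
        va = a.loc[ra].to_numpy(dtype=float)
        vb = b.loc[rb].to_numpy(dtype=float)
        if np.ptp(va) == 0 or np.ptp(vb) == 0:
            records.append((ra, rb, np.nan, np.nan, pd.NA, True))
            continue
        rho, p = stats.spearmanr(va, vb)
        records.append((ra, rb, float(rho), float(p), classify_correlation_strength(rho), False))
    return pd.DataFrame(
        records, columns=["probe_id", "feature_id", "rho", "p", "strength_bin", "undefined"]
    )


def threeway_pattern_assignment(
    methyl_vector,
    expr_summary,
    phenotype,
    site_class: str = "in_site",
):
    """Corner labels and concordance score for the three-way pattern.

    Each axis (methylation, average profile expression, continuous
    aggressiveness phenotype) is median-split into high/low; each sample gets
    a corner label "h/l" per axis. The concordance score is the fraction of
    samples in the two CTCF-consistent corners:

    - ``in_site`` probes: high/high/high and low/low/low (methylation blocks
      CTCF, releasing expression and aggressiveness together);
    - ``not_in_site`` (or ``near_site``) probes: high/low/low and
      low/high/high (conventional repressive promoter methylation).
    """
    m = pd.Series(methyl_vector).astype(float)
    e = pd.Series(expr_summary).astype(float)
    p = pd.Series(phenotype).astype(float)
    if not (len(m) == len(e) == len(p)):
        raise ValueError("axes must have equal length")
    if len(m) < 4:
        raise ValueError("need at least 4 samples")

    def split(v: pd.Series) -> np.ndarray:
        return np.where(v.to_numpy() > np.median(v.to_numpy()), "h", "l")

    corners = pd.Series(
        ["/".join(t) for t in zip(split(m), split(e), split(p))],
        index=m.index,
        name="corner",
    )
    if site_class == "in_site":
        consistent = {"h/h/h", "l/l/l"}
    elif site_class in ("not_in_site", "near_site"):
        consistent = {"h/l/l", "l/h/h"}
    else:
        raise ValueError("site_class must be in_site, near_site or not_in_site")
    score = float(corners.isin(consistent).mean())
    return corners, score
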