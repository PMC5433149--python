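# osteomir

Prognostic scoring, molecular-subtype discovery, methylation/CTCF context
analysis and miRNA-aware gene-regulatory-network inference for
imprinted-locus tumor genomics — the analysis style used to study the
14q32 (*DLK1-DIO3*) non-coding cluster in osteosarcoma, packaged as a
tested, reusable Python library with a synthetic-data generator so every
stage runs and is verifiable without any external download.

## Who this is for

Computational biologists evaluating small miRNA prognostic panels on
censored survival cohorts, and anyone who needs the surrounding statistical
machinery under test: signed-average risk scores with leave-one-out
cross-validation, time-dependent ROC curves, permutation nulls for
differential expression, imprinted-locus methylation–expression correlation,
and PANDA/PUMA message-passing network inference with permuted-background
edge significance.

## The core methods

**Signed-average prognostic index.** For profile features i = 1..k with
signs s_i = sign of the univariate Cox hazard-ratio direction,

    score_j = (1/k) · Σ_i s_i · x_ij

Under LOOCV the signs for sample j are re-estimated without it, so its
outcome never touches its own score. Discrimination at horizon t is the
cumulative/dynamic time-dependent ROC AUC with Kaplan-Meier-weighted
sensitivity/specificity; significance is a label-permutation p-value.

**Subtype statistics.** Average-linkage clustering, classical MDS, Welch
t / Mann-Whitney tests with Benjamini-Hochberg FDR, a 100-random-splits null
for the global differential count, Fisher/hypergeometric exact tests, and
KS/LS functional class scoring.

**Methylation in CTCF context.** β → M = log2(β/(1−β)); probes classified as
in / near / outside CTCF binding sites; Spearman correlation tables with the
field's strength bins (|ρ| ≥ 0.5 strong, 0.3–0.5 moderately strong,
0.15–0.3 moderate); three-way methylation/expression/phenotype corner
scores. Methylation *inside* a CTCF site correlates positively with cluster
expression (the enhancer block is relieved); conventional methylation
outside correlates negatively.

**PUMA network inference.** PANDA-style message passing over a target prior
W, a cooperativity prior P and gene coexpression C through a continuous
Tanimoto kernel, with the miRNA constraint that P rows/columns of miRNA
regulators are pinned to their prior. Differential edges between sample
groups are flagged when the score difference exceeds 4 standard deviations
of a label-permuted background.

See `docs/methods.md` for assumptions, parameter derivations and limits.

## Worked example

```python
from osteomir import synthdata as sd
from osteomir.prognosis import loocv_risk_scores
from osteomir.tdroc import tdroc_curve, auc_permutation_pvalue
from osteomir.subtypes import hierarchical_cluster

expr, surv, labels = sd.generate_cohort(sd.CohortConfig(n_samples=100, seed=1))
profile = expr.feature_ids[:5]                      # 5-feature locus profile
scores, signs = loocv_risk_scores(expr.subset_features(profile), surv)
roc = tdroc_curve(scores, surv, horizon=60)
perm = auc_permutation_pvalue(scores, surv, 60, n_permutations=199, seed=1)
print(f"AUC(60 mo) = {roc.auc:.3f}, permutation p = {perm.p_value:.3f}")

clusters = hierarchical_cluster(expr.subset_features(expr.feature_ids[:62]),
                                k=2, distance="euclidean")
```

prints

```
AUC(60 mo) = 0.816, permutation p = 0.005
```

i.e. the out-of-fold signed-average score of a 5-feature planted profile
discriminates 60-month outcomes well above chance (AUC 0.5), and the planted
subtype structure is recoverable by unsupervised clustering (on this seed,
adjusted Rand index 0.88 against the true labels).

The same pipeline is scriptable from the shell:

```bash
osteomir synth cohort --n-samples 100 --seed 1 --out cohort/
osteomir prep qn --in cohort/expression.tsv --out qn.tsv
osteomir prog loocv --expr cohort/expression.tsv --surv cohort/survival.tsv --out scores.tsv
osteomir tdroc perm --scores scores.tsv --surv cohort/survival.tsv --horizon 60 --out roc.json
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the synthetic world from the given seed and runs the whole
pipeline from scratch — quantile normalization and variance filtering, LOOCV
signed-average scoring with tdROC and its permutation p-value, subtype
re-discovery by clustering with the log-rank comparison and the
random-splits differential-expression null, the methylation/CTCF correlation
table, and PUMA inference with 4-SD differential-edge calling — printing a
summary of each stage and writing the JSON result object to `--out`.
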