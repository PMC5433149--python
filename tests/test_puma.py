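import numpy as np
import pandas as pd
import pytest

from osteomir.containers import RegulatoryPriors
from osteomir.puma import (
    differential_targeting,
    drug_interaction_screen,
    edge_significance,
    extract_module,
    normalize_matrix_zscores,
    puma_infer,
    tanimoto_similarity,
)
from osteomir import synthdata as sd


# ---------------------------------------------------------------------------
# Independent reference: loop-based PANDA/PUMA coded directly from the update
# equations, entry by entry, with no shared code with the implementation.
# ---------------------------------------------------------------------------
def ref_normalize(x):
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    overall = x.std()
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            rs = x[i].std() or overall
            cs = x[:, j].std() or overall
            out[i, j] = ((x[i, j] - x[i].mean()) / rs + (x[i, j] - x[:, j].mean()) / cs) / np.sqrt(2)
    return out


def ref_tanimoto(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = np.empty((a.shape[0], b.shape[1]))
    for i in range(a.shape[0]):
        for j in range(b.shape[1]):
            num = float(a[i] @ b[:, j])
            den = np.sqrt(a[i] @ a[i] + b[:, j] @ b[:, j] - abs(num))
            out[i, j] = num / max(den, 1e-10)  # same zero guard as implementation
    return out


def ref_diag(sim, alpha, step):
    sim = sim.copy()
    n = sim.shape[0]
    for i in range(n):
        row = np.delete(sim[i], i)
        sim[i, i] = row.std() * np.sqrt(n) * np.exp(2 * alpha * step)
    return sim


def ref_panda(w0, p0, expr, mirna_idx=(), alpha=0.1, tol=1e-3, max_iter=200):
    c0 = np.corrcoef(np.asarray(expr, dtype=float))
    np.fill_diagonal(c0, 1.0)
    w = ref_normalize(w0)
    p = ref_normalize(p0)
    c = ref_normalize(c0)
    p_prior = p.copy()
    mirna_idx = list(mirna_idx)
    for step in range(max_iter):
        r = ref_tanimoto(p, w)
        a = ref_tanimoto(w, c.T)
        w_new = (1 - alpha) * w + alpha * (r + a) / 2
        gap = np.abs(w_new - w).mean()
        w = w_new
        if gap < tol:
            break
        p_new = ref_diag(ref_tanimoto(w, w.T), alpha, step)
        p = (1 - alpha) * p + alpha * p_new
        for i in mirna_idx:
            p[i, :] = p_prior[i, :]
            p[:, i] = p_prior[:, i]
        c_new = ref_diag(ref_tanimoto(w.T, w), alpha, step)
        c = (1 - alpha) * c + alpha * c_new
    return w


def toy_priors(seed=0, m=5, n=20, n_samples=30, mirnas=()):
    rng = np.random.default_rng(seed)
    w0 = (rng.random((m, n)) < 0.3).astype(float)
    w0[0, 0] = 1.0  # no empty prior
    p0 = np.eye(m)
    p0[0, 1] = p0[1, 0] = 0.5
    expr = rng.normal(size=(n, n_samples))
    regs = [f"r{i}" for i in range(m)]
    genes = [f"g{j}" for j in range(n)]
    return RegulatoryPriors(
        motif=pd.DataFrame(w0, index=regs, columns=genes),
        ppi=pd.DataFrame(p0, index=regs, columns=regs),
        expression=pd.DataFrame(expr, index=genes, columns=[f"s{k}" for k in range(n_samples)]),
        mirna_regulators=[regs[i] for i in mirnas],
    )


class TestNormalize:
    def test_hand_worked_2x2(self):
        x = np.array([[1.0, 3.0], [2.0, 8.0]])
        got = normalize_matrix_zscores(x)
        assert np.allclose(got, ref_normalize(x), atol=1e-12)

    def test_constant_row_fallback_no_nan(self):
        x = np.array([[1.0, 1.0, 1.0], [0.0, 2.0, 5.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            got = normalize_matrix_zscores(x)
        assert np.all(np.isfinite(got))

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            normalize_matrix_zscores(np.ones((3, 3)))


class TestTanimoto:
    def test_unit_self_similarity(self):
        v = np.array([[0.6, 0.8]])
        assert np.isclose(tanimoto_similarity(v, v.T)[0, 0], 1.0)

    def test_orthogonal_zero(self):
        a = np.array([[1.0, 0.0]])
        b = np.array([[0.0], [1.0]])
        assert np.isclose(tanimoto_similarity(a, b)[0, 0], 0.0)

    def test_matches_loop_oracle(self, rng):
        a = rng.normal(size=(3, 4))
        b = rng.normal(size=(4, 2))
        assert np.allclose(tanimoto_similarity(a, b), ref_tanimoto(a, b), atol=1e-12)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            tanimoto_similarity(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))


class TestPumaInfer:
    def test_equals_reference_panda_without_mirnas(self):
        priors = toy_priors(seed=1)
        net = puma_infer(priors)
        ref = ref_panda(
            priors.motif.to_numpy(), priors.ppi.to_numpy(), priors.expression.to_numpy()
        )
        assert net.converged
        assert np.allclose(net.scores.to_numpy(), ref, atol=1e-8)

    def test_equals_reference_puma_with_mirnas(self):
        priors = toy_priors(seed=2, mirnas=(0, 2))
        net = puma_infer(priors, debug_assert=True)
        ref = ref_panda(
            priors.motif.to_numpy(),
            priors.ppi.to_numpy(),
            priors.expression.to_numpy(),
            mirna_idx=[0, 2],
        )
        assert np.allclose(net.scores.to_numpy(), ref, atol=1e-8)

    def test_all_mirnas_keep_cooperativity_at_prior(self):
        priors = toy_priors(seed=3, mirnas=(0, 1, 2, 3, 4))
        net = puma_infer(priors, debug_assert=True)
        prior_norm = normalize_matrix_zscores(priors.ppi.to_numpy())
        assert np.array_equal(net.final_cooperativity.to_numpy(), prior_norm)

    def test_deterministic(self):
        priors = toy_priors(seed=4)
        a = puma_infer(priors).scores
        b = puma_infer(priors).scores
        assert a.equals(b)

    def test_planted_truth_ranked_high(self):
        priors, truth, _ = sd.generate_network_truth(sd.NetworkTruthConfig(seed=5))
        net = puma_infer(priors)
        from sklearn.metrics import roc_auc_score

        auc = roc_auc_score(truth.to_numpy().ravel(), net.scores.to_numpy().ravel())
        assert auc > 0.9

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            puma_infer(toy_priors(), alpha=1.5)


class TestEdgeSignificance:
    def test_null_groups_flag_almost_nothing(self):
        rng = np.random.default_rng(6)
        priors = toy_priors(seed=6, n_samples=40)
        expr = priors.expression
        et = edge_significance(expr.iloc[:, :20], expr.iloc[:, 20:], priors, n_perm=10, seed=0)
        assert et["significant"].mean() <= 0.05
        assert ((et["significant"]) == (et["difference"].abs() > 4 * et["background_sd"])).all()

    def test_planted_differential_regulator_flagged(self):
        n = 500
        rng = np.random.default_rng(11)
        priors, truth, _ = sd.generate_network_truth(
            sd.NetworkTruthConfig(seed=11, noise_sd=0.2, n_samples_expr=n)
        )
        t = truth.to_numpy()
        t_b = t.copy()
        t_b[0, :] = 0  # regulator 0 inert in group B
        expr_a = pd.DataFrame(
            t.T @ rng.standard_normal((5, n)) + 0.2 * rng.standard_normal((20, n)),
            index=priors.genes,
            columns=[f"a{i}" for i in range(n)],
        )
        expr_b = pd.DataFrame(
            t_b.T @ rng.standard_normal((5, n)) + 0.2 * rng.standard_normal((20, n)),
            index=priors.genes,
            columns=[f"b{i}" for i in range(n)],
        )
        et = edge_significance(expr_a, expr_b, priors, n_perm=20, seed=11, tol=1e-2)
        sub = et[(et["regulator"] == "mir_1") & et["gene"].isin(priors.genes[t[0] == 1])]
        assert sub["significant"].any()

    def test_group_size_validation(self):
        priors = toy_priors(seed=7, n_samples=10)
        expr = priors.expression
        with pytest.raises(ValueError):
            edge_significance(expr.iloc[:, :2], expr.iloc[:, 2:], priors, n_perm=10)


class TestDownstream:
    def _net(self, seed):
        return puma_infer(toy_priors(seed=seed))

    def test_identical_networks_zero_difference(self):
        net = self._net(8)
        dt = differential_targeting(net, net)
        assert np.allclose(dt["difference"], 0.0)

    def test_targeting_matches_loop_oracle(self):
        a, b = self._net(8), self._net(9)
        dt = differential_targeting(a, b)
        for reg in a.scores.index:
            expected = sum(a.scores.loc[reg]) - sum(b.scores.loc[reg])
            assert np.isclose(dt.loc[reg, "difference"], expected, atol=1e-10)

    def test_extract_module_truncation_and_order(self, rng):
        edges = pd.DataFrame(
            {
                "regulator": ["r1"] * 6 + ["r2"] * 2,
                "gene": [f"g{i}" for i in range(8)],
                "difference": [0.5, -2.0, 1.0, 0.1, -0.4, 3.0, 0.2, -0.7],
                "significant": [True, True, True, False, True, False, True, True],
            }
        )
        module, nodes = extract_module(edges, ["r1"], top_k=3)
        assert list(module["gene"]) == ["g1", "g2", "g0"]  # |diff| 2.0, 1.0, 0.5
        module_all, _ = extract_module(edges, ["r1"], top_k=20)
        assert len(module_all) == 4  # only significant edges, fewer than top_k
        assert nodes["r1"] == 3

    def test_extract_module_sort_slice_oracle(self, rng):
        edges = pd.DataFrame(
            {
                "regulator": rng.choice(["a", "b"], 50),
                "gene": [f"g{i}" for i in range(50)],
                "difference": rng.normal(size=50),
                "significant": rng.random(50) < 0.7,
            }
        )
        module, _ = extract_module(edges, ["a"], top_k=5)
        sub = edges[(edges.regulator == "a") & edges.significant]
        expected = sub.reindex(
            sub["difference"].abs().sort_values(ascending=False).index
        ).head(5)
        assert list(module["gene"]) == list(expected["gene"])

    def test_extract_module_unknown_regulator(self):
        edges = pd.DataFrame(
            {"regulator": ["a"], "gene": ["g"], "difference": [1.0], "significant": [True]}
        )
        with pytest.raises(KeyError):
            extract_module(edges, ["zzz"])


class TestDrugScreen:
    TABLE = pd.DataFrame(
        {
            "gene": ["GAS1", "CD9", "gas1", "MTOR", "CD9"],
            "drug": ["drugA", "drugB", "drugA", "rapalog", "drugB"],
            "source": ["db1", "db1", "db2", "db1", "db1"],
        }
    )

    def test_empty_gene_list(self):
        assert drug_interaction_screen([], self.TABLE).empty

    def test_case_insensitive_join_and_dedup(self):
        hit = drug_interaction_screen(["Gas1", "cd9"], self.TABLE)
        assert len(hit) == 3  # GAS1/drugA/db1, gas1/drugA/db2, CD9/drugB/db1 (dedup)
        assert set(hit["gene"].str.upper()) == {"GAS1", "CD9"}

    def test_set_intersection_oracle(self, rng):
        genes = [f"G{i}" for i in range(30)]
        table = pd.DataFrame(
            {
                "gene": rng.choice(genes, 100),
                "drug": rng.choice(["d1", "d2", "d3"], 100),
                "source": "db",
            }
        )
        query = list(rng.choice(genes, 10, replace=False))
        hit = drug_interaction_screen(query, table)
        expected = {
            (g, d, s)
            for g, d, s in table.itertuples(index=False)
            if g.upper() in {q.upper() for q in query}
        }
        assert set(map(tuple, hit.to_numpy())) == expected

    def test_missing_columns(self):
        with pytest.raises(ValueError):
            drug_interaction_screen(["X"], pd.DataFrame({"gene": [], "drug": []}))
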