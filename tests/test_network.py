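"""Network construction: adjacency, TOM, modules, eigengenes, statistics."""

import numpy as np
import pandas as pd
import pytest

from nutrinet.network import (
    CoexpressionNetwork,
    detect_modules,
    gene_statistics,
    intramodular_connectivity,
    merge_modules,
    module_eigengenes,
    module_trait_correlation,
    scale_free_fit,
    signed_hybrid_adjacency,
    soft_threshold_scan,
    tom_similarity,
)


def tom_bruteforce(a: np.ndarray) -> np.ndarray:
    """Literal triple-loop TOM definition."""
    n = a.shape[0]
    k = np.array([a[i].sum() - a[i, i] for i in range(n)])
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(
                a[i, u] * a[u, j] for u in range(n) if u != i and u != j
            )
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


def expr_with_correlation(r: float, n: int = 8) -> pd.DataFrame:
    """Two genes with exact sample correlation r, via orthonormal bases."""
    z1 = np.tile([1.0, -1.0], n // 2)
    z2 = np.repeat([1.0, -1.0], n // 2)
    x = z1
    y = r * z1 + np.sqrt(1 - r**2) * z2
    return pd.DataFrame({"g1": x, "g2": y})


class TestAdjacency:
    @pytest.mark.parametrize(
        "cor,beta,expected",
        [
            (-0.5, 8, 0.0),  # signed hybrid zeroes negatives
            (0.5, 8, 0.5**8),
            (0.5, 1, 0.5),
        ],
    )
    def test_exact_correlations(self, cor, beta, expected):
        adj = signed_hybrid_adjacency(expr_with_correlation(cor), beta=beta)
        assert adj.loc["g1", "g2"] == pytest.approx(expected, abs=1e-12)
        assert adj.loc["g1", "g1"] == 1.0

    def test_perfect_correlation_gives_unit_edge(self):
        x = np.arange(6.0)
        expr = pd.DataFrame({"g1": x, "g2": 2 * x + 1})
        adj = signed_hybrid_adjacency(expr, beta=8)
        assert adj.loc["g1", "g2"] == pytest.approx(1.0)

    def test_zero_variance_gene_listed(self):
        expr = pd.DataFrame({"flat": np.ones(5), "ok": np.arange(5.0)})
        with pytest.raises(ValueError, match="flat"):
            signed_hybrid_adjacency(expr)


class TestTOM:
    def test_identical_neighborhoods_give_unit_overlap(self):
        a = np.ones((3, 3))
        tom = tom_similarity(a).to_numpy()
        np.testing.assert_allclose(tom, 1.0)

    def test_isolated_pair_gives_zero(self):
        a = np.eye(4)
        a[2, 3] = a[3, 2] = 0.5  # some edge elsewhere
        tom = tom_similarity(a)
        assert tom.iloc[0, 1] == 0.0

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for n in (4, 10, 25):
            a = rng.uniform(0, 1, (n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            tom = tom_similarity(a).to_numpy()
            np.testing.assert_allclose(tom, tom_bruteforce(a), atol=1e-12)
            assert tom.min() >= 0 and tom.max() <= 1 + 1e-12
            np.testing.assert_allclose(tom, tom.T)

    def test_asymmetric_input_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(a)


class TestSoftThreshold:
    def test_exact_power_law_scores_unit_fit(self):
        # degrees placed at bin centers with frequencies k^-2: the log-log
        # regression is exactly linear with negative slope
        centers = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        counts = np.round(1e5 * centers**-2.0).astype(int)
        k = np.repeat(centers, counts)
        fit, slope = scale_free_fit(k)
        assert fit == pytest.approx(1.0, abs=1e-6)
        assert slope == pytest.approx(-2.0, abs=1e-3)

    def test_scan_reports_all_powers_and_recommends(self, rng):
        expr = pd.DataFrame(rng.normal(size=(20, 60)))
        expr["const"] = 1.0  # constant gene must be dropped, not crash
        table, recommended = soft_threshold_scan(expr, powers=(1, 4, 8))
        assert list(table["power"]) == [1, 4, 8]
        assert recommended in (1, 4, 8)


def _block_expr(rng, sizes, cors, n_samples=40, noise=None):
    """Planted-block expression: each block shares one latent factor."""
    cols = {}
    g = 0
    for size, r in zip(sizes, cors):
        f = rng.normal(size=n_samples)
        for _ in range(size):
            eps = rng.normal(size=n_samples)
            cols[f"g{g}"] = r * f + np.sqrt(1 - r**2) * eps
            g += 1
    return pd.DataFrame(cols)


class TestModuleDetection:
    def test_two_planted_blocks_found_exactly(self, rng):
        expr = _block_expr(rng, [50, 50], [0.95, 0.95])
        adj = signed_hybrid_adjacency(expr, beta=6)
        part = detect_modules(1 - tom_similarity(adj))
        non_grey = part[part != "grey"]
        assert part.nunique() == 2 or (part.nunique() == 3 and "grey" in set(part))
        assert set(non_grey.unique()) == {"turquoise", "blue"}
        # each block maps to exactly one color
        first = part.iloc[:50]
        second = part.iloc[50:]
        assert first.nunique() == 1 and second.nunique() == 1

    def test_undersized_cluster_goes_grey(self, rng):
        expr = _block_expr(rng, [20, 50], [0.95, 0.95])
        adj = signed_hybrid_adjacency(expr, beta=6)
        part = detect_modules(1 - tom_similarity(adj), min_module_size=30)
        assert (part.iloc[:20] == "grey").all()
        assert (part.iloc[20:] != "grey").all()

    def test_gene_permutation_invariance_up_to_labels(self, rng):
        expr = _block_expr(rng, [40, 40], [0.95, 0.95])
        adj = signed_hybrid_adjacency(expr, beta=6)
        diss = 1 - tom_similarity(adj)
        part = detect_modules(diss)
        perm = rng.permutation(diss.index)
        part_perm = detect_modules(diss.loc[perm, perm]).reindex(part.index)
        # same co-assignment structure regardless of gene order
        joint = pd.crosstab(part, part_perm)
        assert (joint.gt(0).sum(axis=1) == 1).all()

    def test_out_of_range_dissimilarity_rejected(self):
        with pytest.raises(ValueError, match="dissimilarity"):
            detect_modules(np.full((3, 3), 1.5))


class TestEigengenes:
    def test_identical_genes_explain_all_variance(self, rng):
        profile = rng.normal(size=12)
        expr = pd.DataFrame({f"g{i}": profile for i in range(5)})
        part = pd.Series("turquoise", index=expr.columns)
        me, var_exp = module_eigengenes(expr, part)
        assert var_exp["turquoise"] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        r = np.corrcoef(me["turquoise"], z)[0, 1]
        assert r == pytest.approx(1.0)

    def test_sign_oriented_toward_module_average(self, rng):
        for seed in range(5):
            local = np.random.default_rng(seed)
            expr = pd.DataFrame(local.normal(size=(15, 8)))
            part = pd.Series("blue", index=expr.columns)
            me, _ = module_eigengenes(expr, part)
            avg = ((expr - expr.mean()) / expr.std(ddof=1)).mean(axis=1)
            assert np.corrcoef(me["blue"], avg)[0, 1] >= 0

    def test_matches_power_iteration_oracle(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 3)))
        part = pd.Series("brown", index=expr.columns)
        me, _ = module_eigengenes(expr, part)
        z = ((expr - expr.mean()) / expr.std(ddof=1)).to_numpy()
        # independent eigen-solver: power iteration on z z^T
        m = z @ z.T
        v = np.ones(len(m)) / np.sqrt(len(m))
        for _ in range(2000):
            v = m @ v
            v /= np.linalg.norm(v)
        assert abs(np.dot(v, me["brown"])) == pytest.approx(1.0, abs=1e-8)

    def test_maximizes_variance_among_unit_vectors(self, rng):
        expr = pd.DataFrame(rng.normal(size=(12, 6)))
        part = pd.Series("red", index=expr.columns)
        me, _ = module_eigengenes(expr, part)
        z = ((expr - expr.mean()) / expr.std(ddof=1)).to_numpy()
        best = np.linalg.norm(z.T @ me["red"].to_numpy())
        for _ in range(100):
            v = rng.normal(size=len(z))
            v /= np.linalg.norm(v)
            assert np.linalg.norm(z.T @ v) <= best + 1e-9

    def test_constant_gene_dropped_with_warning(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 3)), columns=["a", "b", "c"])
        expr["c"] = 7.0
        part = pd.Series("green", index=expr.columns)
        with pytest.warns(UserWarning, match="constant"):
            me, _ = module_eigengenes(expr, part)
        assert me.shape == (10, 1)


class TestMerging:
    def test_highly_correlated_eigengenes_merge(self, rng):
        expr = _block_expr(rng, [40, 40], [0.98, 0.98], n_samples=60)
        # make the second factor nearly identical to the first
        base = expr.iloc[:, 0]
        for c in expr.columns[40:]:
            expr[c] = 0.95 * base + 0.05 * expr[c] + rng.normal(scale=0.1, size=60)
        part = pd.Series(
            ["turquoise"] * 40 + ["blue"] * 40, index=expr.columns
        )
        merged, me, _ = merge_modules(expr, part)
        assert merged.nunique() == 1
        assert me.shape[1] == 1

    def test_moderately_correlated_eigengenes_stay(self, rng):
        expr = _block_expr(rng, [40, 40], [0.95, 0.95])
        part = pd.Series(
            ["turquoise"] * 40 + ["blue"] * 40, index=expr.columns
        )
        merged, me, _ = merge_modules(expr, part)
        assert merged.nunique() == 2

    def test_fixed_point_has_no_pair_above_080(self, rng):
        expr = pd.DataFrame(rng.normal(size=(30, 120)))
        part = pd.Series(
            np.repeat(["a", "b", "c", "d"], 30), index=expr.columns
        )
        merged, me, _ = merge_modules(expr, part, cut_height=0.20)
        if me.shape[1] > 1:
            corr = np.corrcoef(me.to_numpy(), rowvar=False)
            off = corr[np.triu_indices_from(corr, k=1)]
            assert (off <= 0.80 + 1e-9).all()


class TestModuleTrait:
    def test_eigengene_equal_to_trait(self):
        me = pd.DataFrame({"blue": np.arange(10.0)})
        traits = pd.DataFrame({"diet": np.arange(10.0)})
        r, p = module_trait_correlation(me, traits)
        assert r.loc["blue", "diet"] == pytest.approx(1.0)
        assert p.loc["blue", "diet"] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_trait_gives_zero(self):
        me = pd.DataFrame({"blue": [1.0, -1.0, 1.0, -1.0]})
        traits = pd.DataFrame({"t": [1.0, 1.0, -1.0, -1.0]})
        r, p = module_trait_correlation(me, traits)
        assert r.loc["blue", "t"] == pytest.approx(0.0, abs=1e-12)
        assert p.loc["blue", "t"] == pytest.approx(1.0)

    def test_constant_trait_reported_missing(self):
        me = pd.DataFrame({"blue": np.arange(5.0)})
        traits = pd.DataFrame({"t": np.ones(5)})
        r, p = module_trait_correlation(me, traits)
        assert np.isnan(r.loc["blue", "t"]) and np.isnan(p.loc["blue", "t"])

    def test_p_matches_permutation_oracle(self, rng):
        n = 20
        x = rng.normal(size=n)
        y = 0.7 * x + rng.normal(scale=0.7, size=n)
        me = pd.DataFrame({"m": x})
        traits = pd.DataFrame({"t": y})
        r, p = module_trait_correlation(me, traits)
        observed = abs(r.loc["m", "t"])
        n_perm = 100_000
        perms = np.array([rng.permutation(y) for _ in range(n_perm)])
        xc = (x - x.mean()) / x.std()
        pc = (perms - perms.mean(axis=1, keepdims=True)) / perms.std(
            axis=1, keepdims=True
        )
        null_r = np.abs(pc @ xc / n)
        p_perm = (1 + (null_r >= observed).sum()) / (1 + n_perm)
        # Monte-Carlo agreement (3 SE or coarse absolute slack)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p.loc["m", "t"] - p_perm) < max(3 * se + 1e-4, 0.2 * p_perm)


class TestGeneStatistics:
    def test_gene_identical_to_eigengene_scores_unit_kme(self, rng):
        me_vec = rng.normal(size=12)
        expr = pd.DataFrame({"g1": me_vec, "g2": rng.normal(size=12)})
        me = pd.DataFrame({"blue": me_vec})
        kme, gs, primary = gene_statistics(expr, me, rng.normal(size=12))
        assert kme.loc["g1", "blue"] == pytest.approx(1.0)
        assert primary["g1"] == "blue"

    def test_orthogonal_blocks_have_low_cross_kme(self, rng):
        expr = _block_expr(rng, [30, 30], [0.95, 0.95], n_samples=100)
        part = pd.Series(
            ["turquoise"] * 30 + ["blue"] * 30, index=expr.columns
        )
        me, _ = module_eigengenes(expr, part)
        kme, _, primary = gene_statistics(expr, me, rng.normal(size=100))
        own = np.r_[kme.iloc[:30, 0], kme.iloc[30:, 1]]
        cross = np.r_[kme.iloc[:30, 1], kme.iloc[30:, 0]]
        assert own.min() > 0.6
        assert np.abs(cross).mean() < 0.25
        assert (primary.iloc[:30] == "turquoise").all()

    def test_constant_gene_gives_missing(self, rng):
        expr = pd.DataFrame({"flat": np.ones(10), "ok": rng.normal(size=10)})
        me = pd.DataFrame({"m": rng.normal(size=10)})
        kme, gs, _ = gene_statistics(expr, me, rng.normal(size=10))
        assert np.isnan(kme.loc["flat", "m"]) and np.isnan(gs["flat"])


class TestIntramodularConnectivity:
    def test_complete_module_gives_size_minus_one(self):
        genes = [f"g{i}" for i in range(6)]
        adj = pd.DataFrame(np.ones((6, 6)), index=genes, columns=genes)
        part = pd.Series("blue", index=genes)
        np.testing.assert_allclose(intramodular_connectivity(adj, part), 5.0)

    def test_grey_genes_missing_and_isolated_zero(self):
        genes = ["a", "b", "c"]
        adj = pd.DataFrame(np.eye(3), index=genes, columns=genes)
        part = pd.Series({"a": "blue", "b": "blue", "c": "grey"})
        k = intramodular_connectivity(adj, part)
        assert k["a"] == 0.0 and np.isnan(k["c"])

    def test_matches_rowsum_oracle_on_random_module(self, rng):
        n = 20
        genes = [f"g{i}" for i in range(n)]
        a = rng.uniform(0, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        adj = pd.DataFrame(a, index=genes, columns=genes)
        part = pd.Series("red", index=genes)
        k = intramodular_connectivity(adj, part)
        for i, g in enumerate(genes):
            expected = sum(a[i, j] for j in range(n) if j != i)
            assert k[g] == pytest.approx(expected)


class TestEstimator:
    def test_sklearn_surface(self, rng):
        expr = _block_expr(rng, [40, 40], [0.95, 0.95])
        model = CoexpressionNetwork(beta=6)
        assert model.get_params()["beta"] == 6
        labels = model.fit_predict(expr)
        assert labels.shape == (80,)
        assert set(model.partition_.unique()) <= set(
            ("grey", "turquoise", "blue")
        )
        assert model.eigengenes_.shape[0] == 40
        clone_params = model.get_params()
        assert CoexpressionNetwork(**clone_params).get_params() == clone_params
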