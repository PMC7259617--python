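"""Signed network construction, TOM, module detection, eigengenes, traits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from immunecoex.coexpression import (
    cluster_genes,
    merge_close_modules,
    module_eigengene,
    module_eigengenes,
    module_trait_correlation,
    scale_free_fit_index,
    signed_adjacency,
    soft_threshold_scan,
    tom_similarity,
)


def _expr(arr, genes=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=genes, columns=[f"s{j}" for j in range(arr.shape[1])])


def brute_force_tom(A):
    """Triple-loop topological overlap, straight from the definition."""
    n = A.shape[0]
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(A[i, u] * A[u, j] for u in range(n) if u != i and u != j)
            k_i = sum(A[i, u] for u in range(n) if u != i)
            k_j = sum(A[j, u] for u in range(n) if u != j)
            t[i, j] = (l + A[i, j]) / (min(k_i, k_j) + 1 - A[i, j])
    return t


def random_adjacency(rng, n):
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestSignedAdjacency:
    def test_extreme_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        expr = _expr(np.vstack([x, 2 * x, -x]))
        a = signed_adjacency(expr, beta=5)
        assert a.iloc[0, 1] == pytest.approx(1.0)   # r = +1
        assert a.iloc[0, 2] == pytest.approx(0.0)   # r = -1
        assert np.allclose(np.diag(a), 1.0)

    def test_zero_correlation_at_beta_12(self):
        # orthogonal, mean-centered profiles: r exactly 0
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        a = signed_adjacency(_expr(np.vstack([x, y])), beta=12)
        assert a.iloc[0, 1] == pytest.approx(2.0**-12, rel=1e-12)

    def test_monotone_in_correlation(self, rng):
        expr = _expr(rng.normal(size=(20, 15)))
        r = np.corrcoef(expr.to_numpy())
        a = signed_adjacency(expr, beta=6).to_numpy()
        iu = np.triu_indices(20, 1)
        order_r = np.argsort(r[iu])
        assert np.all(np.diff(a[iu][order_r]) >= 0)

    def test_zero_variance_gene_named(self):
        expr = _expr(np.vstack([np.ones(4), np.arange(4.0)]), genes=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            signed_adjacency(expr)


class TestSoftThresholdScan:
    def test_mean_connectivity_decreases_with_beta(self, rng):
        expr = _expr(rng.normal(size=(60, 20)))
        scan = soft_threshold_scan(expr, betas=[1, 4, 8, 12])
        k = scan.table["mean_connectivity"].to_numpy()
        assert np.all(np.diff(k) < 0)

    def test_perfectly_correlated_connectivity(self):
        x = np.arange(10.0)
        expr = _expr(np.vstack([x * c for c in range(1, 41)]))
        scan = soft_threshold_scan(expr, betas=[1, 12])
        assert np.allclose(scan.table["mean_connectivity"], 39.0)

    def test_power_law_degrees_fit_well(self, rng):
        k = (1.0 + rng.pareto(1.5, size=3000)) * 2.0
        assert scale_free_fit_index(k) >= 0.9

    def test_few_genes_warn(self, rng):
        with pytest.warns(UserWarning, match="30 genes"):
            soft_threshold_scan(_expr(rng.normal(size=(10, 8))), betas=[1, 2])


class TestTOM:
    def test_matches_brute_force(self, rng):
        for _ in range(5):
            A = random_adjacency(rng, 8)
            t = tom_similarity(pd.DataFrame(A))
            assert np.allclose(t.to_numpy(), brute_force_tom(A), atol=1e-12)

    def test_isolated_pair_closed_form(self):
        x = 0.37
        A = np.eye(4)
        A[0, 1] = A[1, 0] = x
        t = tom_similarity(pd.DataFrame(A))
        assert t.iloc[0, 1] == pytest.approx(x)  # t = x/(x + 1 - x)

    def test_identical_rows_full_overlap(self):
        A = np.full((3, 3), 1.0)
        t = tom_similarity(pd.DataFrame(A))
        assert np.allclose(t, 1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_bounds_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        t = tom_similarity(pd.DataFrame(random_adjacency(rng, 6))).to_numpy()
        assert np.all(t >= 0.0) and np.all(t <= 1.0)
        assert np.allclose(np.diag(t), 1.0)


def _planted_blocks(rng, sizes, n_samples=30, noise=0.3):
    rows, labels = [], []
    for b, size in enumerate(sizes, start=1):
        f = rng.normal(size=n_samples)
        for _ in range(size):
            rows.append(f + noise * rng.normal(size=n_samples))
            labels.append(b)
    return _expr(np.array(rows)), np.array(labels)


class TestClusterGenes:
    def test_two_planted_blocks_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        expr, labels = _planted_blocks(rng, [50, 50])
        tom = tom_similarity(signed_adjacency(expr, beta=6))
        out = cluster_genes(tom, min_cluster_size=20, deep_split=2)
        assert len(out.module_ids) == 2
        assert adjusted_rand_score(labels, out.labels) == 1.0

    def test_null_data_spurious_modules_bounded(self):
        counts = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            expr = _expr(rng.normal(size=(200, 30)))
            tom = tom_similarity(signed_adjacency(expr, beta=12))
            out = cluster_genes(tom, min_cluster_size=20, deep_split=2)
            counts.append(len(out.module_ids))
        assert max(counts) < 5
        assert np.mean(counts) <= 1.0

    def test_min_size_one_assigns_every_gene(self, rng):
        expr = _expr(rng.normal(size=(30, 12)))
        tom = tom_similarity(signed_adjacency(expr, beta=6))
        out = cluster_genes(tom, min_cluster_size=1, deep_split=2, core_ratio=0.0)
        assert (out.labels > 0).all()

    def test_min_size_exceeding_genes_rejected(self, rng):
        tom = tom_similarity(pd.DataFrame(random_adjacency(rng, 5)))
        with pytest.raises(ValueError, match="min_cluster_size"):
            cluster_genes(tom, min_cluster_size=10)

    def test_labels_sorted_by_size(self, rng):
        expr, _ = _planted_blocks(rng, [60, 30])
        tom = tom_similarity(signed_adjacency(expr, beta=6))
        out = cluster_genes(tom, min_cluster_size=10, deep_split=2)
        sizes = out.sizes
        assert list(sizes.index) == sorted(sizes.index)
        assert np.all(np.diff(sizes.to_numpy()) <= 0)


class TestMergeCloseModules:
    def test_split_block_remerged(self, rng):
        expr, _ = _planted_blocks(rng, [60])
        labels = pd.Series([1] * 30 + [2] * 30, index=expr.index)
        from immunecoex.coexpression import ModuleAssignment

        split = ModuleAssignment(labels=labels, min_cluster_size=20)
        merged = merge_close_modules(expr, split, cut_height=0.05)
        assert len(merged.module_ids) == 1

    def test_distinct_modules_untouched_and_idempotent(self, rng):
        expr, _ = _planted_blocks(rng, [40, 40], noise=0.2)
        labels = pd.Series([1] * 40 + [2] * 40, index=expr.index)
        from immunecoex.coexpression import ModuleAssignment

        a = ModuleAssignment(labels=labels, min_cluster_size=20)
        m1 = merge_close_modules(expr, a, cut_height=0.05)
        assert len(m1.module_ids) == 2
        m2 = merge_close_modules(expr, m1, cut_height=0.05)
        pd.testing.assert_series_equal(m1.labels, m2.labels)

    def test_zero_cut_height_is_identity(self, rng):
        expr, _ = _planted_blocks(rng, [30, 30])
        labels = pd.Series([1] * 30 + [2] * 30, index=expr.index)
        from immunecoex.coexpression import ModuleAssignment

        a = ModuleAssignment(labels=labels, min_cluster_size=20)
        out = merge_close_modules(expr, a, cut_height=0.0)
        assert (out.labels == labels).all()


class TestEigengene:
    def test_identical_genes_rank_one(self, rng):
        x = rng.normal(size=12)
        expr = _expr(np.vstack([x, x, x]))
        eig, load, frac = module_eigengene(expr, expr.index)
        assert frac == pytest.approx(1.0)
        z = (x - x.mean()) / x.std(ddof=1)
        assert abs(np.corrcoef(eig, z)[0, 1]) == pytest.approx(1.0)
        assert np.corrcoef(eig, z)[0, 1] > 0  # sign convention

    def test_planted_factor_recovered(self, rng):
        f = rng.normal(size=40)
        rows = [lam * f + 0.4 * rng.normal(size=40) for lam in rng.uniform(0.5, 1.5, 30)]
        expr = _expr(np.array(rows))
        eig, _, _ = module_eigengene(expr, expr.index)
        assert abs(np.corrcoef(eig, f)[0, 1]) >= 0.9

    def test_sign_convention_positive_mean_correlation(self, rng):
        expr = _expr(rng.normal(size=(10, 15)))
        eig, _, _ = module_eigengene(expr, expr.index)
        Z = ((expr.T - expr.T.mean()) / expr.T.std(ddof=1)).mean(axis=1)
        assert np.corrcoef(eig, Z)[0, 1] > 0

    def test_unit_variance_and_loading_norm(self, rng):
        expr = _expr(rng.normal(size=(8, 20)))
        eig, load, frac = module_eigengene(expr, expr.index)
        assert eig.std(ddof=1) == pytest.approx(1.0)
        assert (load**2).sum() == pytest.approx(1.0)
        assert 0 < frac <= 1

    def test_single_gene_module_rejected(self, rng):
        expr = _expr(rng.normal(size=(3, 5)))
        with pytest.raises(ValueError, match="2 genes"):
            module_eigengene(expr, ["g0"])


def _meta(cell_types):
    samples = [f"s{j}" for j in range(len(cell_types))]
    return pd.DataFrame(
        {"cell_type": cell_types, "individual": samples},
        index=pd.Index(samples, name="sample"),
    )


class TestTraitCorrelation:
    def test_indicator_itself_gives_r_one_p_zero(self):
        ct = ["A"] * 5 + ["B"] * 5
        ind = np.array([1.0] * 5 + [0.0] * 5)
        eig = pd.DataFrame([ind], index=[1], columns=[f"s{j}" for j in range(10)])
        res = module_trait_correlation(eig, _meta(ct))
        assert res.r.loc[1, "A"] == pytest.approx(1.0)
        assert res.p.loc[1, "A"] == 0.0

    def test_zero_correlation_gives_p_one(self):
        ct = ["A", "A", "B", "B"]
        eig = pd.DataFrame(
            [[1.0, -1.0, 1.0, -1.0]], index=[1], columns=[f"s{j}" for j in range(4)]
        )
        res = module_trait_correlation(eig, _meta(ct))
        assert res.p.loc[1, "A"] == pytest.approx(1.0)

    def test_student_t_p_at_r_half_n20(self, rng):
        # construct an eigengene with exact r = 0.5 against the indicator
        ct = ["A"] * 10 + ["B"] * 10
        ind = np.array([1.0] * 10 + [0.0] * 10)
        x = (ind - ind.mean()) / ind.std()
        y = rng.normal(size=20)
        y = y - y.mean()
        y -= x * (x @ y) / (x @ x)            # orthogonal to x
        y /= y.std()
        eig_vec = 0.5 * x + np.sqrt(0.75) * y
        eig = pd.DataFrame([eig_vec], index=[1], columns=[f"s{j}" for j in range(20)])
        res = module_trait_correlation(eig, _meta(ct))
        assert res.r.loc[1, "A"] == pytest.approx(0.5, abs=1e-12)
        assert res.p.loc[1, "A"] == pytest.approx(0.0248, abs=2e-4)

    def test_matches_pearsonr_oracle(self, rng):
        ct = ["A"] * 6 + ["B"] * 6
        vec = rng.normal(size=12)
        eig = pd.DataFrame([vec], index=[1], columns=[f"s{j}" for j in range(12)])
        res = module_trait_correlation(eig, _meta(ct))
        ind = np.array([1.0] * 6 + [0.0] * 6)
        r_ref, p_ref = stats.pearsonr(vec, ind)
        assert res.r.loc[1, "A"] == pytest.approx(r_ref, abs=1e-12)
        assert res.p.loc[1, "A"] == pytest.approx(p_ref, rel=1e-9)

    def test_too_few_samples(self):
        eig = pd.DataFrame([[1.0, 2.0]], index=[1], columns=["s0", "s1"])
        with pytest.raises(ValueError, match="3 samples"):
            module_trait_correlation(eig, _meta(["A", "B"]))


class TestEndToEnd:
    def test_planted_modules_and_traits(self, sim_study):
        from sklearn.metrics import adjusted_rand_score

        from immunecoex import detect_modules

        cm, truth, expr = sim_study
        assignment, eigs, traits = detect_modules(expr, cm.metadata)
        planted = truth.module_labels.loc[expr.index]
        assert adjusted_rand_score(planted, assignment.labels) >= 0.8
        for m in assignment.module_ids:
            genes = set(assignment.genes_in(m))
            overlap = {
                pm: len(genes & set(planted.index[planted == pm]))
                for pm in truth.module_celltypes
            }
            pm = max(overlap, key=overlap.get)
            if overlap[pm] == 0:
                continue
            assert traits.strongest_positive(m) in truth.module_celltypes[pm]
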