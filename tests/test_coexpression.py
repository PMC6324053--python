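import numpy as np
import pytest
import scipy.linalg
from scipy.stats import mannwhitneyu

from conftest import DESK_FRACTION, DESK_REPS, module_masks
from coexbuild import (
    ModuleSpec,
    aggregate_mr,
    build_platform,
    center_genes,
    correlation_from_pcs,
    generate_expression,
    mutual_rank,
    pca_truncate,
    subsample_pcs,
)
from coexbuild.coexpression import mr_to_unit, unit_to_mr
from coexbuild.types import ExpressionMatrix


def centered(values):
    values = np.asarray(values, dtype=float)
    values = values - values.mean(axis=1, keepdims=True)
    g, s = values.shape
    return ExpressionMatrix(
        tuple(f"g{i}" for i in range(g)),
        tuple(f"s{j}" for j in range(s)),
        values,
        "log2",
    )


def brute_force_mutual_rank(corr):
    """Independent O(n^2 log n) oracle: explicit sort-based directed ranks
    (average rank on ties), then the geometric mean."""
    n = corr.shape[0]
    ranks = np.zeros((n, n))
    for a in range(n):
        others = [b for b in range(n) if b != a]
        vals = sorted((-corr[a, b] for b in others))
        for b in others:
            v = -corr[a, b]
            lo = np.searchsorted(vals, v, side="left")
            hi = np.searchsorted(vals, v, side="right")
            ranks[a, b] = (lo + hi + 1) / 2.0  # average of 1-based tied positions
    mr = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a != b:
                mr[a, b] = np.sqrt(ranks[a, b] * ranks[b, a])
    return mr


class TestPCATruncate:
    def test_rank_two_matrix_yields_two_components(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(20, 2))
        v = rng.normal(size=(2, 15))
        m = centered(u @ v)
        d = pca_truncate(m)
        # centering can add at most one dimension; the strong PCs are 2
        assert d.singular_values[1] > 1e3 * (
            d.singular_values[2] if d.n_kept > 2 else 0.0
        )

    def test_truncation_matches_full_svd_oracle(self, rng):
        m = centered(rng.normal(size=(50, 30)))
        d = pca_truncate(m, max_pcs=10)
        assert d.n_kept == 10
        s_full = scipy.linalg.svdvals(m.values)
        np.testing.assert_allclose(d.singular_values, s_full[:10], rtol=1e-10)

    def test_max_pcs_beyond_rank_gives_numeric_rank(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(10, 3))
        v = rng.normal(size=(3, 8))
        m = centered(u @ v)
        d = pca_truncate(m, max_pcs=100)
        assert d.n_kept <= 4  # rank 3 plus at most one from centering
        assert d.n_kept >= 3

    def test_loadings_orthonormal_and_reconstruction_exact(self, rng):
        m = centered(rng.normal(size=(12, 9)))
        d = pca_truncate(m)
        gram = d.components @ d.components.T
        np.testing.assert_allclose(gram, np.eye(d.n_kept), atol=1e-8)
        recon = (d.components.T * d.singular_values) @ d.scores.T
        np.testing.assert_allclose(recon, m.values, atol=1e-8)

    def test_requires_three_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            pca_truncate(centered(np.zeros((5, 2)) + [[1, -1]]))

    def test_rejects_uncentered_input(self, rng):
        values = rng.normal(5, 1, size=(10, 8))
        m = ExpressionMatrix(
            tuple(f"g{i}" for i in range(10)),
            tuple(f"s{j}" for j in range(8)),
            values,
            "log2",
        )
        with pytest.raises(ValueError, match="centered"):
            pca_truncate(m)


class TestSubsamplePCs:
    def _decomp(self, n_kept):
        rng = np.random.default_rng(5)
        m = centered(rng.normal(size=(n_kept + 5, n_kept + 5)))
        return pca_truncate(m, max_pcs=n_kept)

    def test_ten_percent_of_1000_pcs_is_100(self):
        d = self._decomp(1000)
        sel = subsample_pcs(d, 0.10, np.random.default_rng(0))
        assert len(sel) == 100
        assert len(set(sel.tolist())) == 100

    def test_fraction_one_returns_all_sorted(self):
        d = self._decomp(20)
        sel = subsample_pcs(d, 1.0, np.random.default_rng(0))
        np.testing.assert_array_equal(sel, np.arange(20))

    def test_uniform_selection_frequency(self):
        d = self._decomp(20)
        rng = np.random.default_rng(42)
        hits = np.zeros(20)
        n_draws = 10_000
        for _ in range(n_draws):
            hits[subsample_pcs(d, 0.10, rng)] += 1
        freq = hits / n_draws
        # each PC drawn with p = k/n = 0.10; 3 standard errors of the mean
        se = np.sqrt(0.1 * 0.9 / n_draws)
        assert np.all(np.abs(freq - 0.10) < 3 * se + 1e-12), freq

    def test_deterministic_given_rng_state(self):
        d = self._decomp(50)
        a = subsample_pcs(d, 0.2, np.random.default_rng(7))
        b = subsample_pcs(d, 0.2, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_invalid_fraction_rejected(self):
        d = self._decomp(10)
        with pytest.raises(ValueError):
            subsample_pcs(d, 0.0)


class TestCorrelationFromPCs:
    def test_all_pcs_reproduce_plain_pearson(self, rng):
        m = centered(rng.normal(size=(25, 18)))
        d = pca_truncate(m)
        corr = correlation_from_pcs(d, np.arange(d.n_kept))
        np.testing.assert_allclose(corr, np.corrcoef(m.values), atol=1e-8)

    def test_single_pc_gives_sign_correlations(self):
        # two genes loading on one shared pattern: correlation +-1 by sign
        pattern = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5])
        m = centered(np.vstack([pattern, -pattern, 0.5 * pattern]))
        d = pca_truncate(m)
        corr = correlation_from_pcs(d, [0])
        np.testing.assert_allclose(np.abs(corr), 1.0, atol=1e-10)
        assert corr[0, 1] == pytest.approx(-1.0)
        assert corr[0, 2] == pytest.approx(1.0)

    def test_subset_matches_reconstruct_then_correlate_oracle(self, rng):
        m = centered(rng.normal(size=(20, 14)))
        selected = [0, 1, 2]
        # oracle: independent SVD, explicit reconstruction, plain corrcoef
        u, s, vt = scipy.linalg.svd(m.values, full_matrices=False)
        recon = u[:, selected] @ np.diag(s[selected]) @ vt[selected]
        expected = np.corrcoef(recon)
        d = pca_truncate(m)
        corr = correlation_from_pcs(d, selected)
        np.testing.assert_allclose(corr, expected, atol=1e-8)

    def test_zero_variance_gene_flagged_nan(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(6, 8))
        values[5] = 0.0  # a flat gene reconstructs to zero under any subset
        m = centered(values)
        d = pca_truncate(m)
        corr = correlation_from_pcs(d, [0, 1])
        assert np.isnan(corr[5, 0]) and np.isnan(corr[0, 5])
        assert not np.isnan(corr[0, 1])


class TestMutualRank:
    def test_reciprocal_best_pair_has_mr_one(self):
        corr = np.array(
            [
                [1.0, 0.9, 0.1, 0.0],
                [0.9, 1.0, 0.2, 0.1],
                [0.1, 0.2, 1.0, 0.3],
                [0.0, 0.1, 0.3, 1.0],
            ]
        )
        mr = mutual_rank(corr)
        assert mr[0, 1] == pytest.approx(1.0)

    def test_geometric_mean_arithmetic(self):
        # by construction rank(0->1) = 2 and rank(1->0) = 8
        assert np.sqrt(2 * 8) == pytest.approx(4.0)
        n = 9
        corr = np.full((n, n), 0.0)
        np.fill_diagonal(corr, 1.0)
        corr[0, 1] = corr[1, 0] = 0.5
        corr[0, 2] = corr[2, 0] = 0.9  # rank(0->1) = 2
        for j in range(2, n):  # everyone else beats gene 0 in gene 1's list
            corr[1, j] = corr[j, 1] = 0.6 + 0.01 * j
        mr = mutual_rank(corr)
        assert mr[0, 1] == pytest.approx(np.sqrt(2 * 8))

    @pytest.mark.parametrize("n", [12, 20, 30])
    def test_matches_brute_force_oracle(self, n):
        rng = np.random.default_rng(n)
        base = rng.normal(size=(n, n + 3))
        corr = np.corrcoef(base)
        mr = mutual_rank(corr)
        expected = brute_force_mutual_rank(corr)
        off = ~np.eye(n, dtype=bool)
        np.testing.assert_allclose(mr[off], expected[off], atol=1e-10)

    def test_ties_get_average_ranks(self):
        corr = np.zeros((5, 5))
        np.fill_diagonal(corr, 1.0)
        mr = mutual_rank(corr)  # all off-diagonal tied: ranks all (1+4)/2
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_allclose(mr[off], 2.5)

    def test_symmetry_and_range(self, rng):
        corr = np.corrcoef(rng.normal(size=(15, 20)))
        mr = mutual_rank(corr)
        np.testing.assert_allclose(mr, mr.T)
        off = ~np.eye(15, dtype=bool)
        assert mr[off].min() >= 1.0
        assert mr[off].max() <= 14.0

    def test_rejects_tiny_matrix(self):
        with pytest.raises(ValueError, match="3 genes"):
            mutual_rank(np.eye(2))


class TestAggregateMR:
    def test_identical_ensemble_is_fixed_point(self, rng):
        corr = np.corrcoef(rng.normal(size=(10, 12)))
        mr = mutual_rank(corr)
        agg = aggregate_mr([mr] * 5, n_genes=10)
        off = ~np.eye(10, dtype=bool)
        np.testing.assert_allclose(agg[off], mr[off], atol=1e-8)

    def test_logit_symmetry_midpoint(self):
        # unit-interval values 0.2 and 0.8 average to exactly 0.5 in logit space
        n = 12
        mr_a = np.full((n, n), unit_to_mr(0.2, n))
        mr_b = np.full((n, n), unit_to_mr(0.8, n))
        np.fill_diagonal(mr_a, 0.0)
        np.fill_diagonal(mr_b, 0.0)
        agg = aggregate_mr([mr_a, mr_b], n_genes=n)
        off = ~np.eye(n, dtype=bool)
        np.testing.assert_allclose(mr_to_unit(agg, n)[off], 0.5, atol=1e-10)

    def test_matches_scalar_chain_oracle(self, rng):
        n = 10
        mats = [mutual_rank(np.corrcoef(rng.normal(size=(n, 15)))) for _ in range(5)]
        agg = aggregate_mr(mats, n_genes=n)
        from scipy.special import expit, logit

        off = ~np.eye(n, dtype=bool)
        stack = np.stack([(m - 0.5) / (n - 1) for m in mats])
        expected = expit(logit(stack).mean(axis=0)) * (n - 1) + 0.5
        np.testing.assert_allclose(agg[off], expected[off], atol=1e-10)

    def test_missing_entries_averaged_over_valid_repetitions(self, rng):
        n = 8
        a = mutual_rank(np.corrcoef(rng.normal(size=(n, 10))))
        b = a.copy()
        b[0, 1] = b[1, 0] = np.nan
        agg = aggregate_mr([a, b], n_genes=n)
        assert agg[0, 1] == pytest.approx(a[0, 1], abs=1e-8)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            aggregate_mr([np.ones((3, 3)), np.ones((4, 4))], n_genes=3)


class TestBuildPlatform:
    def test_degenerate_ensemble_collapses_to_pearson_mr(self, rng):
        m = centered(rng.normal(size=(30, 25)))
        platform = build_platform(m, subsample_fraction=1.0, n_repetitions=1, seed=0)
        expected = mutual_rank(np.corrcoef(m.values))
        off = ~np.eye(30, dtype=bool)
        np.testing.assert_allclose(platform.mr[off], expected[off], atol=1e-8)

    def test_same_seed_is_bit_identical(self, rng):
        m = centered(rng.normal(size=(15, 12)))
        a = build_platform(m, n_repetitions=5, subsample_fraction=0.3, seed=9)
        b = build_platform(m, n_repetitions=5, subsample_fraction=0.3, seed=9)
        np.testing.assert_array_equal(a.mr, b.mr)
        c = build_platform(m, n_repetitions=5, subsample_fraction=0.3, seed=10)
        assert not np.array_equal(a.mr, c.mr)

    def test_rejects_zero_repetitions(self, rng):
        m = centered(rng.normal(size=(5, 5)))
        with pytest.raises(ValueError):
            build_platform(m, n_repetitions=0)

    def test_planted_modules_have_lower_mr(self, two_module_spec, two_module_platform):
        within, between = module_masks(two_module_spec)
        mr = two_module_platform.mr
        assert np.median(mr[within]) < np.median(mr[between])
        p = mannwhitneyu(mr[within], mr[between], alternative="less").pvalue
        assert p < 0.01

    def test_stronger_modules_give_lower_within_mr(self):
        results = []
        for rho in (0.2, 0.5, 0.8):
            spec = ModuleSpec(
                n_modules=2,
                genes_per_module=10,
                within_corr=rho,
                background_genes=80,
                n_samples=200,
                seed=21,
            )
            m = center_genes(generate_expression(spec))
            platform = build_platform(
                m, n_repetitions=DESK_REPS, subsample_fraction=DESK_FRACTION, seed=5
            )
            within, _ = module_masks(spec)
            results.append(platform.mr[within].mean())
        assert results[0] > results[1] > results[2]
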