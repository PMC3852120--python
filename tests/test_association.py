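import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from genohap.association import (
    HaplotypePairSet,
    RegionGenotypes,
    build_haplotype_matrix,
    collapse_rare_variants,
    fit_null_model,
    group_haplotypes,
    skat_test,
)


def make_region(dosages, maf=None):
    dosages = np.asarray(dosages, dtype=float)
    ids = [f"v{j}" for j in range(dosages.shape[1])]
    return RegionGenotypes(dosages, ids, maf=maf)


class TestCollapse:
    def test_super_variant_capped_at_two(self):
        # a carrier of three rare minor alleles contributes a burden of 2
        n = 300
        d = np.zeros((n, 3))
        d[0] = [1, 1, 1]
        G = make_region(d)
        out = collapse_rare_variants(G, 0.01)
        assert out.has_super_variant
        assert out.matrix[0, -1] == 2.0
        assert out.matrix[1:, -1].max() == 0.0

    def test_no_rare_variants_is_identity(self):
        rng = np.random.default_rng(1)
        d = rng.integers(1, 3, size=(40, 4)).astype(float)  # all common
        G = make_region(d)
        out = collapse_rare_variants(G, 0.01)
        assert not out.has_super_variant
        np.testing.assert_array_equal(out.matrix, d)

    def test_toy_matrix_matches_rowwise_capped_sum(self):
        d = np.array(
            [[1.0, 0.0, 2.0], [1.0, 1.0, 1.0], [0.0, 0.0, 0.0], [0.0, 1.0, 1.0]]
        )
        G = make_region(d, maf=np.array([0.004, 0.004, 0.30]))
        out = collapse_rare_variants(G, 0.01)
        expected_super = np.array([min(2, r[0] + r[1]) for r in d])
        np.testing.assert_array_equal(out.matrix[:, -1], expected_super)
        np.testing.assert_array_equal(out.matrix[:, 0], d[:, 2])

    def test_all_missing_variant_rejected(self):
        d = np.array([[0.0, np.nan], [1.0, np.nan]])
        with pytest.raises(ValueError, match="missing"):
            make_region(d)

    def test_missing_dosages_mean_imputed(self):
        d = np.array([[0.0, 2.0], [np.nan, 0.0], [2.0, 0.0], [0.0, 0.0]])
        G = make_region(d)
        out = collapse_rare_variants(G, 0.3)
        # column 0 is common at this threshold; its missing entry is imputed
        # with the observed mean dosage 2/3
        assert out.matrix[1, 0] == pytest.approx(2.0 / 3.0)


class TestGrouping:
    def test_common_singletons_rare_pooled(self):
        H = HaplotypePairSet(
            [("A", "B")], {"A": 0.60, "B": 0.39, "C": 0.006, "D": 0.004}
        )
        g = group_haplotypes(H, 0.01)
        assert g.reference == {"A"}
        assert {frozenset(x) for x in g.groups} == {
            frozenset({"A"}), frozenset({"B"}), frozenset({"C", "D"})
        }

    def test_two_haplotypes_single_design_column(self):
        H = HaplotypePairSet([("A", "B")], {"A": 0.5, "B": 0.5})
        g = group_haplotypes(H)
        assert g.n_groups == 2
        R = build_haplotype_matrix(H, g)
        assert R.matrix.shape == (1, 1)

    def test_three_bin_fallback_matches_binning_oracle(self):
        # no haplotype reaches 1%: frequencies straddle the 0.05% and 0.1%
        # bin boundaries
        freqs = {}
        for i in range(1000):
            freqs[f"lo{i}"] = 0.0002
        for i in range(500):
            freqs[f"mid{i}"] = 0.0008
        for i in range(250):
            freqs[f"hi{i}"] = 0.0016
        assert sum(freqs.values()) == pytest.approx(1.0)
        assert max(freqs.values()) < 0.01
        H = HaplotypePairSet([("lo0", "hi0")], freqs)
        g = group_haplotypes(H, 0.01)
        assert g.scheme == "three-bin-fallback"
        oracle = {
            "lo": {h for h, f in freqs.items() if f < 0.0005},
            "mid": {h for h, f in freqs.items() if 0.0005 <= f <= 0.001},
            "hi": {h for h, f in freqs.items() if f > 0.001},
        }
        expected = {frozenset(v) for v in oracle.values() if v}
        assert {frozenset(x) for x in g.groups} == expected

    def test_single_haplotype_rejected(self):
        H = HaplotypePairSet([("A", "A")], {"A": 1.0})
        with pytest.raises(ValueError, match="degenerate"):
            group_haplotypes(H)


class TestDesignMatrix:
    def test_both_haplotypes_in_first_group(self):
        H = HaplotypePairSet(
            [("C", "C"), ("A", "A")], {"A": 0.5, "B": 0.25, "C": 0.25}
        )
        g = group_haplotypes(H, 0.01)
        R = build_haplotype_matrix(H, g).matrix
        # A is the reference; individual 0 carries two copies of one
        # non-reference haplotype, individual 1 two reference copies
        assert R.shape == (2, 2)
        assert sorted(R[0].tolist()) == [0.0, 2.0]
        np.testing.assert_array_equal(R[1], [0.0, 0.0])

    def test_row_sums_conserve_haplotype_count(self):
        rng = np.random.default_rng(7)
        names = ["A", "B", "C", "D", "E"]
        pairs = [tuple(rng.choice(names, 2)) for _ in range(10)]
        H = HaplotypePairSet.from_pairs(pairs)
        g = group_haplotypes(H, 0.05)
        R = build_haplotype_matrix(H, g).matrix
        for i, (h1, h2) in enumerate(pairs):
            in_ref = sum(h in g.reference for h in (h1, h2))
            assert R[i].sum() + in_ref == 2

    def test_unknown_haplotype_rejected(self):
        H = HaplotypePairSet([("A", "B")], {"A": 0.5, "B": 0.5})
        g = group_haplotypes(H)
        H2 = HaplotypePairSet([("A", "Z")], {"A": 0.5, "Z": 0.5})
        with pytest.raises(ValueError, match="absent"):
            build_haplotype_matrix(H2, g)


class TestNullModel:
    def test_intercept_only_gaussian(self):
        y = np.array([1.0, 2.0, 4.0, 5.0])
        fit = fit_null_model(y, None, "gaussian")
        assert fit.intercept == pytest.approx(3.0)
        np.testing.assert_allclose(fit.residuals, y - 3.0)

    def test_binary_covariate_is_group_mean_fit(self):
        rng = np.random.default_rng(11)
        c = np.repeat([0.0, 1.0], 15)
        y = rng.standard_normal(30) + 2 * c
        fit = fit_null_model(y, c[:, None], "gaussian")
        for grp in (0, 1):
            np.testing.assert_allclose(
                fit.residuals[c == grp], y[c == grp] - y[c == grp].mean(), atol=1e-10
            )

    def test_binomial_intercept_is_logit_prevalence(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = fit_null_model(y, None, "binomial")
        assert fit.intercept == pytest.approx(np.log(0.3 / 0.7), abs=1e-6)

    def test_rank_deficient_covariates_named(self):
        rng = np.random.default_rng(2)
        c0 = rng.standard_normal(20)
        C = np.column_stack([c0, 2 * c0])
        with pytest.raises(ValueError, match="covariate_1"):
            fit_null_model(rng.standard_normal(20), C, "gaussian")


class TestSkat:
    def test_zero_design_gives_pvalue_one(self):
        rng = np.random.default_rng(0)
        fit = fit_null_model(rng.standard_normal(30), None, "gaussian")
        with pytest.warns(UserWarning, match="no variance"):
            res = skat_test(np.zeros((30, 1)), fit)
        assert res.Q == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(50))
    def test_single_column_equals_classical_score_test(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        y = rng.standard_normal(n)
        x = rng.standard_normal(n)
        fit = fit_null_model(y, None, "gaussian")
        res = skat_test(x, fit)
        full = sm.OLS(y, sm.add_constant(x)).fit()
        null = sm.OLS(y, np.ones((n, 1))).fit()
        lm_p = full.compare_lm_test(null)[1]
        assert res.p_value == pytest.approx(lm_p, abs=1e-6)

    def test_multicolumn_matches_permutation_oracle(self):
        rng = np.random.default_rng(42)
        n, B = 30, 100_000
        y = rng.standard_normal(n)
        X = rng.integers(0, 3, size=(n, 3)).astype(float)
        fit = fit_null_model(y, None, "gaussian")
        res = skat_test(X, fit)
        eps = fit.residuals
        perms = rng.permuted(np.tile(eps, (B, 1)), axis=1)
        U = perms @ X
        stats_perm = np.einsum("bl,bl->b", U, U) / (2 * fit.dispersion)
        p_perm = (np.sum(stats_perm >= res.Q) + 1) / (B + 1)
        se = np.sqrt(p_perm * (1 - p_perm) / B)
        assert abs(res.p_value - p_perm) < 3 * se + 1e-4

    def test_invariant_to_column_order(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal(50)
        X = rng.integers(0, 3, size=(50, 4)).astype(float)
        fit = fit_null_model(y, None, "gaussian")
        a = skat_test(X, fit)
        b = skat_test(X[:, ::-1], fit)
        assert a.Q == pytest.approx(b.Q)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-9)

    def test_null_rejection_rate_calibrated(self):
        # 2000 null Gaussian datasets at n=200; rejection at 0.05 must stay
        # in the 99% binomial band [0.037, 0.064]
        rng = np.random.default_rng(2024)
        n, n_sim = 200, 2000
        X = rng.integers(0, 3, size=(n, 5)).astype(float)
        rej = 0
        for _ in range(n_sim):
            y = rng.standard_normal(n)
            fit = fit_null_model(y, None, "gaussian")
            rej += skat_test(X, fit).p_value < 0.05
        assert 0.037 <= rej / n_sim <= 0.064

    def test_binomial_family_calibrated(self):
        rng = np.random.default_rng(77)
        n, n_sim = 300, 500
        X = rng.integers(0, 3, size=(n, 4)).astype(float)
        rej = 0
        for _ in range(n_sim):
            y = (rng.random(n) < 0.4).astype(float)
            fit = fit_null_model(y, None, "binomial")
            rej += skat_test(X, fit).p_value < 0.05
        band = 3 * np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rej / n_sim - 0.05) < band + 0.01
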