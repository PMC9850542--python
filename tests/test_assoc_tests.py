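import itertools

import numpy as np
import pytest
from scipy import stats

from omninorm.data_model import SampleMetadata
from omninorm.assoc_tests import (
    TauGrid,
    bray_curtis_kernel,
    krv_exhaustive,
    krv_test,
    linear_genotype_kernel,
    linear_test,
    qrank_test,
    run_taxonwise,
    zinq_test,
)
from omninorm.omnibus import cauchy_combine


class TestTauGrid:
    def test_default(self):
        assert TauGrid().levels == (0.1, 0.25, 0.5, 0.75, 0.9)

    @pytest.mark.parametrize("levels", [(), (0.5, 0.5), (0.9, 0.1), (0.0, 0.5), (0.5, 1.0)])
    def test_invalid(self, levels):
        with pytest.raises(ValueError):
            TauGrid(levels)


class TestLinearTest:
    def test_perfect_fit(self, rng):
        v = rng.binomial(1, 0.5, 50).astype(float)
        assert linear_test(v, v).p_value < 1e-12

    def test_constant_response(self, rng):
        v = rng.binomial(1, 0.5, 50).astype(float)
        assert linear_test(np.full(50, 3.0), v).p_value == 1.0

    def test_matches_ols_reference(self, rng):
        """Dual route: p-value equals the statsmodels OLS t-test."""
        import statsmodels.api as sm

        y = rng.normal(size=60)
        v = rng.normal(size=60)
        Z = rng.normal(size=(60, 2))
        res = linear_test(y, v, Z)
        ref = sm.OLS(y, np.column_stack([np.ones(60), v, Z])).fit()
        assert res.p_value == pytest.approx(ref.pvalues[1], abs=1e-12)

    def test_rank_deficient_design(self, rng):
        v = rng.normal(size=30)
        with pytest.raises(np.linalg.LinAlgError):
            linear_test(rng.normal(size=30), v, Z=v[:, None])

    def test_null_calibration(self):
        """Exact t-test: rejection rate at alpha=0.05 is 0.05 +/- 3 MC-SE."""
        rng = np.random.default_rng(31)
        n_rep, hits = 2000, 0
        for _ in range(n_rep):
            y = rng.normal(size=40)
            v = rng.binomial(1, 0.5, 40).astype(float)
            hits += linear_test(y, v).p_value <= 0.05
        rate = hits / n_rep
        assert rate == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / n_rep))


class TestQRankTest:
    def test_strong_signal(self, rng):
        v = rng.binomial(1, 0.5, 150).astype(float)
        y = v + 0.1 * rng.normal(size=150)
        assert qrank_test(y, v).p_value < 1e-3

    def test_constant_response(self, rng):
        v = rng.normal(size=30)
        assert qrank_test(np.zeros(30), v).p_value == 1.0

    def test_median_rank_score_oracle(self, rng):
        """Single-level grid {0.5}: matches the brute-force median
        rank-score (sign-test-like) statistic."""
        y = rng.normal(size=81)  # odd n, continuous: no ties at the median
        v = rng.normal(size=81)
        res = qrank_test(y, v, taus=TauGrid((0.5,)))
        # brute force: score +-0.5 around the empirical median
        med = np.sort(y)[np.ceil(0.5 * 81).astype(int) - 1]
        v_star = v - v.mean()
        b = np.where(y > med, 0.5, -0.5)
        b[y == med] = 0.5 * 81 - (y > med).sum() - 0.5  # fractional tie score
        S = float(v_star @ b)
        chi = S * S / (0.25 * float(v_star @ v_star))
        p_oracle = stats.chi2.sf(chi, 1)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-10)

    def test_monotone_transform_invariance(self, rng):
        """Covariate-free rank scores depend only on the ordering of y."""
        y = rng.gamma(2.0, 5.0, 120)
        v = rng.normal(size=120)
        p1 = qrank_test(y, v).p_value
        p2 = qrank_test(np.exp(y / y.max() * 3), v).p_value
        p3 = qrank_test(y**3, v).p_value
        assert p1 == pytest.approx(p2, abs=1e-12)
        assert p1 == pytest.approx(p3, abs=1e-12)

    def test_covariate_path_null_calibration(self):
        """LP-dual rank scores keep size with covariates in the null design."""
        rng = np.random.default_rng(5)
        n_rep, hits = 300, 0
        for _ in range(n_rep):
            Z = rng.normal(size=(120, 2))
            y = rng.gamma(2, 5, 120) + Z[:, 0]
            v = rng.binomial(1, 0.5, 120).astype(float)
            hits += qrank_test(y, v, Z).p_value <= 0.05
        assert hits / n_rep == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / n_rep))


class TestZinqTest:
    def test_reduces_to_qrank_when_all_positive(self, rng):
        y = rng.gamma(2, 10, 100) + 1.0
        v = rng.binomial(1, 0.5, 100).astype(float)
        assert zinq_test(y, v).p_value == pytest.approx(qrank_test(y, v).p_value, abs=1e-12)

    def test_all_zero_response(self, rng):
        v = rng.binomial(1, 0.5, 50).astype(float)
        with pytest.warns(RuntimeWarning):
            assert zinq_test(np.zeros(50), v).p_value == 1.0

    def test_negative_response_rejected(self, rng):
        with pytest.raises(ValueError):
            zinq_test(np.array([-1.0, 2.0, 3.0]), rng.normal(size=3))

    def test_presence_only_effect_detected_by_zero_part(self):
        """When the outcome moves presence/absence but not positive
        magnitudes, the two-part test beats the positives-only test."""
        rng = np.random.default_rng(17)
        n = 600
        v = rng.binomial(1, 0.5, n).astype(float)
        present = rng.random(n) < np.where(v == 1, 0.85, 0.45)
        y = np.where(present, rng.gamma(2.0, 10.0, n), 0.0)
        p_zinq = zinq_test(y, v).p_value
        pos = y > 0
        p_qrank_pos = qrank_test(y[pos], v[pos]).p_value
        assert p_zinq < 1e-6
        assert p_zinq < p_qrank_pos * 1e-2

    def test_few_positives_uses_zero_part_only(self, rng):
        v = rng.binomial(1, 0.5, 200).astype(float)
        y = np.zeros(200)
        y[:5] = [3.0, 1.0, 4.0, 2.0, 8.0]
        res = zinq_test(y, v)
        assert 0 < res.p_value <= 1


class TestBrayCurtisKernel:
    def test_identical_samples_zero_distance(self):
        M = np.array([[0.2, 0.8], [0.2, 0.8], [0.5, 0.5], [0.1, 0.9]])
        D2 = -2 * bray_curtis_kernel(M)  # not the distance, just smoke shape
        assert D2.shape == (4, 4)
        # identical rows are indistinguishable in the kernel geometry
        K = bray_curtis_kernel(M)
        self_d = K[0, 0] + K[1, 1] - 2 * K[0, 1]
        assert self_d == pytest.approx(0.0, abs=1e-10)

    def test_disjoint_support_maximal(self):
        M = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        from scipy.spatial.distance import braycurtis

        assert braycurtis(M[0], M[1]) == pytest.approx(1.0)

    def test_matches_gower_double_centering(self, rng):
        """Oracle: elementwise double loop of the Gower transform."""
        M = rng.dirichlet(np.ones(6), size=4)
        K = bray_curtis_kernel(M)
        n = 4
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                num = np.abs(M[i] - M[j]).sum()
                den = (M[i] + M[j]).sum()
                D[i, j] = num / den
        G = np.zeros((n, n))
        D2 = D**2
        for i in range(n):
            for j in range(n):
                G[i, j] = -0.5 * (
                    D2[i, j] - D2[i].mean() - D2[:, j].mean() + D2.mean()
                )
        # PSD truncation may perturb, so compare against the truncated oracle
        vals, vecs = np.linalg.eigh(G)
        G_psd = (vecs * np.clip(vals, 0, None)) @ vecs.T
        np.testing.assert_allclose(K, G_psd, atol=1e-10)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis_kernel(np.array([[1.0, -0.5], [0.2, 0.8]]))

    def test_psd(self, rng):
        M = rng.dirichlet(np.ones(10), size=15)
        K = bray_curtis_kernel(M)
        assert np.linalg.eigvalsh(K).min() >= -1e-10


class TestKRV:
    def make_kernels(self, rng, n=12):
        A = rng.normal(size=(n, 5))
        B = rng.normal(size=(n, 4))
        return A @ A.T, B @ B.T

    def test_self_kernel_statistic_one(self, rng):
        K, _ = self.make_kernels(rng)
        res = krv_test(K, K, n_perm=99, seed=1)
        assert res.statistic == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_in_kernels(self, rng):
        K, L = self.make_kernels(rng)
        a = krv_test(K, L, n_perm=99, seed=3).statistic
        b = krv_test(L, K, n_perm=99, seed=3).statistic
        assert a == pytest.approx(b, abs=1e-12)

    def test_relabeling_invariance(self, rng):
        K, L = self.make_kernels(rng)
        perm = rng.permutation(K.shape[0])
        a = krv_test(K, L, n_perm=99, seed=0).statistic
        b = krv_test(K[np.ix_(perm, perm)], L[np.ix_(perm, perm)], n_perm=99, seed=0).statistic
        assert a == pytest.approx(b, abs=1e-10)

    def test_exhaustive_matches_brute_force(self, rng):
        """Full-enumeration p at n=5 equals an independent oracle."""
        K, L = self.make_kernels(rng, n=5)
        res = krv_exhaustive(K, L)
        # independent oracle: explicit double-centering and loops
        n = 5
        H = np.eye(n) - 1 / n
        Kc, Lc = H @ K @ H, H @ L @ H

        def stat(Lp):
            return np.sum(Kc * Lp) / np.sqrt(np.sum(Kc * Kc) * np.sum(Lp * Lp))

        obs = stat(Lc)
        hits = sum(
            stat(Lc[np.ix_(perm, perm)]) >= obs - 1e-12
            for perm in itertools.permutations(range(n))
        )
        assert res.p_value == pytest.approx(hits / 120, abs=1e-15)

    def test_permutation_p_range_and_seed(self, rng):
        K, L = self.make_kernels(rng)
        r1 = krv_test(K, L, n_perm=199, seed=9)
        r2 = krv_test(K, L, n_perm=199, seed=9)
        assert r1.p_value == r2.p_value
        assert 1 / 200 <= r1.p_value <= 1.0

    def test_min_permutations(self, rng):
        K, L = self.make_kernels(rng)
        with pytest.raises(ValueError):
            krv_test(K, L, n_perm=10)


class TestRunTaxonwise:
    def test_shape_and_range(self, small_counts, small_meta):
        P = run_taxonwise(small_counts, small_meta, ["none", "tss", "clr"], test="linear")
        assert P.values.shape == (3, 3)
        assert np.all((P.values >= 0) & (P.values <= 1))
        assert P.method_labels == ["none", "tss", "clr"]

    def test_duplicate_taxa_identical_columns(self, rng):
        from omninorm.data_model import CountMatrix

        base = rng.integers(0, 30, size=(20, 1))
        values = np.column_stack([base, base, rng.integers(0, 30, size=(20, 3))])
        X = CountMatrix(values, [f"s{i}" for i in range(20)], ["a", "a2", "b", "c", "d"])
        meta = SampleMetadata(
            X.sample_ids, rng.binomial(1, 0.5, 20).astype(float)
        )
        P = run_taxonwise(X, meta, ["none", "tss"], test="linear")
        np.testing.assert_allclose(P.values[:, 0], P.values[:, 1], atol=1e-12)

    def test_none_matches_direct_call(self, small_counts, small_meta):
        P = run_taxonwise(small_counts, small_meta, ["none"], test="linear")
        for k in range(small_counts.n_taxa):
            direct = linear_test(
                small_counts.values[:, k].astype(float), small_meta.outcome
            )
            assert P.values[0, k] == pytest.approx(direct.p_value, abs=1e-14)

    def test_unaligned_inputs_rejected(self, small_counts):
        meta = SampleMetadata(["x1", "x2"], np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            run_taxonwise(small_counts, meta, ["none"], test="linear")

    def test_unknown_test(self, small_counts, small_meta):
        with pytest.raises(ValueError):
            run_taxonwise(small_counts, small_meta, ["none"], test="deseq")


def test_genotype_kernel_psd(rng):
    G = rng.binomial(2, 0.3, size=(30, 10)).astype(float)
    L = linear_genotype_kernel(G)
    assert np.allclose(L, L.T)
    assert np.linalg.eigvalsh(L).min() >= -1e-10
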