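import numpy as np
import pytest

from spikeprecision import (SpikeMatrix, MotorScores, standard_score, ksg_mi,
                            mixed_mi_count, timing_mi_decomposed,
                            knn_distance_diagnostics, gaussian_pair,
                            GaussianPairSpec)
from spikeprecision.synthetic import gaussian_pair_true_mi
import spikeprecision.ksg as ksg_mod


def bivariate(rho, n, seed):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    y = rho * z + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
    return z, y


class TestStandardScore:
    def test_zscore(self):
        out = standard_score(np.array([1.0, 2.0, 3.0]))
        assert abs(out.mean()) < 1e-12
        assert abs(out.std(ddof=1) - 1) < 1e-12

    def test_constant_column_zeroed_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = standard_score(np.array([5.0, 5.0, 5.0]))
        assert np.all(out == 0)

    def test_affine_invariance(self):
        x = np.random.default_rng(0).normal(size=(50, 2))
        np.testing.assert_allclose(standard_score(2 * x + 3),
                                   standard_score(x), atol=1e-12)


class TestKsgMi:
    def test_independent_near_zero(self):
        rng = np.random.default_rng(1)
        est = ksg_mi(rng.standard_normal((2500, 1)),
                     rng.standard_normal((2500, 2)), k=4)
        assert abs(est.value) < 0.05

    @pytest.mark.parametrize("rho,tol", [(0.9, 0.1), (0.5, 0.05)])
    def test_bivariate_gaussian_closed_form(self, rho, tol):
        x, y = bivariate(rho, 2500, seed=7)
        expected = -0.5 * np.log2(1 - rho ** 2)
        assert abs(ksg_mi(x, y, 4).value - expected) < tol

    def test_symmetry_exact(self):
        x, y = bivariate(0.7, 500, seed=3)
        assert ksg_mi(x, y, 4).value == ksg_mi(y, x, 4).value

    def test_scale_invariance_exact(self):
        # power-of-two scaling is exact in floating point, so the
        # standard-scored coordinates (and hence the estimate) are identical
        x, y = bivariate(0.7, 400, seed=4)
        assert ksg_mi(4.0 * x, y, 4).value == ksg_mi(x, y, 4).value

    def test_affine_invariance_close(self):
        x, y = bivariate(0.7, 400, seed=4)
        a = ksg_mi(1.7 * x + 0.3, 0.9 * y - 2.0, 4).value
        b = ksg_mi(x, y, 4).value
        assert abs(a - b) < 1e-6

    def test_k_robustness(self):
        sp, mo = gaussian_pair(GaussianPairSpec(n=2000, rho=0.7, seed=9))
        vals = [ksg_mi(sp.times, mo.scores, k).value for k in range(2, 8)]
        assert max(vals) - min(vals) < 0.1

    def test_sample_size_error(self):
        with pytest.raises(ValueError, match="n > k"):
            ksg_mi(np.arange(4.0), np.arange(4.0), k=4)

    def test_zero_dim_error(self):
        with pytest.raises(ValueError, match="column"):
            ksg_mi(np.empty((10, 0)), np.arange(10.0), k=2)

    def test_brute_force_matches_tree(self, monkeypatch):
        x, y = bivariate(0.6, 150, seed=5)
        brute = ksg_mi(x, y, 4).value  # n=150 takes the brute path
        monkeypatch.setattr(ksg_mod, "BRUTE_FORCE_MAX_N", 0)
        tree = ksg_mi(x, y, 4).value
        assert brute == tree

    def test_ties_handled_after_rounding(self):
        # heavy ties (rounded data) must not crash or return +-inf
        x, y = bivariate(0.8, 1000, seed=6)
        xr = np.round(x)  # ~7 distinct values
        est = ksg_mi(xr, y, 4)
        assert np.isfinite(est.value)


class TestMixedMiCount:
    def test_independent_near_zero(self):
        rng = np.random.default_rng(2)
        c = rng.integers(0, 3, 2500)
        est = mixed_mi_count(c, rng.standard_normal((2500, 2)), k=4)
        assert abs(est.value) < 0.05

    def test_deterministic_binary_label_one_bit(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal((2500, 1))
        c = (y[:, 0] > 0).astype(int)
        est = mixed_mi_count(c, y, k=4)
        assert abs(est.value - 1.0) < 0.05

    def test_single_class_exact_zero(self):
        assert mixed_mi_count(np.zeros(100, int),
                              np.random.default_rng(0).normal(size=(100, 1)),
                              4).value == 0.0

    def test_bounded_by_label_entropy(self):
        rng = np.random.default_rng(4)
        y = rng.standard_normal((800, 1))
        c = (y[:, 0] > 0.5).astype(int)
        p = c.mean()
        h = -(p * np.log2(p) + (1 - p) * np.log2(1 - p))
        assert mixed_mi_count(c, y, 4).value <= h + 1e-12

    def test_matches_sklearn_oracle(self):
        # independent mixed-MI implementation as a cross-check
        from sklearn.feature_selection import mutual_info_classif
        rng = np.random.default_rng(5)
        y = rng.standard_normal((2000, 1))
        c = (y[:, 0] + 0.5 * rng.standard_normal(2000) > 0).astype(int)
        ours = mixed_mi_count(c, y, k=4).value
        theirs = mutual_info_classif(y, c, n_neighbors=4,
                                     random_state=0)[0] / np.log(2)
        assert abs(ours - theirs) < 0.05

    def test_count_encoded_as_continuous_consistency(self):
        # the mixed estimator agrees with plain KSG when the label is
        # embedded as a (tie-broken) continuous coordinate
        rng = np.random.default_rng(6)
        y = rng.standard_normal((2500, 2))
        c = (y[:, 0] + 0.8 * rng.standard_normal(2500) > 0).astype(int)
        mixed = mixed_mi_count(c, y, k=4).value
        cont = ksg_mi(c + 1e-6 * rng.standard_normal(2500), y, k=4).value
        assert abs(mixed - cont) < 0.05


class TestTimingDecomposition:
    def test_independent_timing_terms_near_zero(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(1, 4, 1500)
        times = np.full((1500, 3), np.nan)
        for i, c in enumerate(counts):
            times[i, :c] = np.sort(rng.uniform(0, 40, c))
        sm = SpikeMatrix.from_times(times)
        mo = MotorScores.from_array(rng.standard_normal((1500, 2)))
        est = timing_mi_decomposed(sm, mo, 4)
        for cnt, (term, _w) in est.per_count_terms.items():
            if np.isfinite(term):
                assert abs(term) < 0.1

    def test_single_count_reduces_to_ksg(self, gaussian_dataset):
        sp, mo = gaussian_dataset
        est = timing_mi_decomposed(sp, mo, 4)
        direct = ksg_mi(sp.times, mo.scores, 4)
        # count term is exactly 0 (single class); totals agree
        assert est.value == pytest.approx(direct.value, abs=1e-12)

    def test_per_class_terms_match_direct_ksg(self, moth_dataset):
        sp, mo = moth_dataset
        est = timing_mi_decomposed(sp, mo, 4)
        for cnt, (term, w) in est.per_count_terms.items():
            if not np.isfinite(term):
                continue
            idx = np.flatnonzero(sp.counts == cnt)
            direct = ksg_mi(sp.times[idx, :cnt], mo.scores[idx], 4).value
            assert term == pytest.approx(direct, abs=1e-12)
            assert w == pytest.approx(idx.size / sp.n_trials)

    def test_weights_sum_to_one(self, moth_dataset):
        sp, mo = moth_dataset
        est = timing_mi_decomposed(sp, mo, 4)
        assert sum(w for _, w in est.per_count_terms.values()) == pytest.approx(1.0)


class TestKnnDiagnostics:
    def test_zero_noise_delta_exactly_zero(self, moth_dataset):
        sp, mo = moth_dataset
        diag = knn_distance_diagnostics(sp, mo, [0.0, 1.0, 8.0], k=4,
                                        rng=np.random.default_rng(0))
        for cnt, delta in diag.delta_ms.items():
            assert delta[0] == 0.0
            assert np.all(diag.median[cnt] > 0)

    def test_medians_grow_with_noise(self, moth_dataset):
        sp, mo = moth_dataset
        diag = knn_distance_diagnostics(sp, mo, [0.0, 4.0, 32.0], k=4,
                                        rng=np.random.default_rng(1))
        # largest class: median distance should grow with heavy corruption
        biggest = max(diag.median, key=lambda c: np.sum(sp.counts == c))
        med = diag.median[biggest]
        assert med[2] > med[0]
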