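import numpy as np
import pandas as pd
import pytest

from methylvar import (compare_sets_variability, cv2_per_gene,
                       filter_low_expression, loess_residual_variability,
                       loess_smooth, normalize_counts, simple_de, size_factors)


def _counts(arr, samples=None):
    arr = np.asarray(arr)
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                        columns=samples)


class TestLowExpressionFilter:
    def test_all_zero_gene_dropped(self):
        c = _counts(np.vstack([np.zeros(10), np.full(10, 20)]))
        assert filter_low_expression(c).index.tolist() == ["g1"]

    def test_boundary_arithmetic_46_samples(self):
        # 42/46 = 0.913 > 0.9 -> dropped; 41/46 = 0.891 -> kept
        row_drop = np.r_[np.zeros(42), np.full(4, 50)]
        row_keep = np.r_[np.zeros(41), np.full(5, 50)]
        c = _counts(np.vstack([row_drop, row_keep]))
        assert filter_low_expression(c).index.tolist() == ["g1"]


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([10, 100, 1000, 7])
        c = _counts(np.tile(col[:, None], 4))
        np.testing.assert_allclose(size_factors(c), 1.0)

    def test_doubled_column_ratio(self):
        rng = np.random.default_rng(0)
        col = rng.integers(5, 500, 100)
        c = _counts(np.column_stack([col, 2 * col]))
        f = size_factors(c)
        assert f.iloc[1] / f.iloc[0] == pytest.approx(2.0)

    def test_matches_median_of_ratios_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 400, size=(200, 8))
        x[:50] += 1  # guarantee some all-positive genes
        c = _counts(x)
        f = size_factors(c).to_numpy()
        allpos = (x > 0).all(axis=1)
        logs = np.log(x[allpos].astype(float))
        ratios = logs - logs.mean(axis=1, keepdims=True)
        oracle = np.exp(np.median(ratios, axis=0))
        oracle /= np.exp(np.mean(np.log(oracle)))
        np.testing.assert_allclose(f, oracle, atol=1e-10)

    def test_no_universal_gene_rejected(self):
        c = _counts([[0, 5], [5, 0]])
        with pytest.raises(ValueError):
            size_factors(c)


class TestCV2:
    def test_constant_gene_has_zero_cv2(self):
        tab = cv2_per_gene(_counts([[10, 10, 10]]))
        assert tab["cv2"].iloc[0] == 0

    def test_simple_arithmetic(self):
        tab = cv2_per_gene(_counts([[1, 2, 3]]))
        assert tab["mu"].iloc[0] == pytest.approx(2)
        assert tab["cv2"].iloc[0] == pytest.approx(0.25)

    def test_nb_moment_identity(self):
        # NB: CV2 ~ dispersion + 1/mu
        rng = np.random.default_rng(2)
        mu, phi, n = 100.0, 0.1, 1000
        size = 1 / phi
        x = rng.negative_binomial(size, size / (size + mu), n)
        tab = cv2_per_gene(_counts(x[None, :]))
        assert tab["cv2"].iloc[0] == pytest.approx(phi + 1 / mu, abs=0.02)

    def test_requires_three_samples(self):
        with pytest.raises(ValueError):
            cv2_per_gene(_counts([[1, 2]]))


class TestLoessResiduals:
    def _smooth_table(self, n=300, seed=3):
        rng = np.random.default_rng(seed)
        mu = np.exp(rng.uniform(1, 8, n))
        cv2 = 0.1 + 5.0 / mu          # smooth NB-like mean-CV2 trend
        return pd.DataFrame({"mu": mu, "cv2": cv2},
                            index=[f"g{i}" for i in range(n)])

    def test_on_curve_residuals_are_tiny(self):
        tab = loess_residual_variability(self._smooth_table())
        assert tab["residual"].abs().max() < 0.05

    def test_doubled_cv2_gene_has_log2_residual(self):
        tab = self._smooth_table()
        tab.loc["g0", "cv2"] *= 2
        out = loess_residual_variability(tab)
        assert out.loc["g0", "residual"] == pytest.approx(np.log(2), abs=0.1)

    def test_residual_ordering_invariant_to_count_scaling(self):
        rng = np.random.default_rng(4)
        counts = _counts(rng.negative_binomial(5, 0.05, size=(200, 12)) + 1)
        t1 = cv2_per_gene(normalize_counts(counts))
        t2 = cv2_per_gene(normalize_counts(counts * 7))
        r1 = loess_residual_variability(t1)["residual"]
        r2 = loess_residual_variability(t2)["residual"]
        assert (r1.rank() == r2.rank()).all()

    def test_planted_high_dispersion_detected(self):
        rng = np.random.default_rng(5)
        n, n_hi = 2000, 200
        mu = np.exp(rng.uniform(2, 7, n))
        phi = np.full(n, 0.1)
        phi[:n_hi] = 0.2
        size = 1 / phi
        counts = rng.negative_binomial(size[:, None],
                                       (size / (size + mu))[:, None],
                                       size=(n, 30))
        tab = cv2_per_gene(_counts(counts))
        out = loess_residual_variability(tab)
        hi = out["residual"].iloc[:n_hi]
        rest = out["residual"].iloc[n_hi:]
        from scipy.stats import ranksums
        assert ranksums(hi, rest).pvalue < 0.01
        assert hi.median() > rest.median()

    def test_span_validated(self):
        with pytest.raises(ValueError):
            loess_smooth([1, 2, 3], [1, 2, 3], span=0)


class TestCompareSets:
    def _table(self, residuals, population="FC"):
        return pd.DataFrame({
            "residual": residuals,
            "population": population,
        }, index=[f"g{i}" for i in range(len(residuals))])

    def test_clear_separation(self):
        tab = self._table(np.r_[np.full(10, -1.0), np.full(10, 1.0)])
        a = {f"g{i}" for i in range(10)}
        b = {f"g{i}" for i in range(10, 20)}
        res = compare_sets_variability(tab, a, b)
        assert res["p"] < 0.01 and res["direction"] == "A lower"

    def test_paired_degenerate_zero_differences(self):
        fc = self._table(np.ones(6), "FC")
        nc = self._table(np.ones(6), "NC")
        tab = pd.concat([fc, nc])
        res = compare_sets_variability(tab, set(fc.index), paired=True)
        assert res["p"] == 1.0

    def test_paired_detects_planted_direction(self):
        rng = np.random.default_rng(6)
        idx = [f"g{i}" for i in range(200)]
        fc_res = rng.normal(0, 0.2, 200)
        fc_res[:50] -= 0.5     # planted FC-only reduction
        fc = pd.DataFrame({"residual": fc_res, "population": "FC"}, index=idx)
        nc = pd.DataFrame({"residual": rng.normal(0, 0.2, 200),
                           "population": "NC"}, index=idx)
        tab = pd.concat([fc, nc])
        res = compare_sets_variability(tab, set(idx[:50]), set(idx[50:]),
                                       paired=True)
        assert res["p"] < 0.01 and res["direction"] == "A lower"

    def test_power_for_moderate_shift(self):
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(20):
            a_vals = rng.normal(-0.3, 0.5, 200)
            b_vals = rng.normal(0.0, 0.5, 400)
            tab = pd.DataFrame({
                "residual": np.r_[a_vals, b_vals], "population": "FC",
            }, index=[f"g{i}" for i in range(600)])
            res = compare_sets_variability(tab, {f"g{i}" for i in range(200)},
                                           {f"g{i}" for i in range(200, 600)})
            rejections += res["p"] < 0.01
        assert rejections >= 18

    def test_small_sets_rejected(self):
        tab = self._table([0.0, 1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            compare_sets_variability(tab, {"g0"}, {"g1", "g2", "g3"})


class TestSimpleDE:
    def test_identical_groups_are_null(self):
        rng = np.random.default_rng(8)
        c = _counts(rng.poisson(100, size=(100, 12)))
        res = simple_de(c, [0] * 6 + [1] * 6)
        assert abs(res["log2fc"]).median() < 0.2
        assert not res["is_deg"].any()

    def test_planted_twofold_shift_estimated(self):
        # shift a 10% subset so median-of-ratios normalization is unaffected
        rng = np.random.default_rng(9)
        mu = np.full(200, 200.0)
        mu2 = mu.copy()
        mu2[:20] *= 2
        c1 = rng.poisson(mu[:, None], (200, 30))
        c2 = rng.poisson(mu2[:, None], (200, 30))
        res = simple_de(_counts(np.hstack([c1, c2])), [0] * 30 + [1] * 30)
        assert res["log2fc"].iloc[:20].mean() == pytest.approx(1.0, abs=0.1)
        assert (res["q"].iloc[:20] < 1e-6).all()

    def test_lfc_threshold_gates_deg_call(self):
        rng = np.random.default_rng(10)
        mu = np.full(100, 500.0)
        mu2 = mu.copy()
        mu2[:15] *= 1.6                  # ~0.68 log2FC subset
        c1 = rng.poisson(mu[:, None], (100, 20))
        c2 = rng.poisson(mu2[:, None], (100, 20))
        res = simple_de(_counts(np.hstack([c1, c2])), [0] * 20 + [1] * 20)
        sig = res.iloc[:15][res.iloc[:15]["q"] < 0.001]
        assert len(sig) > 0
        assert not sig["is_deg"].any()   # significant but below 2-fold
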