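import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats
from sklearn.mixture import GaussianMixture

from methylvar import (binarize_cpgs_kmeans, call_methylated_genes_intercept,
                       call_methylated_genes_mixture, fit_methylation_mixture,
                       fit_random_intercept_model, methylated_set,
                       population_specific_sets)


class TestMixture:
    def test_recovers_well_separated_components(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-4, 0.5, 500), rng.normal(1, 0.5, 500)])
        fit = fit_methylation_mixture(special.expit(x), use_logit=True, eps=0)
        assert fit.means == pytest.approx([-4, 1], abs=0.15)

    def test_responsibilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        vals = rng.beta(2, 5, 100)
        fit = fit_methylation_mixture(vals)
        resp = fit.responsibilities(vals)
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-12)

    def test_identical_values_trigger_degenerate_fallback(self):
        fit = fit_methylation_mixture(np.full(30, 0.5))
        assert fit.degenerate
        # nothing exceeds the midpoint threshold -> nothing methylated
        assert (fit.posterior_methylated(np.full(5, 0.5)) == 0).all()

    def test_requires_twenty_values(self):
        with pytest.raises(ValueError):
            fit_methylation_mixture(np.linspace(0, 1, 10))


class TestConsistencyRule:
    def _calls(self, posteriors_per_gene):
        """Build a W table whose posteriors are forced via a fixed fit."""
        rng = np.random.default_rng(2)
        w_meth, w_unmeth = 0.9, 0.01
        n = 7
        rows = {}
        for g, k in posteriors_per_gene.items():
            rows[g] = [w_meth] * k + [w_unmeth] * (n - k)
        background = {f"bg{i}": [w_meth] * n if i % 2 else [w_unmeth] * n
                      for i in range(30)}
        rows.update(background)
        W = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=[f"s{i}" for i in range(n)])
        return call_methylated_genes_mixture(W, consistency=0.85)

    def test_85_percent_boundary(self):
        calls = self._calls({"six_of_seven": 6, "five_of_seven": 5,
                             "zero": 0})
        assert calls.loc["six_of_seven", "call"] == "methylated"   # 6/7 = 0.857
        assert calls.loc["five_of_seven", "call"] == "unmethylated"
        assert calls.loc["zero", "call"] == "unmethylated"


class TestKmeansBinarization:
    def test_separated_values(self):
        states = binarize_cpgs_kmeans(np.array([0.00, 0.01, 0.85, 0.90]))
        assert states.tolist() == [0, 0, 1, 1]

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.beta(1, 99, 50), rng.beta(9, 1, 50)])
        perm = rng.permutation(len(x))
        a = binarize_cpgs_kmeans(x)
        b = binarize_cpgs_kmeans(x[perm])
        assert (a[perm] == b).all()

    def test_identical_values_all_zero_with_warning(self):
        assert binarize_cpgs_kmeans(np.full(10, 0.3)).sum() == 0

    def test_agrees_with_midpoint_threshold_oracle(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.beta(1, 99, 2000), rng.beta(9, 1, 2000)])
        states = binarize_cpgs_kmeans(x)
        midpoint = (1 / 100 + 9 / 10) / 2  # between the component means
        oracle = (x > midpoint).astype(int)
        assert (states == oracle).mean() >= 0.99


class TestRandomIntercept:
    def test_sign_of_extreme_genes(self):
        rng = np.random.default_rng(5)
        genes, states = [], []
        for g in range(30):
            p = 0.95 if g == 0 else 0.05
            y = rng.binomial(1, p, 40)
            states.extend(y)
            genes.extend([f"g{g:02d}"] * 40)
        fit = fit_random_intercept_model(np.array(states), np.array(genes))
        assert fit.u["g00"] > 1.0
        assert fit.u["g10"] < 0.5

    def test_gene_at_global_mean_shrinks_to_zero(self):
        rng = np.random.default_rng(6)
        genes, states = [], []
        for g in range(40):
            p = {0: 0.9, 1: 0.1}.get(g % 2, 0.5)
            y = rng.binomial(1, p, 30)
            states.extend(y)
            genes.extend([f"g{g:02d}"] * 30)
        # one gene exactly at the global mean state frequency
        global_mean = np.mean(states)
        k = int(round(global_mean * 30))
        states.extend([1] * k + [0] * (30 - k))
        genes.extend(["gmid"] * 30)
        fit = fit_random_intercept_model(np.array(states), np.array(genes))
        assert abs(fit.u["gmid"]) < 0.5

    def test_rank_correlation_with_simulated_truth(self):
        rng = np.random.default_rng(7)
        u_true = rng.normal(0, 1.5, 50)
        genes, states = [], []
        # enough observations per gene that the conditional modes are
        # informative relative to the binomial sampling noise
        for g in range(50):
            n = int(rng.integers(80, 150))
            y = rng.binomial(1, special.expit(-1.0 + u_true[g]), n)
            states.extend(y)
            genes.extend([f"g{g:02d}"] * n)
        fit = fit_random_intercept_model(np.array(states), np.array(genes))
        rho = stats.spearmanr(fit.u.to_numpy(), u_true).statistic
        assert rho > 0.95

    def test_matches_lme4_conditional_modes(self, tmp_path):
        """Independent GLMM oracle: lme4::glmer on the same observations."""
        rng = np.random.default_rng(8)
        u_true = rng.normal(0, 1.2, 40)
        rows = []
        for g in range(40):
            y = rng.binomial(1, special.expit(-0.5 + u_true[g]), 25)
            rows += [(f"g{g:02d}", int(v)) for v in y]
        df = pd.DataFrame(rows, columns=["gene", "y"])
        df.to_csv(tmp_path / "obs.csv", index=False)
        script = (
            "suppressMessages(library(lme4));"
            f"d <- read.csv('{tmp_path}/obs.csv');"
            "m <- glmer(y ~ 1 + (1|gene), data=d, family=binomial);"
            "r <- ranef(m)$gene;"
            f"write.csv(data.frame(gene=rownames(r), u=r[,1]),"
            f" '{tmp_path}/u.csv', row.names=FALSE)"
        )
        try:
            subprocess.run(["Rscript", "-e", script], check=True,
                           capture_output=True, timeout=300)
        except (FileNotFoundError, subprocess.CalledProcessError) as exc:
            pytest.fail(f"lme4 oracle failed to run: {exc}")
        fit = fit_random_intercept_model(df["y"].to_numpy(),
                                         df["gene"].to_numpy())
        oracle = pd.read_csv(tmp_path / "u.csv").set_index("gene")["u"]
        joined = fit.u.to_frame().join(oracle.rename("u_r")).dropna()
        assert np.corrcoef(joined["u"], joined["u_r"])[0, 1] > 0.99

    def test_requires_two_genes(self):
        with pytest.raises(ValueError):
            fit_random_intercept_model([0, 1, 1], ["g", "g", "g"])

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            fit_random_intercept_model([0, 2], ["a", "b"])


class TestInterceptCalls:
    def test_strict_threshold_boundary(self):
        u = pd.Series({"hi": 2.6, "edge": 2.5, "lo": -3.0})
        calls = call_methylated_genes_intercept(u, threshold=2.5)
        assert methylated_set(calls) == {"hi"}

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            call_methylated_genes_intercept(pd.Series({"a": np.nan}))


class TestPopulationSets:
    def test_partition_example(self):
        sets = population_specific_sets({"a", "b"}, {"b", "c"},
                                        {"a", "b", "c", "d"})
        assert sets == {"shared": {"b"}, "FC_only": {"a"},
                        "NC_only": {"c"}, "neither": {"d"}}

    def test_equal_calls_give_empty_specific_sets(self):
        sets = population_specific_sets({"a"}, {"a"}, {"a", "b"})
        assert sets["FC_only"] == set() and sets["NC_only"] == set()

    def test_sizes_conserve_universe(self):
        rng = np.random.default_rng(9)
        universe = {f"g{i}" for i in range(100)}
        fc = set(rng.choice(sorted(universe), 30, replace=False))
        nc = set(rng.choice(sorted(universe), 40, replace=False))
        sets = population_specific_sets(fc, nc, universe)
        assert sum(len(s) for s in sets.values()) == 100

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError):
            population_specific_sets({"x"}, set(), {"a"})


def test_intercept_distribution_is_bimodal_on_planted_data(small_quant,
                                                           small_dataset):
    """With clearly separated planted states, the u_g distribution has two
    modes (2-component Gaussian mixture beats 1 component by BIC)."""
    from methylvar.methylation_status import intercept_calls_per_population

    filt, mapping, _ = small_quant
    out = intercept_calls_per_population(filt, mapping, small_dataset.design)
    u = out["_fits"]["FC"].u.to_numpy()[:, None]
    bic1 = GaussianMixture(1, random_state=0).fit(u).bic(u)
    bic2 = GaussianMixture(2, random_state=0).fit(u).bic(u)
    assert bic2 < bic1
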