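"""TPM10K scaling, species medians, BM covariance and the PGLS screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from convergeflow import io as cio
from convergeflow.phylo import (
    PglsError,
    bm_covariance,
    pgls_fit,
    pgls_screen,
    species_medians,
    substitute_missing_pi,
    tpm10k,
)
from convergeflow.simulate import simulate_expression_on_tree


class TestTpm10k:
    @pytest.mark.parametrize("tpm,n_ref,expected", [
        (100.0, 500, 5.0),
        (0.0, 13370, 0.0),
        (10.0, 10_000, 10.0),
    ])
    def test_direct_arithmetic(self, tpm, n_ref, expected):
        assert tpm10k(tpm, n_ref) == pytest.approx(expected)

    def test_linearity(self, rng):
        a, b = rng.uniform(0, 100, 2)
        assert tpm10k(a + b, 777) == pytest.approx(tpm10k(a, 777) + tpm10k(b, 777))

    def test_rejects_bad_reference(self):
        with pytest.raises(ValueError):
            tpm10k(1.0, 0)


class TestSpeciesMedians:
    def test_median_per_species(self):
        mat = pd.DataFrame({"a1": [1.0], "a2": [3.0], "a3": [5.0], "b1": [7.0]},
                           index=["g"])
        med = species_medians(mat, {"a1": "A", "a2": "A", "a3": "A", "b1": "B"},
                              require_all=False)
        assert med.loc["g", "A"] == 3.0

    def test_require_all_drops_unexpressed(self):
        mat = pd.DataFrame({"a1": [1.0, 1.0], "b1": [0.0, 2.0]}, index=["g1", "g2"])
        med = species_medians(mat, {"a1": "A", "b1": "B"}, require_all=True)
        assert list(med.index) == ["g2"]

    def test_planted_expressed_in_all_count(self):
        """Generator truth: exactly the expressed-in-all genes survive."""
        tpm, smap, n_ref, truth = simulate_expression_on_tree(
            n_genes=5000, n_unexpressed=4832, seed=5)
        med = species_medians(tpm, smap, require_all=True)
        assert len(med) == 168
        assert set(med.index) == set(truth.loc[truth["expressed_in_all"], "gene"])

    def test_species_without_samples_is_error(self):
        mat = pd.DataFrame({"a1": [1.0]}, index=["g"])
        with pytest.raises(ValueError):
            species_medians(mat, {"a1": "A", "ghost": "B"}, require_all=False)


class TestBmCovariance:
    def test_three_taxon_path_sums(self):
        tree = cio.read_newick("((A:1,B:1):1,C:2);")
        cov = bm_covariance(tree, ["A", "B", "C"])
        assert cov == pytest.approx(np.array([[2, 1, 0], [1, 2, 0], [0, 0, 2]]))

    def test_star_tree_is_identity(self):
        tree = cio.read_newick("(A:1,B:1,C:1,D:1);")
        cov = bm_covariance(tree, list("ABCD"))
        assert cov == pytest.approx(np.eye(4))

    def test_default_tree_psd_and_bounded(self, tree):
        taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
        cov = bm_covariance(tree, taxa)
        assert cov == pytest.approx(cov.T)
        assert np.linalg.eigvalsh(cov).min() >= -1e-10
        for i in range(len(taxa)):
            for j in range(len(taxa)):
                if i != j:
                    assert cov[i, j] <= min(cov[i, i], cov[j, j]) + 1e-12

    def test_unknown_taxon(self, tree):
        with pytest.raises(ValueError):
            bm_covariance(tree, ["Co_hominivorax", "not_a_tip"])


class TestPglsFit:
    def test_identity_covariance_perfect_line(self):
        fit = pgls_fit([1, 3, 5], [0, 1, 2], np.eye(3))
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)
        assert fit.slope == pytest.approx(2.0, abs=1e-10)

    def test_identity_equals_ols_oracle(self, rng):
        """GLS with identity covariance is OLS: slope, intercept, p, R^2."""
        for _ in range(20):
            n = int(rng.integers(5, 12))
            x = rng.normal(size=n)
            y = 1.5 - 2.0 * x + rng.normal(size=n)
            fit = pgls_fit(y, x, np.eye(n))
            ols = stats.linregress(x, y)
            assert fit.slope == pytest.approx(ols.slope, abs=1e-8)
            assert fit.intercept == pytest.approx(ols.intercept, abs=1e-8)
            assert fit.pvalue == pytest.approx(ols.pvalue, abs=1e-8)
            adj = 1 - (1 - ols.rvalue**2) * (n - 1) / (n - 2)
            assert fit.adj_r2 == pytest.approx(adj, abs=1e-8)

    def test_scaled_star_tree_matches_identity(self):
        tree = cio.read_newick("(A:2.5,B:2.5,C:2.5,D:2.5,E:2.5);")
        cov = bm_covariance(tree, list("ABCDE"))
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([0.3, 1.1, 2.4, 2.9, 4.2])
        f1 = pgls_fit(y, x, cov)
        f2 = pgls_fit(y, x, np.eye(5))
        assert f1.slope == pytest.approx(f2.slope, abs=1e-10)
        assert f1.pvalue == pytest.approx(f2.pvalue, abs=1e-10)

    def test_slope_recovery_unbiased_on_bm_noise(self, tree, logit_pis):
        """Mean slope estimate over BM replicates sits on the true value."""
        taxa = sorted(logit_pis)
        cov = bm_covariance(tree, taxa)
        x = np.array([logit_pis[t] for t in taxa])
        chol = np.linalg.cholesky(cov)
        rng = np.random.default_rng(42)
        slopes = []
        for _ in range(500):
            y = 5.0 - 3.0 * x + chol @ rng.normal(size=len(taxa))
            slopes.append(pgls_fit(y, x, cov).slope)
        slopes = np.array(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        # GLS is exactly unbiased, so deviations are pure Monte-Carlo noise;
        # a 3-sigma band keeps the check deterministic-test reliable
        assert abs(slopes.mean() + 3.0) < 3 * se

    def test_constant_predictor_error(self):
        with pytest.raises(PglsError):
            pgls_fit([1, 2, 3], [1, 1, 1], np.eye(3))


class TestPglsScreen:
    def test_null_genes_not_flagged(self, tree, logit_pis, rng):
        taxa = sorted(logit_pis)
        cov = bm_covariance(tree, taxa)
        chol = np.linalg.cholesky(cov)
        med = pd.DataFrame(
            {t: 50 + (chol @ rng.normal(size=(len(taxa), 300)))[i] for i, t in enumerate(taxa)},
            index=[f"g{i}" for i in range(300)],
        )
        res = pgls_screen(med, logit_pis, tree)
        assert res["significant"].sum() <= 3

    def test_recovers_planted_linked_genes(self, tree):
        tpm, smap, n_ref, truth = simulate_expression_on_tree(
            n_genes=1000, n_unexpressed=0, n_linked=12, seed=3)
        from convergeflow.phylo import apply_tpm10k

        mat = apply_tpm10k(tpm, smap, n_ref)
        med = species_medians(mat, smap, require_all=True)
        from convergeflow.simulate import default_logit_pis

        res = pgls_screen(med, default_logit_pis(), tree)
        found = set(res.loc[res["significant"], "gene"])
        planted = set(truth.loc[truth["linked"], "gene"])
        assert planted <= found
        assert len(found - planted) <= 3  # FDR-level leakage only

    def test_constant_gene_reported_na(self, tree, logit_pis):
        taxa = sorted(logit_pis)
        med = pd.DataFrame([[5.0] * 7, list(range(7))], index=["flat", "vary"],
                           columns=taxa, dtype=float)
        res = pgls_screen(med, logit_pis, tree).set_index("gene")
        assert np.isnan(res.loc["flat", "pvalue"])
        assert not np.isnan(res.loc["vary", "pvalue"])

    def test_needs_three_species(self, tree):
        med = pd.DataFrame({"Co_hominivorax": [1.0], "Co_macellaria": [2.0]}, index=["g"])
        with pytest.raises(PglsError):
            pgls_screen(med, {"Co_hominivorax": 0.69, "Co_macellaria": -0.6}, tree)


def test_substitute_missing_pi_rules():
    base = {"a": 0.5, "b": -0.5}
    out = substitute_missing_pi(base, {"c": "a"})
    assert out["c"] == 0.5
    # no-op when the target is already measured
    out = substitute_missing_pi(base, {"b": "a"})
    assert out["b"] == -0.5
    with pytest.raises(KeyError):
        substitute_missing_pi(base, {"c": "ghost"})
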