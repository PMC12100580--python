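"""Shared-DEG classification and the independence-model convergence test."""

import numpy as np
import pandas as pd
import pytest

from convergeflow.de_convergence import (
    TieError,
    bh_fdr,
    call_de_simple,
    classify_shared_degs,
    convergence_test,
    expected_overlap,
    run_convergence_analysis,
)
from convergeflow.simulate import simulate_de_counts


def make_table(sig_up, sig_down, n_total, prefix="OG", ns_padj=0.5):
    """DEG table with the first sig_up genes up, next sig_down down, rest ns."""
    genes = [f"{prefix}{i:05d}" for i in range(n_total)]
    lfc = np.where(np.arange(n_total) < sig_up, 2.0,
                   np.where(np.arange(n_total) < sig_up + sig_down, -2.0, 0.5))
    padj = np.where(np.arange(n_total) < sig_up + sig_down, 1e-4, ns_padj)
    return pd.DataFrame({"gene": genes, "log2fc": lfc,
                         "pvalue": padj / 2, "padj": padj})


class TestBhFdr:
    def test_step_up_hand_computation(self):
        # step-up: max rank-adjusted value propagated downward
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_and_capped(self):
        assert bh_fdr([0.5]) == pytest.approx([0.5])
        assert bh_fdr([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_nan_passthrough(self):
        out = bh_fdr([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        assert not np.isnan(out[0])

    def test_domain_error(self):
        with pytest.raises(ValueError):
            bh_fdr([1.5])


class TestCallDeSimple:
    def test_null_data_yields_no_discoveries(self, rng):
        counts = pd.DataFrame(
            rng.poisson(100, size=(2000, 6)),
            index=[f"g{i}" for i in range(2000)],
            columns=[f"s{i}" for i in range(6)],
        )
        groups = {f"s{i}": ("x" if i < 3 else "y") for i in range(6)}
        res = call_de_simple(counts, groups)
        frac = (res["padj"] < 0.05).mean()
        assert frac <= 0.01

    def test_planted_fold_change_detected(self, rng):
        n = 500
        base = rng.poisson(200, size=(n, 6)).astype(float)
        base[0, :3] *= 8  # log2fc = 3 in the first gene
        counts = pd.DataFrame(base.astype(int), index=[f"g{i}" for i in range(n)],
                              columns=[f"s{i}" for i in range(6)])
        groups = {f"s{i}": ("x" if i < 3 else "y") for i in range(6)}
        res = call_de_simple(counts, groups).set_index("gene")
        assert res.loc["g0", "padj"] < 0.05
        assert res.loc["g0", "log2fc"] > 2

    def test_all_zero_gene_untested(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [0, 6], "s3": [0, 7], "s4": [0, 8]},
                              index=["dead", "alive"])
        groups = {"s1": "x", "s2": "x", "s3": "y", "s4": "y"}
        res = call_de_simple(counts, groups).set_index("gene")
        assert not res.loc["dead", "tested"]
        assert np.isnan(res.loc["dead", "padj"])

    def test_requires_two_samples_per_condition(self):
        counts = pd.DataFrame({"s1": [1], "s2": [2], "s3": [3]}, index=["g"])
        with pytest.raises(ValueError):
            call_de_simple(counts, {"s1": "x", "s2": "x", "s3": "y"})


class TestClassifySharedDegs:
    def test_definition_cases(self):
        ta = pd.DataFrame({"gene": ["g1", "g2", "g3"], "log2fc": [2.0, 2.0, 2.0],
                           "pvalue": [1e-5] * 3, "padj": [1e-4] * 3})
        tb = pd.DataFrame({"gene": ["g1", "g2", "g3"], "log2fc": [1.0, -1.0, 1.0],
                           "pvalue": [1e-5, 1e-5, 0.5], "padj": [1e-4, 1e-4, 0.9]})
        per_gene, counts = classify_shared_degs(ta, tb, 0.05)
        cat = per_gene.set_index("gene")["category"]
        assert cat["g1"] == "concordant_up"
        assert cat["g2"] == "antagonistic"
        assert cat["g3"] == "exclusive_A"
        assert counts["intersection"] == 2

    @pytest.mark.parametrize("up,down,antag,total", [
        (97, 71, 46, 214),   # female comparison structure
        (78, 55, 113, 246),  # larval comparison structure
    ])
    def test_planted_structure_partitions(self, up, down, antag, total):
        n = 2000
        # comparison A: genes 0..(up+down+antag) significant with signs
        # chosen so the planted joint categories come out exactly
        k = up + down + antag
        lfc_a = np.full(n, 0.1)
        lfc_b = np.full(n, 0.1)
        padj_a = np.full(n, 0.8)
        padj_b = np.full(n, 0.8)
        padj_a[:k] = padj_b[:k] = 1e-6
        lfc_a[:up] = 1.5; lfc_b[:up] = 2.5
        lfc_a[up:up + down] = -1.5; lfc_b[up:up + down] = -0.5
        lfc_a[up + down:k] = 1.0; lfc_b[up + down:k] = -1.0
        genes = [f"OG{i}" for i in range(n)]
        ta = pd.DataFrame({"gene": genes, "log2fc": lfc_a, "pvalue": padj_a, "padj": padj_a})
        tb = pd.DataFrame({"gene": genes, "log2fc": lfc_b, "pvalue": padj_b, "padj": padj_b})
        _, counts = classify_shared_degs(ta, tb, 0.05)
        assert counts["intersection"] == total
        assert counts["concordant_up"] == up
        assert counts["concordant_down"] == down
        assert counts["antagonistic"] == antag
        assert (counts["concordant_up"] + counts["concordant_down"]
                + counts["antagonistic"]) == counts["intersection"]

    def test_zero_lfc_on_significant_gene_is_tie_error(self):
        ta = pd.DataFrame({"gene": ["g"], "log2fc": [0.0], "pvalue": [1e-5], "padj": [1e-4]})
        tb = pd.DataFrame({"gene": ["g"], "log2fc": [1.0], "pvalue": [1e-5], "padj": [1e-4]})
        with pytest.raises(TieError):
            classify_shared_degs(ta, tb, 0.05)


class TestExpectedOverlap:
    def test_matches_permutation_oracle(self, rng):
        # mean overlap of random subset pairs equals nA*nB/N
        for n_univ, n_a, n_b in [(50, 10, 20), (30, 5, 25), (12, 6, 6)]:
            universe = np.arange(n_univ)
            draws = 20000
            overlaps = np.empty(draws)
            for i in range(draws):
                a = rng.choice(universe, size=n_a, replace=False)
                b = rng.choice(universe, size=n_b, replace=False)
                overlaps[i] = np.isin(a, b).sum()
            expected = expected_overlap(n_a, n_b, n_univ)
            se = overlaps.std(ddof=1) / np.sqrt(draws)
            assert abs(overlaps.mean() - expected) < 4 * se

    def test_degenerate_cases(self):
        assert expected_overlap(10, 20, 100) == pytest.approx(2.0)
        assert expected_overlap(0, 20, 100) == 0.0
        assert expected_overlap(100, 100, 100) == 100.0
        with pytest.raises(ValueError):
            expected_overlap(1, 1, 0)


class TestConvergenceTest:
    def test_published_scale_counts(self):
        r = convergence_test(97, 28)
        assert r.chi2 == pytest.approx(170.0, abs=0.5)
        assert r.pvalue < 1e-4
        r = convergence_test(71, 24)
        assert r.chi2 == pytest.approx(92.0, abs=0.5)

    def test_observed_equals_expected(self):
        r = convergence_test(5, 5.0)
        assert r.chi2 == 0.0
        assert r.pvalue == 1.0

    def test_pvalue_monotone_in_deviation(self):
        ps = [convergence_test(10 + d, 10.0).pvalue for d in range(0, 20, 3)]
        assert all(b < a for a, b in zip(ps, ps[1:]))

    def test_requires_positive_expectation(self):
        with pytest.raises(ValueError):
            convergence_test(5, 0.0)


class TestRunConvergenceAnalysis:
    def test_planted_concordant_module_detected(self):
        ta = make_table(150, 100, 3000)
        tb = make_table(150, 100, 3000)  # same leading genes -> concordant
        report = run_convergence_analysis(ta, tb, alpha=0.05)
        tests = {t.direction: t for t in report["tests"]}
        assert tests["concordant_up"].pvalue < 1e-6
        assert tests["concordant_down"].pvalue < 1e-6
        assert tests["antagonistic"].observed == 0

    def test_no_significant_genes_in_b_is_untestable(self):
        ta = make_table(50, 50, 500)
        tb = make_table(0, 0, 500)
        report = run_convergence_analysis(ta, tb, alpha=0.05)
        for t in report["tests"]:
            assert np.isnan(t.chi2)

    def test_universe_override_scales_expectation(self):
        ta = make_table(50, 0, 1000)
        tb = make_table(50, 0, 1000)
        r1 = run_convergence_analysis(ta, tb)
        r2 = run_convergence_analysis(ta, tb, universe=2000)
        t1 = {t.direction: t for t in r1["tests"]}["concordant_up"]
        t2 = {t.direction: t for t in r2["tests"]}["concordant_up"]
        assert t2.expected == pytest.approx(t1.expected / 2)

    def test_end_to_end_count_recovery(self):
        """Strong planted fold changes survive DE calling and classification."""
        ca, cb, ga, gb, truth = simulate_de_counts(
            n_genes=1500,
            categories={"concordant_up": 40, "concordant_down": 30,
                        "antagonistic": 20, "exclusive_A": 50, "exclusive_B": 25},
            lfc=4.0, dispersion=0.01, seed=11,
        )
        ta = call_de_simple(ca, ga).drop(columns="tested")
        tb = call_de_simple(cb, gb).drop(columns="tested")
        _, counts = classify_shared_degs(ta, tb, 0.05)
        assert abs(counts["concordant_up"] - 40) <= 4
        assert abs(counts["concordant_down"] - 30) <= 4
        assert abs(counts["antagonistic"] - 20) <= 4
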