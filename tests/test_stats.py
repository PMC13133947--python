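"""Screen statistics: normalization, L2FC, null machinery, FDR, overlap, ROC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from deathscreen import stats as dsstats
from deathscreen.stats import (
    bh_fdr,
    collapse_to_gene,
    empirical_p,
    filter_low_abundance,
    fisher_overlap,
    guide_l2fc,
    make_nt_pseudogenes,
    normalize_size_factors,
    roc_gene_set,
    size_factors,
    zscore_vs_nontargeting,
)


class TestSizeFactors:
    def test_identical_samples_factor_one(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert size_factors(counts).to_numpy() == pytest.approx([1.0, 1.0])

    def test_doubled_sample_factor_ratio_two(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        f = size_factors(counts)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_five_guide_worked_table(self):
        # hand calculation: per-guide geometric means, per-sample median ratio
        counts = pd.DataFrame({"a": [100, 200, 400, 50, 80],
                               "b": [200, 300, 500, 100, 90]})
        geo = np.sqrt(counts["a"] * counts["b"])
        expected_a = np.median(counts["a"] / geo)
        expected_b = np.median(counts["b"] / geo)
        f = size_factors(counts)
        assert f["a"] == pytest.approx(expected_a)
        assert f["b"] == pytest.approx(expected_b)

    def test_matches_pydeseq2_oracle(self):
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.integers(1, 500, size=(40, 3)),
                              columns=["a", "b", "c"])
        _, oracle = pydeseq2.deseq2_norm(counts.T.to_numpy())
        assert size_factors(counts).to_numpy() == pytest.approx(oracle, rel=1e-9)

    def test_all_zero_guides_fall_back_with_warning(self):
        counts = pd.DataFrame({"a": [0, 10], "b": [5, 0]})
        with pytest.warns(UserWarning, match="total-count"):
            f = size_factors(counts)
        assert (f > 0).all()


class TestAbundanceFilter:
    def test_removes_exactly_five_percent_tie_free(self):
        rng = np.random.default_rng(0)
        n = 200
        base = np.sort(rng.permutation(np.arange(100, 100 + n)))  # distinct
        counts = pd.DataFrame({
            "a": base, "b": base + rng.integers(0, 3, n)},
            index=[f"g{i:03d}" for i in range(n)])
        kept, dropped = filter_low_abundance(counts, 0.05)
        assert len(kept) == 190 and len(dropped) == 10

    def test_all_tied_lexical_tiebreak(self):
        counts = pd.DataFrame({"a": [7] * 10, "b": [7] * 10},
                              index=[f"g{i}" for i in range(10)])
        kept, dropped = filter_low_abundance(counts, 0.05)
        assert list(dropped) == ["g0"]  # ceil(0.5) = 1, lexical first

    def test_quantile_zero_keeps_all(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [3, 4]})
        kept, dropped = filter_low_abundance(counts, 0.0)
        assert len(kept) == 2 and len(dropped) == 0

    def test_bad_quantile_rejected(self):
        counts = pd.DataFrame({"a": [1]})
        with pytest.raises(ValueError):
            filter_low_abundance(counts, 1.5)


class TestGuideL2FC:
    @pytest.fixture
    def samples(self):
        return pd.DataFrame(
            {"condition": ["T0", "untreated", "treated"],
             "drug": ["", "", "erl"], "replicate": [1, 1, 1]},
            index=pd.Index(["T0", "u1", "t1"], name="sample"))

    def test_equal_means_zero(self, samples):
        norm = pd.DataFrame({"T0": [5.0], "u1": [10.0], "t1": [10.0]})
        out = guide_l2fc(norm, samples, ("treated", "untreated"), pseudocount=0.5)
        assert out.iloc[0] == pytest.approx(0.0)

    def test_doubling_without_pseudocount(self, samples):
        norm = pd.DataFrame({"T0": [5.0], "u1": [10.0], "t1": [20.0]})
        out = guide_l2fc(norm, samples, ("treated", "untreated"), pseudocount=0.0)
        assert out.iloc[0] == pytest.approx(1.0)

    def test_zero_numerator_with_pseudocount(self, samples):
        den = 12.0
        norm = pd.DataFrame({"T0": [5.0], "u1": [den], "t1": [0.0]})
        out = guide_l2fc(norm, samples, ("treated", "untreated"), pseudocount=0.5)
        assert out.iloc[0] == pytest.approx(np.log2(0.5 / (den + 0.5)))

    def test_missing_condition_rejected(self, samples):
        norm = pd.DataFrame({"T0": [5.0], "u1": [10.0], "t1": [10.0]})
        bad = samples[samples["condition"] != "treated"]
        with pytest.raises(ValueError, match="treated"):
            guide_l2fc(norm, bad, ("treated", "untreated"))


class TestPseudogenes:
    def test_142_guides_make_35_groups_2_left(self, screen_library):
        mapping = make_nt_pseudogenes(screen_library, group_size=4, seed=0)
        assert mapping.nunique() == 35
        assert len(mapping) == 140  # 2 of 142 left unassigned
        assert (mapping.value_counts() == 4).all()

    def test_same_seed_same_assignment(self, screen_library):
        a = make_nt_pseudogenes(screen_library, seed=11)
        b = make_nt_pseudogenes(screen_library, seed=11)
        pd.testing.assert_series_equal(a, b)

    def test_exact_division(self):
        from deathscreen.io import GuideLibrary

        seqs = ["".join(np.random.default_rng(i).choice(list("ACGT"), 20))
                for i in range(8)]
        lib = GuideLibrary(pd.DataFrame({
            "guide_id": [f"nt{i}" for i in range(8)],
            "sequence": seqs,
            "gene": ["NON_TARGETING"] * 8,
            "is_nontargeting": [True] * 8,
        }))
        mapping = make_nt_pseudogenes(lib, group_size=4, seed=0)
        assert mapping.nunique() == 2 and len(mapping) == 8

    def test_too_few_nt_guides_rejected(self, small_library):
        with pytest.raises(ValueError):
            make_nt_pseudogenes(small_library, group_size=4)


class TestCollapse:
    def test_median_and_mean(self):
        scores = pd.Series([1.0, 2.0, 3.0, 10.0], index=list("abcd"))
        g2g = pd.Series({"a": "G1", "b": "G1", "c": "G1", "d": "G1"})
        med = collapse_to_gene(scores, g2g, "median")
        mean = collapse_to_gene(scores, g2g, "mean")
        assert med.loc["G1", "score"] == 2.5
        assert mean.loc["G1", "score"] == 4.0
        assert med.loc["G1", "n_guides"] == 4

    def test_single_guide_gene(self):
        scores = pd.Series([7.0], index=["a"])
        out = collapse_to_gene(scores, pd.Series({"a": "G"}), "median")
        assert out.loc["G", "score"] == 7.0


class TestZScore:
    def test_centering(self):
        nt = pd.Series([0.5, -0.5, 0.1, -0.1])
        z = zscore_vs_nontargeting(pd.Series([nt.mean()]), nt)
        assert z.iloc[0] == pytest.approx(0.0)

    def test_sample_sd_convention(self):
        # nt scores {-1, 1}: sample sd (n-1) = sqrt(2); score 2 -> z = sqrt(2)
        nt = pd.Series([-1.0, 1.0])
        z = zscore_vs_nontargeting(pd.Series([2.0]), nt)
        assert z.iloc[0] == pytest.approx(2.0 / np.sqrt(2.0))

    def test_nt_population_mean_zero(self):
        nt = pd.Series([0.3, -0.2, 0.8, -0.9, 0.05])
        z = zscore_vs_nontargeting(nt, nt)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            zscore_vs_nontargeting(pd.Series([1.0]), pd.Series([2.0, 2.0]))


class TestEmpiricalP:
    def test_central_value_near_one(self):
        rng = np.random.default_rng(0)
        pool = rng.normal(0, 1, 200)
        nt = pd.Series(rng.normal(0, 0.5, 35))
        p = empirical_p(pd.Series({"g": 0.0}), pd.Series({"g": 4}), pool, nt,
                        iterations=2000, seed=1)
        assert p.iloc[0] > 0.9

    def test_extreme_value_hits_add_one_floor(self):
        rng = np.random.default_rng(0)
        pool = rng.normal(0, 1, 200)
        nt = pd.Series(rng.normal(0, 0.5, 35))
        p = empirical_p(pd.Series({"g": 50.0}), pd.Series({"g": 4}), pool, nt,
                        iterations=1000, seed=1)
        assert p.iloc[0] == pytest.approx(1 / 1001)

    def test_null_genes_give_uniform_p(self):
        """Genes resampled from the null pool must give ~Uniform(0,1) p."""
        rng = np.random.default_rng(42)
        pool = rng.normal(0.0, 1.0, 140)
        # pseudo-genes: groups of 4 from the same pool, as in a real screen
        nt_scores = pd.Series(rng.choice(pool, (35, 4)).mean(axis=1))
        n_genes = 400
        gene_scores = pd.Series(rng.choice(pool, (n_genes, 4)).mean(axis=1),
                                index=[f"G{i}" for i in range(n_genes)])
        z = zscore_vs_nontargeting(gene_scores, nt_scores)
        n_guides = pd.Series(4, index=gene_scores.index)
        p = empirical_p(z, n_guides, pool, nt_scores, method="mean",
                        iterations=2000, seed=7)
        ks = sps.kstest(p, "uniform")
        assert ks.pvalue > 0.01


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_step_up_by_hand(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03]))
        assert q == pytest.approx([0.03, 0.03, 0.03])

    def test_all_equal_p_unchanged(self):
        q = bh_fdr(np.array([0.2, 0.2, 0.2]))
        assert q == pytest.approx([0.2, 0.2, 0.2])

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(1)
        p = pd.Series(rng.uniform(0, 1, 100))
        q = bh_fdr(p)
        order = p.sort_values().index
        assert (np.diff(q.loc[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([-0.1]))


class TestFisherOverlap:
    def test_symmetric_table(self):
        universe = set(range(40))
        a = set(range(20))
        b = set(range(10, 30))
        oddsratio, p, table = fisher_overlap(a, b, universe)
        assert table["a"] == 10 and table["d"] == 10
        assert oddsratio == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_independent_random_sets_or_near_one(self):
        rng = np.random.default_rng(3)
        universe = set(range(4000))
        a = set(rng.choice(4000, 1200, replace=False))
        b = set(rng.choice(4000, 1200, replace=False))
        oddsratio, p, _ = fisher_overlap(a, b, universe)
        assert 0.8 < oddsratio < 1.25

    def test_identical_sets_capped_and_flagged(self):
        universe = set(range(30))
        a = set(range(10))
        oddsratio, p, table = fisher_overlap(a, a, universe, or_cap=1e6)
        assert table["haldane_or_capped"]
        assert p < 1e-4

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_overlap(set(), set(), set())


class TestROC:
    def test_perfect_separation(self):
        scores = pd.Series([5.0, 4.0, 1.0, 0.0], index=list("abcd"))
        auc, p, _ = roc_gene_set(scores, {"a", "b"}, bootstrap_iterations=200, seed=0)
        assert auc == 1.0
        assert p < 0.2  # only C(4,2)=6 label permutations exist

    def test_random_scores_auc_half(self):
        rng = np.random.default_rng(2)
        scores = pd.Series(rng.normal(size=500),
                           index=[f"g{i}" for i in range(500)])
        auc, p, _ = roc_gene_set(scores, set(scores.index[:50]),
                                 bootstrap_iterations=300, seed=2)
        assert abs(auc - 0.5) < 0.1
        assert p > 0.05

    def test_tied_scores_flagged(self):
        scores = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        auc, p, flag = roc_gene_set(scores, {"a"})
        assert auc == 0.5 and flag == "all_scores_tied"


class TestPipelineDeterminism:
    def test_fixed_seed_bit_identical_gene_table(self, screen_counts, screen_library):
        filtered, _ = filter_low_abundance(screen_counts.counts)
        norm = normalize_size_factors(filtered)
        l2fc = guide_l2fc(norm, screen_counts.samples,
                          dsstats.CONTRASTS["treated_vs_untreated"])
        out = []
        for _ in range(2):
            pseudo = make_nt_pseudogenes(screen_library, seed=9)
            out.append(dsstats.gene_stat_table(l2fc, screen_library, pseudo,
                                               iterations=200, seed=9))
        pd.testing.assert_frame_equal(out[0], out[1])

    def test_essential_genes_drop_out_over_time(self, screen_counts, screen_library,
                                                screen_truth):
        """Genes with growth multiplier < 1 show negative untreated-vs-T0 L2FC."""
        filtered, _ = filter_low_abundance(screen_counts.counts)
        norm = normalize_size_factors(filtered)
        ess = guide_l2fc(norm, screen_counts.samples, dsstats.CONTRASTS["essentiality"])
        g2g = screen_library.guide_to_gene()
        gene_ess = ess.groupby(g2g.reindex(ess.index)).median()
        slow = screen_truth.genes.index[screen_truth.genes["phi"] < 0.95]
        assert (gene_ess.reindex(slow).dropna() < 0).mean() > 0.95
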