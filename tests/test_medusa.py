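"""MEDUSA forward model, closed-form and grid inversions, gene-level tables."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from deathscreen.medusa import (
    MedusaGrid,
    MedusaScreen,
    ScreenTimeline,
    infer_by_grid,
    infer_knockout_rates,
    predict_l2fc,
    proportional_inhibition,
)
from deathscreen.rates import LN2, RatePair


class TestPredictL2FC:
    def test_wildtype_like_clone_is_silent(self, timeline):
        gT, dT = timeline.treated_rates.g, timeline.treated_rates.d
        A, B = predict_l2fc(1.0, gT, dT, timeline)
        assert A == pytest.approx(0.0, abs=1e-12)
        assert B == pytest.approx(0.0, abs=1e-12)

    def test_essential_gene_negative_essentiality(self, timeline):
        A, _ = predict_l2fc(0.5, 0.5 * timeline.treated_rates.g,
                            timeline.treated_rates.d, timeline)
        assert A < 0

    def test_extra_death_shifts_b_by_closed_form(self, timeline):
        # growth matched to wild type, death raised by delta:
        # B = -delta * t / ln2
        delta = 0.004
        gT, dT = timeline.treated_rates.g, timeline.treated_rates.d
        _, B = predict_l2fc(1.0, gT, dT + delta, timeline)
        assert B == pytest.approx(-delta * timeline.t_treat / LN2, rel=1e-12)

    def test_invalid_parameters_rejected(self, timeline):
        with pytest.raises(ValueError):
            predict_l2fc(0.0, 0.01, 0.01, timeline)
        with pytest.raises(ValueError):
            predict_l2fc(1.0, -0.01, 0.01, timeline)


class TestClosedFormInversion:
    def test_zero_fold_changes_give_wildtype(self, timeline):
        inf = infer_knockout_rates(0.0, 0.0, timeline)
        assert inf.phi == pytest.approx(1.0)
        assert inf.g_i == pytest.approx(timeline.treated_rates.g)
        assert inf.d_i == pytest.approx(timeline.treated_rates.d)

    def test_round_trip_on_dense_grid(self, timeline):
        gT = timeline.treated_rates.g
        worst = 0.0
        for phi in np.linspace(0.25, 2.0, 50):
            for d in np.linspace(0.0, 0.05, 50):
                A, B = predict_l2fc(phi, phi * gT, d, timeline)
                inf = infer_knockout_rates(A, B, timeline)
                worst = max(worst, abs(inf.phi - phi), abs(inf.d_i - d))
        assert worst <= 1e-8

    def test_death_rescue_clone_recovers_basal_death(self, timeline):
        # apoptosome-like knockout: treated death collapses to the basal rate
        d0 = timeline.untreated_rates.d
        gT = timeline.treated_rates.g
        A, B = predict_l2fc(1.0, gT, d0, timeline)
        assert B > 0  # survives drug better than wild type
        inf = infer_knockout_rates(A, B, timeline)
        assert inf.d_i == pytest.approx(d0, abs=1e-10)

    def test_overshooting_b_floors_death_with_residual(self, timeline):
        # more enrichment than zero death can explain under the constraint
        A, B0 = predict_l2fc(1.0, timeline.treated_rates.g, 0.0, timeline)
        inf = infer_knockout_rates(A, B0 + 3.0, timeline)
        assert inf.d_i == 0.0
        assert inf.residual == pytest.approx(3.0)
        assert "d_floored" in inf.flag


class TestGridInversion:
    def test_cross_method_agreement_1000_cases(self, timeline):
        grid = MedusaGrid(timeline)
        phi_cell = np.diff(grid.phi_grid).max()
        d_cell = np.diff(grid.d_grid).max()
        rng = np.random.default_rng(0)
        gT = timeline.treated_rates.g
        for _ in range(1000):
            phi = rng.uniform(0.26, 1.99)
            d = rng.uniform(0.0, grid.d_grid[-1] * 0.99)
            A, B = predict_l2fc(phi, phi * gT, d, timeline)
            gi = grid.invert(A, B)
            cf = infer_knockout_rates(A, B, timeline)
            assert abs(gi.phi - cf.phi) <= phi_cell
            assert abs(gi.d_i - cf.d_i) <= d_cell

    def test_grid_node_is_exact(self, timeline):
        grid = MedusaGrid(timeline)
        phi = grid.phi_grid[17]
        d = grid.d_grid[23]
        A, B = predict_l2fc(phi, proportional_inhibition(phi, timeline), d, timeline)
        inf = grid.invert(A, B)
        assert inf.phi == pytest.approx(phi, rel=1e-9)
        assert inf.d_i == pytest.approx(d, abs=1e-12)

    def test_coarse_grid_bounded_error(self, timeline):
        grid = MedusaGrid(timeline, n_phi=5, n_d=5)
        gT = timeline.treated_rates.g
        A, B = predict_l2fc(0.7, 0.7 * gT, 0.013, timeline)
        inf = grid.invert(A, B)
        assert abs(inf.d_i - 0.013) <= np.diff(grid.d_grid).max()

    def test_out_of_hull_observation_clamped_with_flag(self, timeline):
        inf = infer_by_grid(-50.0, 0.0, timeline)
        assert "clamped" in inf.flag
        assert inf.phi == pytest.approx(0.25, rel=1e-6)


class TestMedusaScreenFit:
    def test_death_rate_recovery_spearman(self, medusa_results, screen_truth):
        """Inferred per-gene death rates track the graded truth (rank rho)
        across the genes whose true death rate differs from wild type."""
        merged = medusa_results.gene_death.join(screen_truth.genes, how="inner")
        death = merged[merged["class"].isin(["death_suppressor", "death_sensitizer"])]
        rho = spearmanr(death["score"], death["d_i"]).statistic
        assert rho >= 0.9

    def test_growth_axis_tracks_essentiality(self, medusa_results, screen_library):
        """MEDUSA growth rates correlate strongly with untreated-vs-T0 L2FC."""
        gt = medusa_results.guide_table
        g2g = screen_library.guide_to_gene()
        ess = gt["l2fc_A"].groupby(g2g.reindex(gt.index)).mean()
        growth = medusa_results.gene_growth
        growth = growth[~growth["is_nontargeting"]]
        common = growth.index.intersection(ess.index)
        rho = spearmanr(growth.loc[common, "score"], ess.loc[common]).statistic
        assert rho > 0.95

    def test_nt_pseudogene_z_mean_zero(self, medusa_results):
        nt = medusa_results.gene_death[medusa_results.gene_death["is_nontargeting"]]
        assert nt["z"].mean() == pytest.approx(0.0, abs=1e-10)
        assert nt["z"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_death_suppressor_gene_detected(self, medusa_results, screen_truth):
        """Strong death-rescued knockouts score negative death z at q < 0.05."""
        dT = 0.01
        strong = screen_truth.genes[
            (screen_truth.genes["class"] == "death_suppressor")
            & (screen_truth.genes["d_i"] < 0.3 * dT)
        ].index
        table = medusa_results.gene_death.reindex(strong).dropna()
        assert (table["z"] < 0).mean() > 0.95
        assert (table["q"] < 0.05).mean() > 0.8

    def test_metadata_records_degeneracy_constraint(self, medusa_results):
        assert medusa_results.metadata["growth_constraint"] == "proportional_inhibition"
        assert "proportional" in medusa_results.summary() or "hits" in medusa_results.summary()

    def test_roc_recovers_true_death_genes(self, medusa_results, screen_truth):
        """True death-affecting genes separate from the rest by |death z|."""
        from deathscreen.stats import roc_gene_set

        table = medusa_results.gene_death
        real = table[~table["is_nontargeting"]]
        positives = set(screen_truth.genes.index[
            screen_truth.genes["class"].isin(["death_suppressor", "death_sensitizer"])])
        auc, p, _ = roc_gene_set(real["z"].abs(), positives,
                                 bootstrap_iterations=200, seed=0)
        assert auc > 0.9
        assert p < 0.01


class TestAllNullScreen:
    def test_hit_count_stays_near_alpha(self, screen_library, timeline):
        """With no true effects, q < 0.05 calls stay a small fraction."""
        from deathscreen import simulate as dssim

        truth = dssim.make_screen_truth(
            screen_library, timeline,
            class_fractions={"death_suppressor": 0, "death_sensitizer": 0,
                             "growth_only": 0, "essential": 0},
            seed=4,
        )
        cm = dssim.simulate_screen(truth, screen_library, timeline, seed=4)
        res = MedusaScreen(cm, screen_library, timeline).fit(iterations=2000, seed=4)
        assert len(res.hits("death")) <= 0.05 * len(truth.genes)
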