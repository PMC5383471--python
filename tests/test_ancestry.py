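"""Diagnostic panel, hybrid-index scoring, and the K=2 admixture EM."""

from fractions import Fraction

import numpy as np
import pytest

from chiffchaff import (
    AdmixtureModel,
    AdmixtureScenario,
    DivergenceModel,
    SampleSpec,
    aggregate_by_region,
    build_panel,
    classify_sites,
    draw_lineage_frequencies,
    em_admixture_k2,
    score_cohort,
    score_individual,
    simulate_genotypes,
)

from .conftest import build_matrix

ALLO = ("allopatric_abietinus", "allopatric_tristis")


class TestPanel:
    def test_panel_equals_brute_force_fixed_list(self, diverged_cohort):
        _, _, _, matrix = diverged_cohort
        panel = build_panel(matrix, *ALLO)
        sc = classify_sites(matrix, *ALLO)
        assert sorted(panel.sites["row"]) == sorted(sc.site_index("fixed"))
        assert len(panel) > 1000

    def test_no_divergence_gives_empty_panel_error(self):
        model = DivergenceModel(n_sites=300, fst=0.0, seed=41)
        freqs = draw_lineage_frequencies(model)
        matrix = simulate_genotypes(freqs, AdmixtureScenario.default_cohort(5), model)
        with pytest.raises(ValueError, match="empty diagnostic panel"):
            build_panel(matrix, *ALLO)

    def test_panel_ordered_by_genome_coordinate(self, diverged_cohort):
        _, _, _, matrix = diverged_cohort
        panel = build_panel(matrix, *ALLO)
        pos = panel.sites["pos"].to_numpy()
        assert (np.diff(pos) > 0).all()

    def test_lineage_alleles_distinct_per_site(self, diverged_cohort):
        _, _, _, matrix = diverged_cohort
        panel = build_panel(matrix, *ALLO)
        # allele_a is 0/1; lineage B carries the complement by construction
        assert set(panel.sites["allele_a"]) <= {0, 1}


class TestScoring:
    def make_panel_matrix(self, genotype_col):
        """3 reference samples per lineage fixed 0/2, plus one scored bird."""
        n = len(genotype_col)
        rows = [[0, 0, 0, 2, 2, 2, genotype_col[i]] for i in range(n)]
        groups = ["allopatric_abietinus"] * 3 + ["allopatric_tristis"] * 3 + ["mystery"]
        m = build_matrix(rows, groups, ids=[f"r{i}" for i in range(6)] + ["bird"])
        return m, build_panel(m, *ALLO)

    def test_pure_lineage_b_scores_zero(self):
        m, panel = self.make_panel_matrix([2] * 20)
        prof = score_individual(panel, m, "bird")
        assert (prof.hom_a, prof.hom_b, prof.het) == (0.0, 1.0, 0.0)
        assert prof.q_hat == 0.0

    def test_all_het_scores_half(self):
        m, panel = self.make_panel_matrix([1] * 20)
        prof = score_individual(panel, m, "bird")
        assert (prof.hom_a, prof.hom_b, prof.het) == (0.0, 0.0, 1.0)
        assert prof.q_hat == 0.5

    def test_missing_panel_sites_excluded_from_denominator(self):
        m, panel = self.make_panel_matrix([0] * 10 + [-1] * 10)
        prof = score_individual(panel, m, "bird")
        assert prof.n_missing == 10
        assert prof.n_called == 10
        assert prof.q_hat == 1.0

    def test_all_missing_rejected(self):
        m, panel = self.make_panel_matrix([-1] * 5)
        with pytest.raises(ValueError, match="no called panel genotypes"):
            score_individual(panel, m, "bird")

    def test_fraction_triplet_sums_to_one_exactly(self):
        m, panel = self.make_panel_matrix([0, 0, 1, 2, 1, 0, 2])
        prof = score_individual(panel, m, "bird")
        total = (
            Fraction(prof.n_hom_a, prof.n_called)
            + Fraction(prof.n_hom_b, prof.n_called)
            + Fraction(prof.n_het, prof.n_called)
        )
        assert total == 1

    def test_backcross_recovery(self):
        """q = 0.75 backcross recovered within 0.03 over ~3,500 panel sites."""
        model = DivergenceModel(n_sites=11_000, fst=0.99, seed=42)
        freqs = draw_lineage_frequencies(model)
        cohort = AdmixtureScenario.default_cohort(10)
        samples = cohort.samples + (
            SampleSpec("BC1", "sympatric_south", 0.75),
        )
        matrix = simulate_genotypes(freqs, AdmixtureScenario(samples), model)
        panel = build_panel(matrix, *ALLO)
        assert len(panel) >= 3000
        prof = score_individual(panel, matrix, "BC1")
        assert prof.q_hat == pytest.approx(0.75, abs=0.03)
        # binomial expectations at q = 0.75: (q^2, (1-q)^2, 2q(1-q))
        assert prof.hom_a == pytest.approx(0.5625, abs=0.05)
        assert prof.het == pytest.approx(0.375, abs=0.05)
        assert prof.hom_b == pytest.approx(0.0625, abs=0.03)


class TestAggregate:
    def test_region_means_match_direct_computation(self, diverged_cohort):
        _, scenario, _, matrix = diverged_cohort
        panel = build_panel(matrix, *ALLO)
        profiles = score_cohort(panel, matrix)
        agg = aggregate_by_region(profiles).set_index("region")
        for region in ("north", "south"):
            sub = profiles[profiles["region"] == region]
            assert agg.loc[region, "het"] == pytest.approx(sub["het"].mean())
            assert agg.loc[region, "q_hat"] == pytest.approx(sub["q_hat"].mean())
        assert agg.loc["total", "q_hat"] == pytest.approx(profiles["q_hat"].mean())

    def test_two_individual_mean(self):
        import pandas as pd

        profiles = pd.DataFrame(
            {
                "id": ["a", "b"],
                "region": ["north", "north"],
                "hom_a": [0.8, 0.6],
                "hom_b": [0.1, 0.2],
                "het": [0.10, 0.20],
                "q_hat": [0.85, 0.7],
            }
        )
        agg = aggregate_by_region(profiles).set_index("region")
        assert agg.loc["north", "het"] == pytest.approx(0.15)

    def test_single_individual_region_equals_individual(self):
        import pandas as pd

        profiles = pd.DataFrame(
            {
                "id": ["a"],
                "region": ["north"],
                "hom_a": [0.8],
                "hom_b": [0.1],
                "het": [0.1],
                "q_hat": [0.85],
            }
        )
        agg = aggregate_by_region(profiles).set_index("region")
        assert agg.loc["north", "q_hat"] == 0.85


@pytest.fixture(scope="module")
def em_cohort():
    model = DivergenceModel(n_sites=3000, fst=0.95, seed=43)
    freqs = draw_lineage_frequencies(model)
    samples = AdmixtureScenario.default_cohort(10).samples + (
        SampleSpec("F1a", "sympatric_north", 0.5, cross="f1"),
        SampleSpec("F1b", "sympatric_south", 0.5, cross="f1"),
    )
    return simulate_genotypes(freqs, AdmixtureScenario(samples), model)


class TestAdmixtureEM:

    def test_pure_groups_recovered(self, em_cohort):
        res = em_admixture_k2(em_cohort, anchor_groups=ALLO, seed=1)
        q = res.q
        a_ids = [f"A{i + 1}" for i in range(10)]
        t_ids = [f"T{i + 1}" for i in range(10)]
        assert (np.abs(q[a_ids] - 1.0) < 0.05).all()
        assert (np.abs(q[t_ids] - 0.0) < 0.05).all()

    def test_f1_individuals_near_half(self, em_cohort):
        res = em_admixture_k2(em_cohort, anchor_groups=ALLO, seed=1)
        assert res.q["F1a"] == pytest.approx(0.5, abs=0.05)
        assert res.q["F1b"] == pytest.approx(0.5, abs=0.05)

    def test_loglik_monotone_nondecreasing(self, em_cohort):
        res = em_admixture_k2(em_cohort, anchor_groups=ALLO, seed=1)
        assert (np.diff(res.loglik_path) >= -1e-8).all()

    def test_supervised_and_unsupervised_agree(self, em_cohort):
        res = em_admixture_k2(em_cohort, anchor_groups=ALLO, seed=1)
        panel = build_panel(em_cohort, *ALLO)
        profiles = score_cohort(panel, em_cohort).set_index("id")
        diff = (res.q - profiles["q_hat"]).abs()
        assert diff.max() < 0.05

    def test_random_init_without_anchor_still_separates(self, em_cohort):
        res = em_admixture_k2(em_cohort, seed=7)
        q = res.q
        spread = abs(q[[f"A{i+1}" for i in range(10)]].mean()
                     - q[[f"T{i+1}" for i in range(10)]].mean())
        assert spread > 0.9  # labels may be flipped; magnitude is what matters

    def test_single_sample_rejected(self):
        m = build_matrix([[0], [1]], ["A"])
        with pytest.raises(ValueError):
            AdmixtureModel(m)

    def test_summary_mentions_fit_dimensions(self, em_cohort):
        res = em_admixture_k2(em_cohort, anchor_groups=ALLO, seed=1)
        text = res.summary()
        assert "samples: 42" in text
        assert "log-likelihood" in text
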