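"""Site classification, W&C F_ST, 2x2 chi-square, genotype PCA."""

import numpy as np
import pytest

from chiffchaff import (
    MISSING,
    AdmixtureScenario,
    DivergenceModel,
    SampleSpec,
    chi2_2x2,
    classify_sites,
    draw_lineage_frequencies,
    fst,
    pca,
    percent_of_total,
    simulate_genotypes,
    weir_cockerham_components,
)

from .conftest import build_matrix

AB = ["A"] * 3 + ["B"] * 3


def classify_one(row):
    m = build_matrix([row], AB)
    sc = classify_sites(m, "A", "B")
    if sc.n_invariant:
        return "invariant"
    return sc.categories.iloc[0]


class TestClassifySites:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([0, 0, 0, 2, 2, 2], "fixed"),
            ([0, 1, 0, 0, 1, 0], "shared"),
            ([0, 1, 0, 0, 0, 0], "private_a"),
            ([0, 0, 0, 0, 1, 0], "private_b"),
            ([0, 0, 0, 0, 0, 0], "invariant"),
            ([2, 2, 2, 2, 2, 2], "invariant"),
            ([1, 1, 1, 0, 0, 0], "private_a"),  # het => polymorphic in A
        ],
    )
    def test_single_site_categories(self, row, expected):
        assert classify_one(row) == expected

    def test_sites_without_calls_in_one_group_excluded(self):
        m = build_matrix([[MISSING, MISSING, MISSING, 0, 1, 0]], AB)
        sc = classify_sites(m, "A", "B")
        assert sc.n_excluded == 1
        assert sc.n_classified == 0

    def test_empty_group_rejected(self):
        m = build_matrix([[0, 1]], ["A", "A"])
        with pytest.raises(KeyError):
            classify_sites(m, "A", "B")

    def test_matches_brute_force_recount_on_simulated_matrix(self):
        model = DivergenceModel(n_sites=1000, fst=0.5, missing_rate=0.1, seed=13)
        freqs = draw_lineage_frequencies(model)
        scenario = AdmixtureScenario.default_cohort(5)
        matrix = simulate_genotypes(freqs, scenario, model)
        sc = classify_sites(matrix, "allopatric_abietinus", "allopatric_tristis")

        # independent per-site recount from allele sets
        counts = {"fixed": 0, "shared": 0, "private_a": 0, "private_b": 0}
        n_inv = n_exc = 0
        ga = matrix.genotypes[:, matrix.samples["group"] == "allopatric_abietinus"]
        gb = matrix.genotypes[:, matrix.samples["group"] == "allopatric_tristis"]
        for i in range(matrix.n_sites):
            def alleles(row):
                out = set()
                for g in row:
                    if g == 0:
                        out.add(0)
                    elif g == 2:
                        out.add(1)
                    elif g == 1:
                        out.update((0, 1))
                return out

            sa, sb = alleles(ga[i]), alleles(gb[i])
            if not sa or not sb:
                n_exc += 1
            elif len(sa) == 2 and len(sb) == 2:
                counts["shared"] += 1
            elif len(sa) == 2:
                counts["private_a"] += 1
            elif len(sb) == 2:
                counts["private_b"] += 1
            elif sa == sb:
                n_inv += 1
            else:
                counts["fixed"] += 1
        assert sc.counts == counts
        assert sc.n_invariant == n_inv
        assert sc.n_excluded == n_exc

    def test_percentages_sum_to_hundred(self, diverged_cohort):
        _, _, _, matrix = diverged_cohort
        sc = classify_sites(matrix, "allopatric_abietinus", "allopatric_tristis")
        assert abs(sum(sc.percentages.values()) - 100.0) <= 0.2


class TestPercentOfTotal:
    @pytest.mark.parametrize(
        "count, total, expected",
        [(3555, 1233236, 0.3), (50, 18014, 0.3), (0, 100, 0.0), (13, 20, 65.0)],
    )
    def test_printed_count_arithmetic(self, count, total, expected):
        assert percent_of_total(count, total) == expected

    def test_half_up_rounding(self):
        assert percent_of_total(15, 1000) == 1.5
        assert percent_of_total(25, 1000, decimals=0) == 3.0  # 2.5 rounds up

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            percent_of_total(1, 0)


class TestFst:
    def test_identical_distributions_near_zero(self):
        rng = np.random.default_rng(31)
        p = rng.uniform(0.2, 0.8, size=10_000)
        geno = rng.binomial(1, p[:, None], size=(10_000, 40)) + rng.binomial(
            1, p[:, None], size=(10_000, 40)
        )
        m = build_matrix(geno.tolist(), ["A"] * 20 + ["B"] * 20)
        est = fst(m, "A", "B")
        assert abs(est.fst) < 0.02

    def test_all_fixed_sites_give_one(self):
        geno = [[0] * 10 + [2] * 10] * 200
        m = build_matrix(geno, ["A"] * 10 + ["B"] * 10)
        est = fst(m, "A", "B")
        assert est.fst == pytest.approx(1.0)

    def test_per_site_components_match_hand_coded_formula(self):
        """W&C (1984) evaluated independently with scalar arithmetic."""
        rng = np.random.default_rng(32)
        geno = rng.choice([0, 1, 2, MISSING], size=(50, 20), p=[0.3, 0.3, 0.3, 0.1])
        m = build_matrix(geno.tolist(), ["A"] * 10 + ["B"] * 10)
        a, b, c, used = weir_cockerham_components(m, "A", "B")

        for i in range(50):
            obs = [
                [g for g in geno[i, :10] if g != MISSING],
                [g for g in geno[i, 10:] if g != MISSING],
            ]
            n1, n2 = len(obs[0]), len(obs[1])
            if n1 < 2 or n2 < 2:
                assert not used[i]
                continue
            p1 = sum(obs[0]) / (2 * n1)
            p2 = sum(obs[1]) / (2 * n2)
            h1 = sum(1 for g in obs[0] if g == 1) / n1
            h2 = sum(1 for g in obs[1] if g == 1) / n2
            r, nbar = 2.0, (n1 + n2) / 2.0
            nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
            pbar = (n1 * p1 + n2 * p2) / (r * nbar)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (n1 * h1 + n2 * h2) / (r * nbar)
            a_i = (nbar / nc) * (
                s2
                - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
            )
            b_i = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - ((r - 1) / r) * s2
                - ((2 * nbar - 1) / (4 * nbar)) * hbar
            )
            c_i = hbar / 2
            assert a[i] == pytest.approx(a_i, abs=1e-12)
            assert b[i] == pytest.approx(b_i, abs=1e-12)
            assert c[i] == pytest.approx(c_i, abs=1e-12)

    def test_hardy_weinberg_two_frequency_case(self):
        """Groups at p=0.2 vs 0.8 under HWE recover a large theta."""
        rng = np.random.default_rng(33)
        n_sites = 5000
        g1 = rng.binomial(2, 0.2, size=(n_sites, 10))
        g2 = rng.binomial(2, 0.8, size=(n_sites, 10))
        m = build_matrix(np.hstack([g1, g2]).tolist(), ["A"] * 10 + ["B"] * 10)
        est = fst(m, "A", "B")
        # population theta for p1=0.2, p2=0.8: s2/(pbar qbar + s2/2) = 0.18/0.34
        assert est.fst == pytest.approx(0.18 / 0.34, abs=0.02)

    def test_monomorphic_everywhere_raises(self):
        m = build_matrix([[0] * 20] * 100, ["A"] * 10 + ["B"] * 10)
        with pytest.raises(ValueError):
            fst(m, "A", "B")

    def test_jackknife_se_positive_and_blocks_counted(self, diverged_cohort):
        _, _, _, matrix = diverged_cohort
        est = fst(matrix, "allopatric_abietinus", "allopatric_tristis")
        assert est.se > 0
        assert est.n_blocks == int(np.ceil(est.n_sites / 50))
        assert len(est.pseudovalues) == est.n_blocks


class TestChi2:
    def test_printed_west_east_contrast(self):
        stat, dof, p = chi2_2x2(13, 7, 6, 49, continuity=True)
        assert round(stat, 1) == 19.9
        assert dof == 1
        assert p < 1e-4

    def test_equal_proportions_zero(self):
        stat, _, _ = chi2_2x2(10, 10, 10, 10)
        assert stat == pytest.approx(0.0)

    def test_uncorrected_matches_expected_count_formula(self):
        stat, _, _ = chi2_2x2(13, 7, 6, 49, continuity=False)
        obs = np.array([[13, 7], [6, 49]], dtype=float)
        row, col, n = obs.sum(1), obs.sum(0), obs.sum()
        exp = np.outer(row, col) / n
        assert stat == pytest.approx(((obs - exp) ** 2 / exp).sum())

    def test_random_tables_match_yates_oracle(self):
        rng = np.random.default_rng(34)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 60, size=4)
            stat, _, _ = chi2_2x2(int(a), int(b), int(c), int(d))
            n = a + b + c + d
            yates = (
                n * max(abs(int(a) * int(d) - int(b) * int(c)) - n / 2, 0) ** 2
                / ((a + b) * (c + d) * (a + c) * (b + d))
            )
            assert stat == pytest.approx(yates, rel=1e-10)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi2_2x2(0, 0, 5, 5)


class TestPca:
    def test_two_fixed_clusters_separate_on_pc1(self):
        geno = [[0] * 5 + [2] * 5] * 300
        m = build_matrix(geno, ["A"] * 5 + ["B"] * 5)
        res = pca(m, n_components=2)
        pc1 = res.coordinates["PC1"].to_numpy()
        assert (np.sign(pc1[:5]) != np.sign(pc1[5:])).all()
        assert res.explained[0] > 0.99

    def test_admixed_sample_at_centroid_midpoint(self):
        model = DivergenceModel(n_sites=3000, fst=0.99, seed=35)
        freqs = draw_lineage_frequencies(model)
        samples = tuple(
            [SampleSpec(f"A{i}", "A", 1.0) for i in range(10)]
            + [SampleSpec(f"B{i}", "B", 0.0) for i in range(10)]
            + [SampleSpec("H", "H", 0.5)]
        )
        matrix = simulate_genotypes(freqs, AdmixtureScenario(samples), model)
        res = pca(matrix, n_components=2)
        pc1 = res.coordinates.set_index("id")["PC1"]
        mid = (pc1.loc[[f"A{i}" for i in range(10)]].mean()
               + pc1.loc[[f"B{i}" for i in range(10)]].mean()) / 2
        dist = abs(pc1.loc[[f"A{i}" for i in range(10)]].mean()
                   - pc1.loc[[f"B{i}" for i in range(10)]].mean())
        assert abs(pc1.loc["H"] - mid) < 0.05 * dist

    def test_duplicated_samples_get_identical_coordinates(self):
        rng = np.random.default_rng(36)
        geno = rng.choice([0, 1, 2], size=(200, 4)).astype(np.int8)
        doubled = np.hstack([geno, geno])
        m = build_matrix(doubled.tolist(), ["A"] * 8)
        res = pca(m, n_components=2)
        c = res.coordinates[["PC1", "PC2"]].to_numpy()
        np.testing.assert_allclose(c[:4], c[4:], atol=1e-8)

    def test_more_components_than_samples_rejected(self):
        m = build_matrix([[0, 1, 2]], ["A"] * 3)
        with pytest.raises(ValueError):
            pca(m, n_components=4)
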