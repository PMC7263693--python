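"""Meiosis, family, half-tetrad, and phenotype simulator behaviour."""
import numpy as np
import pytest

import meiomap as mm
from meiomap.simulate import MISSING

from conftest import make_chrom, y_enumeration_oracle


class TestChromosomeModel:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"L": -1.0},
            {"male": -5.0},
            {"cen": 120.0},
            {"frac": 0.7},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_chrom(**kwargs)

    def test_marker_positions_validated(self):
        c = make_chrom()
        with pytest.raises(ValueError):
            mm.GenomeModel([c], {"c1": np.array([0.0, 120.0])})


class TestMeiosis:
    def test_zero_length_chromosome_returns_parental_haplotype(self):
        c = mm.ChromosomeModel("c0", 0.0, 0.0, 1, 0.0)
        phase = np.array([[0, 0, 0], [1, 1, 1]], dtype=np.int8)
        alleles, origins, xs = mm.simulate_meiosis(
            c, np.zeros(3), phase, "female", np.random.default_rng(0)
        )
        assert xs.size == 0
        assert np.all(origins == origins[0])
        assert np.array_equal(alleles, phase[origins[0]])

    def test_terminal_recombination_matches_haldane(self):
        # r = (1 - exp(-2d)) / 2 at d = 1 Morgan
        c = make_chrom(L=100.0)
        g = mm.simulate_gametes(
            c, np.array([0.0, 100.0]), "female", 30_000, np.random.default_rng(1)
        )
        r = np.mean(g[:, 0] != g[:, 1])
        expected = 0.5 * (1 - np.exp(-2.0))
        se = np.sqrt(expected * (1 - expected) / 30_000)
        assert abs(r - expected) < 4 * se

    def test_male_with_zero_telomere_fraction_never_recombines(self):
        c = make_chrom(frac=0.0)
        g = mm.simulate_gametes(
            c, np.array([0.0, 50.0, 100.0]), "male", 2_000, np.random.default_rng(2)
        )
        assert np.all(g == g[:, [0]])

    def test_male_map_shorter_than_female_when_telomere_restricted(self):
        # thinning into telomeric windows leaves 2 * frac of the intensity
        c = make_chrom(L=100.0, frac=0.1)
        rng = np.random.default_rng(3)
        phase = np.array([[0, 0], [1, 1]], dtype=np.int8)
        pos = np.array([0.0, 100.0])
        counts = {"female": 0, "male": 0}
        for sex in counts:
            for _ in range(3_000):
                _, _, xs = mm.simulate_meiosis(c, pos, phase, sex, rng)
                counts[sex] += xs.size
        assert counts["male"] < 0.35 * counts["female"]
        assert counts["male"] > 0.1 * counts["female"]

    def test_empty_marker_list_rejected(self):
        with pytest.raises(ValueError):
            mm.simulate_meiosis(
                make_chrom(), np.empty(0), np.empty((2, 0)), "female",
                np.random.default_rng(0),
            )


class TestDiploidFamily:
    def test_rates_outside_unit_interval_rejected(self, small_genome):
        mother, father = mm.intercross_founders(small_genome)
        for bad in ({"error_rate": 1.5}, {"missing_rate": -0.1}):
            with pytest.raises(ValueError):
                mm.simulate_diploid_family(
                    small_genome, mother, father, 5, np.random.default_rng(0), **bad
                )

    def test_dimensions_match_request(self, small_genome):
        mother, father = mm.intercross_founders(small_genome)
        fam = mm.simulate_diploid_family(
            small_genome, mother, father, 88, np.random.default_rng(0)
        )
        assert fam.n_offspring == 88
        assert fam.mat_origin.shape == (88, small_genome.marker_table().shape[0])

    def test_error_free_offspring_are_mendelian_mosaics(self, small_family):
        # every origin is one of the two parental haplotypes and genotypes
        # are the sum of the transmitted alleles
        assert set(np.unique(small_family.mat_origin)) <= {0, 1}
        geno = small_family.genotypes().to_numpy()
        expect = (small_family.mat_origin + small_family.pat_origin).T
        assert np.array_equal(geno, expect)
        assert set(np.unique(geno)) <= {0, 1, 2}

    def test_intercross_genotype_ratio_one_two_one(self):
        gen = mm.GenomeModel.regular([make_chrom()], 2)
        mother, father = mm.intercross_founders(gen)
        fam = mm.simulate_diploid_family(
            gen, mother, father, 5_000, np.random.default_rng(7)
        )
        geno = fam.genotypes().to_numpy()[0]
        freqs = np.bincount(geno, minlength=3) / geno.size
        se = np.sqrt(0.25 * 0.75 / 5_000)
        assert abs(freqs[0] - 0.25) < 3 * se
        assert abs(freqs[1] - 0.50) < 3 * np.sqrt(0.5 * 0.5 / 5_000)
        assert abs(freqs[2] - 0.25) < 3 * se

    def test_noise_rates_reproduced(self, small_genome):
        mother, father = mm.intercross_founders(small_genome)
        fam = mm.simulate_diploid_family(
            small_genome, mother, father, 200, np.random.default_rng(9),
            error_rate=0.1, missing_rate=0.2,
        )
        miss = np.mean(fam.mat_origin == MISSING)
        assert abs(miss - 0.2) < 0.01
        observed = fam.mat_origin != MISSING
        flips = np.mean(fam.mat_origin[observed] != fam.mat_truth[observed])
        assert abs(flips - 0.1) < 0.01


class TestHalfTetrad:
    def test_offspring_count_validated(self, small_genome):
        mother, _ = mm.intercross_founders(small_genome)
        with pytest.raises(ValueError):
            mm.simulate_half_tetrad_family(
                small_genome, mother, 0, np.random.default_rng(0)
            )

    def test_marker_at_centromere_always_homozygous(self):
        gen = mm.GenomeModel.regular([make_chrom(L=100.0, cen=0.0)], 2)
        mother, _ = mm.intercross_founders(gen)
        ht = mm.simulate_half_tetrad_family(gen, mother, 500, np.random.default_rng(1))
        assert np.all(ht.states[:, 0] != 1)  # marker at the centromere: y = 0

    def test_y_matches_strand_enumeration_oracle(self):
        # markers at 5 and 20 cM from a telocentric centromere
        chrom = make_chrom(L=100.0, cen=0.0, name="h")
        gen = mm.GenomeModel([chrom], {"h": np.array([5.0, 20.0])})
        mother, _ = mm.intercross_founders(gen)
        ht = mm.simulate_half_tetrad_family(
            gen, mother, 20_000, np.random.default_rng(11)
        )
        y = (ht.states == 1).mean(axis=0)
        for j, d in enumerate([0.05, 0.20]):
            expect = y_enumeration_oracle(d)
            se = np.sqrt(expect * (1 - expect) / 20_000)
            assert abs(y[j] - expect) < 4 * se

    def test_y_asymptote_two_thirds(self):
        chrom = make_chrom(L=300.0, cen=0.0, name="h")
        gen = mm.GenomeModel([chrom], {"h": np.array([0.0, 300.0])})
        mother, _ = mm.intercross_founders(gen)
        ht = mm.simulate_half_tetrad_family(
            gen, mother, 8_000, np.random.default_rng(12)
        )
        y_far = (ht.states[:, 1] == 1).mean()
        assert abs(y_far - 2.0 / 3.0) < 3 * np.sqrt(2 / 9 / 8_000) + 0.01

    def test_y_monotone_in_centromere_distance(self):
        chrom = make_chrom(L=200.0, cen=0.0, name="h")
        gen = mm.GenomeModel.regular([chrom], 21)
        mother, _ = mm.intercross_founders(gen)
        ht = mm.simulate_half_tetrad_family(
            gen, mother, 6_000, np.random.default_rng(13)
        )
        y = (ht.states == 1).mean(axis=0)
        assert np.all(np.diff(y) > -0.03)  # non-decreasing within MC error
        assert y.max() < 2.0 / 3.0 + 0.03


class TestPhenotypes:
    def test_homozygote_classes_differ_by_twice_additive(self, small_family):
        trait = mm.TraitModel(
            qtl=[mm.Qtl("chrA", 50.0, additive=1.5)], residual_sd=0.0
        )
        y = mm.simulate_phenotypes(trait, small_family, np.random.default_rng(0))
        classes = np.unique(y)
        assert np.isclose(classes.max() - classes.min(), 3.0)

    def test_null_trait_uncorrelated_with_markers(self, small_family):
        trait = mm.TraitModel(qtl=[], residual_sd=1.0)
        y = mm.simulate_phenotypes(trait, small_family, np.random.default_rng(5))
        geno = small_family.genotypes().to_numpy().astype(float)
        corr = np.array([np.corrcoef(g, y)[0, 1] for g in geno])
        assert np.max(np.abs(corr)) < 5.0 / np.sqrt(small_family.n_offspring)

    def test_target_pve_reached_by_design_helper(self):
        # variance-decomposition oracle: R^2 of trait on true QTL genotype
        gen = mm.GenomeModel.regular([make_chrom()], 3)
        mother, father = mm.intercross_founders(gen)
        fam = mm.simulate_diploid_family(
            gen, mother, father, 4_000, np.random.default_rng(21)
        )
        sd = mm.residual_sd_for_pve(1.0, 0.0, 0.15)
        trait = mm.TraitModel(qtl=[mm.Qtl("c1", 50.0, 1.0)], residual_sd=sd)
        y = mm.simulate_phenotypes(trait, fam, np.random.default_rng(22))
        mid = fam.markers["pos_cM"].sub(50.0).abs().idxmin()
        g = (fam.mat_truth + fam.pat_truth)[:, mid].astype(float)
        r2 = np.corrcoef(g, y)[0, 1] ** 2
        assert abs(r2 - 0.15) < 0.03

    def test_degenerate_binary_trait_rejected(self, small_family):
        trait = mm.TraitModel(qtl=[], residual_sd=0.0, trait_type="binary")
        with pytest.raises(ValueError):
            mm.simulate_phenotypes(trait, small_family, np.random.default_rng(0))
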