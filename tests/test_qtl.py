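"""Genotype probabilities, kinship, scans, peaks, permutations, PVE."""
import numpy as np
import pandas as pd
import pytest

import meiomap as mm
from meiomap.qtl import haldane_r
from meiomap.simulate import MISSING

from conftest import brute_force_normal_scan, make_chrom


class TestPseudomarkers:
    @pytest.mark.parametrize(
        "markers,step,expected",
        [
            ([0.0, 5.0], 1.0, [0, 1, 2, 3, 4, 5]),
            ([0.0, 2.5], 1.0, [0, 1, 2, 2.5]),
            ([0.0, 3.0], 10.0, [0, 3.0]),
        ],
    )
    def test_grid_union(self, markers, step, expected):
        out = mm.insert_pseudomarkers(np.array(markers), step)
        assert np.allclose(out, expected)

    def test_near_duplicates_removed(self):
        out = mm.insert_pseudomarkers(np.array([0.0, 1.0 + 1e-9, 2.0]), 1.0)
        assert out.size == 3

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            mm.insert_pseudomarkers(np.array([0.0, 5.0]), 0.0)


def two_flank_oracle(gl, gr, d1, d2):
    """Exhaustive path enumeration over the unobserved origin."""
    r1, r2 = haldane_r(d1), haldane_r(d2)
    weights = {}
    for o in (0, 1):
        w1 = 1 - r1 if o == gl else r1
        w2 = 1 - r2 if o == gr else r2
        weights[o] = w1 * w2
    z = weights[0] + weights[1]
    return weights[1] / z


class TestGenoprob:
    def grid(self, mat, pat, marker_pos, eval_pos):
        return mm.calc_genoprob(
            np.asarray(mat, dtype=np.int8),
            np.asarray(pat, dtype=np.int8),
            np.asarray(marker_pos, float),
            np.asarray(eval_pos, float),
        )

    def test_degenerate_at_observed_marker(self):
        g = self.grid([[0, 1]], [[1, 1]], [0.0, 10.0], [0.0, 10.0])
        assert np.allclose(g.pm[0], [0.0, 1.0])
        assert np.allclose(g.pp[0], [1.0, 1.0])

    def test_midpoint_matches_path_enumeration(self):
        # pseudomarker midway between identical flanks 10 cM apart
        g = self.grid([[1, 1]], [[0, 0]], [0.0, 10.0], [0.0, 5.0, 10.0])
        expect = two_flank_oracle(1, 1, 5.0, 5.0)
        assert expect == pytest.approx(0.997510, abs=1e-6)
        assert g.pm[0, 1] == pytest.approx(expect, abs=1e-12)
        # discordant flanks
        g2 = self.grid([[1, 0]], [[0, 0]], [0.0, 10.0], [0.0, 2.0, 10.0])
        assert g2.pm[0, 1] == pytest.approx(two_flank_oracle(1, 0, 2.0, 8.0), abs=1e-12)

    def test_missing_flanks_fall_back(self):
        g = self.grid([[MISSING, 1]], [[MISSING, MISSING]], [0.0, 10.0], [0.0, 5.0])
        # maternal: only right flank informative
        assert g.pm[0, 1] == pytest.approx(1 - haldane_r(5.0))
        # paternal: nothing informative -> uniform prior
        assert np.allclose(g.pp[0], 0.5)

    def test_class_probabilities_sum_to_one(self, small_family):
        grid = mm.grid_from_family(small_family, step=1.0)
        probs = grid.class_probs()
        assert probs.min() >= 0
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-12)


class TestKinship:
    def test_self_kinship_is_one(self, small_family):
        grid = mm.grid_from_family(small_family, step=1.0)
        K = mm.calc_kinship(grid)
        assert np.allclose(np.diag(K), 1.0)
        assert np.allclose(K, K.T)

    def test_clone_pair_equals_self_kinship(self):
        gen = mm.GenomeModel.regular([make_chrom()], 20)
        mother, father = mm.intercross_founders(gen)
        fam = mm.simulate_diploid_family(gen, mother, father, 2, np.random.default_rng(0))
        fam.mat_origin[1] = fam.mat_origin[0]
        fam.pat_origin[1] = fam.pat_origin[0]
        K = mm.calc_kinship(mm.grid_from_family(fam), thin_step=3.0)
        assert K[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_full_sib_expectation_matches_enumeration(self, small_family):
        # independent uniform origins: P(same genotype class) = 6/16
        combos = [
            (m1, p1, m2, p2)
            for m1 in (0, 1)
            for p1 in (0, 1)
            for m2 in (0, 1)
            for p2 in (0, 1)
        ]
        expect = np.mean([(m1 + p1) == (m2 + p2) for m1, p1, m2, p2 in combos])
        grid = mm.grid_from_family(small_family, step=1.0)
        K = mm.calc_kinship(grid)
        off_diag = K[np.triu_indices_from(K, k=1)]
        # markers are linked so per-pair values vary; the mean should agree
        assert abs(off_diag.mean() - expect) < 0.02


class TestScanNormal:
    def test_constant_trait_gives_zero_lod(self, small_family):
        grid = mm.grid_from_family(small_family, step=2.0)
        scan = mm.scan_normal(grid, np.full(small_family.n_offspring, 3.0))
        assert np.allclose(scan.lod, 0.0, atol=1e-8)

    def test_matches_brute_force_regression(self, small_family):
        grid = mm.grid_from_family(small_family, step=2.0)
        rng = np.random.default_rng(17)
        y = rng.normal(size=small_family.n_offspring)
        scan = mm.scan_normal(grid, y)
        assert np.allclose(scan.lod, brute_force_normal_scan(grid, y), atol=1e-8)

    def test_detects_planted_qtl(self, small_genome, small_family):
        sd = mm.residual_sd_for_pve(1.0, 0.0, 0.25)
        trait = mm.TraitModel(qtl=[mm.Qtl("chrA", 50.0, 1.0)], residual_sd=sd)
        y = mm.simulate_phenotypes(trait, small_family, np.random.default_rng(3))
        grid = mm.grid_from_family(small_family, step=1.0)
        scan = mm.scan_normal(grid, y)
        peak = scan.positions[np.argmax(scan.lod)]
        assert scan.lgs[np.argmax(scan.lod)] == "chrA"
        assert abs(peak - 50.0) < 15.0

    def test_kinship_scan_close_to_plain_on_sib_design(self, small_family):
        rng = np.random.default_rng(19)
        y = rng.normal(size=small_family.n_offspring)
        grid = mm.grid_from_family(small_family, step=2.0)
        K = mm.calc_kinship(grid)
        scan_k = mm.scan_normal(grid, y, kinship=K)
        scan_p = mm.scan_normal(grid, y)
        assert scan_k.model == "normal+kinship"
        assert np.all(scan_k.lod >= 0)
        # a null trait has no genetic variance: both scans should agree closely
        assert np.corrcoef(scan_k.lod, scan_p.lod)[0, 1] > 0.95


class TestScanBinary:
    def test_null_binary_trait_flat(self, small_family):
        rng = np.random.default_rng(23)
        y = (rng.random(small_family.n_offspring) < 0.5).astype(float)
        grid = mm.grid_from_family(small_family, step=2.0)
        scan = mm.scan_binary(grid, y)
        assert scan.lod.max() < 3.0

    def test_perfect_separation_reaches_clamp(self):
        # marker splitting 50/50 classes: LOD -> n log10 2
        gen = mm.GenomeModel.regular([make_chrom()], 2)
        mother, father = mm.intercross_founders(gen)
        fam = mm.simulate_diploid_family(gen, mother, father, 100, np.random.default_rng(2))
        fam.mat_origin[:50, :] = 0
        fam.mat_origin[50:, :] = 1
        fam.pat_origin[:, :] = 0
        grid = mm.grid_from_family(fam, step=200.0)
        y = np.concatenate([np.zeros(50), np.ones(50)])
        scan = mm.scan_binary(grid, y)
        assert scan.lod.max() == pytest.approx(100 * np.log10(2), rel=1e-4)

    def test_single_class_rejected(self, small_family):
        grid = mm.grid_from_family(small_family, step=5.0)
        with pytest.raises(ValueError):
            mm.scan_binary(grid, np.ones(small_family.n_offspring))


def make_scan(lod, positions=None, lg="LG1", n=100):
    lod = np.asarray(lod, dtype=float)
    positions = np.arange(lod.size, dtype=float) if positions is None else positions
    return mm.ScanResult(
        positions=positions,
        lgs=np.array([lg] * lod.size),
        lod=lod,
        model="normal",
        n=n,
        additive=np.zeros(lod.size),
        dominance=np.zeros(lod.size),
    )


class TestFindPeaks:
    def test_single_peak(self):
        lod = np.full(20, 0.5)
        lod[3] = 6.5
        peaks = mm.find_peaks_ci(make_scan(lod))
        assert len(peaks) == 1
        assert peaks[0].position == 3.0
        assert peaks[0].ci_low <= 3.0 <= peaks[0].ci_high

    def test_shallow_valley_merges_peaks(self):
        lod = np.concatenate(
            [np.linspace(0, 5, 10), np.linspace(5, 4, 5), np.linspace(4, 4.5, 5)]
        )
        peaks = mm.find_peaks_ci(make_scan(lod), threshold=3.0, peakdrop=2.0)
        assert len(peaks) == 1
        assert peaks[0].lod == pytest.approx(5.0)

    def test_deep_valley_separates_peaks(self):
        lod = np.concatenate(
            [np.linspace(0, 5, 10), np.linspace(5, 1, 6), np.linspace(1, 4.5, 6)]
        )
        peaks = mm.find_peaks_ci(make_scan(lod), threshold=3.0, peakdrop=2.0)
        assert len(peaks) == 2

    def test_flat_profile_single_peak_wide_ci(self):
        lod = np.full(100, 3.5)
        peaks = mm.find_peaks_ci(make_scan(lod))
        assert len(peaks) == 1
        width = peaks[0].ci_high - peaks[0].ci_low
        assert width >= 0.9 * 99

    def test_adjacent_cis_get_merge_flag(self):
        lod = np.concatenate(
            [np.linspace(0, 8, 12), np.linspace(8, 1, 10), np.linspace(1, 7.5, 10)]
        )
        peaks = mm.find_peaks_ci(make_scan(lod), threshold=3.0, peakdrop=2.0)
        if len(peaks) == 2 and peaks[0].ci_high >= peaks[1].ci_low:
            assert peaks[0].merge_flag and peaks[1].merge_flag


class TestPermutations:
    def test_null_peak_p_near_half(self, small_family):
        grid = mm.grid_from_family(small_family, step=3.0)
        rng = np.random.default_rng(29)
        y = pd.Series(
            rng.normal(size=small_family.n_offspring), index=small_family.offspring_ids
        )
        scan = mm.scan_normal(grid, y)
        fake_peak = mm.QtlPeak(
            lg="chrA", position=0.0, lod=float(np.median(scan.lod)),
            ci_low=0.0, ci_high=1.0,
        )
        peaks, threshold, maxima = mm.permutation_pvalues(
            lambda yy: mm.scan_normal(grid, yy), y, [fake_peak], n_perm=120,
            rng=np.random.default_rng(30),
        )
        assert 0.5 < peaks[0].p_value <= 1.0  # median of the curve < max
        assert threshold > float(np.median(maxima))

    def test_extreme_peak_floored(self, small_family):
        grid = mm.grid_from_family(small_family, step=5.0)
        rng = np.random.default_rng(31)
        y = pd.Series(
            rng.normal(size=small_family.n_offspring), index=small_family.offspring_ids
        )
        peak = mm.QtlPeak(lg="chrA", position=0.0, lod=80.0, ci_low=0.0, ci_high=1.0)
        peaks, *_ = mm.permutation_pvalues(
            lambda yy: mm.scan_normal(grid, yy), y, [peak], n_perm=100,
            rng=np.random.default_rng(0),
        )
        assert peaks[0].p_value == pytest.approx(1 / 101)
        assert peaks[0].p_label.startswith("<")

    def test_small_n_perm_warns(self, small_family):
        grid = mm.grid_from_family(small_family, step=10.0)
        y = np.random.default_rng(0).normal(size=small_family.n_offspring)
        with pytest.warns(UserWarning, match="n_perm"):
            mm.permutation_pvalues(
                lambda yy: mm.scan_normal(grid, yy), y, [], n_perm=10,
                rng=np.random.default_rng(0),
            )


class TestPve:
    @pytest.mark.parametrize(
        "lod,n,expected",
        [
            (8.538, 323, 0.115),
            (8.04, 323, 0.108),
            (6.563, 143, 0.191),
            (4.855, 143, 0.145),
            (4.401, 179, 0.107),
            (3.796, 179, 0.093),
            (0.0, 100, 0.0),
        ],
    )
    def test_reference_values(self, lod, n, expected):
        assert round(mm.pve(lod, n), 3) == pytest.approx(expected)

    def test_monotonicity(self):
        lods = np.linspace(0, 20, 30)
        vals = [mm.pve(l, 150) for l in lods]
        assert np.all(np.diff(vals) > 0)
        ns = np.arange(10, 400, 25)
        vals_n = [mm.pve(5.0, n) for n in ns]
        assert np.all(np.diff(vals_n) < 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mm.pve(1.0, 0)
        with pytest.raises(ValueError):
            mm.pve(-1.0, 100)
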