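"""Gene dropping and CNV simulation: Mendelian and frequency oracles."""

import numpy as np
import pytest

from omicsim.distributions import PointMass, PointSimplex
from omicsim.fixtures import generate_cnv_profile, generate_reference_panel
from omicsim.genomics import (CNV_COPIES, CNV_STATES, Genotypes, Pedigree,
                              RecombinationMap, cnv_gamete, drop_pedigree,
                              drop_unrelated, sample_gamete, simulate_cnv)


class TestSampleGamete:
    def test_no_recombination_returns_one_parental_haplotype(self, rng):
        a = np.array([0, 0, 0, 0, 1], dtype=np.uint8)
        b = np.array([1, 1, 1, 1, 0], dtype=np.uint8)
        g = sample_gamete(a, b, RecombinationMap.zero(5), rng)
        assert np.array_equal(g, a) or np.array_equal(g, b)

    def test_free_recombination_switches_half_the_intervals(self, rng):
        # with theta = 0.5 each interval is an independent fair coin
        a = np.zeros(21, dtype=np.uint8)
        b = np.ones(21, dtype=np.uint8)
        rmap = RecombinationMap(np.full(20, 0.5))
        switches = []
        for _ in range(500):
            g = sample_gamete(a, b, rmap, rng)
            switches.append(np.mean(np.diff(g.astype(int)) != 0))
        se = np.sqrt(0.25 / (500 * 20))
        assert abs(np.mean(switches) - 0.5) < 4 * se

    def test_homozygous_parent_is_crossover_invariant(self, rng):
        h = np.array([0, 1, 0, 1], dtype=np.uint8)
        rmap = RecombinationMap(np.full(3, 0.5))
        for _ in range(10):
            assert np.array_equal(sample_gamete(h, h, rmap, rng), h)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="length"):
            sample_gamete(np.zeros(4, dtype=np.uint8), np.zeros(4, dtype=np.uint8),
                          RecombinationMap.zero(3), rng)


class TestDropUnrelated:
    def test_monomorphic_panel_gives_homozygous_reference(self, rng):
        panel = generate_reference_panel(10, 0, PointMass(0.2), seed=0)
        panel.matrix = np.zeros((10, 3), dtype=np.uint8)
        panel.variant_ids = ["a", "b", "c"]
        panel.positions = np.array([1, 2, 3])
        panel.alleles = [("A", "G")] * 3
        geno = drop_unrelated(panel, RecombinationMap.zero(3), 20, rng)
        assert not geno.dosage().any()

    def test_allele_frequency_conservation(self, rng):
        panel = generate_reference_panel(2000, 1, PointMass(0.2),
                                         ld_block_length=1, seed=5)
        geno = drop_unrelated(panel, RecombinationMap.zero(1), 10_000, rng)
        f_panel = panel.alt_frequencies()[0]
        f_sample = geno.dosage().mean() / 2
        se = np.sqrt(f_panel * (1 - f_panel) / 20_000)
        assert abs(f_sample - f_panel) < 3 * se

    def test_frequency_conservation_across_all_variants(self, small_panel, zero_rmap):
        geno = drop_unrelated(small_panel, zero_rmap, 5000,
                              np.random.default_rng(42))
        f_panel = small_panel.alt_frequencies()
        f_sample = geno.dosage().mean(axis=0) / 2
        se = np.sqrt(f_panel * (1 - f_panel) / 10_000)
        assert np.all(np.abs(f_sample - f_panel) < 4 * se)

    def test_same_seed_identical_matrix(self, small_panel, zero_rmap):
        a = drop_unrelated(small_panel, zero_rmap, 50, np.random.default_rng(3))
        b = drop_unrelated(small_panel, zero_rmap, 50, np.random.default_rng(3))
        assert np.array_equal(a.paternal, b.paternal)
        assert np.array_equal(a.maternal, b.maternal)

    def test_nonpositive_n_rejected(self, small_panel, zero_rmap, rng):
        with pytest.raises(ValueError):
            drop_unrelated(small_panel, zero_rmap, 0, rng)


TRIO = Pedigree([("f", None, None, 1), ("m", None, None, 2), ("c", "f", "m", 1)])


class TestDropPedigree:
    def test_opposite_homozygotes_force_heterozygous_child(self, rng):
        panel = generate_reference_panel(4, 0, PointMass(0.2), seed=0)
        panel.matrix = np.zeros((4, 5), dtype=np.uint8)
        panel.variant_ids = list("abcde")
        panel.positions = np.arange(1, 6)
        panel.alleles = [("A", "G")] * 5
        rmap = RecombinationMap.zero(5)
        haps = drop_pedigree(panel, rmap, TRIO, rng)
        # rebuild: force father hom-ref, mother hom-alt, redrop the child
        haps["f"] = (np.zeros(5, dtype=np.uint8), np.zeros(5, dtype=np.uint8))
        haps["m"] = (np.ones(5, dtype=np.uint8), np.ones(5, dtype=np.uint8))
        child_pat = sample_gamete(*haps["f"], rmap, rng)
        child_mat = sample_gamete(*haps["m"], rmap, rng)
        assert np.all(child_pat == 0) and np.all(child_mat == 1)

    def test_trio_mendelian_consistency(self, small_panel, rng):
        rmap = RecombinationMap(np.full(small_panel.n_variants - 1, 0.1))
        for _ in range(20):
            haps = drop_pedigree(small_panel, rmap, TRIO, rng)
            for j in range(small_panel.n_variants):
                assert haps["c"][0][j] in (haps["f"][0][j], haps["f"][1][j])
                assert haps["c"][1][j] in (haps["m"][0][j], haps["m"][1][j])

    def test_whole_chromosome_transmission_without_recombination(self, small_panel, rng):
        ped = Pedigree([("gf", None, None, 1), ("gm", None, None, 2),
                        ("f", None, None, 1), ("m", "gf", "gm", 2),
                        ("c", "f", "m", 1)])
        rmap = RecombinationMap.zero(small_panel.n_variants)
        for _ in range(10):
            haps = drop_pedigree(small_panel, rmap, ped, rng)
            # the child's maternal haplotype is one of the mother's intact
            assert any(np.array_equal(haps["c"][1], h) for h in haps["m"])
            # and the mother's haplotypes are intact grandparental ones
            assert any(np.array_equal(haps["m"][0], h) for h in haps["gf"])

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle|unknown"):
            Pedigree([("a", "b", "c", 1), ("b", "a", "c", 1), ("c", None, None, 2)])

    def test_single_parent_rejected(self):
        with pytest.raises(ValueError, match="both"):
            Pedigree([("f", None, None, 1), ("c", "f", None, 1)])


class TestCNV:
    def test_always_normal_profile(self, rng):
        prof = generate_cnv_profile(3, PointSimplex((0, 1, 0, 0)), seed=0)
        cnv = simulate_cnv(prof, 50, rng)
        assert np.all(cnv.s1 == 1) and np.all(cnv.s2 == 1)
        assert np.all(cnv.copy_number() == 2)

    def test_deletion_frequency_recovered(self, rng):
        prof = generate_cnv_profile(1, PointSimplex((0.2, 0.8, 0, 0)), seed=0)
        cnv = simulate_cnv(prof, 10_000, rng)
        f = np.mean(np.concatenate([cnv.s1, cnv.s2]) == 0)
        se = np.sqrt(0.2 * 0.8 / 20_000)
        assert abs(f - 0.2) < 3 * se

    def test_copy_number_matches_exact_convolution(self, rng):
        freqs = (0.1, 0.6, 0.2, 0.1)
        prof = generate_cnv_profile(1, PointSimplex(freqs), seed=0)
        cnv = simulate_cnv(prof, 20_000, rng)
        copies = np.array([0, 1, 2, 3])
        # exact distribution of the sum of two independent per-chromosome draws
        conv = np.zeros(7)
        for i, fi in enumerate(freqs):
            for j, fj in enumerate(freqs):
                conv[copies[i] + copies[j]] += fi * fj
        emp = np.bincount(cnv.copy_number().ravel(), minlength=7) / 20_000
        assert np.all(np.abs(emp - conv) < 4 * np.sqrt(conv * (1 - conv) / 20_000) + 1e-12)

    def test_copy_number_range_and_diplotype_closure(self, rng):
        prof = generate_cnv_profile(4, PointSimplex((0.25, 0.25, 0.25, 0.25)), seed=0)
        cnv = simulate_cnv(prof, 500, rng)
        cn = cnv.copy_number()
        assert cn.min() >= 0 and cn.max() <= 6
        # the 10 unordered state pairs partition all outcomes
        pairs = {tuple(sorted((a, b))) for a, b in
                 zip(cnv.s1.ravel(), cnv.s2.ravel())}
        assert pairs <= {(i, j) for i in range(4) for j in range(i, 4)}

    def test_gamete_from_homozygous_deletion_parent(self, rng):
        prof = generate_cnv_profile(2, PointSimplex((1, 0, 0, 0)), seed=0)
        cnv = simulate_cnv(prof, 1, rng)
        for _ in range(10):
            assert np.all(cnv_gamete(cnv, 0, rng) == 0)

    def test_heterozygous_transmission_is_fair(self, rng):
        prof = generate_cnv_profile(1, PointSimplex((0, 1, 0, 0)), seed=0)
        cnv = simulate_cnv(prof, 1, rng)
        cnv.s1[0, 0] = 0  # force (D, N) parent
        cnv.s2[0, 0] = 1
        draws = np.array([cnv_gamete(cnv, 0, rng)[0] for _ in range(4000)])
        assert set(np.unique(draws)) <= {0, 1}  # closure: always a parental state
        f_d = np.mean(draws == 0)
        assert abs(f_d - 0.5) < 4 * np.sqrt(0.25 / 4000)


def test_state_coding_tables_are_consistent():
    assert [CNV_COPIES[s] for s in CNV_STATES] == [0, 1, 2, 3]
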