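"""RNA-seq simulation: NB moments, eQTL means, ASE splits, eQTM link."""

import numpy as np
import pytest

from omicsim.distributions import PointMass
from omicsim.fixtures import generate_reference_panel, generate_rnaseq_profile
from omicsim.genomics import RecombinationMap, drop_unrelated
from omicsim.transcriptomics import (ASE_READ_FRACTION, CountMatrix, DEGeneSpec,
                                     EQTLSpec, EQTMSpec, apply_eqtm, nb_mean,
                                     sample_count, simulate_ase, simulate_rnaseq,
                                     smoothed_bootstrap_c)
from omicsim.distributions import LogNormal


class TestNBMean:
    def test_lambda_times_c(self):
        assert nb_mean(100.0, 1.2)[0] == pytest.approx(120.0)

    def test_eqtl_genotype_multipliers(self):
        spec = EQTLSpec("s", "g", fold_change=1.5)
        mu_aa = nb_mean(100.0, 1.0, genotype=[2], eqtl=spec)[0]
        mu_het = nb_mean(100.0, 1.0, genotype=[1], eqtl=spec)[0]
        assert mu_het == pytest.approx(150.0)
        assert mu_aa == pytest.approx(200.0)  # (2h - 1) mu

    def test_unit_fold_change_is_identity(self):
        de = DEGeneSpec("g", fold_change=1.0)
        assert nb_mean(50.0, 1.0, is_case=[True], de=de)[0] == pytest.approx(50.0)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            nb_mean(0.0, 1.0)


class TestSampleCount:
    def test_poisson_limit_moments(self, rng):
        x = sample_count(np.full(100_000, 4.0), 0.0, rng)
        assert abs(x.mean() - 4.0) < 0.05
        assert abs(x.var() - 4.0) < 0.15

    def test_nb_variance_inflation(self, rng):
        x = sample_count(np.full(100_000, 100.0), 0.5, rng)
        assert abs(x.mean() - 100.0) < 2.0
        assert abs(x.var() - 5100.0) < 0.1 * 5100.0

    def test_counts_are_nonnegative_integers(self, rng):
        x = sample_count(np.full(1000, 7.3), 0.2, rng)
        assert x.dtype.kind == "i" and x.min() >= 0

    def test_invalid_parameters_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_count(10.0, -0.1, rng)


class TestSmoothedBootstrap:
    def test_degenerate_reference_passes_through(self, rng):
        c = np.ones(10)
        out = smoothed_bootstrap_c(c, 50, rng)
        assert np.all(out == 1.0)  # zero Silverman bandwidth

    def test_mean_preserved_and_positive(self, rng):
        c = rng.lognormal(0.0, 0.3, 80)
        out = smoothed_bootstrap_c(c, 20_000, rng)
        assert out.min() > 0
        assert abs(out.mean() - c.mean()) < 4 * c.std() / np.sqrt(20_000) + 0.05

    def test_plain_resampling_when_reference_suffices(self, rng):
        c = np.array([0.5, 1.0, 2.0])
        out = smoothed_bootstrap_c(c, 3, rng)
        assert set(out) <= set(c)

    def test_empty_reference_rejected(self, rng):
        with pytest.raises(ValueError):
            smoothed_bootstrap_c(np.array([]), 5, rng)


class TestSimulateASE:
    def test_allele_specific_read_total_is_exact(self, rng):
        ref, alt = simulate_ase(10_000, effect_size=1.0, rng=rng)
        assert ref[0] + alt[0] == 50  # round(0.005 * 10000)

    def test_symmetric_split_for_null_effect(self, rng):
        ref, alt = simulate_ase(np.full(5000, 10_000), 0.0, rng=rng)
        frac = alt.sum() / (ref + alt).sum()
        assert abs(frac - 0.5) < 0.02

    def test_effect_size_one_gives_two_thirds_alt(self, rng):
        ref, alt = simulate_ase(np.full(10_000, 10_000), 1.0, rho=0.1, rng=rng)
        frac = alt.sum() / (alt + ref).sum()
        assert abs(frac - 2 / 3) < 0.02  # p = 2^e / (1 + 2^e)

    def test_overdispersion_inflates_variance(self, rng):
        n = np.full(20_000, 10_000)
        _, alt0 = simulate_ase(n, 0.0, rho=0.0, rng=rng)
        _, alt1 = simulate_ase(n, 0.0, rho=0.1, rng=rng)
        v_binom = 50 * 0.25
        assert abs(alt0.var() - v_binom) < 0.1 * v_binom
        assert alt1.var() > 2 * v_binom

    def test_invalid_overdispersion_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_ase(100, 0.0, rho=1.0, rng=rng)


class TestApplyEQTM:
    def test_zero_slope_matches_baseline_nb_moments(self, rng):
        x = rng.random(50_000)
        counts = apply_eqtm(100.0, 0.0, x, 0.05, rng)
        assert abs(counts.mean() - 100.0) < 1.0
        assert abs(counts.var() - (100 + 0.05 * 100 ** 2)) < 0.1 * 600

    def test_ols_recovers_the_slope(self, rng):
        x = rng.random(2000)
        counts = apply_eqtm(100.0, 50.0, x, 0.02, rng)
        slope = np.polyfit(x, counts, 1)[0]
        assert slope == pytest.approx(50.0, abs=6.0)

    def test_floor_prevents_nonpositive_means(self, rng):
        counts = apply_eqtm(10.0, -1000.0, np.ones(100), 0.1, rng)
        assert np.all(counts >= 0)  # mean floored, draws valid


def _labelled_status(n_case, n_ctrl):
    return np.r_[np.ones(n_case, dtype=bool), np.zeros(n_ctrl, dtype=bool)]


class TestSimulateRNASeq:
    def test_null_specs_groups_exchangeable(self, rna_profile, rng):
        status = _labelled_status(200, 200)
        cm = simulate_rnaseq(rna_profile, status, technical_variation=False, rng=rng)
        lib = cm.counts.sum(axis=0).astype(float)
        diff = lib[status].mean() - lib[~status].mean()
        se = np.sqrt(lib[status].var() / 200 + lib[~status].var() / 200)
        assert abs(diff) < 4 * se

    def test_de_fold_change_recovered(self, rna_profile, rng):
        status = _labelled_status(500, 500)
        cm = simulate_rnaseq(rna_profile, status,
                             de=[DEGeneSpec("gene1", 1.5)], rng=rng)
        adj = cm.counts[cm.row("gene1")] / cm.c
        ratio = adj[status].mean() / adj[~status].mean()
        assert ratio == pytest.approx(1.5, rel=0.1)

    def test_eqtl_group_means_ordered_with_ratio(self, rna_profile, rng):
        panel = generate_reference_panel(2000, 1, PointMass(0.4),
                                         ld_block_length=1, seed=2)
        panel.variant_ids = ["eqtl"]
        geno = drop_unrelated(panel, RecombinationMap.zero(1), 4000, rng)
        status = np.zeros(4000, dtype=bool)
        cm = simulate_rnaseq(rna_profile, status,
                             eqtl=[EQTLSpec("eqtl", "gene1", 1.5)],
                             genotypes=geno, technical_variation=False, rng=rng)
        dose = geno.dosage()[:, 0]
        m = [cm.counts[cm.row("gene1"), dose == d].mean() for d in (0, 1, 2)]
        assert m[0] < m[1] < m[2]
        assert m[2] / m[0] == pytest.approx(2 * 1.5 - 1, rel=0.1)

    def test_ase_totals_and_heterozygote_flags(self, rna_profile, rng):
        panel = generate_reference_panel(200, 1, PointMass(0.5),
                                         ld_block_length=1, seed=2)
        panel.variant_ids = ["eqtl"]
        geno = drop_unrelated(panel, RecombinationMap.zero(1), 300, rng)
        cm = simulate_rnaseq(rna_profile, np.zeros(300, dtype=bool),
                             eqtl=[EQTLSpec("eqtl", "gene1", 1.5)],
                             genotypes=geno, technical_variation=False, rng=rng)
        g = cm.row("gene1")
        tot = cm.ase["ref"][0] + cm.ase["alt"][0]
        assert np.array_equal(tot, np.round(ASE_READ_FRACTION * cm.counts[g]))
        assert np.array_equal(cm.ase["het"][0], geno.dosage()[:, 0] == 1)

    def test_conflicting_eqtl_eqtm_specs_rejected(self, rna_profile, rng):
        with pytest.raises(ValueError, match="both"):
            simulate_rnaseq(rna_profile, np.zeros(10, dtype=bool),
                            eqtl=[EQTLSpec("s", "gene1", 1.5)],
                            eqtm=[EQTMSpec("c", ["gene1"], 50, 20)],
                            rng=rng)

    def test_seeded_determinism_of_full_matrix(self, rna_profile):
        status = _labelled_status(50, 50)
        a = simulate_rnaseq(rna_profile, status, de=[DEGeneSpec("gene2", 2.0)],
                            rng=np.random.default_rng(77))
        b = simulate_rnaseq(rna_profile, status, de=[DEGeneSpec("gene2", 2.0)],
                            rng=np.random.default_rng(77))
        assert np.array_equal(a.counts, b.counts)
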