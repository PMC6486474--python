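"""Penetrance codings, ascertainment and prevalence calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from omicsim.distributions import PointMass, PointSimplex
from omicsim.fixtures import generate_cnv_profile
from omicsim.genomics import CNVData, Genotypes, drop_unrelated, simulate_cnv
from omicsim.phenotype import (DiseaseModel, InteractionSpec, MainEffectSpec,
                               ascertain_case_control, assign_affection,
                               beta0_for_prevalence, code_genotype,
                               code_interaction, penetrance)


class TestCodeGenotype:
    @pytest.mark.parametrize("pat,mat,model,expected", [
        (0, 1, "additive", 1), (1, 1, "additive", 2), (0, 0, "additive", 0),
        (0, 1, "dominant", 1), (0, 0, "dominant", 0),
        (1, 1, "recessive", 1), (0, 1, "recessive", 0),
    ])
    def test_standard_codings(self, pat, mat, model, expected):
        assert code_genotype([pat], [mat], model)[0] == expected

    def test_copy_weighted_coding_counts_alleles_across_copies(self):
        # alt allele on a duplicated (U) chromosome, ref on a normal one:
        # the additive coding counts the alt twice
        g = code_genotype([1], [0], "additive",
                          copy_paternal=[2], copy_maternal=[1])
        assert g[0] == 2

    def test_copy_weighted_thresholds(self):
        # het with the alt on a deleted chromosome contributes nothing
        assert code_genotype([1], [0], "dominant",
                             copy_paternal=[0], copy_maternal=[1])[0] == 0
        # recessive reached through one allele on a UU chromosome
        assert code_genotype([1], [0], "recessive",
                             copy_paternal=[3], copy_maternal=[1])[0] == 1

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            code_genotype([1], [0], "overdominant")


class TestCodeInteraction:
    @pytest.mark.parametrize("gm,gn,model,expected", [
        (2, 1, "product", 2), (0, 2, "product", 0),
        (1, 0, "joint_dominant", 0), (2, 1, "joint_dominant", 1),
        (2, 2, "joint_recessive", 1), (2, 1, "joint_recessive", 0),
        (1, 0, "xor", 1), (1, 1, "xor", 0), (0, 0, "xor", 0),
    ])
    def test_models(self, gm, gn, model, expected):
        assert code_interaction([gm], [gn], model)[0] == expected

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            code_interaction([1], [1], "epistatic-magic")


def _geno(pat, mat, ids=None):
    pat = np.asarray(pat, dtype=np.uint8).reshape(1, -1)
    mat = np.asarray(mat, dtype=np.uint8).reshape(1, -1)
    ids = ids or [f"s{i}" for i in range(pat.shape[1])]
    return Genotypes(ids, pat, mat)


class TestPenetrance:
    def test_null_model_returns_baseline(self):
        model = DiseaseModel(beta0=float(logit(0.1)))
        p = penetrance(model, _geno([0], [1]))
        assert p[0] == pytest.approx(0.1, abs=1e-12)

    def test_single_additive_snp_matches_direct_formula(self):
        # hom-alt with OR 1.5: expit(logit(0.1) + 2*ln 1.5)
        model = DiseaseModel(beta0=float(logit(0.1)),
                             mains=[MainEffectSpec("s0", float(np.log(1.5)),
                                                   model="additive")])
        p = penetrance(model, _geno([1], [1]))
        assert p[0] == pytest.approx(expit(logit(0.1) + 2 * np.log(1.5)), abs=1e-12)

    def test_cnv_coding_contribution(self):
        # diplotype (D, N): coding sum -1 + 0, per-copy beta ln(0.67)
        cnv = CNVData(["r1"], np.array([[0]]), np.array([[1]]))
        model = DiseaseModel(beta0=float(logit(0.1)),
                             mains=[MainEffectSpec("r1", float(np.log(0.67)),
                                                   is_cnv=True)])
        p = penetrance(model, cnv=cnv)
        assert p[0] == pytest.approx(expit(logit(0.1) - np.log(0.67) * 1), abs=1e-12) \
            or p[0] == pytest.approx(expit(logit(0.1) + np.log(0.67) * -1), abs=1e-12)

    @given(st.floats(0.01, 0.99), st.floats(-1.5, 1.5))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_positive_beta_coding(self, base, beta):
        model = DiseaseModel(beta0=float(logit(base)),
                             mains=[MainEffectSpec("s0", beta, model="additive")])
        ps = [penetrance(model, _geno([a], [b]))[0]
              for a, b in ((0, 0), (0, 1), (1, 1))]
        if beta > 1e-6:
            assert ps[0] < ps[1] < ps[2]
        elif beta < -1e-6:
            assert ps[0] > ps[1] > ps[2]


class TestAssignAffection:
    def test_boundary_probabilities_rejected(self, rng):
        with pytest.raises(ValueError):
            assign_affection([0.0], rng)
        with pytest.raises(ValueError):
            assign_affection([1.0], rng)

    def test_half_probability_case_fraction(self, rng):
        status = assign_affection(np.full(10_000, 0.5), rng)
        assert abs(status.mean() - 0.5) < 4 * np.sqrt(0.25 / 10_000)

    def test_seeded_determinism(self):
        a = assign_affection(np.full(100, 0.3), np.random.default_rng(5))
        b = assign_affection(np.full(100, 0.3), np.random.default_rng(5))
        assert np.array_equal(a, b)


def _sampler(panel, rmap):
    def sample(n, rng):
        return drop_unrelated(panel, rmap, n, rng), None
    return sample


class TestAscertainment:
    def test_quota_exactness_and_draw_count(self, small_panel, zero_rmap):
        model = DiseaseModel(beta0=0.0)  # prevalence 0.5
        rng = np.random.default_rng(17)
        cohort = ascertain_case_control(_sampler(small_panel, zero_rmap), model,
                                        200, 200, rng, batch=100)
        assert cohort.status.sum() == 200
        assert (~cohort.status).sum() == 200
        assert abs(cohort.prevalence_among_draws - 0.5) < 0.1

    def test_null_model_gives_exchangeable_genotypes(self, small_panel, zero_rmap):
        model = DiseaseModel(beta0=float(logit(0.3)))
        rng = np.random.default_rng(23)
        cohort = ascertain_case_control(_sampler(small_panel, zero_rmap), model,
                                        800, 800, rng)
        dos = cohort.genotypes.dosage()
        case_f = dos[cohort.status].mean(axis=0) / 2
        ctrl_f = dos[~cohort.status].mean(axis=0) / 2
        pool = dos.mean(axis=0) / 2
        se = np.sqrt(pool * (1 - pool) * (1 / 1600 + 1 / 1600))
        assert np.all(np.abs(case_f - ctrl_f) < 4 * se)

    def test_degenerate_model_raises(self, small_panel, zero_rmap):
        model = DiseaseModel(beta0=-30.0)  # prevalence ~ 1e-13
        with pytest.raises(RuntimeError, match="max_draws"):
            ascertain_case_control(_sampler(small_panel, zero_rmap), model, 5, 5,
                                   np.random.default_rng(1), max_draws=2000)


class TestBeta0Calibration:
    def test_null_model_closed_form(self, small_panel, zero_rmap):
        model = DiseaseModel(beta0=0.0)
        b0 = beta0_for_prevalence(0.1, model, _sampler(small_panel, zero_rmap),
                                  np.random.default_rng(2))
        assert b0 == pytest.approx(float(logit(0.1)), abs=1e-12)

    def test_recovers_target_with_a_risk_snp(self, small_panel, zero_rmap):
        snp = small_panel.variant_ids[0]
        model = DiseaseModel(beta0=0.0,
                             mains=[MainEffectSpec(snp, float(np.log(1.5)),
                                                   model="additive")])
        rng = np.random.default_rng(31)
        b0 = beta0_for_prevalence(0.1, model, _sampler(small_panel, zero_rmap),
                                  rng, n_mc=30_000)
        model.beta0 = b0
        geno, _ = _sampler(small_panel, zero_rmap)(30_000, np.random.default_rng(99))
        assert np.mean(penetrance(model, geno)) == pytest.approx(0.1, abs=0.005)

    def test_monotone_in_target(self, small_panel, zero_rmap):
        snp = small_panel.variant_ids[0]
        model = DiseaseModel(beta0=0.0,
                             mains=[MainEffectSpec(snp, 0.4, model="additive")])
        b_lo = beta0_for_prevalence(0.05, model, _sampler(small_panel, zero_rmap),
                                    np.random.default_rng(7), n_mc=5000)
        b_hi = beta0_for_prevalence(0.2, model, _sampler(small_panel, zero_rmap),
                                    np.random.default_rng(7), n_mc=5000)
        assert b_hi > b_lo
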