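"""Declarative scenario configurations and the end-to-end pipeline.

A :class:`ScenarioConfig` declares every layer of a simulation — panel and
profile fixture parameters, the disease architecture (causal SNPs/CNVs with
odds ratios and interactions), differential methylation/expression and the
meQTL/eQTL/eQTM links, sample sizes and seeds. Two builders ship ready-made
architectures:

* :func:`build_breast_cancer_scenario` — a hypothetical breast-cancer
  pathway: a protective deletion (OR 0.67, frequency 20%), three common
  risk SNPs (ORs 1.5), three sets of five rare variants interacting
  (ORs 5) with an meQTL SNP, a cis-eQTL SNP and a regulatory SNP, a 10%
  case-control methylation difference at the meQTL CpG, and fold change 1.5
  for both the eQTL and case-control differential expression of one gene.
* :func:`build_ov_scenario` — an ovarian-cancer-scale survival model: one
  low-methylated CpG (2.0% short-term vs 2.3% long-term survivors) acting
  as an eQTM on three genes (slopes Normal(50, 20), fold change 0.6
  short/long) plus an independently differential gene (fold change 2),
  across 2,884 CNV regions, 2,753 CpGs, 12,004 genes and 200 proteins.

Configs are plain data: they serialize to YAML and re-parse identically.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from ._rng import module_rng
from . import fixtures as fx
from .distributions import Gamma, LogNormal
from .genomics import CNVData, Genotypes, RecombinationMap, drop_unrelated, simulate_cnv
from .methylation import (DifferentialMethylationSpec, MeQTLSpec, MethylationData,
                          methylation_proportion, simulate_wgbs)
from .phenotype import (DiseaseModel, InteractionSpec, MainEffectSpec,
                        ascertain_case_control, beta0_for_prevalence)
from .proteomics import ProteinMatrix, simulate_protein
from .transcriptomics import CountMatrix, DEGeneSpec, EQTLSpec, EQTMSpec, simulate_rnaseq


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SampleSizes(_Model):
    training_cases: int = 500
    training_controls: int = 500
    validation_cases: int = 100
    validation_controls: int = 100


class SnpRole(_Model):
    name: str
    maf: float = Field(gt=0, le=0.5)


class PanelConfig(_Model):
    n_haplotypes: int = 1000
    n_filler: int = 10  # neutral variants beyond the named roles
    ld_block_length: int = 10
    maf_low: float = 0.05
    maf_high: float = 0.5
    mutation_rate: float = 0.05
    recombination_rate_per_bp: float = 1e-8  # Morgans per bp (Haldane map)
    roles: list[SnpRole] = Field(default_factory=list)


class CnvConfig(_Model):
    n_regions: int = 1
    # causal region (first region) state frequencies (f_D, f_N, f_U, f_UU)
    causal_freqs: tuple[float, float, float, float] | None = None
    # neutral regions draw frequencies from a Dirichlet with this alpha
    background_alpha: tuple[float, float, float, float] = (2.0, 30.0, 2.0, 1.0)
    region_length: int = 10_000


class CnvMainConfig(_Model):
    region: str
    odds_ratio: float = Field(gt=0)


class SnpMainConfig(_Model):
    snp: str
    model: str = "additive"
    odds_ratio: float = Field(gt=0)


class InteractionConfig(_Model):
    snp_m: str
    snp_n: str
    model: str = "product"
    odds_ratio: float = Field(gt=0)


class DiseaseConfig(_Model):
    prevalence: float = Field(default=0.1, gt=0, lt=1)
    cnv_mains: list[CnvMainConfig] = Field(default_factory=list)
    snp_mains: list[SnpMainConfig] = Field(default_factory=list)
    interactions: list[InteractionConfig] = Field(default_factory=list)


class DMConfig(_Model):
    delta: float
    cpg_ids: list[str] | None = None
    p_methylated: float = 0.0
    p_unmethylated: float = 0.0
    p_partial: float = 0.0


class MeQTLConfig(_Model):
    snp: str
    cpg_ids: list[str]
    ratio: float = Field(gt=0)


class MethylationConfig(_Model):
    n_cpgs: int = 688
    depth_mean: float = 30.0
    depth_dispersion: float = 0.1
    status_mix: tuple[float, float, float] = (0.3, 0.5, 0.2)
    override_rates: dict[str, float] = Field(default_factory=dict)
    dm: DMConfig | None = None
    meqtl: MeQTLConfig | None = None


class DEConfig(_Model):
    gene: str
    fold_change: float = Field(gt=0)


class EQTLConfig(_Model):
    snp: str
    gene: str
    fold_change: float = Field(gt=0.5)
    cis: bool = True


class EQTMConfig(_Model):
    cpg: str
    genes: list[str]
    beta_mean: float
    beta_sd: float = Field(ge=0)


class RnaseqConfig(_Model):
    n_genes: int = 100
    n_ref_samples: int = 100
    lambda_log_mean: float = 5.3  # log-scale mean of per-gene lambda
    lambda_log_sd: float = 1.0
    omega_shape: float = 2.0
    omega_scale: float = 0.1
    c_log_sd: float = 0.15  # c ~ LogNormal(0, sd), centered near 1
    technical_variation: bool = True
    de: list[DEConfig] = Field(default_factory=list)
    eqtl: list[EQTLConfig] = Field(default_factory=list)
    eqtm: list[EQTMConfig] = Field(default_factory=list)


class ProteinConfig(_Model):
    n_proteins: int = 100
    tau_log_mean: float = -1.6  # tau ~ LogNormal, median ~0.2
    tau_log_sd: float = 0.3
    kappa_s: float = 1.0
    kappa_d: float = 1.0
    n_steps: int = 10


class ScenarioConfig(_Model):
    name: str
    seed: int = 1
    samples: SampleSizes = Field(default_factory=SampleSizes)
    panel: PanelConfig = Field(default_factory=PanelConfig)
    cnv: CnvConfig = Field(default_factory=CnvConfig)
    disease: DiseaseConfig | None = None
    methylation: MethylationConfig = Field(default_factory=MethylationConfig)
    rnaseq: RnaseqConfig = Field(default_factory=RnaseqConfig)
    protein: ProteinConfig = Field(default_factory=ProteinConfig)

    def to_yaml(self) -> str:
        return yaml.safe_dump(json.loads(self.model_dump_json()), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ScenarioConfig":
        return cls.model_validate(yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]


def _deep_merge(base: dict, overrides: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in overrides.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def _with_overrides(base: ScenarioConfig, overrides: dict | None) -> ScenarioConfig:
    if not overrides:
        return base
    return ScenarioConfig.model_validate(
        _deep_merge(json.loads(base.model_dump_json()), overrides))


# ---------------------------------------------------------------------------
# shipped scenarios

RARE_SETS = {"comt": "meqtl_snp", "gstm": "eqtl_snp", "gstt": "reg_snp"}


def build_breast_cancer_scenario(overrides: dict | None = None) -> ScenarioConfig:
    """Hypothetical breast-cancer pathway architecture (fixture scale)."""
    roles = [SnpRole(name=f"common{i}", maf=0.2) for i in (1, 2, 3)]
    for prefix in RARE_SETS:
        roles += [SnpRole(name=f"{prefix}{i}", maf=0.02) for i in range(1, 6)]
    roles += [SnpRole(name=n, maf=0.3) for n in ("meqtl_snp", "eqtl_snp", "reg_snp")]

    interactions = [
        InteractionConfig(snp_m=f"{prefix}{i}", snp_n=partner, odds_ratio=5.0)
        for prefix, partner in RARE_SETS.items() for i in range(1, 6)
    ]
    cfg = ScenarioConfig(
        name="breast_cancer",
        samples=SampleSizes(training_cases=500, training_controls=500,
                            validation_cases=100, validation_controls=100),
        # causal roles live in distinct genes, so keep them unlinked: every
        # variant is its own LD block and penetrance terms stay separately
        # identifiable when the model is refit
        panel=PanelConfig(roles=roles, ld_block_length=1),
        cnv=CnvConfig(n_regions=1, causal_freqs=(0.2, 0.8, 0.0, 0.0)),
        disease=DiseaseConfig(
            prevalence=0.1,
            cnv_mains=[CnvMainConfig(region="cnv1", odds_ratio=0.67)],
            snp_mains=[SnpMainConfig(snp=f"common{i}", odds_ratio=1.5)
                       for i in (1, 2, 3)],
            interactions=interactions,
        ),
        methylation=MethylationConfig(
            n_cpgs=688,
            override_rates={"cpg1": 0.4},
            dm=DMConfig(delta=0.10, cpg_ids=["cpg1"]),
            meqtl=MeQTLConfig(snp="meqtl_snp", cpg_ids=["cpg1"], ratio=1.2),
        ),
        rnaseq=RnaseqConfig(
            n_genes=100,
            de=[DEConfig(gene="gene1", fold_change=1.5)],
            eqtl=[EQTLConfig(snp="eqtl_snp", gene="gene1", fold_change=1.5)],
        ),
        protein=ProteinConfig(n_proteins=100),
    )
    return _with_overrides(cfg, overrides)


def scenario3_sizes() -> dict:
    """Override dict for the larger-sample variant of the breast-cancer run."""
    return {"samples": {"training_cases": 1500, "training_controls": 1500,
                        "validation_cases": 500, "validation_controls": 500}}


def build_ov_scenario(overrides: dict | None = None) -> ScenarioConfig:
    """Ovarian-cancer-scale survival scenario (short- vs long-term groups).

    The 'case' label is short-term survival. The eQTM CpG's profile rate is
    the long-term (control) rate 2.3%; the case delta of -0.3 percentage
    points yields the 2.0% short-term rate.
    """
    eqtm_genes = ["gene1", "gene2", "gene3"]
    cfg = ScenarioConfig(
        name="ov",
        samples=SampleSizes(training_cases=500, training_controls=500,
                            validation_cases=0, validation_controls=0),
        panel=PanelConfig(n_haplotypes=500, n_filler=10, roles=[]),
        cnv=CnvConfig(n_regions=2884),
        disease=None,  # survival groups are assigned, not ascertained
        methylation=MethylationConfig(
            n_cpgs=2753, depth_mean=50.0,
            override_rates={"cpg1": 0.023},
            dm=DMConfig(delta=-0.003, cpg_ids=["cpg1"]),
        ),
        rnaseq=RnaseqConfig(
            n_genes=12_004, n_ref_samples=173,
            de=[DEConfig(gene=g, fold_change=0.6) for g in eqtm_genes]
               + [DEConfig(gene="gene4", fold_change=2.0)],
            eqtm=[EQTMConfig(cpg="cpg1", genes=eqtm_genes,
                             beta_mean=50.0, beta_sd=20.0)],
        ),
        protein=ProteinConfig(n_proteins=200),
    )
    return _with_overrides(cfg, overrides)


def ov_scaled(factor: int = 10, overrides: dict | None = None) -> ScenarioConfig:
    """The OV scenario with layer dimensions divided by ``factor``."""
    base = {"cnv": {"n_regions": max(2884 // factor, 1)},
            "methylation": {"n_cpgs": max(2753 // factor, 4)},
            "rnaseq": {"n_genes": max(12_004 // factor, 8)},
            "protein": {"n_proteins": max(200 // factor, 2)}}
    return build_ov_scenario(_deep_merge(base, overrides or {}))


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class ScenarioFixtures:
    panel: fx.HaplotypePanel
    rmap: RecombinationMap
    cnv_profile: fx.CNVProfile
    meth_profile: fx.MethylationProfile
    rna_profile: fx.RNAProfile
    protein_profile: fx.ProteinProfile


@dataclass
class CohortOmics:
    """One cohort's aligned multi-omics output."""

    status: np.ndarray  # True = case / short-term group
    genotypes: Genotypes | None
    cnv: CNVData | None
    methylation: MethylationData | None
    expression: CountMatrix | None
    proteins: ProteinMatrix | None
    prevalence_among_draws: float | None = None

    @property
    def n(self) -> int:
        return self.status.size


@dataclass
class OmicsDataset:
    config: ScenarioConfig
    seed: int
    disease_model: DiseaseModel | None
    fixtures: ScenarioFixtures
    training: CohortOmics
    validation: CohortOmics | None


def build_fixtures(config: ScenarioConfig, seed: int) -> ScenarioFixtures:
    """Generate every reference object the scenario needs, deterministically."""
    rng = module_rng(seed, "fixtures")
    pc = config.panel
    role_names = [r.name for r in pc.roles]
    role_mafs = [r.maf for r in pc.roles]
    filler_mafs = rng.uniform(pc.maf_low, pc.maf_high, pc.n_filler)
    mafs = np.concatenate([role_mafs, filler_mafs]) if role_names else filler_mafs
    n_variants = mafs.size
    panel = fx.generate_reference_panel(
        pc.n_haplotypes, n_variants,
        maf_spectrum=_FixedSpectrum(mafs),
        ld_block_length=pc.ld_block_length,
        mutation_rate=pc.mutation_rate,
        seed=rng,
    )
    panel.variant_ids = role_names + [f"snp{i + 1}" for i in range(pc.n_filler)]
    rmap = RecombinationMap.from_rate_per_bp(pc.recombination_rate_per_bp, panel.positions)

    cc = config.cnv
    cnv_profile = fx.generate_cnv_profile(
        cc.n_regions, freq_law=_CnvFreqLaw(cc.causal_freqs, cc.background_alpha),
        region_length=cc.region_length, seed=rng)

    mc = config.methylation
    meth_profile = fx.generate_methylation_profile(
        mc.n_cpgs, status_mix=mc.status_mix, depth_mean=mc.depth_mean,
        depth_dispersion=mc.depth_dispersion, seed=rng)
    for cid, rate in mc.override_rates.items():
        j = meth_profile.cpg_ids.index(cid)
        meth_profile.rate[j] = rate
        meth_profile.status[j] = next(
            st for st, (lo, hi) in fx.STATUS_BANDS.items() if lo <= rate <= hi)

    rc = config.rnaseq
    rna_profile = fx.generate_rnaseq_profile(
        rc.n_genes, rc.n_ref_samples,
        lambda_law=LogNormal(rc.lambda_log_mean, rc.lambda_log_sd),
        omega_law=Gamma(rc.omega_shape, rc.omega_scale),
        c_law=LogNormal(0.0, rc.c_log_sd), seed=rng)
    # the pipeline addresses configured genes by id, so keep profile ids aligned
    rna_profile.gene_ids = [f"gene{i + 1}" for i in range(rc.n_genes)]

    pr = config.protein
    protein_profile = fx.generate_protein_profile(
        pr.n_proteins, tau_law=LogNormal(pr.tau_log_mean, pr.tau_log_sd),
        kappa_s=pr.kappa_s, kappa_d=pr.kappa_d, n_steps=pr.n_steps, seed=rng)

    return ScenarioFixtures(panel, rmap, cnv_profile, meth_profile,
                            rna_profile, protein_profile)


class _FixedSpectrum:
    """Per-variant target MAFs (roles first, then filler)."""

    def __init__(self, mafs):
        self.mafs = np.asarray(mafs, dtype=float)

    def sample(self, rng, size):
        if size != self.mafs.size:
            raise ValueError("spectrum length mismatch")
        return self.mafs.copy()


class _CnvFreqLaw:
    """First region pinned to the causal frequencies, rest Dirichlet."""

    def __init__(self, causal_freqs, alpha):
        self.causal = causal_freqs
        self.alpha = np.asarray(alpha, dtype=float)

    def sample(self, rng, size):
        out = rng.dirichlet(self.alpha, size)
        if self.causal is not None and size >= 1:
            out[0] = np.asarray(self.causal, dtype=float)
        return out


def build_disease_model(config: ScenarioConfig, fixtures_: ScenarioFixtures,
                        seed: int) -> DiseaseModel | None:
    """Translate the disease config into penetrance terms (OR -> log-odds)
    and calibrate the baseline for the target prevalence by Monte Carlo."""
    dc = config.disease
    if dc is None:
        return None
    mains = [MainEffectSpec(target=m.region, beta=float(np.log(m.odds_ratio)), is_cnv=True)
             for m in dc.cnv_mains]
    mains += [MainEffectSpec(target=m.snp, beta=float(np.log(m.odds_ratio)), model=m.model)
              for m in dc.snp_mains]
    interactions = [InteractionSpec(snp_m=i.snp_m, snp_n=i.snp_n,
                                    beta=float(np.log(i.odds_ratio)), model=i.model)
                    for i in dc.interactions]
    model = DiseaseModel(beta0=0.0, mains=mains, interactions=interactions)
    rng = module_rng(seed, "phenotype")
    sampler = make_genome_sampler(fixtures_)
    model.beta0 = beta0_for_prevalence(dc.prevalence, model, sampler, rng, n_mc=20_000)
    return model


def make_genome_sampler(fixtures_: ScenarioFixtures):
    """Population sampler: (Genotypes, CNVData) for n fresh individuals."""

    def sampler(n, rng):
        geno = drop_unrelated(fixtures_.panel, fixtures_.rmap, n, rng)
        cnv = simulate_cnv(fixtures_.cnv_profile, n, rng)
        return geno, cnv

    return sampler


def _simulate_cohort(config: ScenarioConfig, fixtures_: ScenarioFixtures,
                     model: DiseaseModel | None, n_cases: int, n_controls: int,
                     geno_rng, layer_seed: int, tag: str) -> CohortOmics:
    sampler = make_genome_sampler(fixtures_)
    if model is not None:
        cohort = ascertain_case_control(sampler, model, n_cases, n_controls, geno_rng)
        geno, cnv, status = cohort.genotypes, cohort.cnv, cohort.status
        prevalence = cohort.prevalence_among_draws
    else:
        n = n_cases + n_controls
        geno, cnv = sampler(n, geno_rng)
        status = np.zeros(n, dtype=bool)
        status[:n_cases] = True
        prevalence = None

    mc = config.methylation
    meth_rng = module_rng(layer_seed, "methylation")
    dm = None
    if mc.dm is not None:
        dm = DifferentialMethylationSpec(
            delta=mc.dm.delta, cpg_ids=mc.dm.cpg_ids,
            p_methylated=mc.dm.p_methylated, p_unmethylated=mc.dm.p_unmethylated,
            p_partial=mc.dm.p_partial)
    meqtl = None
    if mc.meqtl is not None:
        meqtl = MeQTLSpec(snp_id=mc.meqtl.snp, cpg_ids=mc.meqtl.cpg_ids,
                          ratio=mc.meqtl.ratio)
    meth = simulate_wgbs(fixtures_.meth_profile, status, genotypes=geno,
                         dm=dm, meqtl=meqtl, rng=meth_rng)

    rc = config.rnaseq
    rna_rng = module_rng(layer_seed, "transcriptomics")
    meth_props = {s.cpg: methylation_proportion(meth, s.cpg) for s in rc.eqtm}
    expr = simulate_rnaseq(
        fixtures_.rna_profile, status,
        de=[DEGeneSpec(s.gene, s.fold_change) for s in rc.de],
        eqtl=[EQTLSpec(s.snp, s.gene, s.fold_change, cis=s.cis) for s in rc.eqtl],
        eqtm=[EQTMSpec(s.cpg, s.genes, s.beta_mean, s.beta_sd) for s in rc.eqtm],
        genotypes=geno, methylation_proportions=meth_props,
        technical_variation=rc.technical_variation, rng=rna_rng)

    prot_rng = module_rng(layer_seed, "proteomics")
    proteins = simulate_protein(expr, fixtures_.protein_profile, rng=prot_rng)

    return CohortOmics(status=status, genotypes=geno, cnv=cnv, methylation=meth,
                       expression=expr, proteins=proteins,
                       prevalence_among_draws=prevalence)


def run_scenario(config: ScenarioConfig, seed: int | None = None) -> OmicsDataset:
    """Run the full multi-omics pipeline for a scenario configuration."""
    seed = config.seed if seed is None else seed
    fixtures_ = build_fixtures(config, seed)
    model = build_disease_model(config, fixtures_, seed)
    geno_rng = module_rng(seed, "genomics")
    ss = config.samples
    training = _simulate_cohort(config, fixtures_, model, ss.training_cases,
                                ss.training_controls, geno_rng, seed, "training")
    validation = None
    if ss.validation_cases > 0 and ss.validation_controls > 0:
        validation = _simulate_cohort(config, fixtures_, model, ss.validation_cases,
                                      ss.validation_controls, geno_rng, seed + 1,
                                      "validation")
    return OmicsDataset(config=config, seed=seed, disease_model=model,
                        fixtures=fixtures_, training=training, validation=validation)
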