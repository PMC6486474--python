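"""Scenario-level parameter recovery.

Each function simulates the relevant layer under a scenario configuration
and estimates a configured parameter back from the output. ``omicsim
validate`` wraps :func:`recover_scenario`, which assembles them into a
recovery-report table. Layers are simulated exactly the way the pipeline
simulates them; the estimators come from :mod:`omicsim.validation`.

Design-layer recoveries (odds ratios) refit the logistic penetrance using
the same codings that generated the data — the identifiability condition
for case-control sampling, whose intercept absorbs the ascertainment.
"""

from __future__ import annotations

import numpy as np

from ._rng import as_rng, module_rng
from .distributions import Uniform
from .genomics import simulate_cnv
from .methylation import DifferentialMethylationSpec, MeQTLSpec, simulate_wgbs
from .phenotype import ascertain_case_control, design_matrix
from .scenarios import (ScenarioConfig, build_disease_model, build_fixtures,
                        make_genome_sampler)
from .transcriptomics import (ASE_OVERDISPERSION, ASE_READ_FRACTION, DEGeneSpec,
                              EQTLSpec, EQTMSpec, apply_eqtm, simulate_ase,
                              simulate_rnaseq)
from .validation import (RecoveryReport, empirical_state_frequency,
                         estimate_eqtm_slopes, estimate_fold_change,
                         estimate_methylation_difference, estimate_or,
                         fit_beta_binomial_ci, within_relative, within_se)


def recover_cnv_state_frequency(config: ScenarioConfig, seed: int,
                                n: int = 10_000, region: str = "cnv1",
                                state: str = "D") -> dict:
    """Empirical per-chromosome state frequency in an unascertained sample."""
    fx_ = build_fixtures(config, seed)
    rng = module_rng(seed, "genomics")
    cnv = simulate_cnv(fx_.cnv_profile, n, rng)
    est = empirical_state_frequency(cnv, region, state)
    reg = next(r for r in fx_.cnv_profile.regions if r.region_id == region)
    from .genomics import CNV_STATES
    conf = reg.state_freqs[CNV_STATES.index(state)]
    se = float(np.sqrt(conf * (1 - conf) / (2 * n)))
    return {"configured": float(conf), "estimate": est, "se": se, "n": n}


def recover_odds_ratios(config: ScenarioConfig, seed: int, n_cases: int = 2000,
                        n_controls: int = 2000) -> dict:
    """Ascertain a case-control sample and refit every generating term.

    Returns {term name: (configured OR, estimated OR, SE of log OR)}.
    """
    fx_ = build_fixtures(config, seed)
    model = build_disease_model(config, fx_, seed)
    if model is None:
        raise ValueError("scenario has no disease model")
    rng = module_rng(seed, "phenotype")
    cohort = ascertain_case_control(make_genome_sampler(fx_), model,
                                    n_cases, n_controls, rng)
    X, names = design_matrix(model, cohort.genotypes, cohort.cnv)
    betas = ([m.beta for m in model.cnv_mains] + [m.beta for m in model.snp_mains]
             + [it.beta for it in model.interactions])
    out = {}
    for k, (name, beta) in enumerate(zip(names, betas)):
        orhat, se = estimate_or(X, cohort.status, k)
        out[name] = (float(np.exp(beta)), orhat, se)
    return out


def recover_methylation_difference(config: ScenarioConfig, seed: int,
                                   n_cases: int = 500, n_controls: int = 500) -> dict:
    """Simulate the methylation layer for labelled (unascertained) groups and
    estimate the case-minus-control proportion difference at the DM CpG."""
    mc = config.methylation
    if mc.dm is None or not mc.dm.cpg_ids:
        raise ValueError("scenario configures no differential CpG")
    fx_ = build_fixtures(config, seed)
    n = n_cases + n_controls
    status = np.zeros(n, dtype=bool)
    status[:n_cases] = True
    rng = module_rng(seed, "genomics")
    geno = None
    meqtl = None
    if mc.meqtl is not None:
        from .genomics import drop_unrelated
        geno = drop_unrelated(fx_.panel, fx_.rmap, n, rng)
        meqtl = MeQTLSpec(mc.meqtl.snp, mc.meqtl.cpg_ids, mc.meqtl.ratio)
    dm = DifferentialMethylationSpec(delta=mc.dm.delta, cpg_ids=mc.dm.cpg_ids)
    data = simulate_wgbs(fx_.meth_profile, status, genotypes=geno, dm=dm,
                         meqtl=meqtl, rng=module_rng(seed, "methylation"))
    cpg = mc.dm.cpg_ids[0]
    diff, se = estimate_methylation_difference(data, cpg, status)
    return {"configured": mc.dm.delta, "estimate": diff, "se": se, "n": n,
            "cpg": cpg, "data": data, "status": status}


def recover_expression_fold_changes(config: ScenarioConfig, seed: int,
                                    n_cases: int = 500, n_controls: int = 500) -> dict:
    """Simulate the RNA-seq layer for labelled groups and estimate each DE
    gene's ratio of c-adjusted group means (cases / controls)."""
    rc = config.rnaseq
    if not rc.de:
        raise ValueError("scenario configures no DE genes")
    fx_ = build_fixtures(config, seed)
    n = n_cases + n_controls
    status = np.zeros(n, dtype=bool)
    status[:n_cases] = True
    geno = None
    if rc.eqtl:
        from .genomics import drop_unrelated
        geno = drop_unrelated(fx_.panel, fx_.rmap, n, module_rng(seed, "genomics"))
    meth_props = {}
    if rc.eqtm:
        from .methylation import methylation_proportion
        if config.methylation.dm is None:
            raise ValueError("eQTM needs a simulated methylation layer")
        mdict = recover_methylation_difference(config, seed, n_cases, n_controls)
        for s in rc.eqtm:
            meth_props[s.cpg] = methylation_proportion(mdict["data"], s.cpg)
    expr = simulate_rnaseq(
        fx_.rna_profile, status,
        de=[DEGeneSpec(s.gene, s.fold_change) for s in rc.de],
        eqtl=[EQTLSpec(s.snp, s.gene, s.fold_change, cis=s.cis) for s in rc.eqtl],
        eqtm=[EQTMSpec(s.cpg, s.genes, s.beta_mean, s.beta_sd) for s in rc.eqtm],
        genotypes=geno, methylation_proportions=meth_props,
        technical_variation=rc.technical_variation,
        rng=module_rng(seed, "transcriptomics"))
    out = {}
    for s in rc.de:
        est = estimate_fold_change(expr.counts[expr.row(s.gene)], status, expr.c)
        out[s.gene] = (s.fold_change, est)
    return out


def recover_ase_fraction(total_count: int = 10_000, effect_size: float = 1.0,
                         seed: int = 0) -> float:
    """Fraction of a gene's reads emitted as allele-specific reads."""
    ref, alt = simulate_ase(total_count, effect_size, rng=as_rng(seed))
    return float((ref[0] + alt[0]) / total_count)


def recover_ase_overdispersion(n_obs: int = 5000, reads_each: int = 50,
                               effect_size: float = 0.0,
                               rho: float = ASE_OVERDISPERSION, seed: int = 0) -> dict:
    """Simulate allele-specific splits and refit the beta-binomial by MLE."""
    rng = as_rng(seed)
    totals = np.full(n_obs, int(round(reads_each / ASE_READ_FRACTION)))
    ref, alt = simulate_ase(totals, effect_size, rho=rho, rng=rng)
    fit = fit_beta_binomial_ci(alt, ref + alt)
    fit.update({"configured": rho, "n": n_obs})
    return fit


def recover_eqtm_slope_mean(beta_mean: float = 50.0, beta_sd: float = 20.0,
                            n_genes: int = 200, n: int = 1000,
                            alpha: float = 200.0, phi: float = 0.05,
                            seed: int = 0) -> dict:
    """Simulate eQTM genes with methylation proportions spanning (0, 1) and
    recover the mean per-gene least-squares slope."""
    rng = as_rng(seed)
    x = Uniform(0.0, 1.0).sample(rng, n)
    betas = rng.normal(beta_mean, beta_sd, n_genes)
    counts = np.vstack([apply_eqtm(alpha, b, x, phi, rng) for b in betas])
    _, mean, se = estimate_eqtm_slopes(counts, x, range(n_genes))
    return {"configured": beta_mean, "estimate": mean, "se": se,
            "n": n_genes, "realized_mean": float(betas.mean())}


def recover_scenario(config: ScenarioConfig, seed: int = 1,
                     or_sample: int = 2000) -> list:
    """Full recovery-report table for a scenario configuration."""
    reports: list[RecoveryReport] = []

    if config.cnv.causal_freqs is not None:
        r = recover_cnv_state_frequency(config, seed)
        reports.append(RecoveryReport(
            "cnv:f_D", r["configured"], r["estimate"], r["se"], r["n"],
            "within 3 SE", within_se(r["configured"], r["estimate"], r["se"])))

    if config.disease is not None:
        ors = recover_odds_ratios(config, seed, or_sample, or_sample)
        for name, (conf, est, se) in ors.items():
            reports.append(RecoveryReport(
                f"OR[{name}]", conf, est, se, 2 * or_sample,
                "log-OR within 3 Wald SE",
                within_se(conf, est, se, log_scale=True)))

    if config.methylation.dm is not None and config.methylation.dm.cpg_ids:
        r = recover_methylation_difference(config, seed)
        reports.append(RecoveryReport(
            f"meth_diff[{r['cpg']}]", r["configured"], r["estimate"], r["se"],
            r["n"], "within 3 SE",
            within_se(r["configured"], r["estimate"], r["se"])))

    if config.rnaseq.de:
        fc = recover_expression_fold_changes(config, seed)
        for gene, (conf, est) in fc.items():
            reports.append(RecoveryReport(
                f"fold_change[{gene}]", conf, est, None, 1000,
                "within 10% relative", within_relative(conf, est, 0.10)))

    for s in config.rnaseq.eqtm:
        r = recover_eqtm_slope_mean(s.beta_mean, s.beta_sd, seed=seed)
        reports.append(RecoveryReport(
            f"eqtm_slope_mean[{s.cpg}]", r["configured"], r["estimate"], r["se"],
            r["n"], "within 3 SE of the mean",
            within_se(r["configured"], r["estimate"], r["se"])))

    return reports
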