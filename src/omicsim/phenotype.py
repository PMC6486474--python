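"""Disease model: logistic penetrance over coded SNP and CNV terms.

Affection status is Bernoulli with

    logit P(affected) = b0 + sum_i bC_i (C_i1 + C_i2)
                        + sum_j bG_j G_j + sum_(m,n) b_mn G_mn

where C_i1/C_i2 code the two chromosome CNV states (-1/0/1/2 for D/N/U/UU,
N baseline), G_j is the SNP coding under an additive/dominant/recessive
model (copy-weighted when the SNP sits inside a CNV region), and G_mn is a
pairwise interaction coding. Case-control samples are assembled by rejection
sampling against fixed quotas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from ._rng import as_rng
from .genomics import CNVData, Genotypes

SNP_MODELS = ("additive", "dominant", "recessive")
INTERACTION_MODELS = ("product", "joint_dominant", "joint_recessive", "xor")


@dataclass
class MainEffectSpec:
    """One main-effect term. ``target`` is a SNP id (model required) or a CNV
    region id (per-copy coefficient applied to both chromosome codings)."""

    target: str
    beta: float
    model: str | None = None  # SNPs only
    is_cnv: bool = False

    def __post_init__(self):
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if not self.is_cnv:
            if self.model not in SNP_MODELS:
                raise ValueError(f"SNP main effect needs a model from {SNP_MODELS}")


@dataclass
class InteractionSpec:
    snp_m: str
    snp_n: str
    beta: float
    model: str = "product"

    def __post_init__(self):
        if self.snp_m == self.snp_n:
            raise ValueError("interaction requires two distinct SNPs")
        if self.model not in INTERACTION_MODELS:
            raise ValueError(f"unknown interaction model {self.model!r}")


@dataclass
class DiseaseModel:
    beta0: float
    mains: list = field(default_factory=list)
    interactions: list = field(default_factory=list)

    @property
    def snp_mains(self):
        return [m for m in self.mains if not m.is_cnv]

    @property
    def cnv_mains(self):
        return [m for m in self.mains if m.is_cnv]


def code_genotype(paternal, maternal, model: str, copy_paternal=None,
                  copy_maternal=None) -> np.ndarray:
    """Code a SNP genotype (vectorised over individuals).

    Without CNV context the additive coding is the alt-allele count {0,1,2};
    dominant is 1[count >= 1]; recessive 1[count == 2]. Inside a CNV region
    each chromosome's allele is weighted by that chromosome's copy count
    (D=0, N=1, U=2, UU=3) and dominant/recessive threshold the weighted
    count at >= 1 and >= 2 respectively.
    """
    if model not in SNP_MODELS:
        raise ValueError(f"unknown SNP model {model!r}")
    pat = np.asarray(paternal, dtype=float)
    mat = np.asarray(maternal, dtype=float)
    cp = np.ones_like(pat) if copy_paternal is None else np.asarray(copy_paternal, dtype=float)
    cm = np.ones_like(mat) if copy_maternal is None else np.asarray(copy_maternal, dtype=float)
    count = pat * cp + mat * cm
    if model == "additive":
        return count
    if model == "dominant":
        return (count >= 1).astype(float)
    return (count >= 2).astype(float)


def code_interaction(g_m, g_n, model: str = "product") -> np.ndarray:
    """Pairwise interaction coding from two per-SNP codings.

    product: g_m * g_n (intended for additive codings); joint_dominant:
    1 iff both carriers; joint_recessive: 1 iff both codings >= 2;
    xor: 1 iff exactly one of the pair is a carrier.
    """
    g_m = np.asarray(g_m, dtype=float)
    g_n = np.asarray(g_n, dtype=float)
    if model == "product":
        return g_m * g_n
    if model == "joint_dominant":
        return ((g_m >= 1) & (g_n >= 1)).astype(float)
    if model == "joint_recessive":
        return ((g_m >= 2) & (g_n >= 2)).astype(float)
    if model == "xor":
        return ((g_m >= 1) ^ (g_n >= 1)).astype(float)
    raise ValueError(f"unknown interaction model {model!r}")


def design_matrix(model: DiseaseModel, genotypes: Genotypes | None,
                  cnv: CNVData | None, cnv_region_of_snp: dict | None = None):
    """Columns of coded terms in model order (CNV mains, SNP mains,
    interactions) plus their labels. This is the exact design used both to
    generate penetrance and, in the validation module, to re-fit it."""
    cols, names = [], []
    cnv_region_of_snp = cnv_region_of_snp or {}

    def snp_coding(snp_id, coding_model):
        j = genotypes.column(snp_id)
        pat, mat = genotypes.paternal[:, j], genotypes.maternal[:, j]
        region = cnv_region_of_snp.get(snp_id)
        if region is not None:
            from .genomics import _COPIES  # state -> copies lookup
            k = cnv.column(region)
            return code_genotype(pat, mat, coding_model,
                                 _COPIES[cnv.s1[:, k]], _COPIES[cnv.s2[:, k]])
        return code_genotype(pat, mat, coding_model)

    for m in model.cnv_mains:
        c1, c2 = cnv.coding()
        k = cnv.column(m.target)
        cols.append(c1[:, k] + c2[:, k])  # same per-copy beta on both chromosomes
        names.append(f"cnv:{m.target}")
    for m in model.snp_mains:
        cols.append(snp_coding(m.target, m.model))
        names.append(f"snp:{m.target}:{m.model}")
    for it in model.interactions:
        gm = snp_coding(it.snp_m, "additive")
        gn = snp_coding(it.snp_n, "additive")
        cols.append(code_interaction(gm, gn, it.model))
        names.append(f"ix:{it.snp_m}x{it.snp_n}:{it.model}")
    X = np.column_stack(cols) if cols else np.zeros((_n_rows(genotypes, cnv), 0))
    return X, names


def _n_rows(genotypes, cnv):
    if genotypes is not None:
        return genotypes.n_individuals
    if cnv is not None:
        return cnv.n_individuals
    raise ValueError("need genotypes or CNV data")


def _betas(model: DiseaseModel) -> np.ndarray:
    return np.array([m.beta for m in model.cnv_mains]
                    + [m.beta for m in model.snp_mains]
                    + [it.beta for it in model.interactions])


def penetrance(model: DiseaseModel, genotypes: Genotypes | None = None,
               cnv: CNVData | None = None,
               cnv_region_of_snp: dict | None = None) -> np.ndarray:
    """Per-individual P(affected) under the logistic penetrance function."""
    X, _ = design_matrix(model, genotypes, cnv, cnv_region_of_snp)
    eta = model.beta0 + (X @ _betas(model) if X.shape[1] else 0.0)
    p = expit(np.broadcast_to(eta, (_n_rows(genotypes, cnv),)).astype(float))
    # mathematically strictly inside (0,1); keep the float there too
    return np.clip(p, 1e-12, 1 - 1e-12)


def assign_affection(p, rng) -> np.ndarray:
    """Bernoulli affection labels (True = case) from penetrances in (0, 1)."""
    rng = as_rng(rng)
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("penetrance must lie strictly inside (0, 1)")
    return rng.random(p.size) < p


@dataclass
class Cohort:
    """An ascertained case-control sample with its genomic data aligned."""

    genotypes: Genotypes | None
    cnv: CNVData | None
    status: np.ndarray  # True = case
    penetrance: np.ndarray
    prevalence_among_draws: float

    @property
    def n(self) -> int:
        return self.status.size


def ascertain_case_control(genome_simulator, model: DiseaseModel, n_cases: int,
                           n_controls: int, rng, max_draws: int | None = None,
                           cnv_region_of_snp: dict | None = None,
                           batch: int = 2000) -> Cohort:
    """Rejection-sample individuals until the case and control quotas fill.

    ``genome_simulator(n, rng)`` must return ``(Genotypes | None,
    CNVData | None)`` for a fresh batch of n individuals. Surplus individuals
    beyond a filled quota are discarded, so retained draws are i.i.d. given
    their label. The realized prevalence among all draws is recorded.
    """
    rng = as_rng(rng)
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("n_cases and n_controls must be positive")
    if max_draws is None:
        max_draws = 1000 * (n_cases + n_controls)

    kept_geno, kept_cnv, kept_status, kept_pen = [], [], [], []
    need_cases, need_controls = n_cases, n_controls
    total_draws = total_cases = 0
    while need_cases > 0 or need_controls > 0:
        if total_draws >= max_draws:
            raise RuntimeError(
                f"ascertainment exceeded max_draws={max_draws}; the disease "
                "model is likely degenerate (prevalence near 0 or 1)")
        n = min(batch, max_draws - total_draws)
        geno, cnv = genome_simulator(n, rng)
        p = penetrance(model, geno, cnv, cnv_region_of_snp)
        status = assign_affection(p, rng)
        total_draws += n
        total_cases += int(status.sum())
        take = np.zeros(n, dtype=bool)
        case_idx = np.flatnonzero(status)[:need_cases]
        ctrl_idx = np.flatnonzero(~status)[:need_controls]
        take[case_idx] = True
        take[ctrl_idx] = True
        need_cases -= case_idx.size
        need_controls -= ctrl_idx.size
        rows = np.flatnonzero(take)
        kept_geno.append(geno.subset(rows) if geno is not None else None)
        kept_cnv.append(cnv.subset(rows) if cnv is not None else None)
        kept_status.append(status[rows])
        kept_pen.append(p[rows])

    def _cat_geno(parts):
        if parts[0] is None:
            return None
        return Genotypes(parts[0].variant_ids,
                         np.concatenate([g.paternal for g in parts]),
                         np.concatenate([g.maternal for g in parts]))

    def _cat_cnv(parts):
        if parts[0] is None:
            return None
        return CNVData(parts[0].region_ids,
                       np.concatenate([c.s1 for c in parts]),
                       np.concatenate([c.s2 for c in parts]))

    return Cohort(
        genotypes=_cat_geno(kept_geno),
        cnv=_cat_cnv(kept_cnv),
        status=np.concatenate(kept_status),
        penetrance=np.concatenate(kept_pen),
        prevalence_among_draws=total_cases / total_draws,
    )


def beta0_for_prevalence(target: float, model: DiseaseModel, population_sampler,
                         rng, n_mc: int = 20_000, tol: float = 0.002) -> float:
    """Find b0 so that mean penetrance over a population sample hits
    ``target`` (Monte-Carlo bisection; closed form when the model is null).

    ``population_sampler(n, rng)`` returns (Genotypes | None, CNVData | None).
    """
    rng = as_rng(rng)
    if not 0 < target < 1:
        raise ValueError("target prevalence must lie in (0, 1)")
    if not model.mains and not model.interactions:
        return float(logit(target))

    geno, cnv = population_sampler(n_mc, rng)
    X, _ = design_matrix(model, geno, cnv)
    score = X @ _betas(model)

    def prev(b0):
        return float(np.mean(expit(b0 + score)))

    lo, hi = logit(target) - 1.0, logit(target) + 1.0
    for _ in range(60):  # widen until bracketing
        if prev(lo) < target:
            break
        lo -= 2.0
    for _ in range(60):
        if prev(hi) > target:
            break
        hi += 2.0
    if not (prev(lo) < target < prev(hi)):
        raise RuntimeError("could not bracket the target prevalence")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        pm = prev(mid)
        if abs(pm - target) <= tol:
            return float(mid)
        if pm < target:
            lo = mid
        else:
            hi = mid
    return float(0.5 * (lo + hi))
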