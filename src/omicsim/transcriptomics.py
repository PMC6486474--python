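"""RNA-seq count simulation: negative-binomial model with normalization
factors, differential expression, eQTL genotype means, beta-binomial
allele-specific reads and the methylation -> expression (eQTM) link.

The count of gene i in individual j is NB with mean mu_ij = lambda_i * c_j
and dispersion omega_i, where variance = mu + omega * mu^2 (omega = 0 is
Poisson). A differentially expressed gene multiplies the case mean by its
fold change f_i. An eQTL with fold change h scales the mean by 1, h, 2h-1
for genotypes AA, Aa, aa. An eQTM gene's mean is alpha_ij + beta_i * x_ij
with x the methylation proportion of the driving CpG. Allele-specific reads
for a cis-eQTL gene are a fixed 0.005 fraction of the gene total, split by a
beta-binomial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import as_rng
from .fixtures import RNAProfile
from .genomics import Genotypes

#: fraction of a gene's reads that are allele-specific (mapped over
#: heterozygous sites), an empirical constant from real RNA-seq data
ASE_READ_FRACTION = 0.005
#: default beta-binomial overdispersion of allele-specific read splits
ASE_OVERDISPERSION = 0.1
#: floor applied to NB means that a steep negative eQTM slope would push <= 0
MU_FLOOR = 1e-3


@dataclass
class DEGeneSpec:
    gene_id: str
    fold_change: float  # case mean multiplier

    def __post_init__(self):
        if self.fold_change <= 0:
            raise ValueError("fold change must be positive")


@dataclass
class EQTLSpec:
    snp_id: str
    gene_id: str
    fold_change: float  # h: genotype means mu, h*mu, (2h-1)*mu
    cis: bool = True
    effect_size: float | None = None  # log2 alt/ref allele expression (ASE)

    def __post_init__(self):
        if self.fold_change <= 0.5:
            raise ValueError("eQTL fold change must exceed 0.5 (so 2h-1 > 0)")
        if self.effect_size is None:
            # allele-level ratio implied by the genotype means: the ref
            # allele contributes mu/2, the alt allele (h - 1/2) mu
            self.effect_size = float(np.log2(2 * self.fold_change - 1))


@dataclass
class EQTMSpec:
    cpg_id: str
    gene_ids: list
    beta_mean: float
    beta_sd: float

    def __post_init__(self):
        if self.beta_sd < 0:
            raise ValueError("beta_sd must be non-negative")


@dataclass
class CountMatrix:
    """Genes x individuals integer counts, with optional allele-specific
    companion counts for ASE genes."""

    gene_ids: list
    counts: np.ndarray
    # {"gene_ids": [...], "ref": genes x individuals, "alt": ..., "het": bool mask}
    ase: dict | None = None
    eqtm_betas: dict | None = None  # realized per-gene eQTM slopes
    c: np.ndarray | None = None  # per-individual normalization factors used

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape[0] != len(self.gene_ids):
            raise ValueError("gene_ids length disagrees with count matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def row(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)


def nb_mean(lam, c, is_case=False, de: DEGeneSpec | None = None,
            genotype=None, eqtl: EQTLSpec | None = None) -> np.ndarray:
    """Per-individual NB mean mu = lambda*c, times the DE fold change for
    cases and the eQTL genotype multiplier {1, h, 2h-1} for {AA, Aa, aa}."""
    mu = np.atleast_1d(np.asarray(lam, dtype=float) * np.asarray(c, dtype=float))
    if de is not None:
        mu = mu * np.where(np.asarray(is_case, dtype=bool), de.fold_change, 1.0)
    if eqtl is not None and genotype is not None:
        g = np.asarray(genotype, dtype=float)
        h = eqtl.fold_change
        mult = np.select([g == 0, g == 1], [1.0, h], default=2 * h - 1)
        mu = mu * mult
    if np.any(mu <= 0):
        raise ValueError("NB mean must be positive")
    return mu


def sample_count(mu, omega, rng) -> np.ndarray:
    """NB draw with variance mu + omega*mu^2; omega = 0 degenerates to
    Poisson. Scalar or broadcastable arrays."""
    rng = as_rng(rng)
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    omega = np.broadcast_to(np.asarray(omega, dtype=float), mu.shape)
    if np.any(mu <= 0) or np.any(omega < 0):
        raise ValueError("need mu > 0 and omega >= 0")
    out = np.empty(mu.shape, dtype=np.int64)
    pois = omega == 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        r = 1.0 / omega[~pois]
        p = r / (r + mu[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    return out


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb kernel bandwidth for a 1-d sample."""
    x = np.asarray(x, dtype=float)
    n = x.size
    sd = x.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread == 0:
        return 0.0
    return 0.9 * spread * n ** (-0.2)


def smoothed_bootstrap_c(c, n: int, rng) -> np.ndarray:
    """Normalization factors for n individuals from a reference vector c.

    If n <= len(c), plain bootstrap resampling. Otherwise each draw is a
    resampled reference value plus Gaussian kernel noise at the Silverman
    bandwidth, reflected at zero to stay positive.
    """
    rng = as_rng(rng)
    c = np.asarray(c, dtype=float)
    if c.size == 0:
        raise ValueError("empty normalization-factor vector")
    if np.any(c <= 0):
        raise ValueError("normalization factors must be positive")
    base = rng.choice(c, size=n, replace=True)
    if n <= c.size:
        return base
    h = silverman_bandwidth(c)
    if h == 0:
        return base
    return np.abs(base + rng.normal(0.0, h, size=n))


def betabinom_params(p: float, rho: float) -> tuple:
    """(alpha, beta) of a beta-binomial with mean p and overdispersion rho."""
    if not 0 <= rho < 1:
        raise ValueError("overdispersion must lie in [0, 1)")
    if rho == 0:
        return np.inf, np.inf
    return p * (1 - rho) / rho, (1 - p) * (1 - rho) / rho


def simulate_ase(total_count, effect_size: float, rho: float = ASE_OVERDISPERSION,
                 rng=None) -> tuple:
    """Allele-specific (ref_reads, alt_reads) for one gene-individual.

    n_as = round(0.005 * t) (round-half-to-even); alt reads are
    beta-binomial with mean p = 2^e / (1 + 2^e) and overdispersion rho.
    Vectorised over individuals.
    """
    rng = as_rng(rng)
    t = np.atleast_1d(np.asarray(total_count))
    if np.any(t < 0):
        raise ValueError("total counts must be non-negative")
    n_as = np.round(ASE_READ_FRACTION * t).astype(np.int64)
    p = 2.0 ** effect_size / (1.0 + 2.0 ** effect_size)
    if rho == 0:
        alt = rng.binomial(n_as, p)
    else:
        a, b = betabinom_params(p, rho)
        q = rng.beta(a, b, size=n_as.shape)
        alt = rng.binomial(n_as, q)
    return n_as - alt, alt


def apply_eqtm(alpha, beta: float, x, phi, rng) -> np.ndarray:
    """Counts for an eQTM gene: NB(max(alpha + beta*x, floor), phi)."""
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("methylation proportions must lie in [0, 1]")
    mu = np.maximum(np.asarray(alpha, dtype=float) + beta * x, MU_FLOOR)
    return sample_count(mu, phi, rng)


def simulate_rnaseq(profile: RNAProfile, status, n_individuals: int | None = None,
                    de: list | None = None, eqtl: list | None = None,
                    eqtm: list | None = None, genotypes: Genotypes | None = None,
                    methylation_proportions: dict | None = None,
                    rng=None, n_genes: int | None = None,
                    technical_variation: bool = True) -> CountMatrix:
    """Simulate the full genes x individuals count matrix.

    Per-gene (lambda, omega) pairs are resampled with replacement from the
    profile; per-individual c factors are bootstrap-resampled (smoothed when
    the cohort exceeds the reference count) unless ``technical_variation``
    is off, in which case c = 1. ``methylation_proportions`` maps CpG ids to
    per-individual proportions for the eQTM link. Allele-specific reads are
    emitted for every cis-eQTL gene (effect size 0 for homozygotes).
    """
    rng = as_rng(rng)
    status = np.asarray(status, dtype=bool)
    n = status.size if n_individuals is None else n_individuals
    de = de or []
    eqtl = eqtl or []
    eqtm = eqtm or []

    eqtl_genes = {s.gene_id for s in eqtl}
    eqtm_genes = {g for s in eqtm for g in s.gene_ids}
    clash = eqtl_genes & eqtm_genes
    if clash:
        raise ValueError(f"genes driven by both an eQTL and an eQTM: {sorted(clash)}")

    n_genes = profile.n_genes if n_genes is None else n_genes
    gene_ids = [f"gene{i + 1}" for i in range(n_genes)] \
        if n_genes != profile.n_genes else list(profile.gene_ids)
    pick = rng.integers(profile.n_genes, size=n_genes)
    lam = profile.lam[pick]
    omega = profile.omega[pick]

    if technical_variation:
        c = smoothed_bootstrap_c(profile.c, n, rng)
    else:
        c = np.ones(n)

    de_by_gene = {s.gene_id: s for s in de}
    eqtl_by_gene = {s.gene_id: s for s in eqtl}
    eqtm_by_gene = {}
    for s in eqtm:
        for g in s.gene_ids:
            eqtm_by_gene[g] = s
    for gid in list(de_by_gene) + list(eqtl_by_gene) + list(eqtm_by_gene):
        if gid not in gene_ids:
            raise KeyError(f"spec references unknown gene {gid!r}")

    mu = lam[:, None] * c[None, :]
    eqtm_betas: dict = {}
    for i, gid in enumerate(gene_ids):
        spec = eqtm_by_gene.get(gid)
        if spec is not None:
            if methylation_proportions is None or spec.cpg_id not in methylation_proportions:
                raise ValueError(f"eQTM spec needs methylation proportions for {spec.cpg_id}")
            x = np.asarray(methylation_proportions[spec.cpg_id], dtype=float)
            beta_i = float(rng.normal(spec.beta_mean, spec.beta_sd))
            eqtm_betas[gid] = beta_i
            mu[i] = np.maximum(mu[i] + beta_i * np.nan_to_num(x, nan=float(np.nanmean(x))),
                               MU_FLOOR)
        spec = eqtl_by_gene.get(gid)
        if spec is not None:
            if genotypes is None:
                raise ValueError("eQTL spec requires genotypes")
            g = genotypes.dosage()[:, genotypes.column(spec.snp_id)].astype(float)
            h = spec.fold_change
            mu[i] = mu[i] * np.select([g == 0, g == 1], [1.0, h], default=2 * h - 1)
        spec = de_by_gene.get(gid)
        if spec is not None:
            mu[i] = mu[i] * np.where(status, spec.fold_change, 1.0)

    counts = sample_count(mu, omega[:, None], rng)

    ase = None
    cis = [s for s in eqtl if s.cis]
    if cis:
        ase_ids, refs, alts, hets = [], [], [], []
        for s in cis:
            i = gene_ids.index(s.gene_id)
            g = genotypes.dosage()[:, genotypes.column(s.snp_id)]
            het = g == 1
            ref = np.zeros(n, dtype=np.int64)
            alt = np.zeros(n, dtype=np.int64)
            if het.any():
                r, a = simulate_ase(counts[i, het], s.effect_size, rng=rng)
                ref[het], alt[het] = r, a
            if (~het).any():
                r, a = simulate_ase(counts[i, ~het], 0.0, rng=rng)
                ref[~het], alt[~het] = r, a
            ase_ids.append(s.gene_id)
            refs.append(ref)
            alts.append(alt)
            hets.append(het)
        ase = {"gene_ids": ase_ids, "ref": np.vstack(refs), "alt": np.vstack(alts),
               "het": np.vstack(hets)}

    return CountMatrix(gene_ids, counts, ase=ase, eqtm_betas=eqtm_betas or None, c=c)
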