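"""Synthetic reference panels and per-layer profiles.

Real analyses feed the simulator a haplotype panel from a population-genetic
sequence generator and profiles compiled from large consortium datasets
(per-CpG methylation rates and depths, per-gene RNA-seq means/dispersions and
normalization factors, per-protein noise SDs, CNV state frequencies). This
module generates statistically equivalent stand-ins with known parameters, so
every downstream recovery check has a ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import as_rng
from .distributions import Law, PointSimplex, sample_positive

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
FUZZY = "fuzzy"

#: rate bands defining the three methylation status categories
STATUS_BANDS = {
    METHYLATED: (0.7, 1.0),
    UNMETHYLATED: (0.0, 0.3),
    FUZZY: (0.3, 0.7),
}


@dataclass
class HaplotypePanel:
    """Reference haplotypes over a set of biallelic variants.

    ``matrix`` is n_haplotypes x n_variants with 0 = reference allele and
    1 = alternative allele; positions are 1-based and strictly increasing.
    """

    variant_ids: list
    positions: np.ndarray
    alleles: list  # per-variant (ref, alt)
    matrix: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        n_hap, n_var = self.matrix.shape
        if n_hap < 2 or n_hap % 2:
            raise ValueError("panel needs an even number (>= 2) of haplotypes")
        if n_var != len(self.variant_ids) or n_var != len(self.positions):
            raise ValueError("variant annotation lengths disagree with matrix")
        if n_var and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_variants(self) -> int:
        return self.matrix.shape[1]

    def alt_frequencies(self) -> np.ndarray:
        if self.n_variants == 0:
            return np.zeros(0)
        return self.matrix.mean(axis=0)


@dataclass
class MethylationProfile:
    """Per-CpG reference profile: position spacing, methylation rate, status
    band and a negative-binomial read-depth model (mean, dispersion)."""

    cpg_ids: list
    distance_to_next: np.ndarray
    rate: np.ndarray
    status: list
    depth_mean: np.ndarray
    depth_dispersion: np.ndarray

    def __post_init__(self):
        self.rate = np.asarray(self.rate, dtype=float)
        self.distance_to_next = np.asarray(self.distance_to_next, dtype=np.int64)
        self.depth_mean = np.asarray(self.depth_mean, dtype=float)
        self.depth_dispersion = np.asarray(self.depth_dispersion, dtype=float)
        if np.any((self.rate < 0) | (self.rate > 1)):
            raise ValueError("methylation rates must lie in [0, 1]")
        if np.any(self.depth_mean <= 0):
            raise ValueError("depth_mean must be positive")
        for st in self.status:
            if st not in STATUS_BANDS:
                raise ValueError(f"unknown methylation status {st!r}")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    def positions(self, start: int = 1) -> np.ndarray:
        """Cumulative 1-based CpG coordinates implied by the spacings."""
        if self.n_cpgs == 0:
            return np.zeros(0, dtype=np.int64)
        pos = np.empty(self.n_cpgs, dtype=np.int64)
        pos[0] = start
        if self.n_cpgs > 1:
            pos[1:] = start + np.cumsum(self.distance_to_next[:-1])
        return pos


@dataclass
class RNAProfile:
    """Per-gene NB means and dispersions plus reference normalization factors."""

    gene_ids: list
    lam: np.ndarray  # common mean per gene, > 0
    omega: np.ndarray  # dispersion per gene, >= 0 (variance = mu + omega*mu^2)
    c: np.ndarray  # per-reference-individual normalization factors, > 0

    def __post_init__(self):
        self.lam = np.asarray(self.lam, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.lam.size != self.omega.size or self.lam.size != len(self.gene_ids):
            raise ValueError("lambda/omega/gene_ids lengths disagree")
        if np.any(self.lam <= 0):
            raise ValueError("all lambda must be positive")
        if np.any(self.omega < 0):
            raise ValueError("dispersions must be non-negative")
        if np.any(self.c <= 0):
            raise ValueError("all normalization factors must be positive")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class ProteinProfile:
    """Per-protein observation SDs and kinetic rates for the mass-action model."""

    protein_ids: list
    tau: np.ndarray
    kappa_s: float = 1.0
    kappa_d: float = 1.0
    n_steps: int = 10

    def __post_init__(self):
        self.tau = np.asarray(self.tau, dtype=float)
        if np.any(self.tau <= 0):
            raise ValueError("all tau must be positive")
        if self.kappa_d <= 0:
            raise ValueError("kappa_d must be positive")


@dataclass
class CNVProfile:
    """A list of CNV regions (see :mod:`omicsim.genomics`), non-overlapping."""

    regions: list

    def __post_init__(self):
        by_chrom: dict = {}
        for r in self.regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for regs in by_chrom.values():
            regs = sorted(regs, key=lambda r: r.start)
            for a, b in zip(regs, regs[1:]):
                if b.start <= a.end:
                    raise ValueError(f"overlapping CNV regions {a.region_id} / {b.region_id}")

    @property
    def n_regions(self) -> int:
        return len(self.regions)


def generate_reference_panel(n_haplotypes: int, n_variants: int, maf_spectrum: Law,
                             ld_block_length: int = 20, seed=0,
                             mutation_rate: float = 0.05) -> HaplotypePanel:
    """Generate a synthetic haplotype panel with block-structured LD.

    Each haplotype carries one latent ancestry value per LD block; within a
    block the allele at variant v is the indicator 1[u < p_v] of that shared
    ancestry against the variant's target alternative-allele frequency p_v,
    except that with probability ``mutation_rate`` the allele is resampled
    independently (Bernoulli(p_v)). Marginally every allele is exactly
    Bernoulli(p_v), so empirical frequencies track the requested spectrum at
    binomial precision, while variants within a block are positively
    correlated and variants in different blocks independent.
    """
    rng = as_rng(seed)
    if n_haplotypes < 2 or n_haplotypes % 2:
        raise ValueError("n_haplotypes must be even and >= 2")
    if ld_block_length < 1:
        raise ValueError("ld_block_length must be >= 1")
    p = np.asarray(maf_spectrum.sample(rng, n_variants), dtype=float)
    if n_variants and (p.min() <= 0 or p.max() > 0.5):
        raise ValueError("maf_spectrum must yield values in (0, 0.5]")

    matrix = np.empty((n_haplotypes, n_variants), dtype=np.uint8)
    for b0 in range(0, n_variants, ld_block_length):
        b1 = min(b0 + ld_block_length, n_variants)
        u = rng.random(n_haplotypes)[:, None]  # shared block ancestry
        block = (u < p[None, b0:b1]).astype(np.uint8)
        if mutation_rate > 0:
            resample = rng.random((n_haplotypes, b1 - b0)) < mutation_rate
            fresh = (rng.random((n_haplotypes, b1 - b0)) < p[None, b0:b1])
            block = np.where(resample, fresh, block).astype(np.uint8)
        matrix[:, b0:b1] = block

    positions = np.arange(1, n_variants + 1, dtype=np.int64) * 100
    variant_ids = [f"snp{i + 1}" for i in range(n_variants)]
    alleles = [("A", "G")] * n_variants
    return HaplotypePanel(variant_ids, positions, alleles, matrix)


def generate_methylation_profile(n_cpgs: int, status_mix=(0.3, 0.5, 0.2),
                                 depth_mean: float = 30.0,
                                 depth_dispersion: float = 0.1,
                                 mean_distance: int = 100, seed=0) -> MethylationProfile:
    """Generate a per-CpG profile with the given status mixture.

    ``status_mix`` gives proportions of (methylated, unmethylated, fuzzy)
    CpGs; rates are drawn uniformly within each status band.
    """
    rng = as_rng(seed)
    mix = np.asarray(status_mix, dtype=float)
    if mix.size != 3 or abs(mix.sum() - 1.0) > 1e-6 or mix.min() < 0:
        raise ValueError("status_mix must be 3 proportions summing to 1")
    statuses = [METHYLATED, UNMETHYLATED, FUZZY]
    status = [statuses[k] for k in rng.choice(3, size=n_cpgs, p=mix)]
    rate = np.empty(n_cpgs)
    for i, st in enumerate(status):
        lo, hi = STATUS_BANDS[st]
        rate[i] = rng.uniform(lo, hi)
    distance = rng.geometric(1.0 / mean_distance, size=n_cpgs).astype(np.int64)
    return MethylationProfile(
        cpg_ids=[f"cpg{i + 1}" for i in range(n_cpgs)],
        distance_to_next=distance,
        rate=rate,
        status=status,
        depth_mean=np.full(n_cpgs, float(depth_mean)),
        depth_dispersion=np.full(n_cpgs, float(depth_dispersion)),
    )


def generate_rnaseq_profile(n_genes: int, n_ref_samples: int, lambda_law: Law,
                            omega_law: Law, c_law: Law, seed=0) -> RNAProfile:
    """Generate per-gene (lambda, omega) pairs and reference c factors."""
    rng = as_rng(seed)
    lam = sample_positive(lambda_law, rng, n_genes)
    omega = np.clip(np.asarray(omega_law.sample(rng, n_genes), dtype=float), 0.0, None)
    c = sample_positive(c_law, rng, n_ref_samples)
    return RNAProfile(
        gene_ids=[f"gene{i + 1}" for i in range(n_genes)],
        lam=lam, omega=omega, c=c,
    )


def generate_protein_profile(n_proteins: int, tau_law: Law, kappa_s: float = 1.0,
                             kappa_d: float = 1.0, n_steps: int = 10,
                             seed=0) -> ProteinProfile:
    rng = as_rng(seed)
    tau = sample_positive(tau_law, rng, n_proteins)
    return ProteinProfile(
        protein_ids=[f"prot{i + 1}" for i in range(n_proteins)],
        tau=tau, kappa_s=kappa_s, kappa_d=kappa_d, n_steps=n_steps,
    )


def generate_cnv_profile(n_regions: int, freq_law: Law = PointSimplex((0.0, 1.0, 0.0, 0.0)),
                         region_length: int = 10_000, chrom: str = "1",
                         seed=0) -> CNVProfile:
    """Generate non-overlapping CNV regions with state-frequency vectors
    (f_D, f_N, f_U, f_UU) drawn from ``freq_law`` (a law over the simplex)."""
    from .genomics import CNVRegion  # local import to avoid cycle

    rng = as_rng(seed)
    freqs = np.asarray(freq_law.sample(rng, n_regions), dtype=float)
    if n_regions:
        freqs = freqs.reshape(n_regions, -1)
        if freqs.shape[1] != 4:
            raise ValueError("freq_law must yield 4-vectors (f_D, f_N, f_U, f_UU)")
        if np.any(freqs < 0) or np.any(np.abs(freqs.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("state frequencies must lie on the simplex")
    regions = []
    gap = 1000
    start = 1
    for i in range(n_regions):
        regions.append(CNVRegion(
            region_id=f"cnv{i + 1}", chrom=chrom,
            start=start, end=start + region_length - 1,
            state_freqs=tuple(freqs[i]),
        ))
        start += region_length + gap
    return CNVProfile(regions=regions)
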