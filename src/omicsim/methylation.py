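"""Bisulphite-sequencing read-count simulation.

For each CpG and individual a total read count is drawn from the profile's
negative-binomial depth model and a methylated count Binomial(total, rate).
The per-individual rate starts from the profile rate and is modified by

* an meQTL: the rate is multiplied by a user ratio once per alternative
  allele at the driving SNP,
* case-control differential methylation: an additive delta on the rate for
  cases at selected CpGs,
* allele-specific methylation (ASM): reads split evenly between the
  paternal and maternal allele, each methylated at its own rate,
* a DMR: CpGs in the region use an alternate tissue/cell-type profile for a
  designated group of individuals.

Rates are clamped to [0, 1] after all modifications. One chromosome's CpGs
are simulated per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import as_rng
from .fixtures import MethylationProfile
from .genomics import Genotypes


@dataclass
class MeQTLSpec:
    snp_id: str
    cpg_ids: list
    ratio: float  # multiplicative factor on the profile rate per alt allele

    def __post_init__(self):
        if self.ratio <= 0:
            raise ValueError("meQTL ratio must be positive")


@dataclass
class DifferentialMethylationSpec:
    """Case-control differential methylation.

    Either name the CpGs directly (``cpg_ids``) or give per-band proportions
    (methylated / unmethylated / partially methylated CpGs) to be selected at
    random. ``delta`` is added to the case rate; sign as given.
    """

    delta: float
    cpg_ids: list | None = None
    p_methylated: float = 0.0
    p_unmethylated: float = 0.0
    p_partial: float = 0.0

    def __post_init__(self):
        if abs(self.delta) > 1:
            raise ValueError("|delta| cannot exceed 1")
        for p in (self.p_methylated, self.p_unmethylated, self.p_partial):
            if not 0 <= p <= 1:
                raise ValueError("band proportions must lie in [0, 1]")


@dataclass
class ASMSpec:
    cpg_ids: list
    paternal_rate: float
    maternal_rate: float

    def __post_init__(self):
        for r in (self.paternal_rate, self.maternal_rate):
            if not 0 <= r <= 1:
                raise ValueError("ASM rates must lie in [0, 1]")


@dataclass
class DMRSpec:
    """CpGs re-simulated from an alternate cell/tissue profile for the
    individuals flagged in ``group_mask`` (True = alternate profile)."""

    cpg_ids: list
    alternate_rates: np.ndarray  # aligned with cpg_ids
    group_mask: np.ndarray  # per individual

    def __post_init__(self):
        self.alternate_rates = np.asarray(self.alternate_rates, dtype=float)
        if self.alternate_rates.size != len(self.cpg_ids):
            raise ValueError("alternate profile must cover every DMR CpG")


@dataclass
class MethylationData:
    """Counts per individual (rows) and CpG (columns)."""

    cpg_ids: list
    total: np.ndarray
    methylated: np.ndarray
    differential_cpgs: list = field(default_factory=list)
    # per-allele counts, present only when ASM is active:
    # {"total_pat": ..., "meth_pat": ..., "total_mat": ..., "meth_mat": ...}
    allele_counts: dict | None = None

    def __post_init__(self):
        self.total = np.asarray(self.total, dtype=np.int64)
        self.methylated = np.asarray(self.methylated, dtype=np.int64)
        if self.total.shape != self.methylated.shape:
            raise ValueError("total/methylated shapes disagree")
        if np.any(self.methylated > self.total) or np.any(self.methylated < 0):
            raise ValueError("need 0 <= methylated <= total")

    def column(self, cpg_id: str) -> int:
        return self.cpg_ids.index(cpg_id)


def effective_rate(base_rate, is_case=None, dm: DifferentialMethylationSpec | None = None,
                   dm_selected: bool = True, genotype_at_meqtl=None,
                   meqtl: MeQTLSpec | None = None) -> np.ndarray:
    """Per-individual methylation rate after meQTL and differential effects.

    rate = clamp(base * ratio**alt_count + delta * 1[case and selected], 0, 1).
    """
    rate = np.atleast_1d(np.asarray(base_rate, dtype=float)).copy()
    if np.any((rate < 0) | (rate > 1)):
        raise ValueError("base_rate must lie in [0, 1]")
    if meqtl is not None and genotype_at_meqtl is not None:
        rate = rate * meqtl.ratio ** np.asarray(genotype_at_meqtl, dtype=float)
    if dm is not None and dm_selected and is_case is not None:
        rate = rate + dm.delta * np.asarray(is_case, dtype=float)
    return np.clip(rate, 0.0, 1.0)


def _select_differential(profile: MethylationProfile, dm: DifferentialMethylationSpec,
                         rng) -> list:
    if dm.cpg_ids is not None:
        unknown = set(dm.cpg_ids) - set(profile.cpg_ids)
        if unknown:
            raise KeyError(f"differential spec references unknown CpGs: {sorted(unknown)}")
        return list(dm.cpg_ids)
    props = {"methylated": dm.p_methylated, "unmethylated": dm.p_unmethylated,
             "fuzzy": dm.p_partial}
    chosen = []
    for band, prop in props.items():
        idx = [i for i, st in enumerate(profile.status) if st == band]
        k = int(round(prop * len(idx)))
        if k:
            pick = rng.choice(len(idx), size=k, replace=False)
            chosen.extend(profile.cpg_ids[idx[i]] for i in pick)
    return chosen


def _sample_depth(profile: MethylationProfile, n: int, rng) -> np.ndarray:
    """NB total read counts, individuals x cpgs (variance = m + d*m^2)."""
    m = profile.depth_mean[None, :]
    d = profile.depth_dispersion[None, :]
    shape = (n, profile.n_cpgs)
    out = np.empty(shape, dtype=np.int64)
    poisson = (d <= 0)
    lam = np.broadcast_to(m, shape)
    if poisson.any():
        mask = np.broadcast_to(poisson, shape)
        out[mask] = rng.poisson(lam[mask])
    nbmask = ~poisson
    if nbmask.any():
        mask = np.broadcast_to(nbmask, shape)
        r = np.broadcast_to(1.0 / np.where(d > 0, d, 1.0), shape)
        p = r / (r + lam)
        out[mask] = rng.negative_binomial(r[mask], p[mask])
    return out


def simulate_wgbs(profile: MethylationProfile, status, genotypes: Genotypes | None = None,
                  dm: DifferentialMethylationSpec | None = None,
                  meqtl: MeQTLSpec | None = None, asm: ASMSpec | None = None,
                  dmr: DMRSpec | None = None, rng=None) -> MethylationData:
    """Simulate methylated/total read counts for a cohort.

    ``status`` is the per-individual case indicator (True = case).
    """
    rng = as_rng(rng)
    if profile.n_cpgs == 0:
        raise ValueError("empty methylation profile")
    status = np.asarray(status, dtype=bool)
    n = status.size

    for spec in (meqtl, asm):
        if spec is not None:
            unknown = set(spec.cpg_ids) - set(profile.cpg_ids)
            if unknown:
                raise KeyError(f"spec references unknown CpGs: {sorted(unknown)}")
    if meqtl is not None and genotypes is None:
        raise ValueError("meQTL spec requires genotypes")

    # individuals x cpgs base rates
    rates = np.tile(profile.rate[None, :], (n, 1))
    if dmr is not None:
        mask = np.asarray(dmr.group_mask, dtype=bool)
        for cid, alt in zip(dmr.cpg_ids, dmr.alternate_rates):
            j = profile.cpg_ids.index(cid)
            rates[mask, j] = alt

    if meqtl is not None:
        j_snp = genotypes.column(meqtl.snp_id)
        alt_count = genotypes.dosage()[:, j_snp].astype(float)
        for cid in meqtl.cpg_ids:
            j = profile.cpg_ids.index(cid)
            rates[:, j] = rates[:, j] * meqtl.ratio ** alt_count

    differential: list = []
    if dm is not None:
        differential = _select_differential(profile, dm, rng)
        cols = [profile.cpg_ids.index(c) for c in differential]
        rates[np.ix_(status, cols)] += dm.delta
    rates = np.clip(rates, 0.0, 1.0)

    total = _sample_depth(profile, n, rng)
    methylated = rng.binomial(total, rates)

    allele_counts = None
    if asm is not None:
        if genotypes is None:
            raise ValueError("ASM requires phased genotypes (parental origin)")
        cols = [profile.cpg_ids.index(c) for c in asm.cpg_ids]
        total_pat = rng.binomial(total[:, cols], 0.5)
        total_mat = total[:, cols] - total_pat
        meth_pat = rng.binomial(total_pat, asm.paternal_rate)
        meth_mat = rng.binomial(total_mat, asm.maternal_rate)
        methylated[:, cols] = meth_pat + meth_mat
        allele_counts = {"cpg_ids": list(asm.cpg_ids),
                         "total_pat": total_pat, "meth_pat": meth_pat,
                         "total_mat": total_mat, "meth_mat": meth_mat}

    return MethylationData(list(profile.cpg_ids), total, methylated,
                           differential_cpgs=differential,
                           allele_counts=allele_counts)


def methylation_proportion(data: MethylationData, cpg_id: str,
                           individuals=None) -> np.ndarray:
    """Per-individual methylated/total proportion; zero-depth individuals
    come back as NaN (missing) for downstream exclusion."""
    j = data.column(cpg_id)
    total = data.total[:, j] if individuals is None else data.total[individuals, j]
    meth = data.methylated[:, j] if individuals is None else data.methylated[individuals, j]
    if not np.any(total > 0):
        raise ValueError(f"CpG {cpg_id} has zero depth in every individual")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, meth / np.where(total > 0, total, 1), np.nan)
    return out
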