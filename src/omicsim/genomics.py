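"""SNP gene dropping and four-state CNV simulation.

Genotypes are produced by dropping gametes from virtual parents sampled out
of a reference haplotype panel (random mating with crossovers), or through
an explicit pedigree. CNVs take one of four per-chromosome states — deletion
(D), normal (N), one duplication (U), two duplications (UU) — giving ten
unordered diplotype classes and total copy numbers 0..6. CNV transmission
uses the single-copy crossover model: crossovers fall between regions, never
inside one, so each parental chromosome state is transmitted intact per
region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import as_rng
from .fixtures import CNVProfile, HaplotypePanel

# per-chromosome CNV states, in coding order
CNV_STATES = ("D", "N", "U", "UU")
#: copies contributed by each state
CNV_COPIES = {"D": 0, "N": 1, "U": 2, "UU": 3}
#: penetrance coding (N is the baseline state)
CNV_CODING = {"D": -1, "N": 0, "U": 1, "UU": 2}

_STATE_INDEX = {s: i for i, s in enumerate(CNV_STATES)}
_COPIES = np.array([CNV_COPIES[s] for s in CNV_STATES])
_CODING = np.array([CNV_CODING[s] for s in CNV_STATES])


@dataclass
class RecombinationMap:
    """Per-interval recombination fractions between adjacent variants."""

    theta: np.ndarray

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.size and (self.theta.min() < 0 or self.theta.max() > 0.5):
            raise ValueError("recombination fractions must lie in [0, 0.5]")

    @classmethod
    def zero(cls, n_variants: int) -> "RecombinationMap":
        return cls(np.zeros(max(n_variants - 1, 0)))

    @classmethod
    def from_rate_per_bp(cls, rate_per_bp: float, positions) -> "RecombinationMap":
        """Constant Morgans-per-bp rate converted to interval fractions via
        Haldane's map function theta = (1 - exp(-2d)) / 2."""
        positions = np.asarray(positions, dtype=float)
        d = rate_per_bp * np.diff(positions)  # genetic distance in Morgans
        return cls(0.5 * (1.0 - np.exp(-2.0 * d)))

    @property
    def n_intervals(self) -> int:
        return self.theta.size


@dataclass
class Pedigree:
    """Individuals with optional parents; founders have both parents None."""

    members: list  # of (individual_id, father_id, mother_id, sex)

    def __post_init__(self):
        ids = [m[0] for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids in pedigree")
        known = set(ids)
        for iid, f, m, _sex in self.members:
            if (f is None) != (m is None):
                raise ValueError(f"{iid}: both parents must be given or both null")
            for p in (f, m):
                if p is not None and p not in known:
                    raise ValueError(f"{iid}: unknown parent {p}")
        self._order = self._toposort()

    def _toposort(self):
        parents = {iid: (f, m) for iid, f, m, _ in self.members}
        order, state = [], {}

        def visit(iid):
            if state.get(iid) == 2:
                return
            if state.get(iid) == 1:
                raise ValueError("pedigree contains a cycle")
            state[iid] = 1
            f, m = parents[iid]
            if f is not None:
                visit(f)
                visit(m)
            state[iid] = 2
            order.append(iid)

        for iid in parents:
            visit(iid)
        return order

    @property
    def order(self):
        """Ids in an order where parents precede children."""
        return list(self._order)

    def parents_of(self, iid):
        for i, f, m, _ in self.members:
            if i == iid:
                return f, m
        raise KeyError(iid)


@dataclass
class Genotypes:
    """Phased genotypes: ordered (paternal, maternal) haplotype matrices.

    The paternal/maternal order is preserved end-to-end because
    allele-specific methylation needs it.
    """

    variant_ids: list
    paternal: np.ndarray  # n_individuals x n_variants, uint8
    maternal: np.ndarray

    def __post_init__(self):
        self.paternal = np.asarray(self.paternal, dtype=np.uint8)
        self.maternal = np.asarray(self.maternal, dtype=np.uint8)
        if self.paternal.shape != self.maternal.shape:
            raise ValueError("paternal/maternal shapes disagree")
        if self.paternal.shape[1] != len(self.variant_ids):
            raise ValueError("variant_ids length disagrees with matrices")

    @property
    def n_individuals(self) -> int:
        return self.paternal.shape[0]

    @property
    def n_variants(self) -> int:
        return self.paternal.shape[1]

    def dosage(self) -> np.ndarray:
        """Additive alt-allele counts, n_individuals x n_variants."""
        return self.paternal.astype(np.int16) + self.maternal

    def column(self, variant_id: str) -> int:
        return self.variant_ids.index(variant_id)

    def subset(self, rows) -> "Genotypes":
        rows = np.asarray(rows)
        return Genotypes(self.variant_ids, self.paternal[rows], self.maternal[rows])


@dataclass
class CNVRegion:
    region_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    state_freqs: tuple  # (f_D, f_N, f_U, f_UU)

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.region_id}: start > end")
        f = np.asarray(self.state_freqs, dtype=float)
        if f.size != 4 or f.min() < 0 or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.region_id}: state_freqs must be a 4-simplex vector")


@dataclass
class CNVData:
    """Per-individual per-region chromosome states (integer codes 0..3)."""

    region_ids: list
    s1: np.ndarray  # n_individuals x n_regions
    s2: np.ndarray

    def __post_init__(self):
        self.s1 = np.asarray(self.s1, dtype=np.int8)
        self.s2 = np.asarray(self.s2, dtype=np.int8)
        if self.s1.shape != self.s2.shape:
            raise ValueError("s1/s2 shapes disagree")

    @property
    def n_individuals(self) -> int:
        return self.s1.shape[0]

    def copy_number(self) -> np.ndarray:
        return _COPIES[self.s1] + _COPIES[self.s2]

    def coding(self) -> tuple:
        """Penetrance codings (C_1, C_2): D=-1, N=0, U=1, UU=2 per chromosome."""
        return _CODING[self.s1], _CODING[self.s2]

    def states(self, individual: int, region: int) -> tuple:
        return (CNV_STATES[self.s1[individual, region]],
                CNV_STATES[self.s2[individual, region]])

    def column(self, region_id: str) -> int:
        return self.region_ids.index(region_id)

    def subset(self, rows) -> "CNVData":
        rows = np.asarray(rows)
        return CNVData(self.region_ids, self.s1[rows], self.s2[rows])


def sample_gamete(hap_a: np.ndarray, hap_b: np.ndarray, rmap: RecombinationMap,
                  rng) -> np.ndarray:
    """Transmit one recombinant gamete from a parent's two haplotypes.

    The starting haplotype is chosen uniformly; a crossover occurs between
    variants t and t+1 with probability ``rmap.theta[t]``.
    """
    rng = as_rng(rng)
    hap_a = np.asarray(hap_a)
    hap_b = np.asarray(hap_b)
    n = hap_a.size
    if rmap.n_intervals != max(n - 1, 0):
        raise ValueError("recombination map length disagrees with haplotypes")
    if n == 0:
        return hap_a.copy()
    start = rng.integers(2)
    switches = rng.random(n - 1) < rmap.theta
    source = (start + np.concatenate(([0], np.cumsum(switches)))) % 2
    return np.where(source == 0, hap_a, hap_b).astype(np.uint8)


def _gametes_batch(hap_a, hap_b, rmap, rng, n):
    """Vectorised: n gametes, each from its own parental haplotype pair."""
    m = hap_a.shape[1]
    if m == 0:
        return hap_a.copy()
    start = rng.integers(2, size=(n, 1))
    switches = rng.random((n, m - 1)) < rmap.theta[None, :]
    source = (start + np.concatenate(
        [np.zeros((n, 1), dtype=np.int64), np.cumsum(switches, axis=1)], axis=1)) % 2
    return np.where(source == 0, hap_a, hap_b).astype(np.uint8)


def drop_unrelated(panel: HaplotypePanel, rmap: RecombinationMap, n: int, rng) -> Genotypes:
    """Gene-drop ``n`` unrelated individuals from the panel.

    Each individual has two virtual parents; a parent is a haplotype pair
    sampled (with replacement) from the panel and transmits one recombinant
    gamete.
    """
    rng = as_rng(rng)
    if n <= 0:
        raise ValueError("n must be positive")
    if panel.n_haplotypes == 0:
        raise ValueError("empty panel")
    if rmap.n_intervals != max(panel.n_variants - 1, 0):
        raise ValueError("recombination map length disagrees with panel")

    def one_gamete_set():
        idx_a = rng.integers(panel.n_haplotypes, size=n)
        idx_b = rng.integers(panel.n_haplotypes, size=n)
        return _gametes_batch(panel.matrix[idx_a], panel.matrix[idx_b], rmap, rng, n)

    paternal = one_gamete_set()
    maternal = one_gamete_set()
    return Genotypes(list(panel.variant_ids), paternal, maternal)


def drop_pedigree(panel: HaplotypePanel, rmap: RecombinationMap, ped: Pedigree,
                  rng) -> dict:
    """Gene-drop a pedigree; returns {individual_id: (paternal, maternal)}.

    Founders are drawn from the panel as in :func:`drop_unrelated`;
    non-founders receive one recombinant gamete from each listed parent
    (from the father's pair into the paternal slot, mother's into maternal).
    """
    rng = as_rng(rng)
    haps: dict = {}
    for iid in ped.order:
        f, m = ped.parents_of(iid)
        if f is None:
            pat = sample_gamete(panel.matrix[rng.integers(panel.n_haplotypes)],
                                panel.matrix[rng.integers(panel.n_haplotypes)], rmap, rng)
            mat = sample_gamete(panel.matrix[rng.integers(panel.n_haplotypes)],
                                panel.matrix[rng.integers(panel.n_haplotypes)], rmap, rng)
        else:
            pat = sample_gamete(*haps[f], rmap, rng)
            mat = sample_gamete(*haps[m], rmap, rng)
        haps[iid] = (pat, mat)
    return haps


def simulate_cnv(profile: CNVProfile, n: int, rng) -> CNVData:
    """Draw each chromosome's CNV state independently from the region's
    state-frequency vector for ``n`` individuals."""
    rng = as_rng(rng)
    if n <= 0:
        raise ValueError("n must be positive")
    r = profile.n_regions
    s1 = np.empty((n, r), dtype=np.int8)
    s2 = np.empty((n, r), dtype=np.int8)
    for k, region in enumerate(profile.regions):
        p = np.asarray(region.state_freqs, dtype=float)
        s1[:, k] = rng.choice(4, size=n, p=p)
        s2[:, k] = rng.choice(4, size=n, p=p)
    return CNVData([reg.region_id for reg in profile.regions], s1, s2)


def cnv_gamete(parent: CNVData, individual: int, rng) -> np.ndarray:
    """Transmit one chromosome state per region (single-copy crossover model:
    regions segregate independently, a region's state is never split)."""
    rng = as_rng(rng)
    pick = rng.integers(2, size=parent.s1.shape[1])
    return np.where(pick == 0, parent.s1[individual], parent.s2[individual]).astype(np.int8)
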