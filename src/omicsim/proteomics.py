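"""Protein-expression simulation via the mass-action kinetic model.

A protein k in individual j has a latent mean eta updated as

    eta_{t+1} = eta_t + (x * kappa_s - eta_t * kappa_d)

where x is the MAD-normalized expression of the encoding gene, and kappa_s /
kappa_d are synthesis and degradation rates (kappa_d defaults to 1, at which
the recurrence reaches its fixed point eta* = x * kappa_s / kappa_d in one
step). The observed level is Normal(eta_final, tau_k) with tau_k resampled
with replacement from the profile's SD vector — an RPPA-like normalized,
real-valued readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import as_rng
from .fixtures import ProteinProfile
from .transcriptomics import CountMatrix

MAD_CONSISTENCY = 1.4826  # Gaussian consistency constant


class ZeroMADError(ValueError):
    """Raised when a gene's counts are constant across individuals."""


def mad_normalize(values) -> np.ndarray:
    """Median/MAD scale normalization of one gene's counts across individuals.

    x = (v - median(v)) / (1.4826 * MAD(v)); raises :class:`ZeroMADError`
    for a constant gene (zero MAD).
    """
    v = np.asarray(values, dtype=float)
    if np.unique(v).size < 2:
        raise ZeroMADError("zero MAD: gene is constant across individuals")
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        raise ZeroMADError("zero MAD: more than half the values are tied at the median")
    return (v - med) / (MAD_CONSISTENCY * mad)


def kinetic_step(eta, x, kappa_s: float, kappa_d: float) -> np.ndarray:
    """One mass-action update eta + (x*kappa_s - eta*kappa_d)."""
    eta = np.asarray(eta, dtype=float)
    x = np.asarray(x, dtype=float)
    return eta + (x * kappa_s - eta * kappa_d)


@dataclass
class ProteinMatrix:
    protein_ids: list
    gene_ids: list  # encoding gene per protein
    levels: np.ndarray  # proteins x individuals
    tau: np.ndarray  # realized per-protein SD

    def row(self, protein_id: str) -> int:
        return self.protein_ids.index(protein_id)


def simulate_protein(expr: CountMatrix, profile: ProteinProfile,
                     gene_for_protein: dict | None = None, rng=None) -> ProteinMatrix:
    """Simulate observed protein levels from a count matrix.

    ``gene_for_protein`` maps protein id -> encoding gene id; by default
    protein k maps to the k-th gene of the expression matrix. eta starts at
    the normalized expression x and is iterated ``profile.n_steps`` times.
    """
    rng = as_rng(rng)
    if gene_for_protein is None:
        if len(profile.protein_ids) > len(expr.gene_ids):
            raise ValueError("more proteins than genes and no explicit mapping")
        gene_for_protein = {pid: expr.gene_ids[k]
                            for k, pid in enumerate(profile.protein_ids)}
    missing = [g for g in gene_for_protein.values() if g not in expr.gene_ids]
    if missing:
        raise KeyError(f"proteins map to genes absent from the count matrix: {missing}")

    n_prot = len(profile.protein_ids)
    n_ind = expr.counts.shape[1]
    tau = rng.choice(profile.tau, size=n_prot, replace=True)
    levels = np.empty((n_prot, n_ind))
    genes = []
    for k, pid in enumerate(profile.protein_ids):
        gid = gene_for_protein[pid]
        genes.append(gid)
        x = mad_normalize(expr.counts[expr.row(gid)])
        eta = x.copy()
        for _ in range(profile.n_steps):
            eta = kinetic_step(eta, x, profile.kappa_s, profile.kappa_d)
        levels[k] = eta if tau[k] == 0 else rng.normal(eta, tau[k])
    return ProteinMatrix(list(profile.protein_ids), genes, levels, tau)
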