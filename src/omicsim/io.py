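"""Readers and writers for the on-disk formats.

Genotypes go out as phased VCF 4.2 (via pysam) and as an additive-dosage
TSV; CNVs as a per-individual TSV plus a BED of region coordinates (0-based
half-open, as BED requires — everything else in the package is 1-based
inclusive); methylation as bismark-coverage-style TSV; count and protein
matrices as TSV or MatrixMarket with row/column sidecars. Fixture panels
and profiles round-trip through documented TSV schemas. A run manifest
records the config hash, seed and per-file checksums so a rerun can be
verified bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy import io as spio
from scipy import sparse

from .fixtures import (CNVProfile, HaplotypePanel, MethylationProfile,
                       ProteinProfile, RNAProfile)
from .genomics import CNV_STATES, CNVData, CNVRegion, Genotypes
from .methylation import MethylationData


# --- haplotype panel (HAPGEN2-style matrix + variant table) ----------------

def write_panel(panel: HaplotypePanel, prefix) -> tuple:
    """Write ``<prefix>.hap`` (one haplotype per row, space-separated 0/1)
    and ``<prefix>.variants.tsv`` (id, pos, ref, alt, maf)."""
    prefix = Path(prefix)
    hap_path = prefix.with_suffix(".hap")
    var_path = prefix.parent / (prefix.name + ".variants.tsv")
    np.savetxt(hap_path, panel.matrix, fmt="%d", delimiter=" ")
    pd.DataFrame({
        "id": panel.variant_ids,
        "pos": panel.positions,
        "ref": [a[0] for a in panel.alleles],
        "alt": [a[1] for a in panel.alleles],
        "maf": panel.alt_frequencies(),
    }).to_csv(var_path, sep="\t", index=False)
    return hap_path, var_path


def read_panel(prefix) -> HaplotypePanel:
    prefix = Path(prefix)
    matrix = np.loadtxt(prefix.with_suffix(".hap"), dtype=np.uint8, ndmin=2)
    var = pd.read_csv(prefix.parent / (prefix.name + ".variants.tsv"), sep="\t")
    return HaplotypePanel(
        variant_ids=list(var["id"]),
        positions=var["pos"].to_numpy(),
        alleles=list(zip(var["ref"], var["alt"])),
        matrix=matrix,
    )


# --- profiles ---------------------------------------------------------------

def write_methylation_profile(profile: MethylationProfile, path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "cpg_id": profile.cpg_ids,
        "distance_to_next": profile.distance_to_next,
        "rate": profile.rate,
        "status": profile.status,
        "depth_mean": profile.depth_mean,
        "depth_dispersion": profile.depth_dispersion,
    }).to_csv(path, sep="\t", index=False)
    return path


def read_methylation_profile(path) -> MethylationProfile:
    df = pd.read_csv(path, sep="\t")
    return MethylationProfile(
        cpg_ids=list(df["cpg_id"]), distance_to_next=df["distance_to_next"].to_numpy(),
        rate=df["rate"].to_numpy(), status=list(df["status"]),
        depth_mean=df["depth_mean"].to_numpy(),
        depth_dispersion=df["depth_dispersion"].to_numpy())


def write_rnaseq_profile(profile: RNAProfile, path) -> Path:
    """Gene rows first (gene_id, lambda, omega), then reference-individual
    rows (ref_id, c) — a single long TSV with a `kind` column."""
    path = Path(path)
    genes = pd.DataFrame({"kind": "gene", "id": profile.gene_ids,
                          "value1": profile.lam, "value2": profile.omega})
    refs = pd.DataFrame({"kind": "ref", "id": [f"ref{i + 1}" for i in range(profile.c.size)],
                         "value1": profile.c, "value2": np.nan})
    pd.concat([genes, refs]).to_csv(path, sep="\t", index=False)
    return path


def read_rnaseq_profile(path) -> RNAProfile:
    df = pd.read_csv(path, sep="\t")
    genes = df[df["kind"] == "gene"]
    refs = df[df["kind"] == "ref"]
    return RNAProfile(gene_ids=list(genes["id"]), lam=genes["value1"].to_numpy(),
                      omega=genes["value2"].to_numpy(), c=refs["value1"].to_numpy())


def write_protein_profile(profile: ProteinProfile, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#kappa_s={profile.kappa_s}\t#kappa_d={profile.kappa_d}"
                 f"\t#n_steps={profile.n_steps}\n")
        pd.DataFrame({"protein_id": profile.protein_ids, "tau": profile.tau}
                     ).to_csv(fh, sep="\t", index=False)
    return path


def read_protein_profile(path) -> ProteinProfile:
    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh, sep="\t")
    meta = dict(item.lstrip("#").split("=") for item in header.split("\t"))
    return ProteinProfile(protein_ids=list(df["protein_id"]), tau=df["tau"].to_numpy(),
                          kappa_s=float(meta["kappa_s"]), kappa_d=float(meta["kappa_d"]),
                          n_steps=int(meta["n_steps"]))


def write_cnv_profile(profile: CNVProfile, path) -> Path:
    path = Path(path)
    rows = [{"region_id": r.region_id, "chrom": r.chrom, "start": r.start,
             "end": r.end, "f_D": r.state_freqs[0], "f_N": r.state_freqs[1],
             "f_U": r.state_freqs[2], "f_UU": r.state_freqs[3]}
            for r in profile.regions]
    pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end",
                                "f_D", "f_N", "f_U", "f_UU"]
                 ).to_csv(path, sep="\t", index=False)
    return path


def read_cnv_profile(path) -> CNVProfile:
    df = pd.read_csv(path, sep="\t")
    regions = [CNVRegion(region_id=row.region_id, chrom=str(row.chrom),
                         start=int(row.start), end=int(row.end),
                         state_freqs=(row.f_D, row.f_N, row.f_U, row.f_UU))
               for row in df.itertuples()]
    return CNVProfile(regions=regions)


# --- genotypes --------------------------------------------------------------

def write_vcf(genotypes: Genotypes, positions, alleles, path, sample_ids=None,
              chrom: str = "1") -> Path:
    """Write phased genotypes as VCF 4.2 (GT like ``0|1``, paternal first)."""
    path = Path(path)
    positions = np.asarray(positions)
    if positions.size and np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    n = genotypes.n_individuals
    sample_ids = sample_ids or [f"ind{i + 1}" for i in range(n)]
    header = pysam.VariantHeader()
    header.add_line("##source=omicsim")
    header.add_line(f"##contig=<ID={chrom}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in sample_ids:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, vid in enumerate(genotypes.variant_ids):
            rec = vcf.new_record(
                contig=chrom, start=int(positions[j]) - 1,
                stop=int(positions[j]), id=str(vid),
                alleles=(str(alleles[j][0]), str(alleles[j][1])))
            for i, s in enumerate(sample_ids):
                rec.samples[s]["GT"] = (int(genotypes.paternal[i, j]),
                                        int(genotypes.maternal[i, j]))
                rec.samples[s].phased = True
            vcf.write(rec)
    return path


def read_vcf(path) -> Genotypes:
    """Read a phased VCF back into paternal/maternal haplotype matrices."""
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        ids, pat, mat = [], [], []
        for rec in vcf:
            ids.append(rec.id)
            gts = [rec.samples[s]["GT"] for s in samples]
            pat.append([g[0] for g in gts])
            mat.append([g[1] for g in gts])
    if not ids:
        return Genotypes([], np.zeros((len(samples), 0)), np.zeros((len(samples), 0)))
    return Genotypes(ids, np.array(pat).T, np.array(mat).T)


def write_dosage(genotypes: Genotypes, path, sample_ids=None) -> Path:
    path = Path(path)
    n = genotypes.n_individuals
    sample_ids = sample_ids or [f"ind{i + 1}" for i in range(n)]
    df = pd.DataFrame(genotypes.dosage().T, index=genotypes.variant_ids,
                      columns=sample_ids)
    df.index.name = "variant_id"
    df.to_csv(path, sep="\t")
    return path


# --- CNV data ---------------------------------------------------------------

def write_cnv_data(cnv: CNVData, path, sample_ids=None) -> Path:
    path = Path(path)
    n = cnv.n_individuals
    sample_ids = sample_ids or [f"ind{i + 1}" for i in range(n)]
    cn = cnv.copy_number()
    rows = []
    for i in range(n):
        for k, rid in enumerate(cnv.region_ids):
            rows.append((sample_ids[i], rid, CNV_STATES[cnv.s1[i, k]],
                         CNV_STATES[cnv.s2[i, k]], cn[i, k]))
    pd.DataFrame(rows, columns=["individual", "region", "s1", "s2", "copy_number"]
                 ).to_csv(path, sep="\t", index=False)
    return path


def write_cnv_bed(profile: CNVProfile, path) -> Path:
    """Region coordinates as BED (0-based half-open)."""
    path = Path(path)
    with open(path, "w") as fh:
        for r in profile.regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.region_id}\n")
    return path


# --- methylation ------------------------------------------------------------

def write_methylation_coverage(data: MethylationData, positions, path,
                               individual: int = 0, chrom: str = "1") -> Path:
    """Bismark-coverage-style TSV for one individual: chrom, pos, pos,
    methylation %, count_methylated, count_unmethylated. Zero-depth CpGs
    are omitted."""
    path = Path(path)
    positions = np.asarray(positions)
    t = data.total[individual]
    m = data.methylated[individual]
    if np.any(m > t):
        raise ValueError("methylated exceeds total")
    keep = t > 0
    df = pd.DataFrame({
        "chrom": chrom, "start": positions[keep], "end": positions[keep],
        "pct": 100.0 * m[keep] / t[keep],
        "count_methylated": m[keep], "count_unmethylated": (t - m)[keep],
    })
    df.to_csv(path, sep="\t", index=False, header=False)
    return path


def read_methylation_coverage(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "pct",
                              "count_methylated", "count_unmethylated"])


# --- matrices ---------------------------------------------------------------

def write_matrix(matrix, row_ids, col_ids, path, fmt: str = "tsv") -> Path:
    """Lossless matrix writer. ``fmt='tsv'`` writes a labelled TSV;
    ``fmt='mtx'`` writes MatrixMarket with ``.rows``/``.cols`` sidecars."""
    path = Path(path)
    matrix = np.asarray(matrix)
    if matrix.shape != (len(row_ids), len(col_ids)):
        raise ValueError("row/col id lengths disagree with the matrix shape")
    if fmt == "tsv":
        df = pd.DataFrame(matrix, index=list(row_ids), columns=list(col_ids))
        df.index.name = "id"
        df.to_csv(path, sep="\t")
    elif fmt == "mtx":
        spio.mmwrite(str(path), sparse.csr_matrix(matrix))
        Path(str(path) + ".rows").write_text("\n".join(map(str, row_ids)) + "\n"
                                             if len(row_ids) else "")
        Path(str(path) + ".cols").write_text("\n".join(map(str, col_ids)) + "\n"
                                             if len(col_ids) else "")
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")
    return path


def read_matrix(path, fmt: str = "tsv"):
    path = Path(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return df.to_numpy(), list(df.index), list(df.columns)
    if fmt == "mtx":
        m = spio.mmread(str(path)).toarray()
        rows = Path(str(path) + ".rows").read_text().splitlines()
        cols = Path(str(path) + ".cols").read_text().splitlines()
        return m, rows, cols
    raise ValueError(f"unknown matrix format {fmt!r}")


def write_ase(ase: dict, path, sample_ids=None) -> Path:
    """Allele-specific read counts: sample, gene, ref_reads, alt_reads, het."""
    path = Path(path)
    n = ase["ref"].shape[1]
    sample_ids = sample_ids or [f"ind{i + 1}" for i in range(n)]
    rows = []
    for g, gid in enumerate(ase["gene_ids"]):
        for i in range(n):
            rows.append((sample_ids[i], gid, ase["ref"][g, i], ase["alt"][g, i],
                         int(ase["het"][g, i])))
    pd.DataFrame(rows, columns=["sample", "gene", "ref_reads", "alt_reads", "het"]
                 ).to_csv(path, sep="\t", index=False)
    return path


def write_phenotype(status, path, sample_ids=None) -> Path:
    """Two-column phenotype TSV, status coded 1 = control, 2 = case."""
    path = Path(path)
    status = np.asarray(status, dtype=bool)
    sample_ids = sample_ids or [f"ind{i + 1}" for i in range(status.size)]
    pd.DataFrame({"sample_id": sample_ids, "status": np.where(status, 2, 1)}
                 ).to_csv(path, sep="\t", index=False)
    return path


# --- full dataset -----------------------------------------------------------

def write_dataset(dataset, out_dir) -> "Path":
    """Write every layer of an :class:`omicsim.scenarios.OmicsDataset` plus
    the config and a checksum manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.yaml").write_text(dataset.config.to_yaml())

    fx_ = dataset.fixtures
    cohorts = [("training", dataset.training)]
    if dataset.validation is not None:
        cohorts.append(("validation", dataset.validation))
    for tag, co in cohorts:
        d = out_dir / tag
        d.mkdir(exist_ok=True)
        samples = [f"{tag}{i + 1}" for i in range(co.n)]
        write_phenotype(co.status, d / "phenotype.tsv", samples)
        if co.genotypes is not None:
            write_vcf(co.genotypes, fx_.panel.positions, fx_.panel.alleles,
                      d / "genotypes.vcf", samples)
            write_dosage(co.genotypes, d / "dosage.tsv", samples)
        if co.cnv is not None:
            write_cnv_data(co.cnv, d / "cnv.tsv", samples)
        if co.methylation is not None:
            write_matrix(co.methylation.total.T, co.methylation.cpg_ids, samples,
                         d / "methylation_total.tsv")
            write_matrix(co.methylation.methylated.T, co.methylation.cpg_ids, samples,
                         d / "methylation_methylated.tsv")
        if co.expression is not None:
            write_matrix(co.expression.counts, co.expression.gene_ids, samples,
                         d / "expression.tsv")
            if co.expression.ase is not None:
                write_ase(co.expression.ase, d / "ase.tsv", samples)
        if co.proteins is not None:
            write_matrix(co.proteins.levels, co.proteins.protein_ids, samples,
                         d / "protein.tsv")
    write_cnv_bed(fx_.cnv_profile, out_dir / "cnv_regions.bed")
    return write_manifest(out_dir, dataset.config.config_hash(), dataset.seed)


# --- manifest ---------------------------------------------------------------

def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(out_dir, config_hash: str, seed: int, version: str = "0.1.0") -> Path:
    """Checksum every file in ``out_dir`` into manifest.json."""
    out_dir = Path(out_dir)
    files = sorted(p for p in out_dir.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config_hash": config_hash,
        "seed": seed,
        "version": version,
        "checksums": {str(p.relative_to(out_dir)): file_checksum(p) for p in files},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
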