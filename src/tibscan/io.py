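"""Shared data model and file IO.

The pipeline's in-memory containers are thin dataclasses around numpy
arrays and a pandas variant table:

* :class:`GenotypeMatrix` — per-sample diploid ALT-dosage calls (0/1/2,
  ``-1`` for missing) over biallelic SNVs.
* :class:`HaplotypeMatrix` — phased 0/1 haplotypes, two per sample, built
  only from sites that are complete (non-missing) and fully phased.
* :class:`GeneInterval` — a gene span in 1-based closed coordinates.

Coordinates are 1-based closed throughout (the VCF/GFF3 convention); BED
input is converted at the boundary.  Only biallelic SNVs enter the
pipeline; other records are skipped with a logged count.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


def make_variant_table(chrom, pos, ref, alt, ids=None) -> pd.DataFrame:
    """Assemble a variant table; SNV ids default to ``chrom:pos``."""
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    if ids is None:
        ids = np.array([f"{c}:{p}" for c, p in zip(chrom, pos)], dtype=object)
    df = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "id": ids, "ref": list(ref), "alt": list(alt)}
    )
    return df


def _check_variants(variants: pd.DataFrame) -> None:
    if list(variants.columns) != VARIANT_COLUMNS:
        raise ValueError(f"variant table must have columns {VARIANT_COLUMNS}")
    for _, sub in variants.groupby("chrom", sort=False):
        d = np.diff(sub["pos"].to_numpy())
        if len(d) and not (d > 0).all():
            raise ValueError("variant positions must be strictly increasing per chrom")
    for col in ("ref", "alt"):
        bases = variants[col].astype(str)
        if not bases.str.fullmatch("[ACGTacgt]").all():
            raise ValueError(f"{col} alleles must be single bases (biallelic SNVs only)")


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls: ALT-allele dosage per sample per site."""

    sample_ids: list[str]
    variants: pd.DataFrame
    calls: np.ndarray  # (n_samples, n_sites) int8; -1 = missing

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError("calls shape does not match sample/variant counts")
        bad = ~np.isin(self.calls, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        _check_variants(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.variants)

    def take_samples(self, keep: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in keep],
            self.variants.reset_index(drop=True),
            self.calls[keep],
        )

    def take_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            list(self.sample_ids),
            self.variants.loc[mask].reset_index(drop=True),
            self.calls[:, mask],
        )

    def missing_fraction_per_sample(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=1)

    def missing_fraction_per_site(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)


@dataclass
class HaplotypeMatrix:
    """Phased haplotypes (0 = ancestral/REF, 1 = derived/ALT), two per sample."""

    haplotype_ids: list[str]
    variants: pd.DataFrame
    alleles: np.ndarray  # (2*n_samples, n_sites) uint8

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.shape != (len(self.haplotype_ids), len(self.variants)):
            raise ValueError("alleles shape does not match haplotype/variant counts")
        if not np.isin(self.alleles, [0, 1]).all():
            raise ValueError("haplotype codes must be 0/1 (complete-case sites only)")
        _check_variants(self.variants)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_ids)

    @property
    def n_sites(self) -> int:
        return len(self.variants)

    @property
    def positions(self) -> np.ndarray:
        return self.variants["pos"].to_numpy()

    def take_haplotypes(self, rows: np.ndarray) -> "HaplotypeMatrix":
        rows = np.asarray(rows)
        return HaplotypeMatrix(
            [self.haplotype_ids[i] for i in rows],
            self.variants.reset_index(drop=True),
            self.alleles[rows],
        )

    def take_sites(self, mask: np.ndarray) -> "HaplotypeMatrix":
        mask = np.asarray(mask)
        return HaplotypeMatrix(
            list(self.haplotype_ids),
            self.variants.loc[mask].reset_index(drop=True),
            self.alleles[:, mask],
        )


@dataclass(frozen=True)
class GeneInterval:
    """A gene span, 1-based closed after normalisation."""

    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start_bp < 1 or self.end_bp < self.start_bp:
            raise ValueError(f"invalid interval for {self.gene_id}")


def read_population_map(path) -> dict[str, str]:
    """TSV with columns sample_id, population (one of T/S/H or any labels)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"population map {path} needs two columns (sample_id, population)")
    col0, col1 = df.columns[:2]
    return dict(zip(df[col0], df[col1]))


def read_vcf(path, population_map: Mapping[str, str] | None = None):
    """Read a VCF into a :class:`GenotypeMatrix` and a :class:`HaplotypeMatrix`.

    Multi-allelic and non-SNV records are skipped (counted in the returned
    stats dict).  The haplotype matrix keeps only sites where every call is
    non-missing and every heterozygote is phased; unphased heterozygotes at
    otherwise-complete sites drop the site from the haplotype matrix only.

    Returns ``(gm, hm, stats)``.  Raises ``ValueError`` when the VCF lacks
    a GT FORMAT field or contains samples absent from *population_map*.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    try:
        vcf.get_header_type("GT")
    except KeyError:
        raise ValueError(f"{path}: VCF has no GT FORMAT field")
    samples = list(vcf.samples)
    if population_map is not None:
        unknown = [s for s in samples if s not in population_map]
        if unknown:
            raise ValueError(
                f"{path}: samples absent from population map: {', '.join(unknown)}"
            )

    chroms, poss, refs, alts, ids = [], [], [], [], []
    geno_rows = []  # per-site (n_samples, 2) allele arrays, -1 missing
    phased_rows = []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        if v.REF not in "ACGT" or v.ALT[0] not in "ACGT":
            n_skipped += 1
            continue
        g = np.array(v.genotypes, dtype=np.int16)  # (n, 3): a0, a1, phased
        geno_rows.append(g[:, :2])
        phased_rows.append(g[:, 2].astype(bool))
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic/non-SNV records", n_skipped)
    if not chroms:
        raise ValueError(f"{path}: no biallelic SNV records")

    variants = make_variant_table(chroms, poss, refs, alts, ids)
    allele_arr = np.stack(geno_rows, axis=2)  # (n_samples, 2, n_sites)
    phased_arr = np.stack(phased_rows, axis=1)  # (n_samples, n_sites)

    missing = (allele_arr < 0).any(axis=1)  # (n_samples, n_sites)
    calls = allele_arr.clip(min=0).sum(axis=1).astype(np.int8)
    calls[missing] = MISSING
    gm = GenotypeMatrix(samples, variants, calls)

    het = calls == 1
    complete = ~missing.any(axis=0)
    # homozygotes may be written unphased ("/") without ambiguity
    unphased_het = het & ~phased_arr
    fully_phased = ~unphased_het.any(axis=0)
    hap_sites = complete & fully_phased
    n_unphased = int((complete & ~fully_phased).sum())
    if n_unphased:
        logger.info(
            "read_vcf: %d complete sites dropped from haplotypes (unphased hets)",
            n_unphased,
        )
    hap_ids = [f"{s}_{k}" for s in samples for k in (1, 2)]
    # C-order reshape gives rows (s0_h1, s0_h2, s1_h1, ...)
    alleles = allele_arr[:, :, hap_sites].reshape(len(samples) * 2, -1)
    hm = HaplotypeMatrix(
        hap_ids,
        variants.loc[hap_sites].reset_index(drop=True),
        alleles.astype(np.uint8),
    )
    stats = {
        "n_skipped_records": n_skipped,
        "n_sites": int(len(variants)),
        "n_hap_sites": int(hap_sites.sum()),
        "n_unphased_dropped": n_unphased,
    }
    return gm, hm, stats


def write_vcf(path, variants: pd.DataFrame, sample_ids: Sequence[str],
              phased_alleles: np.ndarray) -> None:
    """Write a minimal VCF 4.2 with phased GT.

    *phased_alleles* is ``(n_samples, 2, n_sites)`` int8; a value of -1 in
    either allele writes ``./.`` for that genotype.
    """
    phased_alleles = np.asarray(phased_alleles)
    n_samples, two, n_sites = phased_alleles.shape
    assert two == 2 and n_sites == len(variants) and n_samples == len(sample_ids)
    chroms = variants["chrom"].to_numpy()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(chroms):
            sub = variants.loc[variants["chrom"] == chrom, "pos"]
            fh.write(f"##contig=<ID={chrom},length={int(sub.max()) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for j in range(n_sites):
            row = variants.iloc[j]
            gts = []
            for i in range(n_samples):
                a0, a1 = phased_alleles[i, :, j]
                gts.append("./." if a0 < 0 or a1 < 0 else f"{a0}|{a1}")
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_population_map(path, popmap: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for sample, pop in popmap.items():
            fh.write(f"{sample}\t{pop}\n")


def read_genes(path, fmt: str | None = None) -> list[GeneInterval]:
    """Read gene intervals from BED or GFF3 into 1-based closed coordinates.

    BED half-open ``[start, end)`` becomes ``[start+1, end]``.  For GFF3
    only records of type ``gene`` are used.  Output is sorted by
    (chrom, start); unsorted input is tolerated.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "bed"
    genes: list[GeneInterval] = []
    if fmt == "bed":
        df = pd.read_csv(
            path, sep=r"\s+", comment="#", header=None, dtype={0: str}
        )
        for k, row in enumerate(df.itertuples(index=False)):
            chrom, start, end = str(row[0]), int(row[1]), int(row[2])
            if start < 0:
                raise ValueError(f"{path}: negative BED coordinate at line {k + 1}")
            name = str(row[3]) if len(row) > 3 else f"gene{k + 1}"
            strand = str(row[5]) if len(row) > 5 else "."
            genes.append(GeneInterval(name, chrom, start + 1, end, strand))
    elif fmt == "gff3":
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        for feat in db.features_of_type("gene"):
            if feat.start < 0 or feat.end < 0:
                raise ValueError(f"{path}: negative GFF3 coordinate for {feat.id}")
            gene_id = feat.attributes.get("ID", [feat.id])[0]
            genes.append(
                GeneInterval(gene_id, feat.seqid, feat.start, feat.end, feat.strand or ".")
            )
    else:
        raise ValueError(f"unknown gene format: {fmt!r}")
    genes.sort(key=lambda g: (g.chrom, g.start_bp, g.gene_id))
    return genes


def write_genes_bed(path, genes: Sequence[GeneInterval]) -> None:
    """Write intervals back to BED (0-based half-open)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start_bp - 1}\t{g.end_bp}\t{g.gene_id}\t0\t{g.strand}\n")


def write_genes_gff3(path, genes: Sequence[GeneInterval]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\ttibscan\tgene\t{g.start_bp}\t{g.end_bp}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
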