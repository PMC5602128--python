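"""VCF and table I/O plus gene-interval restriction.

All coordinates follow the VCF convention: 1-based positions, 1-based
inclusive intervals. Genotype calls are stored as small integer codes in a
dense accessions × sites matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

log = logging.getLogger(__name__)

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_CODE_TO_GT = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}


@dataclass(frozen=True)
class VariantSite:
    """One biallelic SNP."""

    site_id: str
    gene: str
    contig: str
    position: int  # 1-based, as in VCF
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles identical at {self.site_id}")


@dataclass(frozen=True)
class GeneInterval:
    """1-based inclusive interval labelling a gene on a contig."""

    gene: str
    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end} ({self.gene})")

    def contains(self, contig: str, position: int) -> bool:
        return contig == self.contig and self.start <= position <= self.end


class GenotypeMatrix:
    """Accessions × sites grid of genotype calls.

    ``calls[i, j]`` is one of HOM_REF, HET, HOM_ALT, MISSING for accession i
    at site j. Site (column) order follows physical order.
    """

    def __init__(self, accessions: Sequence[str], sites: Sequence[VariantSite],
                 calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(accessions), len(sites)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(accessions)} accessions x {len(sites)} sites")
        bad = ~np.isin(calls, (HOM_REF, HET, HOM_ALT, MISSING))
        if bad.any():
            raise ValueError("calls contain codes outside {HOM_REF, HET, HOM_ALT, MISSING}")
        self.accessions = list(accessions)
        self.sites = list(sites)
        self.calls = calls

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset_sites(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(self.accessions, [self.sites[j] for j in idx],
                              self.calls[:, idx])

    def subset_accessions(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix([self.accessions[i] for i in idx], self.sites,
                              self.calls[idx, :])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (self.accessions == other.accessions and self.sites == other.sites
                and np.array_equal(self.calls, other.calls))


def _classify_gt(gt: tuple) -> int:
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return MISSING
    vals = set(alleles)
    if vals == {0}:
        return HOM_REF
    if vals == {1}:
        return HOM_ALT
    return HET


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a multi-sample VCF into a GenotypeMatrix.

    Diploid GT 0/0 → HOM_REF, 1/1 → HOM_ALT, 0/1 or 1/0 → HET, ./. → MISSING;
    phased separators and haploid calls (mapped to the homozygous class) are
    accepted. Records that are not biallelic SNPs are skipped with a warning.
    """
    with pysam.VariantFile(str(path)) as vf:
        if "GT" not in vf.header.formats:
            raise ValueError(f"{path}: VCF has no GT FORMAT definition")
        accessions = list(vf.header.samples)
        sites: list[VariantSite] = []
        rows: list[list[int]] = []
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                log.warning("skipping non-biallelic record %s:%s", rec.contig, rec.pos)
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                log.warning("skipping non-SNP record %s:%s (%s>%s)",
                            rec.contig, rec.pos, ref, alt)
                continue
            gene = rec.info.get("GENE", "") if "GENE" in vf.header.info else ""
            if isinstance(gene, tuple):
                gene = gene[0]
            sites.append(VariantSite(
                site_id=rec.id or f"{rec.contig}_{rec.pos}",
                gene=str(gene), contig=rec.contig, position=rec.pos,
                ref_allele=ref, alt_allele=alt))
            rows.append([_classify_gt(rec.samples[s].get("GT") or ()) for s in accessions])
    calls = (np.array(rows, dtype=np.int8).T if rows
             else np.empty((len(accessions), 0), dtype=np.int8))
    return GenotypeMatrix(accessions, sites, calls)


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as uncompressed VCF v4.2 with per-sample GT."""
    header = pysam.VariantHeader()
    contigs: list[str] = []
    for s in matrix.sites:
        if s.contig not in contigs:
            contigs.append(s.contig)
    for c in contigs:
        header.add_line(f"##contig=<ID={c}>")
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene label">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for name in matrix.accessions:
        header.add_sample(name)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j, site in enumerate(matrix.sites):
            rec = vf.new_record(
                contig=site.contig, start=site.position - 1,
                alleles=(site.ref_allele, site.alt_allele), id=site.site_id)
            if site.gene:
                rec.info["GENE"] = site.gene
            for i, name in enumerate(matrix.accessions):
                rec.samples[name]["GT"] = _CODE_TO_GT[int(matrix.calls[i, j])]
            vf.write(rec)


def restrict_to_intervals(matrix: GenotypeMatrix,
                          intervals: Sequence[GeneInterval]) -> GenotypeMatrix:
    """Keep sites falling inside any interval and label them with its gene.

    Interval ends are inclusive. Overlapping intervals on the same contig with
    different gene labels are rejected (the gene annotation would be ambiguous).
    """
    ivs = list(intervals)
    for i, a in enumerate(ivs):
        for b in ivs[i + 1:]:
            if (a.contig == b.contig and a.gene != b.gene
                    and a.start <= b.end and b.start <= a.end):
                raise ValueError(
                    f"overlapping intervals with conflicting gene labels: "
                    f"{a.gene} and {b.gene} on {a.contig}")
    kept: list[int] = []
    new_sites: list[VariantSite] = []
    for j, site in enumerate(matrix.sites):
        for iv in ivs:
            if iv.contains(site.contig, site.position):
                kept.append(j)
                new_sites.append(replace(site, gene=iv.gene))
                break
    sub = matrix.subset_sites(kept)
    return GenotypeMatrix(sub.accessions, new_sites, sub.calls)


INTERVAL_HEADER = "#coords=1-based-inclusive"


def write_intervals(intervals: Iterable[GeneInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(INTERVAL_HEADER + "\n")
        fh.write("gene\tcontig\tstart\tend\n")
        for iv in intervals:
            fh.write(f"{iv.gene}\t{iv.contig}\t{iv.start}\t{iv.end}\n")


def read_intervals(path: str | Path) -> list[GeneInterval]:
    intervals = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    body = [ln for ln in lines if not ln.startswith("#")]
    for ln in body[1:]:  # skip column header
        gene, contig, start, end = ln.split("\t")
        intervals.append(GeneInterval(gene, contig, int(start), int(end)))
    return intervals


def write_table(rows: Sequence[dict], path: str | Path,
                header_comment: str | None = None) -> None:
    """Write dict rows as a TSV with a header row (deterministic column order)."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        if not rows:
            return
        cols = list(rows[0].keys())
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
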