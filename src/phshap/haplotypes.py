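"""Haplotype definition from genotype matrices.

The core inference: filter sites by minor-allele frequency and accessions by
homozygosity, reconstruct per-accession allele strings (R = reference allele,
A = alternate allele), enumerate distinct haplotypes named H1, H2, ... by
descending membership, choose small informative SNP subsets, and type new
panels against reference haplotypes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .variant_io import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING


@dataclass(frozen=True)
class Haplotype:
    """A distinct allele string over an ordered site list, with its members."""

    name: str
    alleles: str  # string over {R, A}
    members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.alleles) - {"R", "A"}
        if bad:
            raise ValueError(f"haplotype alleles must be over {{R,A}}, got {bad}")

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class FilterReport:
    sites_in: int
    sites_kept: int
    accessions_in: int
    accessions_kept: int
    site_maf: dict[str, float] = field(default_factory=dict)
    accession_homozygosity: dict[str, float] = field(default_factory=dict)


def site_allele_frequency(matrix: GenotypeMatrix, site_index: int) -> float:
    """Minor-allele frequency at one site over non-missing allele counts.

    Homozygous calls contribute two copies of one allele, heterozygous calls
    one of each. Returns 0.0 when every call is missing.
    """
    col = matrix.calls[:, site_index]
    n_ref = 2 * int((col == HOM_REF).sum()) + int((col == HET).sum())
    n_alt = 2 * int((col == HOM_ALT).sum()) + int((col == HET).sum())
    total = n_ref + n_alt
    if total == 0:
        return 0.0
    return min(n_ref, n_alt) / total


def filter_panel(matrix: GenotypeMatrix, maf_min: float = 0.05,
                 hom_min: float = 0.80) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop rare sites, then heterogeneous accessions (strict > thresholds).

    Sites are kept when their minor-allele frequency exceeds *maf_min*;
    accessions are kept when their fraction of homozygous calls among
    non-missing calls over the *kept* sites exceeds *hom_min*. Both
    comparisons are strict, so a site at exactly 5% MAF or an accession at
    exactly 80% homozygosity is dropped.
    """
    if matrix.n_sites == 0 or matrix.n_accessions == 0:
        raise ValueError("cannot filter an empty genotype matrix")
    report = FilterReport(sites_in=matrix.n_sites, sites_kept=0,
                          accessions_in=matrix.n_accessions, accessions_kept=0)
    keep_sites = []
    for j, site in enumerate(matrix.sites):
        maf = site_allele_frequency(matrix, j)
        report.site_maf[site.site_id] = maf
        if maf > maf_min:
            keep_sites.append(j)
    if not keep_sites:
        raise ValueError("all sites removed by the MAF filter")
    sub = matrix.subset_sites(keep_sites)

    keep_acc = []
    for i, name in enumerate(sub.accessions):
        row = sub.calls[i, :]
        non_missing = int((row != MISSING).sum())
        hom = int(((row == HOM_REF) | (row == HOM_ALT)).sum())
        frac = hom / non_missing if non_missing else 0.0
        report.accession_homozygosity[name] = frac
        if frac > hom_min:
            keep_acc.append(i)
    if not keep_acc:
        raise ValueError("all accessions removed by the homozygosity filter")
    out = sub.subset_accessions(keep_acc)
    report.sites_kept = out.n_sites
    report.accessions_kept = out.n_accessions
    return out, report


def reconstruct_haplotypes(matrix: GenotypeMatrix
                           ) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Per-accession allele strings (HOM_REF→R, HOM_ALT→A).

    Accessions with any heterozygous or missing call over the site list are
    returned in the second mapping with the offending site ids.
    """
    strings: dict[str, str] = {}
    unassigned: dict[str, list[str]] = {}
    for i, name in enumerate(matrix.accessions):
        row = matrix.calls[i, :]
        bad = [matrix.sites[j].site_id for j in range(matrix.n_sites)
               if row[j] in (HET, MISSING)]
        if bad:
            unassigned[name] = bad
        else:
            strings[name] = "".join("R" if c == HOM_REF else "A" for c in row)
    return strings, unassigned


def enumerate_haplotypes(strings: Mapping[str, str]) -> list[Haplotype]:
    """Group identical allele strings into named haplotypes.

    Names H1, H2, ... are assigned in descending member count; ties are broken
    by first occurrence in the accession iteration order, so output is
    deterministic for a fixed input ordering.
    """
    if not strings:
        raise ValueError("no allele strings to enumerate")
    order: dict[str, int] = {}
    groups: dict[str, list[str]] = {}
    for idx, (acc, s) in enumerate(strings.items()):
        if s not in groups:
            groups[s] = []
            order[s] = idx
        groups[s].append(acc)
    ranked = sorted(groups, key=lambda s: (-len(groups[s]), order[s]))
    return [Haplotype(name=f"H{r + 1}", alleles=s, members=tuple(groups[s]))
            for r, s in enumerate(ranked)]


def _weighted_maf(haplotypes: Sequence[Haplotype], j: int) -> float:
    total = sum(h.n_members for h in haplotypes)
    if total == 0:
        return 0.0
    n_alt = sum(h.n_members for h in haplotypes if h.alleles[j] == "A")
    return min(n_alt, total - n_alt) / total


def _pairs_distinguished(haplotypes: Sequence[Haplotype],
                         subset: Sequence[int]) -> set[tuple[int, int]]:
    out = set()
    for a, b in itertools.combinations(range(len(haplotypes)), 2):
        if any(haplotypes[a].alleles[j] != haplotypes[b].alleles[j] for j in subset):
            out.add((a, b))
    return out


def select_informative_snps(haplotypes: Sequence[Haplotype], k: int,
                            maf_min: float = 0.30,
                            exhaustive: bool = False) -> tuple[list[int], int]:
    """Pick up to *k* site indices that best distinguish the haplotypes.

    Candidate sites must have accession-weighted minor-allele frequency
    strictly above *maf_min*. The default strategy greedily adds the site
    resolving the most still-unresolved haplotype pairs (ties: larger MAF,
    then left-most position); with ``exhaustive=True`` (candidate counts
    ≤ ~12) the minimum-size subset achieving maximal resolution is found by
    enumeration. Returns (site indices, number of unresolved pairs).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_sites = len(haplotypes[0].alleles)
    candidates = [j for j in range(n_sites)
                  if _weighted_maf(haplotypes, j) > maf_min]
    if not candidates:
        raise ValueError(f"no candidate sites with weighted MAF > {maf_min}")
    all_pairs = set(itertools.combinations(range(len(haplotypes)), 2))

    if exhaustive:
        best: list[int] | None = None
        best_resolved = -1
        for size in range(1, min(k, len(candidates)) + 1):
            for combo in itertools.combinations(candidates, size):
                resolved = len(_pairs_distinguished(haplotypes, combo))
                if resolved > best_resolved:
                    best_resolved = resolved
                    best = list(combo)
            if best is not None and best_resolved == len(all_pairs):
                break
        assert best is not None
        return best, len(all_pairs) - best_resolved

    chosen: list[int] = []
    resolved: set[tuple[int, int]] = set()
    remaining = list(candidates)
    while remaining and len(chosen) < k and resolved != all_pairs:
        def gain(j: int) -> tuple[int, float, int]:
            new = _pairs_distinguished(haplotypes, chosen + [j]) - resolved
            return (len(new), _weighted_maf(haplotypes, j), -j)

        best_site = max(remaining, key=gain)
        if gain(best_site)[0] == 0:
            break
        chosen.append(best_site)
        remaining.remove(best_site)
        resolved = _pairs_distinguished(haplotypes, chosen)
    return chosen, len(all_pairs) - len(resolved)


def assign_to_haplotypes(new_matrix: GenotypeMatrix,
                         subset_site_ids: Sequence[str],
                         references: Sequence[Haplotype],
                         reference_site_ids: Sequence[str]
                         ) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Type a new panel against reference haplotypes projected onto a SNP subset.

    Each accession's homozygous allele string over the subset is matched
    against reference projections: a unique match yields that haplotype name;
    a projection collision yields a compound label ("H5/H7"); an unseen string
    gets a fresh panel-specific name N1, N2, ...; accessions heterozygous or
    missing at any subset site are returned as unassigned with those sites.
    """
    site_pos = {s.site_id: j for j, s in enumerate(new_matrix.sites)}
    missing_ids = [sid for sid in subset_site_ids if sid not in site_pos]
    if missing_ids:
        raise ValueError(f"subset sites absent from new panel: {missing_ids}")
    ref_pos = {sid: j for j, sid in enumerate(reference_site_ids)}
    missing_ref = [sid for sid in subset_site_ids if sid not in ref_pos]
    if missing_ref:
        raise ValueError(f"subset sites absent from reference definition: {missing_ref}")

    projections: dict[str, list[str]] = {}
    for h in references:
        proj = "".join(h.alleles[ref_pos[sid]] for sid in subset_site_ids)
        projections.setdefault(proj, []).append(h.name)

    cols = [site_pos[sid] for sid in subset_site_ids]
    assignments: dict[str, str] = {}
    unassigned: dict[str, list[str]] = {}
    novel: dict[str, str] = {}
    for i, acc in enumerate(new_matrix.accessions):
        row = new_matrix.calls[i, cols]
        bad = [subset_site_ids[j] for j, c in enumerate(row) if c in (HET, MISSING)]
        if bad:
            unassigned[acc] = bad
            continue
        s = "".join("R" if c == HOM_REF else "A" for c in row)
        if s in projections:
            assignments[acc] = "/".join(projections[s])
        else:
            if s not in novel:
                novel[s] = f"N{len(novel) + 1}"
            assignments[acc] = novel[s]
    return assignments, unassigned


def haplotype_table(haplotypes: Sequence[Haplotype]) -> list[dict]:
    """Rows for the haplotype TSV: name, allele string, member count, members."""
    return [{"haplotype": h.name, "alleles": h.alleles,
             "n_members": h.n_members, "members": ",".join(h.members)}
            for h in haplotypes]
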