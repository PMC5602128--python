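"""Synthetic panels, pedigrees, amplicons and metadata.

Generates data with the statistical structure the haplotype analysis assumes:
a diversity panel whose accessions are clonal copies of a small set of
founder haplotypes (the locus is treated as a low-recombination block),
corrupted by heterozygous and missing calls; random breeding pedigrees;
amplicon pairs with a planted restriction site broken by a single SNP; and
grouped germplasm metadata. Every generator is bit-reproducible for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import IUPAC
from .haplotypes import Haplotype
from .markers import Enzyme, digest, scan_motif
from .pedigree import Pedigree
from .variant_io import (GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING,
                         VariantSite)

# gene labels cycled over synthetic sites, echoing the gene content of a
# locus-scale exome-capture interval
DEFAULT_GENES = ("PP1-like", "TaMKK3-A", "ASC1-like", "ERF-C",
                 "LRR-Kinase-1", "LRR-Kinase-2", "PM19-A2", "PM19-A1")


@dataclass(frozen=True)
class SimulationConfig:
    """Panel-generation settings.

    het_rate and missing_rate are per-call corruption probabilities (mutually
    exclusive; missing applied first); maf_floor is the minimum planted
    founder-weighted minor-allele frequency per site.
    """

    n_founder_haplotypes: int = 14
    n_sites: int = 39
    n_accessions: int = 58
    het_rate: float = 0.05
    missing_rate: float = 0.05
    maf_floor: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_founder_haplotypes", "n_sites", "n_accessions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("het_rate", "missing_rate", "maf_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.het_rate + self.missing_rate > 1.0:
            raise ValueError("het_rate + missing_rate must not exceed 1")
        if self.n_sites < 64 and self.n_founder_haplotypes > 2 ** self.n_sites:
            raise ValueError(
                f"{self.n_founder_haplotypes} distinct haplotypes impossible "
                f"over {self.n_sites} biallelic sites")


def generate_founder_haplotypes(config: SimulationConfig) -> list[Haplotype]:
    """Pairwise-distinct founder allele strings with every site segregating."""
    k, L = config.n_founder_haplotypes, config.n_sites
    if k == 1:
        raise ValueError("cannot make every site segregate with a single founder")
    rng = np.random.default_rng(config.seed)
    for _ in range(1000):
        m = rng.integers(0, 2, size=(k, L))
        # resolve duplicate rows
        for _ in range(1000):
            seen: dict[bytes, int] = {}
            dup = None
            for i in range(k):
                key = m[i].tobytes()
                if key in seen:
                    dup = i
                    break
                seen[key] = i
            if dup is None:
                break
            m[dup] = rng.integers(0, 2, size=L)
        else:
            continue
        # force every site to segregate without recreating duplicates
        ok = True
        for j in range(L):
            if len(set(m[:, j])) == 2:
                continue
            rows = rng.permutation(k)
            fixed = False
            for i in rows:
                m[i, j] ^= 1
                if not any(np.array_equal(m[i], m[r]) for r in range(k) if r != i):
                    fixed = True
                    break
                m[i, j] ^= 1
            if not fixed:
                ok = False
                break
        if ok and all(len(set(m[:, j])) == 2 for j in range(L)):
            return [Haplotype(name=f"F{i + 1}",
                              alleles="".join("A" if b else "R" for b in m[i]))
                    for i in range(k)]
    raise ValueError("could not construct distinct, fully segregating founders")


def make_sites(n_sites: int, seed: int = 0,
               genes: Sequence[str] = DEFAULT_GENES) -> list[VariantSite]:
    """Synthetic biallelic SNP sites spread over gene-labelled contigs."""
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    per_gene = int(np.ceil(n_sites / len(genes)))
    sites = []
    for j in range(n_sites):
        gene = genes[j // per_gene]
        ref = bases[rng.integers(4)]
        alt = bases[(bases.index(ref) + 1 + rng.integers(3)) % 4]
        sites.append(VariantSite(
            site_id=f"S{j + 1:03d}", gene=gene, contig=f"contig_{gene}",
            position=100 + 50 * (j % per_gene), ref_allele=ref, alt_allele=alt))
    return sites


@dataclass
class SyntheticPanel:
    """A generated genotype matrix plus the planted truth."""

    matrix: GenotypeMatrix
    founders: list[Haplotype]
    founder_of: dict[str, str] = field(default_factory=dict)
    clean_accessions: tuple[str, ...] = ()


def generate_panel(founders: Sequence[Haplotype], config: SimulationConfig,
                   founder_frequencies: Sequence[float] | None = None,
                   ensure_clean: bool = True,
                   sites: Sequence[VariantSite] | None = None) -> SyntheticPanel:
    """Draw accessions from founder haplotypes and corrupt calls with noise.

    Every founder is used at least once (requires n_accessions ≥ n_founders);
    remaining accessions draw a founder from a categorical distribution
    (uniform unless *founder_frequencies* is given, which lets a major
    haplotype share be planted). Independently per call, the true homozygous
    genotype becomes missing with probability missing_rate, else heterozygous
    with probability het_rate. With *ensure_clean* the first accession
    carrying each founder is left uncorrupted, so every planted haplotype is
    observable in at least one fully homozygous line. Founder assignments are
    redrawn until every site's founder-weighted minor-allele frequency
    reaches maf_floor.
    """
    founders = list(founders)
    if not founders:
        raise ValueError("founders must be nonempty")
    k = len(founders)
    n, L = config.n_accessions, len(founders[0].alleles)
    if n < k:
        raise ValueError(f"{n} accessions cannot cover {k} founders")
    if founder_frequencies is not None:
        freqs = np.asarray(founder_frequencies, dtype=float)
        if len(freqs) != k or abs(freqs.sum() - 1.0) > 1e-9 or (freqs < 0).any():
            raise ValueError("founder_frequencies must be a length-k simplex vector")
    else:
        freqs = np.full(k, 1.0 / k)
    alleles = np.array([[c == "A" for c in f.alleles] for f in founders], dtype=bool)

    rng = np.random.default_rng(config.seed)
    assignment = None
    for _ in range(1000):
        extra = rng.choice(k, size=n - k, p=freqs)
        cand = np.concatenate([np.arange(k), extra])
        rng.shuffle(cand)
        counts = np.bincount(cand, minlength=k)
        planted_alt = counts @ alleles  # per-site alt-carrying accession count
        maf = np.minimum(planted_alt, n - planted_alt) / n
        if (maf >= config.maf_floor).all():
            assignment = cand
            break
    if assignment is None:
        raise ValueError(
            f"could not satisfy maf_floor={config.maf_floor} after 1000 draws; "
            "lower the floor or change the founders")

    names = [f"acc{i + 1:03d}" for i in range(n)]
    clean: list[str] = []
    seen_founder: set[int] = set()
    calls = np.where(alleles[assignment], HOM_ALT, HOM_REF).astype(np.int8)
    u = rng.random(size=(n, L))
    for i in range(n):
        f = int(assignment[i])
        if ensure_clean and f not in seen_founder:
            seen_founder.add(f)
            clean.append(names[i])
            continue
        row = calls[i]
        row[u[i] < config.missing_rate] = MISSING
        row[(u[i] >= config.missing_rate)
            & (u[i] < config.missing_rate + config.het_rate)] = HET
    site_list = list(sites) if sites is not None else make_sites(L, config.seed)
    if len(site_list) != L:
        raise ValueError("sites length does not match founder string length")
    matrix = GenotypeMatrix(names, site_list, calls)
    founder_of = {names[i]: founders[int(assignment[i])].name for i in range(n)}
    return SyntheticPanel(matrix=matrix, founders=founders,
                          founder_of=founder_of, clean_accessions=tuple(clean))


def generate_pedigree(n_founders: int, n_generations: int, seed: int,
                      crosses_per_generation: int | None = None) -> Pedigree:
    """Random breeding pedigree: founders then *n_generations* of crosses.

    Each non-founder has exactly two distinct parents drawn from earlier
    lines, so the graph is acyclic by construction.
    """
    if n_founders < 1 or n_generations < 1:
        raise ValueError("n_founders and n_generations must be >= 1")
    if n_founders < 2:
        raise ValueError("need at least 2 founders to make a cross")
    per_gen = crosses_per_generation or max(1, n_founders - 1)
    rng = np.random.default_rng(seed)
    parents: dict[str, tuple[str | None, str | None]] = {
        f"F{i + 1}": (None, None) for i in range(n_founders)}
    pool = list(parents)
    for g in range(1, n_generations + 1):
        new = []
        for c in range(per_gen):
            p1, p2 = rng.choice(len(pool), size=2, replace=False)
            name = f"G{g}C{c + 1}"
            parents[name] = (pool[int(p1)], pool[int(p2)])
            new.append(name)
        pool.extend(new)
    return Pedigree(parents)


def generate_amplicon_pair(length: int, snp_offset: int, motif: str,
                           cut_offset: int, seed: int,
                           motif_start: int | None = None,
                           alt_base: str | None = None
                           ) -> tuple[str, str, dict]:
    """Two amplicon sequences differing at one SNP that breaks a planted site.

    Allele 1 carries exactly one occurrence of *motif* (both strands counted)
    spanning *snp_offset*; allele 2 differs only at that base, chosen so the
    motif no longer matches and no new occurrence appears. The truth record
    carries the planted coordinates and the expected digest fragment lengths
    per allele.
    """
    motif = motif.upper()
    L = len(motif)
    if not 0 < snp_offset <= length:
        raise ValueError(f"snp_offset {snp_offset} outside sequence (1..{length})")
    if L > length:
        raise ValueError("motif longer than amplicon")
    nondeg = [j for j in range(L) if len(IUPAC[motif[j]]) == 1]
    if not nondeg:
        raise ValueError(
            f"motif {motif} has no non-degenerate base; no single substitution "
            "can break it")
    if motif_start is None:
        motif_start = next(
            (snp_offset - j for j in reversed(nondeg)
             if 1 <= snp_offset - j and snp_offset - j + L - 1 <= length), None)
        if motif_start is None:
            raise ValueError("no motif placement puts the SNP on a "
                             "non-degenerate base inside the sequence")
    j = snp_offset - motif_start  # 0-based index of the SNP within the motif
    if not 0 <= j < L:
        raise ValueError("snp_offset falls outside the placed motif")
    if j not in nondeg:
        raise ValueError(
            f"motif base {motif[j]!r} at the SNP is degenerate; a substitution "
            "there cannot break the site")
    site_base = next(iter(IUPAC[motif[j]]))
    if alt_base is not None:
        alt_base = alt_base.upper()
        if alt_base in IUPAC[motif[j]]:
            raise ValueError(f"alt_base {alt_base!r} still matches the motif")

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    for _ in range(200):
        seq = list(rng.choice(bases, size=length))
        for idx in range(L):
            pool = sorted(IUPAC[motif[idx]])
            seq[motif_start - 1 + idx] = (pool[0] if len(pool) == 1
                                          else str(rng.choice(pool)))
        a2 = alt_base or str(rng.choice([b for b in "ACGT" if b != site_base]))
        planted = set(range(motif_start, motif_start + L))
        # knock out spurious occurrences without touching the planted window
        for _ in range(50):
            spurious = [p for p in scan_motif("".join(seq), motif)
                        if p != motif_start]
            if not spurious:
                break
            p = spurious[0]
            targets = [p + jj for jj in nondeg
                       if (p + jj) not in planted and p + jj != snp_offset
                       and 1 <= p + jj <= length]
            if not targets:
                break  # overlaps the planted window; restart with new sequence
            t = targets[0]
            cur = seq[t - 1]
            seq[t - 1] = str(rng.choice([b for b in "ACGT" if b != cur]))
        seq1 = "".join(seq)
        if scan_motif(seq1, motif) != [motif_start]:
            continue
        seq2 = seq1[:snp_offset - 1] + a2 + seq1[snp_offset:]
        if scan_motif(seq2, motif):
            continue
        enzyme = Enzyme("planted", motif, cut_offset)
        truth = {
            "motif": motif, "motif_start": motif_start, "snp_offset": snp_offset,
            "allele1_base": seq1[snp_offset - 1], "allele2_base": a2,
            "fragments_allele1": digest(seq1, enzyme),
            "fragments_allele2": digest(seq2, enzyme),
        }
        return seq1, seq2, truth
    raise ValueError("failed to construct a clean amplicon pair; "
                     "try a different seed or longer sequence")


def generate_metadata(accessions: Sequence[str], group_labels: Sequence[str],
                      proportions: Sequence[float], seed: int) -> pd.DataFrame:
    """Assign accessions to groups with counts matching proportions.

    Counts follow the largest-remainder rule, so they match the proportions
    up to rounding; which accession lands in which group is a seeded shuffle.
    """
    if len(group_labels) != len(proportions):
        raise ValueError("group_labels and proportions differ in length")
    props = np.asarray(proportions, dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {props.sum()}")
    n = len(accessions)
    raw = props * n
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[:n - counts.sum()]:
        counts[i] += 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    groups = [""] * n
    pos = 0
    for label, c in zip(group_labels, counts):
        for idx in order[pos:pos + c]:
            groups[int(idx)] = label
        pos += c
    return pd.DataFrame({"accession": list(accessions), "group": groups})
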