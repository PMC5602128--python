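"""In-silico CAPS and KASP diagnostic-marker design.

CAPS assays score a SNP by the gain or loss of a restriction-enzyme
recognition site, read as digest fragment ladders on a gel (the classic
example at this locus: an Hpy166II site, GTNNAC, inside an 887-bp amplicon
that is cut into 605 + 282 bp for the dormant allele and left intact for the
non-dormant allele). KASP assays are competitive allele-specific PCR records:
two primers identical except for the 3' base at the SNP, carrying FAM/HEX
dye tails, plus one common primer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from ._seq import IUPAC, revcomp, scan_stranded, validate_motif

# de-facto standard KASP dye-tail sequences (configurable)
FAM_TAIL = "GAAGGTGACCAAGTTCATGCT"
HEX_TAIL = "GAAGGTCGGAGTCAACGGATT"


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: IUPAC recognition motif and top-strand cut offset."""

    name: str
    motif: str
    cut_offset: int  # bases from the motif 5' end to the cut on the top strand

    def __post_init__(self) -> None:
        validate_motif(self.motif)
        if not 0 <= self.cut_offset <= len(self.motif):
            raise ValueError(
                f"{self.name}: cut_offset {self.cut_offset} outside "
                f"[0, {len(self.motif)}]")


HPY166II = Enzyme("Hpy166II", "GTNNAC", 3)  # blunt cutter: GTN^NAC


@dataclass(frozen=True)
class CapsAssay:
    enzyme: Enzyme
    amplicon_length: int
    snp_position: int
    fragments_allele1: tuple[int, ...]
    fragments_allele2: tuple[int, ...]
    discriminating: bool
    site_in_allele: int | None  # 1 or 2: which allele has more cut sites

    def __post_init__(self) -> None:
        for frags in (self.fragments_allele1, self.fragments_allele2):
            if sum(frags) != self.amplicon_length:
                raise ValueError("fragment ladder does not sum to amplicon length")
        differ = sorted(self.fragments_allele1) != sorted(self.fragments_allele2)
        if differ != self.discriminating:
            raise ValueError("discriminating flag inconsistent with ladders")


@dataclass(frozen=True)
class KaspAssay:
    primer_allele1: str  # tailed; 3' base = allele 1
    primer_allele2: str  # tailed; 3' base = allele 2
    common_primer: str
    tail1: str = FAM_TAIL
    tail2: str = HEX_TAIL
    orientation: str = "forward"
    amplicon_span: tuple[int, int] = (0, 0)

    def core_primers(self) -> tuple[str, str]:
        """Allele-specific primers with the dye tails stripped."""
        return (self.primer_allele1[len(self.tail1):],
                self.primer_allele2[len(self.tail2):])


def scan_motif(sequence: str, motif: str) -> list[int]:
    """1-based start positions of motif matches on both strands.

    Reverse-strand matches are reported on the forward coordinate system;
    positions found on both strands (palindromic motifs) are reported once.
    """
    return sorted({pos for pos, _ in scan_stranded(sequence, motif)})


def _cut_positions(sequence: str, enzyme: Enzyme) -> list[int]:
    """0-based positions after which the top strand is cut."""
    length = len(enzyme.motif)
    cuts = set()
    for pos, strand in scan_stranded(sequence, enzyme.motif):
        if strand == "+":
            cut = (pos - 1) + enzyme.cut_offset
        else:
            # bottom-strand site: the top-strand cut mirrors the offset
            cut = (pos - 1) + (length - enzyme.cut_offset)
        if 0 < cut < len(sequence):
            cuts.add(cut)
    return sorted(cuts)


def digest(sequence: str, enzyme: Enzyme) -> list[int]:
    """Ordered fragment lengths from a complete in-silico digest.

    With no recognition site the single full-length fragment is returned;
    fragments always sum to the input length.
    """
    cuts = _cut_positions(sequence, enzyme)
    bounds = [0] + cuts + [len(sequence)]
    return [bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)]


def _resolvability(l1: Sequence[int], l2: Sequence[int]) -> int:
    """Largest band-size difference distinguishing the two ladders on a gel."""
    s1, s2 = sorted(l1), sorted(l2)
    diff1 = [f for f in s1 if f not in s2]
    diff2 = [f for f in s2 if f not in s1]
    best = 0
    for band, other in ((diff1, s2), (diff2, s1)):
        for f in band:
            nearest = min((abs(f - g) for g in other), default=f)
            best = max(best, nearest)
    return best


def find_caps_candidates(allele_seq_1: str, allele_seq_2: str, snp_position: int,
                         enzymes: Sequence[Enzyme]) -> list[CapsAssay]:
    """Digest both allele sequences with each enzyme; keep discriminating assays.

    Sequences must be equal length and differ at exactly the one SNP position.
    Both loss-of-site and gain-of-site assays are reported, annotated with the
    allele that retains (or gains) the site, sorted most gel-resolvable first.
    """
    if len(allele_seq_1) != len(allele_seq_2):
        raise ValueError("allele sequences differ in length")
    diffs = [i + 1 for i, (a, b) in enumerate(zip(allele_seq_1, allele_seq_2))
             if a != b]
    if diffs != [snp_position]:
        raise ValueError(
            f"sequences must differ exactly at position {snp_position}, "
            f"differ at {diffs}")
    assays = []
    for enz in enzymes:
        f1 = tuple(digest(allele_seq_1, enz))
        f2 = tuple(digest(allele_seq_2, enz))
        if sorted(f1) == sorted(f2):
            continue
        if len(f1) == len(f2):
            site_in = None  # site moved rather than gained/lost
        else:
            site_in = 1 if len(f1) > len(f2) else 2
        assays.append(CapsAssay(
            enzyme=enz, amplicon_length=len(allele_seq_1),
            snp_position=snp_position, fragments_allele1=f1,
            fragments_allele2=f2, discriminating=True, site_in_allele=site_in))
    assays.sort(key=lambda a: -_resolvability(a.fragments_allele1,
                                              a.fragments_allele2))
    return assays


def design_kasp(template: str, snp_position: int, ref_allele: str,
                alt_allele: str, primer_length: int,
                tails: tuple[str, str] = (FAM_TAIL, HEX_TAIL),
                orientation: str = "forward") -> KaspAssay:
    """Build a KASP assay record around a SNP on a template sequence.

    The allele-specific primers are the ``primer_length`` window ending at the
    SNP on the chosen strand, identical except for the 3' base; the FAM tail
    is prepended to the first-listed (reference) allele's primer and the HEX
    tail to the second. The common primer is taken from the opposite strand at
    the far end of the template.

    ``orientation="forward"`` places the allele-specific primers on the given
    strand (window ends at ``snp_position``); ``"reverse"`` places them on the
    reverse complement (their 3' base is then the complement of the allele).
    """
    template = template.upper()
    n = len(template)
    if not 1 <= snp_position <= n:
        raise ValueError(f"snp_position {snp_position} outside template (1..{n})")
    if template[snp_position - 1] != ref_allele.upper():
        raise ValueError(
            f"template base at {snp_position} is {template[snp_position - 1]!r}, "
            f"not the stated reference allele {ref_allele!r}")
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    if orientation == "forward":
        if snp_position < primer_length:
            raise ValueError("allele-specific window runs off the 5' end")
        stem = template[snp_position - primer_length:snp_position - 1]
        p1 = stem + ref_allele.upper()
        p2 = stem + alt_allele.upper()
        if n - snp_position < primer_length:
            raise ValueError("no room for the common primer 3' of the SNP")
        common = revcomp(template[n - primer_length:])
        span = (snp_position - primer_length + 1, n)
    elif orientation == "reverse":
        if snp_position + primer_length - 1 > n:
            raise ValueError("allele-specific window runs off the 3' end")
        window_rc = revcomp(template[snp_position - 1:snp_position + primer_length - 1])
        stem = window_rc[:-1]
        p1 = stem + comp[ref_allele.upper()]
        p2 = stem + comp[alt_allele.upper()]
        if snp_position - 1 < primer_length:
            raise ValueError("no room for the common primer 5' of the SNP")
        common = template[:primer_length]
        span = (1, snp_position + primer_length - 1)
    else:
        raise ValueError(f"orientation must be 'forward' or 'reverse', got {orientation!r}")
    return KaspAssay(primer_allele1=tails[0] + p1, primer_allele2=tails[1] + p2,
                     common_primer=common, tail1=tails[0], tail2=tails[1],
                     orientation=orientation, amplicon_span=span)


def read_enzyme_table(path: str | Path) -> list[Enzyme]:
    """Read an enzyme TSV (name, motif, cut_offset)."""
    enzymes = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    for ln in lines[1:]:
        name, motif, cut_offset = ln.split("\t")
        enzymes.append(Enzyme(name, motif, int(cut_offset)))
    return enzymes


def write_enzyme_table(enzymes: Sequence[Enzyme], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tmotif\tcut_offset\n")
        for e in enzymes:
            fh.write(f"{e.name}\t{e.motif}\t{e.cut_offset}\n")


def virtual_gel(assay: CapsAssay, width: int = 40) -> str:
    """Crude text rendering of the two digest ladders for quick inspection."""
    scale = assay.amplicon_length / width
    lines = [f"{assay.enzyme.name}  amplicon {assay.amplicon_length} bp"]
    for label, frags in (("allele1", assay.fragments_allele1),
                         ("allele2", assay.fragments_allele2)):
        for f in sorted(frags, reverse=True):
            bar = "#" * max(1, round(f / scale))
            lines.append(f"{label:>8} {f:>6} bp |{bar}")
    return "\n".join(lines)
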