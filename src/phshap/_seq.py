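"""Shared nucleotide-sequence helpers: IUPAC ambiguity codes and motif scanning."""

from __future__ import annotations

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def validate_motif(motif: str) -> None:
    """Raise ValueError if *motif* contains a non-IUPAC character."""
    bad = [c for c in motif.upper() if c not in IUPAC]
    if bad:
        raise ValueError(f"invalid IUPAC code(s) in motif {motif!r}: {bad}")


def revcomp(seq: str) -> str:
    """Reverse complement; accepts IUPAC ambiguity codes."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"cannot complement character {exc.args[0]!r}") from exc


def matches_at(seq: str, motif: str, start0: int) -> bool:
    """True if *motif* matches ``seq`` at 0-based offset *start0* (forward strand)."""
    if start0 < 0 or start0 + len(motif) > len(seq):
        return False
    return all(seq[start0 + j] in IUPAC[motif[j]] for j in range(len(motif)))


def scan_stranded(seq: str, motif: str) -> list[tuple[int, str]]:
    """All (1-based forward-coordinate start, strand) matches of *motif* in *seq*.

    Reverse-strand recognition sites are found by matching the reverse
    complement of the motif on the forward strand; the reported position is
    the leftmost base of the site in forward coordinates.
    """
    validate_motif(motif)
    seq = seq.upper()
    motif = motif.upper()
    rc = revcomp(motif)
    hits: list[tuple[int, str]] = []
    for i in range(len(seq) - len(motif) + 1):
        if matches_at(seq, motif, i):
            hits.append((i + 1, "+"))
        if matches_at(seq, rc, i):
            hits.append((i + 1, "-"))
    return hits
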