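"""Germplasm allele-frequency summaries and the 2×2 contingency test.

Percentages are reported as nearest integers (ties away from zero), matching
how allele-survey counts are conventionally printed; the association between
market class and allele is a Pearson chi-square without continuity
correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GroupCount:
    """Carriers of the focal allele within a germplasm group."""

    group: str
    carriers: int
    total: int

    def __post_init__(self) -> None:
        if not 0 <= self.carriers <= self.total:
            raise ValueError(f"carriers {self.carriers} outside [0, {self.total}]")

    @property
    def percent(self) -> int | None:
        return None if self.total == 0 else percent(self.carriers, self.total)


def percent(carriers: int, total: int) -> int:
    """100·carriers/total rounded to the nearest integer, ties away from zero."""
    if total < 1:
        raise ValueError("total must be >= 1")
    return int(math.floor(100 * carriers / total + 0.5))


def group_allele_frequency(metadata: pd.DataFrame, genotype_col: str,
                           group_col: str, focal_allele: str = "C",
                           missing: tuple[str, ...] = ("", "NA", "missing"),
                           valid_alleles: tuple[str, ...] = ("C", "A"),
                           ) -> list[GroupCount]:
    """Per-group carrier counts of the focal allele among non-missing accessions.

    Genotypes must be one of *valid_alleles* or a missing marker; anything
    else raises with the offending value named.
    """
    counts: list[GroupCount] = []
    for group, sub in metadata.groupby(group_col, sort=False):
        carriers = 0
        total = 0
        for value in sub[genotype_col]:
            v = "" if pd.isna(value) else str(value)
            if v in missing:
                continue
            if v not in valid_alleles:
                raise ValueError(f"unknown genotype symbol {v!r} in group {group!r}")
            total += 1
            if v == focal_allele:
                carriers += 1
        counts.append(GroupCount(group=str(group), carriers=carriers, total=total))
    return counts


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = trait classes and columns = allele classes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("all cells must be non-negative")

    def as_array(self):
        return [[self.a, self.b], [self.c, self.d]]


def chi_square_2x2(table: ContingencyTable2x2) -> tuple[float, float, int]:
    """Pearson chi-square without continuity correction; df = 1.

    Raises on a zero row or column margin (the test is undefined); warns when
    any expected count falls below 5.
    """
    obs = table.as_array()
    (a, b), (c, d) = obs
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("chi-square undefined: a row or column margin is zero")
    stat, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    if expected.min() < 5:
        warnings.warn(
            f"expected count {expected.min():.2f} < 5; "
            "chi-square approximation may be unreliable", stacklevel=2)
    return float(stat), float(p), int(dof)


def frequency_table(counts: list[GroupCount]) -> list[dict]:
    return [{"group": g.group, "carriers": g.carriers, "total": g.total,
             "percent": "NA" if g.percent is None else g.percent}
            for g in counts]
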