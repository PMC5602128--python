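"""Coefficient of parentage (COP) over breeding pedigrees.

COP(x, y) is the probability that alleles drawn from two fully inbred lines
are identical by descent. The inbred-line convention is used throughout:
COP(x, x) = 1, distinct founders have COP 0, unknown parents contribute 0
relatedness, and the recursion

    COP(x, y) = 1/2 * (COP(x, p1(y)) + COP(x, p2(y)))

expands the descendant-side line. This is the standard convention for wheat
germplasm diversity studies, where lines are homozygous and self-COP
self-evaluates to 1.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class Pedigree:
    """Directed acyclic parent graph over named lines.

    Each line has up to two named parents; ``None`` marks an unknown parent.
    Cycles are rejected at construction.
    """

    def __init__(self, parents: Mapping[str, tuple[str | None, str | None]]):
        self.parents: dict[str, tuple[str | None, str | None]] = {}
        for name, (p1, p2) in parents.items():
            for p in (p1, p2):
                if p is not None and p not in parents:
                    raise ValueError(f"parent {p!r} of {name!r} has no pedigree row")
            self.parents[name] = (p1, p2)
        self._depth = self._compute_depths()
        self._cop_cache: dict[tuple[str, str], float] = {}

    def _compute_depths(self) -> dict[str, int]:
        depth: dict[str, int] = {}
        state: dict[str, int] = {}  # 1 = visiting, 2 = done

        def visit(name: str, stack: list[str]) -> int:
            if state.get(name) == 2:
                return depth[name]
            if state.get(name) == 1:
                cycle = stack[stack.index(name):] + [name]
                raise ValueError(f"pedigree cycle detected: {' -> '.join(cycle)}")
            state[name] = 1
            stack.append(name)
            ps = [p for p in self.parents[name] if p is not None]
            depth[name] = 1 + max((visit(p, stack) for p in ps), default=-1)
            stack.pop()
            state[name] = 2
            return depth[name]

        for name in self.parents:
            visit(name, [])
        return depth

    @property
    def lines(self) -> list[str]:
        return list(self.parents)

    def is_founder(self, name: str) -> bool:
        return self.parents[name] == (None, None)

    def topological_order(self) -> list[str]:
        return sorted(self.parents, key=lambda n: (self._depth[n], n))

    # ------------------------------------------------------------------ COP

    def cop(self, x: str, y: str) -> float:
        """Coefficient of parentage between two lines (memoized recursion)."""
        for name in (x, y):
            if name not in self.parents:
                raise KeyError(f"unknown line {name!r}")
        return self._cop(x, y)

    def _cop(self, x: str, y: str) -> float:
        if x == y:
            return 1.0
        key = (x, y) if x < y else (y, x)
        if key in self._cop_cache:
            return self._cop_cache[key]
        # expand the deeper (descendant-side) line; equal depths mean neither
        # is an ancestor of the other, so either is safe to expand
        if self._depth[x] > self._depth[y]:
            x, y = y, x
        if self._depth[y] == 0:  # both founders (depth 0 ⟺ no known parents)
            value = 0.0
        else:
            value = self._expand(x, y)
        self._cop_cache[key] = value
        return value

    def _expand(self, x: str, y: str) -> float:
        p1, p2 = self.parents[y]
        total = 0.0
        for p in (p1, p2):
            if p is not None:
                total += self._cop(x, p)
        return total / 2.0

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Pedigree":
        """Read a pedigree TSV (name, parent1, parent2; empty = unknown)."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                         comment="#")
        parents = {}
        for _, row in df.iterrows():
            p1 = row.get("parent1", "") or None
            p2 = row.get("parent2", "") or None
            parents[row["name"]] = (p1, p2)
        return cls(parents)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("name\tparent1\tparent2\n")
            for name, (p1, p2) in self.parents.items():
                fh.write(f"{name}\t{p1 or ''}\t{p2 or ''}\n")


def cop_matrix(lines: Sequence[str], pedigree: Pedigree) -> pd.DataFrame:
    """Symmetric COP matrix (diagonal 1) over a line set."""
    names = list(lines)
    m = np.ones((len(names), len(names)))
    for i, x in enumerate(names):
        for j in range(i + 1, len(names)):
            m[i, j] = m[j, i] = pedigree.cop(x, names[j])
    return pd.DataFrame(m, index=names, columns=names)


def _usable(lines: Iterable[str], pedigree: Pedigree) -> list[str]:
    # lines absent from the pedigree table have wholly unknown pedigrees and
    # are excluded from group means (founders recorded with unknown parents
    # are legitimate lines and stay)
    return [ln for ln in lines if ln in pedigree.parents]


def mean_cop(lines: Iterable[str], pedigree: Pedigree) -> tuple[float, int]:
    """Mean COP over all unordered distinct pairs; pair count n(n−1)/2."""
    usable = _usable(lines, pedigree)
    n = len(usable)
    if n < 2:
        raise ValueError(f"need at least 2 usable lines, got {n}")
    total = sum(pedigree.cop(usable[i], usable[j])
                for i in range(n) for j in range(i + 1, n))
    n_pairs = n * (n - 1) // 2
    return total / n_pairs, n_pairs


def mean_cop_between(group_a: Iterable[str], group_b: Iterable[str],
                     pedigree: Pedigree) -> tuple[float, int]:
    """Mean COP over the |a|·|b| cross pairs of two disjoint groups."""
    a = _usable(group_a, pedigree)
    b = _usable(group_b, pedigree)
    overlap = set(a) & set(b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if not a or not b:
        raise ValueError("both groups must contain at least one usable line")
    total = sum(pedigree.cop(x, y) for x in a for y in b)
    n_pairs = len(a) * len(b)
    return total / n_pairs, n_pairs


def gene_drop_cop(pedigree: Pedigree, x: str, y: str, n_drops: int,
                  seed: int) -> tuple[float, float]:
    """Monte-Carlo COP estimate by gene dropping; returns (estimate, std error).

    Each drop gives every founder (and every unknown-parent slot) a unique
    allele; a child inherits the allele of a uniformly chosen parent. The COP
    estimate is the fraction of drops in which x and y carry the same allele.
    """
    rng = np.random.default_rng(seed)
    order = pedigree.topological_order()
    alleles: dict[str, np.ndarray] = {}
    next_label = 0
    for name in order:
        p1, p2 = pedigree.parents[name]
        if p1 is None and p2 is None:
            alleles[name] = np.full(n_drops, next_label)
            next_label += 1
            continue
        choice = rng.integers(0, 2, size=n_drops)
        sources = []
        for p in (p1, p2):
            if p is None:
                sources.append(np.full(n_drops, next_label))
                next_label += 1
            else:
                sources.append(alleles[p])
        alleles[name] = np.where(choice == 0, sources[0], sources[1])
    match = (alleles[x] == alleles[y]).mean()
    se = float(np.sqrt(match * (1 - match) / n_drops))
    return float(match), se


def group_summary(groups: Mapping[str, Sequence[str]], allele_class: Mapping[str, str],
                  pedigree: Pedigree) -> list[dict]:
    """Rows for a group-mean COP TSV (group, allele class, mean to 2 dp, pairs)."""
    rows = []
    for label, members in groups.items():
        mean, n_pairs = mean_cop(members, pedigree)
        rows.append({"group": label, "allele": allele_class.get(label, "NA"),
                     "mean_cop": f"{mean:.2f}", "n_pairs": n_pairs})
    return rows
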