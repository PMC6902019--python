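"""Gene-set integration: regulated-list filtering and Venn region counts."""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd


@dataclass
class GeneSet:
    """Named set of gene symbols, upper-cased and deduplicated on load."""

    name: str
    genes: frozenset = field(default_factory=frozenset)
    provenance: str = ""

    def __post_init__(self):
        self.genes = frozenset(str(g).upper() for g in self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_file(cls, path, name: str | None = None, provenance: str = "") -> "GeneSet":
        """Load from one-symbol-per-line text or a two-column TSV (symbol
        in the first column)."""
        symbols = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                symbols.append(line.split("\t")[0])
        return cls(name=name or str(path), genes=frozenset(symbols), provenance=provenance)


def filter_regulated(changes: pd.Series, threshold: float) -> GeneSet:
    """Genes whose absolute relative change strictly exceeds ``threshold``.

    ``changes`` maps gene → relative change (e.g. |fold change − 1| or
    |%change|/100); direction is ignored (absolute regulation).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    selected = changes.index[changes.abs() > threshold]
    return GeneSet(name=f"regulated>{threshold:g}", genes=frozenset(selected))


def venn_counts(sets: list[GeneSet]) -> dict[str, int]:
    """Counts of every Venn region for 2 or 3 gene sets.

    Region keys join member-set names with ``&``; regions are disjoint and
    partition the union.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_counts supports 2 or 3 sets")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("set names must be distinct")
    membership: dict[str, tuple] = {}
    for gene in set().union(*(s.genes for s in sets)):
        key = tuple(s.name for s in sets if gene in s.genes)
        membership.setdefault(key, []).append(gene)
    counts = {}
    for r in range(1, len(sets) + 1):
        for combo in combinations(names, r):
            counts["&".join(combo)] = len(membership.get(tuple(combo), []))
    return counts
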