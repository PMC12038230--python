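"""Unique duplication-mode assignment from per-mode duplicate-pair lists.

Pair discovery (homology + synteny) happens upstream; this module applies the
priority rule WGD > TD > PD > TRD > DSD to give every gene exactly one label,
with genes in no pair reported as singletons, plus the proximal-distance rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

MODES = ("WGD", "TD", "PD", "TRD", "DSD")
_PRIORITY = {m: i for i, m in enumerate(MODES)}

__all__ = ["MODES", "DupPairList", "DupAssignment", "assign_unique_mode",
           "proximal_check", "read_pair_list"]


@dataclass
class DupPairList:
    mode: str
    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown duplication mode {self.mode!r}")
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair {a!r} in {self.mode} list")


@dataclass
class DupAssignment:
    modes: dict[str, str]  # gene -> mode or "singleton"
    mode_counts: dict[str, int]


def read_pair_list(path: str | Path, mode: str) -> DupPairList:
    """Read a two-column (gene_a, gene_b) TSV of duplicate pairs."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            pairs.append((f[0], f[1]))
    return DupPairList(mode=mode, pairs=pairs)


def assign_unique_mode(
    pair_lists: Iterable[DupPairList], all_genes: Iterable[str]
) -> DupAssignment:
    """Label every gene with its highest-priority duplication mode.

    Genes appearing in no pair list are singletons.  A pair referencing a gene
    outside ``all_genes`` is an error.
    """
    genes = list(all_genes)
    gene_set = set(genes)
    best: dict[str, str] = {}
    for plist in pair_lists:
        for a, b in plist.pairs:
            for g in (a, b):
                if g not in gene_set:
                    raise ValueError(
                        f"gene {g!r} in {plist.mode} pair list is not in all_genes"
                    )
                cur = best.get(g)
                if cur is None or _PRIORITY[plist.mode] < _PRIORITY[cur]:
                    best[g] = plist.mode
    modes = {g: best.get(g, "singleton") for g in genes}
    counts = {m: 0 for m in (*MODES, "singleton")}
    for m in modes.values():
        counts[m] += 1
    return DupAssignment(modes=modes, mode_counts=counts)


def proximal_check(
    gene_order: Mapping[str, tuple[str, int]],
    pair: Sequence[str],
    max_intervals: int = 10,
    strict: bool = True,
    exclude_tandem: bool = True,
) -> bool:
    """Proximal-duplicate test for one pair.

    ``gene_order`` maps gene -> (chromosome, rank).  True iff the genes share
    a chromosome and their rank distance is below ``max_intervals`` (``<=``
    when ``strict=False``).  Rank distance 1 (tandem-adjacent) is excluded by
    default so PD stays disjoint from TD.
    """
    a, b = pair
    for g in (a, b):
        if g not in gene_order:
            raise ValueError(f"gene {g!r} has no chromosome/rank")
    chrom_a, rank_a = gene_order[a]
    chrom_b, rank_b = gene_order[b]
    if chrom_a != chrom_b:
        return False
    d = abs(rank_a - rank_b)
    if exclude_tandem and d <= 1:
        return False
    return d < max_intervals if strict else d <= max_intervals
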