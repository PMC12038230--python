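"""Synthetic family x genome occupancy matrices with planted pan categories."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ..pangenome import CATEGORIES, FamilyMatrix, PanThresholds

__all__ = ["PangenomeSimSpec", "simulate_family_matrix"]


@dataclass(frozen=True)
class PangenomeSimSpec:
    n_genomes: int
    n_families: int
    category_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "core": 0.44, "softcore": 0.08, "dispensable": 0.47, "private": 0.01
        }
    )
    genes_per_family_mean: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("n_genomes must be >= 2")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if set(self.category_fractions) != set(CATEGORIES):
            raise ValueError(f"fractions must name exactly {CATEGORIES}")
        if abs(sum(self.category_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("category fractions must sum to 1")
        if self.genes_per_family_mean < 1:
            raise ValueError("genes_per_family_mean must be >= 1")


def _allocate_counts(spec: PangenomeSimSpec) -> dict[str, int]:
    """Largest-remainder apportionment of families to categories."""
    raw = {c: spec.category_fractions[c] * spec.n_families for c in CATEGORIES}
    counts = {c: math.floor(v) for c, v in raw.items()}
    short = spec.n_families - sum(counts.values())
    by_rem = sorted(CATEGORIES, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in by_rem[:short]:
        counts[c] += 1
    return counts


def _occupancy_band(category: str, th: PanThresholds) -> tuple[int, int] | None:
    """Inclusive occupancy range for a category, or None if the band is empty."""
    n = th.n
    if category == "core":
        return (n, n)
    if category == "private":
        return (1, 1)
    if category == "softcore":
        lo, hi = th.softcore_min, n - 1
    else:  # dispensable
        lo, hi = 2, min(th.softcore_min - 1, n - 1)
    return (lo, hi) if lo <= hi else None


def simulate_family_matrix(
    spec: PangenomeSimSpec,
) -> tuple[FamilyMatrix, dict[str, str]]:
    """Generate a matrix whose classified categories match a planted truth map.

    Occupancies are drawn uniformly within each category's band for
    ``spec.n_genomes``; member counts per present genome are 1 + Poisson.
    Categories whose band is empty at this genome count (e.g. softcore at
    n=4) are reassigned to the nearest feasible category with a warning, and
    the returned truth reflects the reassignment.
    """
    rng = np.random.default_rng(spec.seed)
    th = PanThresholds.from_n(spec.n_genomes)
    counts = _allocate_counts(spec)

    # reassign infeasible categories: softcore -> dispensable -> core
    for cat in ("softcore", "dispensable"):
        if counts[cat] and _occupancy_band(cat, th) is None:
            fallback = "dispensable" if cat == "softcore" else "core"
            if _occupancy_band(fallback, th) is None:
                fallback = "core"
            warnings.warn(
                f"{cat} band empty at n_genomes={spec.n_genomes}; "
                f"{counts[cat]} families reassigned to {fallback}"
            )
            counts[fallback] += counts[cat]
            counts[cat] = 0

    genomes = [f"G{j+1:02d}" for j in range(spec.n_genomes)]
    families: list[str] = []
    members: dict[str, dict[str, list[str]]] = {}
    truth: dict[str, str] = {}
    gene_serial = {g: 0 for g in genomes}
    fam_idx = 0
    for cat in CATEGORIES:
        band = _occupancy_band(cat, th)
        for _ in range(counts[cat]):
            fam_idx += 1
            fam = f"F{fam_idx:06d}"
            occ = int(rng.integers(band[0], band[1] + 1))
            present = rng.choice(spec.n_genomes, size=occ, replace=False)
            row: dict[str, list[str]] = {}
            for j in sorted(present):
                genome = genomes[j]
                n_genes = 1 + int(rng.poisson(spec.genes_per_family_mean - 1.0))
                genes = []
                for _ in range(n_genes):
                    gene_serial[genome] += 1
                    genes.append(f"{genome}_g{gene_serial[genome]}")
                row[genome] = genes
            families.append(fam)
            members[fam] = row
            truth[fam] = cat
    matrix = FamilyMatrix(genomes=genomes, families=families, members=members)
    return matrix, truth
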