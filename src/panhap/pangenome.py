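"""Gene-family occupancy matrices, pan-category classification and saturation.

A :class:`FamilyMatrix` holds, for every gene family and genome, the list of
member gene identifiers.  Families are classified by *occupancy* (number of
genomes with at least one member) into four categories:

- ``core``        — present in every genome,
- ``softcore``    — present in at least ``ceil(0.8 * n)`` genomes but not all,
- ``dispensable`` — present in 2 or more genomes below the softcore band,
- ``private``     — present in exactly one genome.

Saturation (rarefaction) curves report pan and core family counts over genome
subsets of every size, exhaustively when feasible and by seeded sampling
otherwise.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CATEGORIES = ("core", "softcore", "dispensable", "private")

__all__ = [
    "CATEGORIES",
    "FamilyMatrix",
    "PanThresholds",
    "PanClassification",
    "SaturationCurve",
    "read_family_matrix",
    "write_family_matrix",
    "classify_families",
    "saturation_curves",
    "per_genome_composition",
    "singleton_genes",
    "crosstab_categories",
    "category_fractions",
]


@dataclass
class FamilyMatrix:
    """Family x genome membership matrix.

    Parameters
    ----------
    genomes : list of str
        Genome identifiers (column order).
    families : list of str
        Family identifiers (row order).
    members : dict
        ``family -> genome -> [gene ids]``; absent cells may be missing or
        hold an empty list.
    """

    genomes: list[str]
    families: list[str]
    members: dict[str, dict[str, list[str]]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for fam, row in self.members.items():
            for genome, genes in row.items():
                if genome not in self.genomes:
                    raise ValueError(f"unknown genome {genome!r} in family {fam!r}")
                for g in genes:
                    if g in seen:
                        raise ValueError(
                            f"gene {g!r} appears in families {seen[g]!r} and {fam!r}"
                        )
                    seen[g] = fam

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    @property
    def n_families(self) -> int:
        return len(self.families)

    def occupancy(self, family: str) -> int:
        row = self.members.get(family, {})
        return sum(1 for genes in row.values() if genes)

    def presence(self) -> np.ndarray:
        """Boolean presence matrix, shape (n_families, n_genomes)."""
        out = np.zeros((self.n_families, self.n_genomes), dtype=bool)
        gidx = {g: j for j, g in enumerate(self.genomes)}
        for i, fam in enumerate(self.families):
            for genome, genes in self.members.get(fam, {}).items():
                if genes:
                    out[i, gidx[genome]] = True
        return out

    def gene_to_family(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for fam, row in self.members.items():
            for genes in row.values():
                for g in genes:
                    out[g] = fam
        return out


@dataclass(frozen=True)
class PanThresholds:
    """Occupancy thresholds for pan-category classification."""

    n: int
    softcore_min: int
    rationale: str = "softcore band = ceil(0.8 n) .. n-1"

    @classmethod
    def from_n(cls, n: int, softcore_frac: float = 0.8) -> "PanThresholds":
        if n < 2:
            raise ValueError("need at least 2 genomes")
        softcore_min = max(2, math.ceil(softcore_frac * n))
        return cls(n=n, softcore_min=softcore_min)


@dataclass
class PanClassification:
    categories: dict[str, str]
    category_counts: dict[str, int]
    category_fractions: dict[str, float]
    thresholds: PanThresholds


@dataclass
class SaturationCurve:
    sizes: list[int]
    pan_mean: list[float]
    core_mean: list[float]
    pan_quantiles: dict[float, list[float]]
    core_quantiles: dict[float, list[float]]
    n_combinations_evaluated: list[int]
    mode: list[str]
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        data = {
            "m": self.sizes,
            "pan_mean": self.pan_mean,
            "core_mean": self.core_mean,
            "n_combinations": self.n_combinations_evaluated,
            "mode": self.mode,
        }
        for q, vals in self.pan_quantiles.items():
            data[f"pan_q{q}"] = vals
        for q, vals in self.core_quantiles.items():
            data[f"core_q{q}"] = vals
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# I/O — Orthogroups TSV dialect: column 1 = family id, one column per genome,
# cells are ", "-joined gene lists, empty cell = absent.
# ---------------------------------------------------------------------------

def read_family_matrix(
    path: str | Path,
    genome_ids: Sequence[str] | None = None,
    unassigned: Mapping[str, Iterable[str]] | None = None,
) -> FamilyMatrix:
    """Read an orthogroups-style TSV into a :class:`FamilyMatrix`.

    Parameters
    ----------
    genome_ids : optional
        Expected genome columns; a header column outside this set is an error.
    unassigned : optional
        ``genome -> gene ids`` for genes not clustered into any family; each
        is appended as a one-gene family (occupancy 1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 1:
        raise ValueError("orthogroups table must have a family-id column")
    genome_cols = list(df.columns[1:])
    if genome_ids is not None:
        unknown = set(genome_cols) - set(genome_ids)
        if unknown:
            raise ValueError(f"unknown genome column(s): {sorted(unknown)}")
        genome_cols = [g for g in genome_ids if g in genome_cols]
    families = list(df.iloc[:, 0])
    members: dict[str, dict[str, list[str]]] = {}
    for _, row in df.iterrows():
        fam = row.iloc[0]
        cell: dict[str, list[str]] = {}
        for g in genome_cols:
            raw = row[g].strip()
            if raw:
                cell[g] = [x.strip() for x in raw.split(",") if x.strip()]
        members[fam] = cell
    genomes = list(genome_cols)
    if unassigned:
        idx = 0
        for genome, genes in unassigned.items():
            if genome not in genomes:
                raise ValueError(f"unknown genome {genome!r} in unassigned genes")
            for gene in genes:
                idx += 1
                fam = f"UN{idx:07d}"
                families.append(fam)
                members[fam] = {genome: [gene]}
    return FamilyMatrix(genomes=genomes, families=families, members=members)


def write_family_matrix(matrix: FamilyMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(matrix.genomes) + "\n")
        for fam in matrix.families:
            row = matrix.members.get(fam, {})
            cells = [", ".join(row.get(g, [])) for g in matrix.genomes]
            fh.write(fam + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_occupancy(occupancy: int, thresholds: PanThresholds) -> str:
    """Category of a single occupancy value."""
    n = thresholds.n
    if not 1 <= occupancy <= n:
        raise ValueError(f"occupancy {occupancy} outside [1, {n}]")
    if occupancy == n:
        return "core"
    if occupancy == 1:
        return "private"
    if thresholds.softcore_min <= occupancy <= n - 1:
        return "softcore"
    return "dispensable"


def classify_families(
    matrix: FamilyMatrix, thresholds: PanThresholds | None = None
) -> PanClassification:
    """Classify every family of *matrix* by occupancy.

    Occupancy-0 families are an error: they must be filtered upstream.
    """
    if thresholds is None:
        thresholds = PanThresholds.from_n(matrix.n_genomes)
    cats: dict[str, str] = {}
    for fam in matrix.families:
        occ = matrix.occupancy(fam)
        if occ == 0:
            raise ValueError(f"family {fam!r} has occupancy 0")
        cats[fam] = classify_occupancy(occ, thresholds)
    counts = {c: 0 for c in CATEGORIES}
    for c in cats.values():
        counts[c] += 1
    total = len(cats)
    fracs = {c: (counts[c] / total if total else 0.0) for c in CATEGORIES}
    return PanClassification(
        categories=cats,
        category_counts=counts,
        category_fractions=fracs,
        thresholds=thresholds,
    )


def category_fractions(
    counts: Mapping[str, int], as_percent: bool = False, ndigits: int | None = None
) -> dict[str, float]:
    """Fractions (or percents) per category from raw counts.

    ``ndigits`` rounds each value; ``ndigits=0`` rounds percents to whole
    numbers (returned as int in that case).
    """
    total = sum(counts.values())
    if total == 0:
        return {c: 0.0 for c in counts}
    scale = 100.0 if as_percent else 1.0
    out: dict[str, float] = {}
    for c, v in counts.items():
        x = scale * v / total
        if ndigits is not None:
            x = round(x, ndigits)
            if ndigits == 0:
                x = int(x)
        out[c] = x
    return out


# ---------------------------------------------------------------------------
# Saturation curves
# ---------------------------------------------------------------------------

def _pan_core(presence: np.ndarray, cols: Sequence[int]) -> tuple[int, int]:
    sub = presence[:, list(cols)]
    return int(sub.any(axis=1).sum()), int(sub.all(axis=1).sum())


def saturation_curves(
    matrix: FamilyMatrix,
    max_exhaustive: int = 10_000,
    n_samples: int = 100,
    seed: int | None = None,
    quantiles: Sequence[float] = (2.5, 50.0, 97.5),
) -> SaturationCurve:
    """Pan/core family counts over genome subsets of each size ``m``.

    All C(n, m) subsets are enumerated when their number does not exceed
    ``max_exhaustive``; otherwise ``n_samples`` distinct subsets are drawn with
    a seeded generator.
    """
    if matrix.n_genomes < 2:
        raise ValueError("need at least 2 genomes")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    presence = matrix.presence()
    n = matrix.n_genomes
    rng = random.Random(seed)
    sizes, pan_mean, core_mean, n_eval, modes = [], [], [], [], []
    pan_q: dict[float, list[float]] = {q: [] for q in quantiles}
    core_q: dict[float, list[float]] = {q: [] for q in quantiles}
    for m in range(1, n + 1):
        n_comb = math.comb(n, m)
        if n_comb <= max_exhaustive:
            subsets: Iterable[tuple[int, ...]] = combinations(range(n), m)
            mode = "exhaustive"
        else:
            chosen: set[tuple[int, ...]] = set()
            limit = min(n_samples, n_comb)
            while len(chosen) < limit:
                chosen.add(tuple(sorted(rng.sample(range(n), m))))
            subsets = sorted(chosen)
            mode = "sampled"
        pans, cores = [], []
        for cols in subsets:
            p, c = _pan_core(presence, cols)
            pans.append(p)
            cores.append(c)
        sizes.append(m)
        pan_mean.append(float(np.mean(pans)))
        core_mean.append(float(np.mean(cores)))
        n_eval.append(len(pans))
        modes.append(mode)
        for q in quantiles:
            pan_q[q].append(float(np.percentile(pans, q)))
            core_q[q].append(float(np.percentile(cores, q)))
    return SaturationCurve(
        sizes=sizes,
        pan_mean=pan_mean,
        core_mean=core_mean,
        pan_quantiles=pan_q,
        core_quantiles=core_q,
        n_combinations_evaluated=n_eval,
        mode=modes,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Gene-level summaries
# ---------------------------------------------------------------------------

def per_genome_composition(
    matrix: FamilyMatrix, classification: PanClassification
) -> pd.DataFrame:
    """Per-genome gene counts and fractions by pan category.

    Counts member *genes* (not families): a genome's fraction of core genes is
    the number of its genes sitting in core families over its clustered total.
    """
    rows = []
    for genome in matrix.genomes:
        counts = {c: 0 for c in CATEGORIES}
        for fam in matrix.families:
            genes = matrix.members.get(fam, {}).get(genome, [])
            if genes:
                counts[classification.categories[fam]] += len(genes)
        total = sum(counts.values())
        row: dict[str, object] = {"genome": genome, "total_genes": total}
        for c in CATEGORIES:
            row[f"{c}_genes"] = counts[c]
            row[f"{c}_frac"] = counts[c] / total if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("genome")


def singleton_genes(matrix: FamilyMatrix) -> set[str]:
    """All member genes of occupancy-1 families."""
    out: set[str] = set()
    for fam in matrix.families:
        if matrix.occupancy(fam) == 1:
            for genes in matrix.members.get(fam, {}).values():
                out.update(genes)
    return out


def crosstab_categories(
    gene_list: Iterable[str],
    matrix: FamilyMatrix,
    classification: PanClassification,
) -> pd.DataFrame:
    """Cross-tabulate an external gene list against pan categories.

    Genes whose family cannot be resolved are counted as ``unassigned``.
    Fractions use the full list length as denominator.
    """
    g2f = matrix.gene_to_family()
    counts = {c: 0 for c in CATEGORIES}
    counts["unassigned"] = 0
    genes = list(gene_list)
    for g in genes:
        fam = g2f.get(g)
        if fam is None:
            counts["unassigned"] += 1
        else:
            counts[classification.categories[fam]] += 1
    total = len(genes)
    return pd.DataFrame(
        {
            "count": counts,
            "fraction": {c: (v / total if total else 0.0) for c, v in counts.items()},
        }
    )
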