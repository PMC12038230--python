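"""Allele-specific expression between two haplotype genomes.

Genes are paired one-to-one across haplotypes via collinearity anchors; each
pair is called per condition against TPM and log2 fold-change thresholds
(defaults: TPM >= 2 and |log2FC| >= 2), and classified across conditions as
consistently biased toward one haplotype, inconsistent, or not ASE.

Sign convention: positive log2FC means hap1-biased.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AllelePair",
    "AseThresholds",
    "ConditionCall",
    "AseClassification",
    "read_anchors",
    "pair_alleles",
    "call_ase",
    "classify_consistency",
    "chromosome_bias_summary",
    "ase_sv_overlap",
]

CATEGORIES = ("consistent_hap1", "consistent_hap2", "inconsistent", "not_ase")


@dataclass(frozen=True)
class AseThresholds:
    """``tpm_rule`` is ``max`` (expressed allele >= tpm_min) or ``both``."""

    tpm_min: float = 2.0
    lfc_min: float = 2.0
    tpm_rule: str = "max"

    def __post_init__(self) -> None:
        if self.tpm_min <= 0:
            raise ValueError("tpm_min must be > 0")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")
        if self.tpm_rule not in ("max", "both"):
            raise ValueError("tpm_rule must be 'max' or 'both'")


@dataclass
class ConditionCall:
    tpm1: float
    tpm2: float
    log2fc: float  # +inf/-inf when exactly one allele is silent
    significant: bool
    direction: str  # hap1 | hap2 | none


@dataclass
class AllelePair:
    hap1_gene: str
    hap2_gene: str
    chrom: str | None = None
    score: float = 0.0
    calls: dict[str, ConditionCall] = field(default_factory=dict)


@dataclass
class AseClassification:
    categories: dict[str, str]  # hap1 gene id -> category
    counts: dict[str, int]
    pairs: list[AllelePair]


# ---------------------------------------------------------------------------
# Pairing
# ---------------------------------------------------------------------------

def read_anchors(path: str | Path) -> list[tuple[str, str, float]]:
    """Read an anchors table: '#' block headers, rows gene1<TAB>gene2<TAB>score."""
    rows: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            score = float(f[2]) if len(f) > 2 and f[2] not in ("", "-") else 0.0
            rows.append((f[0], f[1], score))
    return rows


def pair_alleles(
    anchors: Sequence[tuple[str, str, float]],
    hap1_genes: Iterable[str],
    hap2_genes: Iterable[str],
    chrom_map: Mapping[str, str] | None = None,
) -> tuple[list[AllelePair], float]:
    """One-to-one allele pairs from anchor rows.

    A gene occurring in several rows is kept in its best-scoring row (ties:
    first occurrence).  Rows referencing unknown genes are skipped with a
    warning.  ``pairing_rate`` = paired genes / total annotated genes.
    """
    hap1 = set(hap1_genes)
    hap2 = set(hap2_genes)
    order = sorted(range(len(anchors)), key=lambda i: (-anchors[i][2], i))
    used1: set[str] = set()
    used2: set[str] = set()
    chosen: list[tuple[int, AllelePair]] = []
    for i in order:
        g1, g2, score = anchors[i]
        if g1 not in hap1 or g2 not in hap2:
            warnings.warn(f"anchor row ({g1}, {g2}) references unknown gene; skipped")
            continue
        if g1 in used1 or g2 in used2:
            continue
        used1.add(g1)
        used2.add(g2)
        chrom = chrom_map.get(g1) if chrom_map else None
        chosen.append((i, AllelePair(g1, g2, chrom=chrom, score=score)))
    chosen.sort()
    pairs = [p for _, p in chosen]
    total = len(hap1) + len(hap2)
    rate = (2 * len(pairs) / total) if total else 0.0
    return pairs, rate


# ---------------------------------------------------------------------------
# Per-condition calling
# ---------------------------------------------------------------------------

def _call_one(tpm1: float, tpm2: float, th: AseThresholds) -> ConditionCall:
    if tpm1 < 0 or tpm2 < 0:
        raise ValueError("negative TPM")
    if tpm1 == 0 and tpm2 == 0:
        return ConditionCall(tpm1, tpm2, 0.0, False, "none")
    if tpm1 == 0 or tpm2 == 0:
        lfc = math.inf if tpm1 > 0 else -math.inf
        expressed = max(tpm1, tpm2)
        sig = expressed >= th.tpm_min
        direction = ("hap1" if tpm1 > 0 else "hap2") if sig else "none"
        return ConditionCall(tpm1, tpm2, lfc, sig, direction)
    lfc = math.log2(tpm1 / tpm2)
    if th.tpm_rule == "max":
        tpm_ok = max(tpm1, tpm2) >= th.tpm_min
    else:
        tpm_ok = min(tpm1, tpm2) >= th.tpm_min
    sig = tpm_ok and abs(lfc) >= th.lfc_min
    direction = "none"
    if sig:
        direction = "hap1" if tpm1 > tpm2 else "hap2"
    return ConditionCall(tpm1, tpm2, lfc, sig, direction)


def call_ase(
    pairs: Iterable[AllelePair],
    tpm: pd.DataFrame,
    conditions: Mapping[str, str],
    thresholds: AseThresholds | None = None,
) -> list[AllelePair]:
    """Attach per-condition ASE calls to each pair.

    ``tpm`` is genes x samples; ``conditions`` maps sample -> condition and
    replicate samples are averaged per condition before the fold change.
    Pairs with a gene missing from the matrix are dropped with a warning.
    """
    th = thresholds or AseThresholds()
    by_cond: dict[str, list[str]] = {}
    for sample, cond in conditions.items():
        if sample not in tpm.columns:
            raise KeyError(f"sample {sample!r} not in TPM matrix")
        by_cond.setdefault(cond, []).append(sample)
    means = pd.DataFrame({c: tpm[cols].mean(axis=1) for c, cols in by_cond.items()})
    out: list[AllelePair] = []
    for pair in pairs:
        if pair.hap1_gene not in means.index or pair.hap2_gene not in means.index:
            warnings.warn(
                f"pair ({pair.hap1_gene}, {pair.hap2_gene}) missing from TPM "
                "matrix; dropped"
            )
            continue
        pair.calls = {
            cond: _call_one(
                float(means.at[pair.hap1_gene, cond]),
                float(means.at[pair.hap2_gene, cond]),
                th,
            )
            for cond in means.columns
        }
        out.append(pair)
    return out


# ---------------------------------------------------------------------------
# Cross-condition consistency
# ---------------------------------------------------------------------------

def classify_consistency(
    pairs: Iterable[AllelePair], strict: bool = True
) -> AseClassification:
    """Classify called pairs across conditions.

    ``consistent_hapX``: significant with direction X in every condition.
    ``not_ase``: significant in no condition.  Everything else (direction
    flips and, under ``strict``, partial significance with a constant
    direction) is ``inconsistent``.  With ``strict=False`` a pair significant
    in at least one condition and never in the opposite direction counts as
    consistent.
    """
    pairs = list(pairs)
    cats: dict[str, str] = {}
    for pair in pairs:
        if len(pair.calls) < 2:
            raise ValueError(
                f"pair ({pair.hap1_gene}, {pair.hap2_gene}): consistency "
                "needs >= 2 conditions"
            )
        dirs = [c.direction for c in pair.calls.values()]
        sig = [c.significant for c in pair.calls.values()]
        if not any(sig):
            cat = "not_ase"
        elif all(sig) and len(set(dirs)) == 1:
            cat = f"consistent_{dirs[0]}"
        elif not strict and len({d for d in dirs if d != "none"}) == 1:
            biased = next(d for d in dirs if d != "none")
            cat = f"consistent_{biased}"
        else:
            cat = "inconsistent"
        cats[pair.hap1_gene] = cat
    counts = {c: 0 for c in CATEGORIES}
    for c in cats.values():
        counts[c] += 1
    return AseClassification(categories=cats, counts=counts, pairs=pairs)


def chromosome_bias_summary(
    classification: AseClassification,
    chrom_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-chromosome counts of consistent pairs and the dominant haplotype."""
    rows: dict[str, dict[str, int]] = {}
    for pair in classification.pairs:
        cat = classification.categories.get(pair.hap1_gene)
        if cat not in ("consistent_hap1", "consistent_hap2"):
            continue
        chrom = (chrom_map or {}).get(pair.hap1_gene, pair.chrom) or "NA"
        row = rows.setdefault(chrom, {"consistent_hap1": 0, "consistent_hap2": 0})
        row[cat] += 1
    records = []
    for chrom in sorted(rows):
        n1 = rows[chrom]["consistent_hap1"]
        n2 = rows[chrom]["consistent_hap2"]
        dominant = "tie" if n1 == n2 else ("hap1" if n1 > n2 else "hap2")
        records.append(
            {"chrom": chrom, "consistent_hap1": n1, "consistent_hap2": n2,
             "dominant": dominant}
        )
    return pd.DataFrame(
        records, columns=["chrom", "consistent_hap1", "consistent_hap2", "dominant"]
    ).set_index("chrom") if records else pd.DataFrame(
        columns=["consistent_hap1", "consistent_hap2", "dominant"]
    )


def ase_sv_overlap(
    classification: AseClassification,
    sv_plus_genes: Iterable[str],
    upstream_sv_genes: Iterable[str] = (),
) -> dict[str, float]:
    """Overlap of significant ASE genes (hap1 ids) with SV gene sets."""
    ase_genes = {
        g for g, cat in classification.categories.items() if cat != "not_ase"
    }
    body = ase_genes & set(sv_plus_genes)
    upstream = ase_genes & set(upstream_sv_genes)
    n = len(ase_genes)
    return {
        "n_ase": n,
        "n_sv_body": len(body),
        "n_sv_upstream": len(upstream),
        "frac_sv_body": len(body) / n if n else 0.0,
        "frac_sv_upstream": len(upstream) / n if n else 0.0,
    }
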