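"""Structural-variant extraction from whole-genome-alignment call tables.

Consumes the SyRI output dialect (12 tab-separated columns, 1-based inclusive
coordinates) and provides SV classification into six categories, length
binning, gene-overlap screening (gene body and strand-aware upstream 2 kb),
highly-diverged-region (HDR) detection from syntenic coverage, and a Welch
two-sample comparison of numeric gene attributes.

All internal coordinates are 0-based half-open.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

SV_TYPES = ("INS", "DEL", "INV", "TRANS", "DUP", "CNV")

#: alignment-code -> SV category.  Copy gain/loss (CPG/CPL) fold into CNV;
#: inverted translocations/duplications fold into TRANS/DUP.
DEFAULT_CODE_MAP: dict[str, str] = {
    "INS": "INS",
    "DEL": "DEL",
    "INV": "INV",
    "TRANS": "TRANS",
    "INVTR": "TRANS",
    "DUP": "DUP",
    "INVDP": "DUP",
    "CPG": "CNV",
    "CPL": "CNV",
}

DEFAULT_BIN_EDGES = (50.0, 100.0, 500.0, 1e3, 5e3, 1e4, float("inf"))

__all__ = [
    "SV_TYPES",
    "DEFAULT_CODE_MAP",
    "DEFAULT_BIN_EDGES",
    "SyriRecord",
    "SvRecord",
    "GeneModel",
    "SvFilterParams",
    "HdrSegment",
    "GroupComparison",
    "parse_syri",
    "parse_syri_lines",
    "extract_svs",
    "partition_records",
    "length_histogram",
    "annotate_sv_genes",
    "detect_hdr",
    "compare_groups",
    "read_gene_models",
]


@dataclass
class SyriRecord:
    """One raw alignment/variant record (internal half-open coordinates)."""

    ref_chrom: str | None
    ref_start: int | None
    ref_end: int | None
    qry_chrom: str | None
    qry_start: int | None
    qry_end: int | None
    rec_id: str
    parent: str | None
    code: str
    copy_status: str | None
    is_syntenic: bool

    @property
    def ref_span(self) -> int:
        if self.ref_start is None or self.ref_end is None:
            return 0
        return self.ref_end - self.ref_start

    @property
    def qry_span(self) -> int:
        if self.qry_start is None or self.qry_end is None:
            return 0
        return self.qry_end - self.qry_start


@dataclass
class SvRecord:
    type: str
    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str | None
    qry_start: int | None
    qry_end: int | None
    length: int
    source_code: str


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")


@dataclass(frozen=True)
class SvFilterParams:
    """``min_len`` is an exclusive lower bound: kept iff length > min_len."""

    min_len: int = 50
    types_kept: frozenset[str] = frozenset(SV_TYPES)
    code_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_CODE_MAP))


@dataclass
class HdrSegment:
    chrom: str
    start: int
    end: int
    diverged_fraction: float
    gene_ids: list[str] = field(default_factory=list)


@dataclass
class GroupComparison:
    labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    t: float
    p: float
    test: str = "welch"
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _coord(x: str) -> int | None:
    return None if x == "-" else int(x)


def parse_syri_lines(lines: Iterable[str], source: str = "<lines>") -> list[SyriRecord]:
    """Parse SyRI-dialect lines (see :func:`parse_syri`)."""
    records: list[SyriRecord] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 11:
            raise ValueError(
                f"{source}:{lineno}: expected >=11 tab-separated fields, "
                f"got {len(fields)}"
            )
        try:
            ref_start = _coord(fields[1])
            ref_end = _coord(fields[2])
            qry_start = _coord(fields[6])
            qry_end = _coord(fields[7])
        except ValueError as exc:
            raise ValueError(f"{source}:{lineno}: bad coordinate ({exc})") from None
        # qry coords may be emitted reversed for inverted alignments
        if qry_start is not None and qry_end is not None and qry_start > qry_end:
            qry_start, qry_end = qry_end, qry_start
        code = fields[10]
        records.append(
            SyriRecord(
                ref_chrom=None if fields[0] == "-" else fields[0],
                ref_start=None if ref_start is None else ref_start - 1,
                ref_end=ref_end,
                qry_chrom=None if fields[5] == "-" else fields[5],
                qry_start=None if qry_start is None else qry_start - 1,
                qry_end=qry_end,
                rec_id=fields[8],
                parent=None if fields[9] == "-" else fields[9],
                code=code,
                copy_status=fields[11] if len(fields) > 11 and fields[11] != "-" else None,
                is_syntenic=code.startswith("SYN"),
            )
        )
    return records


def parse_syri(path: str | Path) -> list[SyriRecord]:
    """Parse a SyRI-dialect output table.

    Input coordinates are 1-based inclusive and converted to 0-based
    half-open; ``-`` fields become ``None``.  Records whose annotation code
    starts with ``SYN`` are flagged syntenic.
    """
    with open(path) as fh:
        return parse_syri_lines(fh, source=str(path))


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from a GFF3 (``gene`` features only) or BED file."""
    genes: list[GeneModel] = []
    path = Path(path)
    is_bed = path.suffix.lower() == ".bed"
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if is_bed:
                gid = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
                strand = f[5] if len(f) > 5 else "+"
                genes.append(GeneModel(gid, f[0], int(f[1]), int(f[2]), strand))
            else:
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                gid = attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}")
                genes.append(
                    GeneModel(gid, f[0], int(f[3]) - 1, int(f[4]), f[6])
                )
    return genes


# ---------------------------------------------------------------------------
# SV extraction
# ---------------------------------------------------------------------------

def _to_sv(rec: SyriRecord, sv_type: str) -> SvRecord:
    length = max(rec.ref_span, rec.qry_span)
    return SvRecord(
        type=sv_type,
        ref_chrom=rec.ref_chrom or "",
        ref_start=rec.ref_start if rec.ref_start is not None else 0,
        ref_end=rec.ref_end if rec.ref_end is not None else 0,
        qry_chrom=rec.qry_chrom,
        qry_start=rec.qry_start,
        qry_end=rec.qry_end,
        length=length,
        source_code=rec.code,
    )


def partition_records(
    records: Iterable[SyriRecord], params: SvFilterParams | None = None
) -> dict[str, list]:
    """Split parsed records into kept SVs / length-filtered / syntenic / other.

    ``kept + filtered + syntenic + other`` conserves the input count.
    Unknown (unmapped) annotation codes raise a warning and land in ``other``.
    """
    if params is None:
        params = SvFilterParams()
    out: dict[str, list] = {"kept": [], "filtered": [], "syntenic": [], "other": []}
    warned: set[str] = set()
    for rec in records:
        if rec.is_syntenic:
            out["syntenic"].append(rec)
            continue
        sv_type = params.code_map.get(rec.code)
        if sv_type is None or sv_type not in params.types_kept:
            if sv_type is None and rec.code not in warned:
                warnings.warn(f"unknown annotation code {rec.code!r}; record kept as-is")
                warned.add(rec.code)
            out["other"].append(rec)
            continue
        sv = _to_sv(rec, sv_type)
        if sv.length > params.min_len:
            out["kept"].append(sv)
        else:
            out["filtered"].append(sv)
    return out


def extract_svs(
    records: Iterable[SyriRecord], params: SvFilterParams | None = None
) -> list[SvRecord]:
    """SVs of the six categories with length strictly above ``min_len``."""
    return partition_records(records, params)["kept"]


def length_histogram(
    svs: Iterable[SvRecord], bin_edges: Sequence[float] = DEFAULT_BIN_EDGES
) -> pd.DataFrame:
    """Counts per (edge_i, edge_{i+1}] bin per SV type.

    SVs no longer than the first edge fall into an ``underflow`` column.
    """
    edges = list(bin_edges)
    if any(b >= c for b, c in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    labels = ["underflow"] + [
        f"({_fmt(a)},{_fmt(b)}]" for a, b in zip(edges, edges[1:])
    ]
    table = {t: [0] * len(labels) for t in SV_TYPES}
    for sv in svs:
        if sv.type not in table:
            table[sv.type] = [0] * len(labels)
        if sv.length <= edges[0]:
            idx = 0
        else:
            # (a, b] binning: first upper edge with length <= b
            idx = 1 + next(i for i, b in enumerate(edges[1:]) if sv.length <= b)
        table[sv.type][idx] += 1
    return pd.DataFrame(table, index=labels).T


def _fmt(x: float) -> str:
    if x == float("inf"):
        return "inf"
    return str(int(x)) if float(x).is_integer() else str(x)


# ---------------------------------------------------------------------------
# Gene overlap
# ---------------------------------------------------------------------------

def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    iv = sorted(iv)
    merged: list[tuple[int, int]] = []
    for s, e in iv:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _overlaps(merged: list[tuple[int, int]], start: int, end: int) -> bool:
    # merged sorted non-overlapping; binary search on starts
    starts = [s for s, _ in merged]
    i = bisect_right(starts, end - 1)
    for s, e in merged[max(0, i - 2) : i]:
        if s < end and start < e:
            return True
    return False


def gene_windows(
    gene: GeneModel, region: str, upstream: int = 2000
) -> list[tuple[str, int, int]]:
    """Intervals screened for a gene under the given region mode."""
    wins: list[tuple[str, int, int]] = []
    if region in ("body", "both"):
        wins.append((gene.chrom, gene.start, gene.end))
    if region in ("upstream2k", "both"):
        if gene.strand == "+":
            wins.append((gene.chrom, max(0, gene.start - upstream), gene.start))
        elif gene.strand == "-":
            wins.append((gene.chrom, gene.end, gene.end + upstream))
        else:
            raise ValueError(
                f"gene {gene.gene_id}: strand {gene.strand!r} unusable for "
                "upstream windows"
            )
    return wins


def annotate_sv_genes(
    svs: Iterable[SvRecord],
    genes: Iterable[GeneModel],
    region: str = "body",
    upstream: int = 2000,
) -> tuple[set[str], set[str]]:
    """Split genes into SV+ / SV- by >=1 bp overlap with SV reference spans.

    ``region`` is ``body`` (gene interval), ``upstream2k`` (strand-aware
    2 kb window upstream of the start) or ``both``.
    """
    if region not in ("body", "upstream2k", "both"):
        raise ValueError(f"unknown region mode {region!r}")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for sv in svs:
        if sv.ref_end > sv.ref_start:
            by_chrom.setdefault(sv.ref_chrom, []).append((sv.ref_start, sv.ref_end))
    merged = {c: _merge_intervals(iv) for c, iv in by_chrom.items()}
    plus: set[str] = set()
    minus: set[str] = set()
    for gene in genes:
        hit = False
        for chrom, s, e in gene_windows(gene, region, upstream):
            if e > s and chrom in merged and _overlaps(merged[chrom], s, e):
                hit = True
                break
        (plus if hit else minus).add(gene.gene_id)
    return plus, minus


# ---------------------------------------------------------------------------
# HDR detection
# ---------------------------------------------------------------------------

def detect_hdr(
    records: Iterable[SyriRecord],
    window: int = 100_000,
    min_diverged_fraction: float = 0.5,
    merge_gap: int = 0,
    genes: Iterable[GeneModel] | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[HdrSegment]:
    """Highly diverged regions: windows poorly covered by syntenic alignment.

    Each reference chromosome is tiled into ``window``-bp windows; a window's
    diverged fraction is the share not covered by syntenic records.  Windows at
    or above ``min_diverged_fraction`` are merged when separated by at most
    ``merge_gap`` bp.  Genes overlapping a merged segment are attached.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    records = list(records)
    syn: dict[str, list[tuple[int, int]]] = {}
    span_max: dict[str, int] = {}
    for rec in records:
        if rec.ref_chrom is None or rec.ref_start is None or rec.ref_end is None:
            continue
        span_max[rec.ref_chrom] = max(span_max.get(rec.ref_chrom, 0), rec.ref_end)
        if rec.is_syntenic:
            syn.setdefault(rec.ref_chrom, []).append((rec.ref_start, rec.ref_end))
    if chrom_lengths:
        for c, ln in chrom_lengths.items():
            span_max[c] = max(span_max.get(c, 0), ln)
    segments: list[HdrSegment] = []
    for chrom in sorted(span_max):
        length = span_max[chrom]
        merged_syn = _merge_intervals(syn.get(chrom, []))
        flagged: list[tuple[int, int, float]] = []
        for w0 in range(0, length, window):
            w1 = min(w0 + window, length)
            cov = sum(
                max(0, min(e, w1) - max(s, w0)) for s, e in merged_syn
            )
            frac = 1.0 - cov / (w1 - w0)
            if frac >= min_diverged_fraction:
                flagged.append((w0, w1, frac))
        # merge flagged windows with gaps <= merge_gap
        i = 0
        while i < len(flagged):
            s, e, _ = flagged[i]
            j = i + 1
            while j < len(flagged) and flagged[j][0] - e <= merge_gap:
                e = flagged[j][1]
                j += 1
            cov = sum(max(0, min(se, e) - max(ss, s)) for ss, se in merged_syn)
            segments.append(
                HdrSegment(chrom=chrom, start=s, end=e,
                           diverged_fraction=1.0 - cov / (e - s))
            )
            i = j
    if genes is not None:
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for seg in segments:
            seg.gene_ids = sorted(
                g.gene_id
                for g in by_chrom.get(seg.chrom, [])
                if g.start < seg.end and seg.start < g.end
            )
    return segments


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Welch two-sample t-test between two numeric groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    degenerate = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
    if degenerate and a.mean() == b.mean():
        return GroupComparison(
            labels=labels, n=(a.size, b.size), means=(a.mean(), b.mean()),
            t=0.0, p=1.0, degenerate=True,
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # zero variance in both groups, unequal means
        return GroupComparison(
            labels=labels, n=(a.size, b.size), means=(a.mean(), b.mean()),
            t=float("inf") if a.mean() > b.mean() else float("-inf"),
            p=0.0, degenerate=True,
        )
    return GroupComparison(
        labels=labels, n=(a.size, b.size),
        means=(float(a.mean()), float(b.mean())), t=t, p=p,
        degenerate=bool(degenerate),
    )
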