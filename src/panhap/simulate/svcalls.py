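"""Synthetic whole-genome-alignment SV tables with planted truth.

Produces a SyRI-dialect table over one reference/query chromosome pair:
syntenic blocks covering the unaffected sequence plus SV records of the six
categories, a set of gene models planted inside, bordering and away from the
SVs, and an exact truth object (SV list and SV+ gene set).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ..sv import GeneModel

#: emitted annotation code per SV category (CNV alternates CPG/CPL)
_TYPE_CODES = {
    "INS": ["INS"],
    "DEL": ["DEL"],
    "INV": ["INV"],
    "TRANS": ["TRANS"],
    "DUP": ["DUP"],
    "CNV": ["CPG", "CPL"],
}

__all__ = ["SvSimSpec", "PlantedSv", "simulate_sv_calls", "write_syri", "write_gff3"]


@dataclass(frozen=True)
class SvSimSpec:
    genome_length: int = 1_000_000
    n_sv_per_type: Mapping[str, int] = field(
        default_factory=lambda: {t: 5 for t in _TYPE_CODES}
    )
    length_range_per_type: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {t: (100, 2000) for t in _TYPE_CODES}
    )
    gene_count: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1000:
            raise ValueError("genome_length too small")
        for t in self.n_sv_per_type:
            if t not in _TYPE_CODES:
                raise ValueError(f"unknown SV type {t!r}")
        for t, (lo, hi) in self.length_range_per_type.items():
            if not 1 <= lo <= hi:
                raise ValueError(f"bad length range for {t}: ({lo}, {hi})")


@dataclass
class PlantedSv:
    type: str
    code: str
    ref_start: int  # 0-based half-open reference anchor span
    ref_end: int
    length: int


def simulate_sv_calls(
    spec: SvSimSpec,
) -> tuple[list[list[str]], list[GeneModel], dict]:
    """Generate (syri_rows, gene_models, truth).

    ``syri_rows`` are 12-column rows in the SyRI dialect (1-based inclusive
    coordinates, tab-joinable).  ``truth`` holds the planted SV list, the SV+
    gene-id set (>=1 bp gene-body overlap with any planted SV reference span)
    and per-gene placement labels.
    """
    rng = np.random.default_rng(spec.seed)
    # --- plant non-overlapping reference intervals -------------------------
    planted: list[PlantedSv] = []
    occupied: list[tuple[int, int]] = []
    total_needed = 0
    for t, n in spec.n_sv_per_type.items():
        lo, hi = spec.length_range_per_type.get(t, (100, 2000))
        total_needed += n * (1 if t == "INS" else hi)
    if total_needed > 0.7 * spec.genome_length:
        raise ValueError("genome too short to place the requested SVs")

    def _free(s: int, e: int) -> bool:
        return all(e <= a or b <= s for a, b in occupied)

    serial: dict[str, int] = {}
    for t in sorted(spec.n_sv_per_type):
        n = spec.n_sv_per_type[t]
        lo, hi = spec.length_range_per_type.get(t, (100, 2000))
        codes = _TYPE_CODES[t]
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            ref_span = 1 if t == "INS" else length
            for _ in range(10_000):
                s = int(rng.integers(1, spec.genome_length - ref_span - 1))
                # 1-bp pad keeps planted spans strictly disjoint from borders
                if _free(s - 1, s + ref_span + 1):
                    break
            else:
                raise ValueError("genome too short to place the requested SVs")
            occupied.append((s, s + ref_span))
            serial[t] = serial.get(t, 0) + 1
            planted.append(
                PlantedSv(
                    type=t,
                    code=codes[(serial[t] - 1) % len(codes)],
                    ref_start=s,
                    ref_end=s + ref_span,
                    length=length,
                )
            )
    planted.sort(key=lambda p: p.ref_start)

    # --- emit SyRI rows: syntenic gaps + SV records ------------------------
    ref_chrom, qry_chrom = "chr1", "chr1"
    rows: list[list[str]] = []
    cursor_ref, cursor_qry, n_syn = 0, 0, 0

    def _row(rs, re, qs, qe, rid, code):
        return [
            ref_chrom, str(rs + 1), str(re), "-", "-",
            qry_chrom, str(qs + 1), str(qe), rid, "-", code, "-",
        ]

    for p in planted:
        gap = p.ref_start - cursor_ref
        if gap > 0:
            n_syn += 1
            rows.append(
                _row(cursor_ref, cursor_ref + gap, cursor_qry, cursor_qry + gap,
                     f"SYN{n_syn}", "SYN")
            )
            cursor_ref += gap
            cursor_qry += gap
        qry_span = 1 if p.type == "DEL" else p.length
        rows.append(
            _row(p.ref_start, p.ref_end, cursor_qry, cursor_qry + qry_span,
                 f"{p.code}{sum(1 for q in planted if q is p or q.ref_start < p.ref_start)}",
                 p.code)
        )
        cursor_ref = p.ref_end
        cursor_qry += qry_span
    if cursor_ref < spec.genome_length:
        n_syn += 1
        tail = spec.genome_length - cursor_ref
        rows.append(
            _row(cursor_ref, spec.genome_length, cursor_qry, cursor_qry + tail,
                 f"SYN{n_syn}", "SYN")
        )

    # --- plant genes inside / bordering / outside the SVs ------------------
    genes: list[GeneModel] = []
    placement: dict[str, str] = {}
    kinds = ["inside", "outside", "border"]
    for gi in range(spec.gene_count):
        kind = kinds[gi % len(kinds)]
        strand = "+" if gi % 2 == 0 else "-"
        gid = f"SIM_g{gi + 1}"
        interval: tuple[int, int] | None = None
        if kind == "inside" and planted:
            p = planted[(gi // 3) % len(planted)]
            a = p.ref_start
            interval = (max(0, a - 100), min(spec.genome_length, a + 101))
        elif kind == "border" and planted:
            # left-adjacent, half-open: touches but does not overlap
            for p in rng.permutation(len(planted)):
                a = planted[int(p)].ref_start
                s, e = max(0, a - 200), a
                if e > s and _free(s, e):
                    interval = (s, e)
                    break
            if interval is None:
                kind = "outside"
        if interval is None:  # outside (or fallback)
            for _ in range(10_000):
                s = int(rng.integers(0, spec.genome_length - 200))
                if _free(s, s + 200):
                    interval = (s, s + 200)
                    break
            else:
                raise ValueError("could not place an SV-free gene")
            kind = "outside"
        genes.append(GeneModel(gid, ref_chrom, interval[0], interval[1], strand))
        placement[gid] = kind

    sv_plus = {
        g.gene_id
        for g in genes
        if any(g.start < p.ref_end and p.ref_start < g.end for p in planted)
    }
    truth = {
        "svs": planted,
        "sv_plus_genes": sv_plus,
        "gene_placement": placement,
    }
    return rows, genes, truth


def write_syri(rows: Sequence[Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(row) + "\n")


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tpanhap\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
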