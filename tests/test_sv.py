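"""SV parsing, extraction, binning, gene overlap, HDR and group comparison."""

import math

import numpy as np
import pytest

from panhap import sv
from panhap.simulate import SvSimSpec, simulate_sv_calls, write_syri


def _line(ref_chrom, rs, re, qchrom, qs, qe, rid, code):
    return "\t".join(
        [ref_chrom, str(rs), str(re), "-", "-", qchrom, str(qs), str(qe),
         rid, "-", code, "-"]
    )


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

class TestParse:
    def test_coordinate_convention(self):
        rec = sv.parse_syri_lines([_line("c1", 1, 1000, "c1", 1, 1000, "INV1", "INV")])[0]
        assert (rec.ref_start, rec.ref_end) == (0, 1000)
        assert rec.ref_span == 1000

    def test_syn_flagged_and_excluded(self):
        recs = sv.parse_syri_lines([
            _line("c1", 1, 100, "c1", 1, 100, "SYN1", "SYN"),
            _line("c1", 101, 300, "c1", 101, 300, "INV1", "INV"),
        ])
        assert recs[0].is_syntenic and not recs[1].is_syntenic
        assert len(sv.extract_svs(recs)) == 1

    def test_dash_fields_become_none(self):
        rec = sv.parse_syri_lines([_line("c1", 1, 100, "-", "-", "-", "NOTAL1", "NOTAL")])[0]
        assert rec.qry_chrom is None and rec.qry_start is None

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "bad.out"
        p.write_text("c1\t1\t100\n")
        with pytest.raises(ValueError, match=":1:"):
            sv.parse_syri(p)

    def test_file_round_trip_spans(self, tmp_path):
        rows, _, _ = simulate_sv_calls(SvSimSpec(seed=0))
        p = tmp_path / "syri.out"
        write_syri(rows, p)
        recs = sv.parse_syri(p)
        assert len(recs) == len(rows)
        for row, rec in zip(rows, recs):
            # 1-based inclusive -> half-open preserves span
            assert rec.ref_span == int(row[2]) - int(row[1]) + 1

    def test_unknown_code_warns_and_keeps(self):
        recs = sv.parse_syri_lines([_line("c1", 1, 100, "c1", 1, 100, "X1", "WEIRD")])
        with pytest.warns(UserWarning, match="WEIRD"):
            parts = sv.partition_records(recs)
        assert len(parts["other"]) == 1


# ---------------------------------------------------------------------------
# Extraction and the strict >50 filter
# ---------------------------------------------------------------------------

class TestExtract:
    def test_length_50_excluded_51_included(self):
        recs = sv.parse_syri_lines([
            _line("c1", 101, 150, "c1", 101, 150, "DEL1", "DEL"),  # span 50
            _line("c1", 201, 251, "c1", 201, 201, "DEL2", "DEL"),  # span 51
        ])
        svs = sv.extract_svs(recs)
        assert [s.length for s in svs] == [51]

    def test_length_is_max_of_spans(self):
        # insertion: 1 bp on reference, 300 bp on query
        recs = sv.parse_syri_lines([_line("c1", 100, 100, "c1", 100, 399, "INS1", "INS")])
        (s,) = sv.extract_svs(recs)
        assert s.length == 300

    def test_code_mapping(self):
        codes = ["INS", "DEL", "INV", "TRANS", "INVTR", "DUP", "INVDP", "CPG", "CPL"]
        lines = [
            _line("c1", 1 + i * 1000, 200 + i * 1000, "c1", 1 + i * 1000,
                  200 + i * 1000, f"r{i}", code)
            for i, code in enumerate(codes)
        ]
        svs = sv.extract_svs(sv.parse_syri_lines(lines))
        got = [s.type for s in svs]
        assert got == ["INS", "DEL", "INV", "TRANS", "TRANS", "DUP", "DUP", "CNV", "CNV"]

    def test_conservation(self):
        rows, _, _ = simulate_sv_calls(SvSimSpec(seed=1))
        recs = sv.parse_syri_lines("\t".join(r) for r in rows)
        parts = sv.partition_records(recs)
        assert sum(len(v) for v in parts.values()) == len(recs)


# ---------------------------------------------------------------------------
# Length histogram
# ---------------------------------------------------------------------------

class TestHistogram:
    def test_default_bins(self):
        svs = [
            sv.SvRecord("DEL", "c1", 0, 60, None, None, None, 60, "DEL"),
            sv.SvRecord("DEL", "c1", 0, 2000, None, None, None, 2000, "DEL"),
        ]
        hist = sv.length_histogram(svs)
        assert hist.loc["DEL", "(50,100]"] == 1
        assert hist.loc["DEL", "(1000,5000]"] == 1
        assert hist.loc["DEL"].sum() == 2

    def test_empty(self):
        hist = sv.length_histogram([])
        assert (hist.to_numpy() == 0).all()

    def test_underflow(self):
        svs = [sv.SvRecord("INV", "c1", 0, 10, None, None, None, 10, "INV")]
        hist = sv.length_histogram(svs)
        assert hist.loc["INV", "underflow"] == 1

    def test_bad_edges(self):
        with pytest.raises(ValueError):
            sv.length_histogram([], bin_edges=(100, 50))


# ---------------------------------------------------------------------------
# Gene overlap vs O(n*m) oracle
# ---------------------------------------------------------------------------

def overlap_oracle(svs, genes, region="body", upstream=2000):
    """All-pairs >=1 bp overlap scan (independent of the module's sweep)."""
    plus = set()
    for g in genes:
        windows = []
        if region in ("body", "both"):
            windows.append((g.chrom, g.start, g.end))
        if region in ("upstream2k", "both"):
            if g.strand == "+":
                windows.append((g.chrom, max(0, g.start - upstream), g.start))
            else:
                windows.append((g.chrom, g.end, g.end + upstream))
        for s in svs:
            for chrom, a, b in windows:
                if chrom == s.ref_chrom and a < s.ref_end and s.ref_start < b:
                    plus.add(g.gene_id)
    return plus, {g.gene_id for g in genes} - plus


class TestGeneOverlap:
    def test_simple_overlap(self):
        svs = [sv.SvRecord("DEL", "c1", 150, 160, None, None, None, 10, "DEL")]
        genes = [sv.GeneModel("g1", "c1", 100, 200)]
        plus, minus = sv.annotate_sv_genes(svs, genes)
        assert plus == {"g1"} and minus == set()

    def test_half_open_adjacency(self):
        svs = [sv.SvRecord("DEL", "c1", 200, 210, None, None, None, 10, "DEL")]
        genes = [sv.GeneModel("g1", "c1", 100, 200)]
        plus, minus = sv.annotate_sv_genes(svs, genes)
        assert plus == set() and minus == {"g1"}

    def test_unknown_strand_upstream_errors(self):
        genes = [sv.GeneModel("g1", "c1", 100, 200, strand=".")]
        with pytest.raises(ValueError, match="strand"):
            sv.annotate_sv_genes([], genes, region="upstream2k")

    @pytest.mark.parametrize("region", ["body", "upstream2k", "both"])
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle(self, region, seed):
        rows, genes, _ = simulate_sv_calls(
            SvSimSpec(seed=seed, gene_count=40, genome_length=500_000)
        )
        recs = sv.parse_syri_lines("\t".join(r) for r in rows)
        svs = sv.extract_svs(recs)
        got = sv.annotate_sv_genes(svs, genes, region=region)
        expected = overlap_oracle(svs, genes, region=region)
        assert got == expected


# ---------------------------------------------------------------------------
# HDR detection
# ---------------------------------------------------------------------------

class TestHdr:
    def test_fully_syntenic(self):
        recs = sv.parse_syri_lines([_line("c1", 1, 500_000, "c1", 1, 500_000, "SYN1", "SYN")])
        assert sv.detect_hdr(recs, window=100_000) == []

    def test_threshold_edge(self):
        # 100 kb window with 60 kb non-syntenic -> fraction 0.6 >= 0.5
        recs = sv.parse_syri_lines([
            _line("c1", 1, 40_000, "c1", 1, 40_000, "SYN1", "SYN"),
            _line("c1", 40_001, 100_000, "c1", 40_001, 100_000, "NOTAL1", "NOTAL"),
        ])
        segs = sv.detect_hdr(recs, window=100_000, min_diverged_fraction=0.5)
        assert len(segs) == 1
        assert segs[0].diverged_fraction == pytest.approx(0.6)

    def test_planted_block_recovered(self):
        # 500 kb diverged block inside 2 Mb of synteny
        window = 100_000
        recs = sv.parse_syri_lines([
            _line("c1", 1, 1_000_000, "c1", 1, 1_000_000, "SYN1", "SYN"),
            _line("c1", 1_000_001, 1_500_000, "c1", 1_000_001, 1_500_000, "TRANS1", "TRANS"),
            _line("c1", 1_500_001, 2_000_000, "c1", 1_500_001, 2_000_000, "SYN2", "SYN"),
        ])
        segs = sv.detect_hdr(recs, window=window, min_diverged_fraction=0.5)
        assert len(segs) == 1
        assert abs(segs[0].start - 1_000_000) <= window
        assert abs(segs[0].end - 1_500_000) <= window

    def test_monotone_in_threshold(self):
        rows, _, _ = simulate_sv_calls(SvSimSpec(seed=2))
        recs = sv.parse_syri_lines("\t".join(r) for r in rows)
        total_prev = math.inf
        for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
            segs = sv.detect_hdr(recs, window=10_000, min_diverged_fraction=thr)
            total = sum(s.end - s.start for s in segs)
            assert total <= total_prev
            total_prev = total

    def test_gene_attachment(self):
        recs = sv.parse_syri_lines([
            _line("c1", 1, 100_000, "c1", 1, 100_000, "NOTAL1", "NOTAL"),
        ])
        genes = [sv.GeneModel("g1", "c1", 500, 900),
                 sv.GeneModel("g2", "c2", 500, 900)]
        segs = sv.detect_hdr(recs, window=100_000, genes=genes)
        assert segs[0].gene_ids == ["g1"]

    def test_bad_window(self):
        with pytest.raises(ValueError):
            sv.detect_hdr([], window=0)


# ---------------------------------------------------------------------------
# Welch comparison vs closed-form oracle
# ---------------------------------------------------------------------------

def welch_oracle(a, b):
    """Closed-form Welch statistic with Satterthwaite df, via scipy only for
    the t CDF."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, p


class TestCompareGroups:
    def test_identical_groups(self):
        res = sv.compare_groups([1, 2, 3], [1, 2, 3])
        assert res.t == 0 and res.p == pytest.approx(1.0)

    def test_shift_detected(self):
        res = sv.compare_groups([1, 2, 3], [11, 12, 13])
        t, p = welch_oracle([1, 2, 3], [11, 12, 13])
        assert res.t == pytest.approx(t)
        assert res.p == pytest.approx(p)
        assert res.p < 0.01

    def test_swap_negates_t(self):
        a, b = [1.0, 2.5, 3.5, 4.0], [2.0, 2.0, 5.0, 7.0]
        r1 = sv.compare_groups(a, b)
        r2 = sv.compare_groups(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_small_groups_error(self):
        with pytest.raises(ValueError):
            sv.compare_groups([1], [1, 2])

    def test_degenerate_flagged(self):
        res = sv.compare_groups([2, 2, 2], [2, 2, 2])
        assert res.degenerate and res.t == 0 and res.p == 1.0
        res2 = sv.compare_groups([2, 2], [3, 3])
        assert res2.degenerate and res2.p == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_random_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 2, 15)
        res = sv.compare_groups(a, b)
        t, p = welch_oracle(a, b)
        assert res.t == pytest.approx(t)
        assert res.p == pytest.approx(p)
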