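"""k-mer spectra, genome-size estimation and LTR insertion dating.

The genome size estimate is the plain peak-coverage formula

    G = N * (L - k + 1) / F

with N reads of length L and F the k-mer multiplicity at the spectrum peak
above the error cutoff.  The error cutoff defaults to the first local minimum
of the multiplicity histogram (the end of the low-multiplicity error spike)
and can be overridden.

LTR insertion times follow T = K / (2 r) with divergence K and per-site
per-year substitution rate r (default 3.39e-9).
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

DEFAULT_LTR_RATE = 3.39e-9

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

__all__ = [
    "DEFAULT_LTR_RATE",
    "KmerSpectrum",
    "SizeEstimate",
    "LtrAge",
    "build_spectrum",
    "estimate_genome_size",
    "find_error_cutoff",
    "ltr_insertion_time",
    "read_fastx",
]


@dataclass
class KmerSpectrum:
    k: int
    counts: dict[int, int]  # multiplicity -> number of distinct canonical k-mers
    total_kmer_instances: int

    def dense(self) -> np.ndarray:
        """Histogram as an array indexed by multiplicity (index 0 unused)."""
        if not self.counts:
            return np.zeros(1, dtype=np.int64)
        arr = np.zeros(max(self.counts) + 1, dtype=np.int64)
        for mult, n in self.counts.items():
            arr[mult] = n
        return arr


@dataclass
class SizeEstimate:
    G: float
    N: int
    L: int
    k: int
    F: int
    error_cutoff: int


@dataclass
class LtrAge:
    K_div: float
    r: float
    T: float


def _canonical(kmer: str, rc: str) -> str:
    return kmer if kmer <= rc else rc


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def build_spectrum(reads: Iterable[str], k: int, skip_short: bool = True) -> KmerSpectrum:
    """Count canonical k-mers (lexicographic min of a k-mer and its reverse
    complement) over all reads.

    Windows containing non-ACGT characters are skipped.  Reads shorter than k
    are skipped when ``skip_short`` else raise.  If no read yields a k-mer the
    call errors.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counter: Counter[str] = Counter()
    any_used = False
    for read in reads:
        seq = read.upper()
        if len(seq) < k:
            if skip_short:
                continue
            raise ValueError(f"read of length {len(seq)} < k={k}")
        any_used = True
        rc = revcomp(seq)
        L = len(seq)
        for i in range(L - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            counter[_canonical(kmer, rc[L - k - i : L - i])] += 1
    if not any_used:
        raise ValueError("k exceeds every read length")
    hist: Counter[int] = Counter(counter.values())
    total = sum(m * c for m, c in hist.items())
    return KmerSpectrum(k=k, counts=dict(hist), total_kmer_instances=total)


def find_error_cutoff(spectrum: KmerSpectrum) -> int:
    """First local minimum of the multiplicity histogram.

    Error k-mers form a descending spike at low multiplicity; the cutoff is
    the multiplicity where counts stop falling.  If the histogram rises
    immediately (no error spike) the cutoff is 0.  A monotonically
    non-increasing histogram has no usable peak and raises.
    """
    arr = spectrum.dense()
    if len(arr) <= 2:
        raise ValueError("spectrum too small to locate an error cutoff")
    if arr[1] <= arr[2]:
        return 0
    m = 1
    while m + 1 < len(arr) and arr[m + 1] < arr[m]:
        m += 1
    if m + 1 >= len(arr):
        raise ValueError(
            "histogram is monotonically non-increasing; no peak beyond the "
            "error spike — supply error_cutoff manually"
        )
    return m


def estimate_genome_size(
    spectrum: KmerSpectrum,
    n_reads: int,
    read_length: int,
    error_cutoff: int | str = "auto",
    smooth_window: int = 3,
) -> SizeEstimate:
    """Genome size via G = N (L - k + 1) / F.

    F is the multiplicity of the histogram maximum restricted to
    multiplicities strictly above ``error_cutoff``.  The histogram is
    smoothed with a centered moving average of width ``smooth_window``
    before locating the peak (sampling noise makes the raw argmax jitter
    across the flat top of the coverage distribution); set it to 1 for the
    raw argmax.
    """
    if not spectrum.counts:
        raise ValueError("empty spectrum")
    if read_length < spectrum.k:
        raise ValueError("read length must be >= k")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    cutoff = find_error_cutoff(spectrum) if error_cutoff == "auto" else int(error_cutoff)
    arr = spectrum.dense()
    if cutoff + 1 >= len(arr):
        raise ValueError(f"error cutoff {cutoff} leaves no multiplicities")
    raw_region = arr[cutoff + 1 :].astype(float)
    peak_region = raw_region
    if smooth_window > 1 and len(peak_region) > smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        peak_region = np.convolve(raw_region, kernel, mode="same")
    # smoothed ties (sparse spectra) resolve to the largest raw count
    candidates = np.nonzero(peak_region >= peak_region.max() - 1e-9)[0]
    j = candidates[int(np.argmax(raw_region[candidates]))]
    F = cutoff + 1 + int(j)
    G = n_reads * (read_length - spectrum.k + 1) / F
    return SizeEstimate(
        G=G, N=n_reads, L=read_length, k=spectrum.k, F=F, error_cutoff=cutoff
    )


def ltr_insertion_time(k_div, rate: float = DEFAULT_LTR_RATE):
    """Insertion time(s) T = K / (2 r) in years; elementwise on arrays."""
    if rate <= 0:
        raise ValueError("mutation rate must be > 0")
    k_arr = np.asarray(k_div, dtype=float)
    if (k_arr < 0).any():
        raise ValueError("divergence must be >= 0")
    t = k_arr / (2.0 * rate)
    if np.isscalar(k_div) or k_arr.ndim == 0:
        return LtrAge(K_div=float(k_arr), r=rate, T=float(t))
    return t


# ---------------------------------------------------------------------------
# Sequence input
# ---------------------------------------------------------------------------

def read_fastx(path: str | Path) -> list[str]:
    """Sequences from a FASTA/FASTQ file, plain or gzipped."""
    from Bio import SeqIO

    path = Path(path)
    name = path.name.lower()
    opener = gzip.open if name.endswith(".gz") else open
    stem = name[:-3] if name.endswith(".gz") else name
    fmt = "fastq" if stem.endswith((".fq", ".fastq")) else "fasta"
    with opener(path, "rt") as fh:
        return [str(rec.seq) for rec in SeqIO.parse(fh, fmt)]
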