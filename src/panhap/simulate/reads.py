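"""Uniform single-end read simulation from a random reference."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

__all__ = ["ReadSimSpec", "simulate_reads", "write_fasta", "write_fastq"]


@dataclass(frozen=True)
class ReadSimSpec:
    genome_length: int = 100_000
    read_length: int = 100
    coverage: float = 20.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < self.read_length:
            raise ValueError("genome shorter than read length")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")

    @property
    def n_reads(self) -> int:
        return round(self.coverage * self.genome_length / self.read_length)


def simulate_reads(spec: ReadSimSpec) -> tuple[str, list[str]]:
    """Return (reference sequence, reads).

    Reads are sampled uniformly from the forward strand with per-base
    substitution errors at ``error_rate`` (an error always changes the base).
    """
    rng = np.random.default_rng(spec.seed)
    ref = _BASES[rng.integers(0, 4, size=spec.genome_length)]
    n = spec.n_reads
    starts = rng.integers(0, spec.genome_length - spec.read_length + 1, size=n)
    reads: list[str] = []
    for s in starts:
        read = ref[s : s + spec.read_length].copy()
        if spec.error_rate > 0:
            hits = np.nonzero(rng.random(spec.read_length) < spec.error_rate)[0]
            if hits.size:
                # shift by 1..3 positions in the base alphabet: never identity
                shift = rng.integers(1, 4, size=hits.size)
                idx = (np.searchsorted(_BASES, read[hits]) + shift) % 4
                read[hits] = _BASES[idx]
        reads.append(read.tobytes().decode())
    return ref.tobytes().decode(), reads


def write_fasta(sequences: Sequence[str], path: str | Path, prefix: str = "seq") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(sequences, start=1):
            fh.write(f">{prefix}{i}\n{seq}\n")


def write_fastq(reads: Sequence[str], path: str | Path, prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads, start=1):
            fh.write(f"@{prefix}{i}\n{seq}\n+\n{'I' * len(seq)}\n")
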