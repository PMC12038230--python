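"""Synthetic paired-allele TPM matrices with planted ASE truth."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ..ase import AllelePair, AseThresholds

__all__ = ["AseSimSpec", "simulate_ase_matrix"]

#: log2 margin by which planted effects clear the fold-change threshold
_MARGIN_LOG2 = 2.0


@dataclass(frozen=True)
class AseSimSpec:
    n_pairs: int = 100
    n_conditions: int = 3
    n_consistent: int = 20
    n_inconsistent: int = 20
    baseline_tpm: float = 10.0
    noise_cv: float = 0.0
    n_chromosomes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conditions < 2:
            raise ValueError("n_conditions must be >= 2")
        if self.n_consistent + self.n_inconsistent > self.n_pairs:
            raise ValueError("planted categories exceed n_pairs")
        if self.baseline_tpm <= 0:
            raise ValueError("baseline_tpm must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def _noise_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def simulate_ase_matrix(
    spec: AseSimSpec, thresholds: AseThresholds | None = None
) -> tuple[list[AllelePair], pd.DataFrame, dict[str, str]]:
    """Generate (pairs, tpm_matrix, truth).

    Planted consistent pairs clear both thresholds with a fixed direction in
    every condition (log2FC margin of 2 above ``lfc_min``); inconsistent
    pairs either flip direction or fall below threshold in one condition;
    the remainder stay unbiased.  Multiplicative log-normal noise with the
    requested coefficient of variation is applied to every TPM entry.

    Truth labels per hap1 gene: ``consistent_hap1``, ``consistent_hap2``,
    ``inconsistent`` or ``none``.

    Raises if ``noise_cv`` is so large that planted effects cannot be
    guaranteed (margin below ~4 sd of the fold-change noise).
    """
    th = thresholds or AseThresholds()
    sigma = _noise_sigma(spec.noise_cv)
    lfc_sd = math.sqrt(2.0) * sigma / math.log(2.0)
    if spec.noise_cv > 0 and _MARGIN_LOG2 < 4.0 * lfc_sd:
        raise ValueError(
            f"noise_cv={spec.noise_cv} too large: planted effects not "
            f"guaranteed (margin {_MARGIN_LOG2} < 4 x lfc sd {lfc_sd:.2f})"
        )
    rng = np.random.default_rng(spec.seed)
    ratio = 2.0 ** (th.lfc_min + _MARGIN_LOG2)
    base = max(spec.baseline_tpm, 2.0 * th.tpm_min)
    conditions = [f"cond{j + 1}" for j in range(spec.n_conditions)]

    pairs: list[AllelePair] = []
    truth: dict[str, str] = {}
    tpm1 = np.zeros((spec.n_pairs, spec.n_conditions))
    tpm2 = np.zeros((spec.n_pairs, spec.n_conditions))
    for i in range(spec.n_pairs):
        g1, g2 = f"hap1_g{i + 1}", f"hap2_g{i + 1}"
        chrom = f"chr{(i % spec.n_chromosomes) + 1}"
        pairs.append(AllelePair(g1, g2, chrom=chrom, score=100.0))
        if i < spec.n_consistent:
            direction = "hap1" if i % 2 == 0 else "hap2"
            hi, lo = base * ratio, base
            for j in range(spec.n_conditions):
                tpm1[i, j] = hi if direction == "hap1" else lo
                tpm2[i, j] = lo if direction == "hap1" else hi
            truth[g1] = f"consistent_{direction}"
        elif i < spec.n_consistent + spec.n_inconsistent:
            flip = i % 2 == 0  # alternate: direction flip vs partial significance
            for j in range(spec.n_conditions):
                if j == spec.n_conditions - 1:
                    if flip:
                        tpm1[i, j], tpm2[i, j] = base, base * ratio
                    else:
                        tpm1[i, j] = tpm2[i, j] = base
                else:
                    tpm1[i, j], tpm2[i, j] = base * ratio, base
            truth[g1] = "inconsistent"
        else:
            tpm1[i, :] = base
            tpm2[i, :] = base
            truth[g1] = "none"
    if spec.noise_cv > 0:
        mu = -0.5 * sigma * sigma  # unit-mean log-normal
        tpm1 *= rng.lognormal(mu, sigma, size=tpm1.shape)
        tpm2 *= rng.lognormal(mu, sigma, size=tpm2.shape)
    matrix = pd.DataFrame(
        np.vstack([tpm1, tpm2]),
        index=[p.hap1_gene for p in pairs] + [p.hap2_gene for p in pairs],
        columns=conditions,
    )
    return pairs, matrix, truth
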