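"""Pipeline orchestration and summary-report assembly.

``run_pipeline`` executes the requested stages — on synthetic inputs (specs
embedded in the config) or on files — and collects per-stage count tables
into a :class:`SummaryReport`.  ``arithmetic_checks`` verifies the internal
partition sums and percentage roundings of every table.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__, ase as ase_mod, dup as dup_mod
from . import pangenome as pan_mod, survey as survey_mod, sv as sv_mod
from .simulate import (
    AseSimSpec,
    PangenomeSimSpec,
    ReadSimSpec,
    SvSimSpec,
    simulate_ase_matrix,
    simulate_family_matrix,
    simulate_reads,
    simulate_sv_calls,
)

logger = logging.getLogger("panhap")

__all__ = ["RunConfig", "SummaryReport", "Check", "run_pipeline",
           "arithmetic_checks", "sum_partition", "percent", "load_config"]


@dataclass
class RunConfig:
    stages: list[str]
    seed: int = 0
    out_dir: str | None = None
    parameters: dict[str, Any] = field(default_factory=dict)
    synthetic: dict[str, Any] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)


@dataclass
class SummaryReport:
    tables: dict[str, Any]
    provenance: dict[str, Any]

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {"tables": self.tables, "provenance": self.provenance},
            indent=2, sort_keys=True, default=_jsonable, **kwargs,
        )


@dataclass
class Check:
    name: str
    passed: bool
    detail: str = ""


def _jsonable(x):
    if isinstance(x, set):
        return sorted(x)
    if hasattr(x, "item"):
        return x.item()
    return str(x)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(
        stages=list(raw.get("stages", [])),
        seed=int(raw.get("seed", 0)),
        out_dir=raw.get("out_dir"),
        parameters=dict(raw.get("parameters", {})),
        synthetic=dict(raw.get("synthetic", {})),
        inputs=dict(raw.get("inputs", {})),
    )


# ---------------------------------------------------------------------------
# Arithmetic helpers (partition sums and printed-precision percentages)
# ---------------------------------------------------------------------------

def sum_partition(parts: Mapping[str, int] | list[int]) -> int:
    values = list(parts.values()) if isinstance(parts, Mapping) else list(parts)
    return int(sum(values))


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage rounded to the printed precision; int when ndigits == 0."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    x = round(100.0 * numerator / denominator, ndigits)
    return int(x) if ndigits == 0 else x


# ---------------------------------------------------------------------------
# Stage runners (synthetic-first; file inputs when configured)
# ---------------------------------------------------------------------------

def _stage_pangenome(cfg: RunConfig) -> dict[str, Any]:
    syn = cfg.synthetic.get("pangenome")
    if syn is not None:
        spec = PangenomeSimSpec(seed=cfg.seed, **syn)
        matrix, truth = simulate_family_matrix(spec)
    else:
        matrix = pan_mod.read_family_matrix(cfg.inputs["orthogroups"])
        truth = None
    cls = pan_mod.classify_families(matrix)
    params = cfg.parameters.get("pangenome", {})
    curve = pan_mod.saturation_curves(
        matrix,
        max_exhaustive=params.get("max_exhaustive", 2000),
        n_samples=params.get("n_samples", 50),
        seed=cfg.seed,
    )
    comp = pan_mod.per_genome_composition(matrix, cls)
    table: dict[str, Any] = {
        "n_families": matrix.n_families,
        "n_genomes": matrix.n_genomes,
        "category_counts": cls.category_counts,
        "category_percent": pan_mod.category_fractions(
            cls.category_counts, as_percent=True, ndigits=0
        ),
        "n_singleton_genes": len(pan_mod.singleton_genes(matrix)),
        "saturation": curve.to_frame().to_dict(orient="list"),
        "per_genome_composition": comp.reset_index().to_dict(orient="list"),
    }
    if truth is not None:
        planted = {c: 0 for c in pan_mod.CATEGORIES}
        for cat in truth.values():
            planted[cat] += 1
        table["planted_counts"] = planted
    return table


def _stage_sv(cfg: RunConfig) -> dict[str, Any]:
    syn = cfg.synthetic.get("sv")
    params = cfg.parameters.get("sv", {})
    if syn is not None:
        spec = SvSimSpec(seed=cfg.seed, **syn)
        rows, genes, truth = simulate_sv_calls(spec)
        records = sv_mod.parse_syri_lines("\t".join(row) for row in rows)
    else:
        records = sv_mod.parse_syri(cfg.inputs["syri"])
        genes = sv_mod.read_gene_models(cfg.inputs["genes"]) if "genes" in cfg.inputs else []
        truth = None
    filt = sv_mod.SvFilterParams(min_len=params.get("min_len", 50))
    svs = sv_mod.extract_svs(records, filt)
    hist = sv_mod.length_histogram(svs)
    plus, minus = sv_mod.annotate_sv_genes(svs, genes, region="body")
    type_counts: dict[str, int] = {t: 0 for t in sv_mod.SV_TYPES}
    for s in svs:
        type_counts[s.type] += 1
    table: dict[str, Any] = {
        "n_records": len(records),
        "sv_type_counts": type_counts,
        "n_sv_total": sum(type_counts.values()),
        "length_histogram": hist.to_dict(orient="index"),
        "n_sv_plus_genes": len(plus),
        "n_sv_minus_genes": len(minus),
    }
    if truth is not None:
        table["planted_sv_plus_genes"] = len(truth["sv_plus_genes"])
    return table


def _stage_ase(cfg: RunConfig) -> dict[str, Any]:
    syn = cfg.synthetic.get("ase")
    params = cfg.parameters.get("ase", {})
    th = ase_mod.AseThresholds(
        tpm_min=params.get("tpm_min", 2.0),
        lfc_min=params.get("lfc_min", 2.0),
        tpm_rule=params.get("tpm_rule", "max"),
    )
    if syn is not None:
        spec = AseSimSpec(seed=cfg.seed, **syn)
        pairs, tpm, truth = simulate_ase_matrix(spec, th)
        conditions = {c: c for c in tpm.columns}
    else:
        import pandas as pd

        anchors = ase_mod.read_anchors(cfg.inputs["anchors"])
        tpm = pd.read_csv(cfg.inputs["tpm"], sep="\t", index_col=0)
        cond_df = pd.read_csv(cfg.inputs["conditions"], sep="\t")
        conditions = dict(zip(cond_df.iloc[:, 0], cond_df.iloc[:, 1]))
        hap1 = [g for g in tpm.index if g in {a for a, _, _ in anchors}]
        hap2 = [g for g in tpm.index if g in {b for _, b, _ in anchors}]
        pairs, _ = ase_mod.pair_alleles(anchors, hap1, hap2)
        truth = None
    called = ase_mod.call_ase(pairs, tpm, conditions, th)
    cls = ase_mod.classify_consistency(called)
    bias = ase_mod.chromosome_bias_summary(cls)
    table: dict[str, Any] = {
        "n_pairs": len(called),
        "counts": cls.counts,
        "n_ase": sum(v for k, v in cls.counts.items() if k != "not_ase"),
        "n_consistent": cls.counts["consistent_hap1"] + cls.counts["consistent_hap2"],
        "chromosome_bias": bias.reset_index().to_dict(orient="list"),
    }
    if truth is not None:
        planted = {"consistent_hap1": 0, "consistent_hap2": 0,
                   "inconsistent": 0, "none": 0}
        for cat in truth.values():
            planted[cat] += 1
        table["planted_counts"] = planted
    return table


def _stage_dup(cfg: RunConfig) -> dict[str, Any]:
    pair_lists = []
    for mode in dup_mod.MODES:
        key = f"dup_{mode.lower()}"
        if key in cfg.inputs:
            pair_lists.append(dup_mod.read_pair_list(cfg.inputs[key], mode))
    with open(cfg.inputs["gene_list"]) as fh:
        all_genes = [ln.strip() for ln in fh if ln.strip()]
    assignment = dup_mod.assign_unique_mode(pair_lists, all_genes)
    return {"mode_counts": assignment.mode_counts, "n_genes": len(all_genes)}


def _stage_survey(cfg: RunConfig) -> dict[str, Any]:
    syn = cfg.synthetic.get("reads")
    params = cfg.parameters.get("survey", {})
    k = params.get("k", 21)
    if syn is not None:
        spec = ReadSimSpec(seed=cfg.seed, **syn)
        _, reads = simulate_reads(spec)
        n_reads, read_len = len(reads), spec.read_length
        true_size = spec.genome_length
    else:
        reads = survey_mod.read_fastx(cfg.inputs["reads"])
        n_reads = len(reads)
        read_len = max(len(r) for r in reads)
        true_size = None
    spectrum = survey_mod.build_spectrum(reads, k)
    est = survey_mod.estimate_genome_size(
        spectrum, n_reads, read_len, params.get("error_cutoff", "auto")
    )
    table: dict[str, Any] = {
        "k": k,
        "n_reads": n_reads,
        "read_length": read_len,
        "peak_multiplicity": est.F,
        "error_cutoff": est.error_cutoff,
        "genome_size_estimate": est.G,
    }
    if true_size is not None:
        table["true_genome_size"] = true_size
    return table


_STAGES = {
    "pangenome": _stage_pangenome,
    "sv": _stage_sv,
    "ase": _stage_ase,
    "dup": _stage_dup,
    "survey": _stage_survey,
}


def run_pipeline(config: RunConfig) -> SummaryReport:
    """Execute the configured stages and assemble a summary report.

    Stage failures abort with a stage-tagged error.  Identical config and
    seed produce identical reports.
    """
    tables: dict[str, Any] = {}
    for stage in config.stages:
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        t0 = time.monotonic()
        logger.info("stage %s: start", stage)
        try:
            tables[stage] = _STAGES[stage](config)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s: done in %.2fs", stage, time.monotonic() - t0)
    report = SummaryReport(
        tables=tables,
        provenance={
            "version": __version__,
            "seed": config.seed,
            "stages": list(config.stages),
            "parameters": config.parameters,
        },
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
    return report


def arithmetic_checks(report: SummaryReport) -> list[Check]:
    """Internal-consistency checks on every report table.

    Verifies partition sums (category counts vs totals) and printed-precision
    percentage roundings (integer percents for family categories).
    """
    checks: list[Check] = []
    t = report.tables
    if "pangenome" in t:
        tab = t["pangenome"]
        total = sum_partition(tab["category_counts"])
        checks.append(
            Check(
                "pangenome.category_counts_sum",
                total == tab["n_families"],
                f"{total} vs {tab['n_families']}",
            )
        )
        expected = pan_mod.category_fractions(
            tab["category_counts"], as_percent=True, ndigits=0
        )
        checks.append(
            Check(
                "pangenome.category_percent_rounding",
                expected == tab["category_percent"],
                f"{expected} vs {tab['category_percent']}",
            )
        )
    if "sv" in t:
        tab = t["sv"]
        checks.append(
            Check(
                "sv.type_counts_sum",
                sum_partition(tab["sv_type_counts"]) == tab["n_sv_total"],
            )
        )
    if "ase" in t:
        tab = t["ase"]
        checks.append(
            Check(
                "ase.counts_partition",
                sum_partition(tab["counts"]) == tab["n_pairs"],
            )
        )
        checks.append(
            Check(
                "ase.consistent_sum",
                tab["counts"]["consistent_hap1"] + tab["counts"]["consistent_hap2"]
                == tab["n_consistent"],
            )
        )
    if "dup" in t:
        tab = t["dup"]
        checks.append(
            Check(
                "dup.mode_counts_sum",
                sum_partition(tab["mode_counts"]) == tab["n_genes"],
            )
        )
    return checks
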