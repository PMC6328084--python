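"""Manifest-driven execution over patient pairs and trios.

A trio (tumour + PDX + PDO) is always decomposed into the three ordered
pairwise comparisons TvsX, TvsO, XvsO and each pair is scored exactly as a
standalone pair would be; every statistic is a pure function of the two
samples' call sets, so trio results are simple restrictions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import yaml

from . import __version__
from .cnv import (
    CnConcordance,
    cn_concordance,
    cn_concordance_by_chromosome,
    intersect_segments,
    ploidy_qc,
    rescale_by_ploidy,
)
from .io_formats import (
    read_cn_segments,
    read_manifest,
    read_ssm_vcf,
    read_sv_bedpe,
    write_report_tables,
)
from .model import SampleManifest
from .ssm import SsmJaccardRow, jaccard_all_mutations, jaccard_by_type
from .sv import (
    CategoryJaccardRow,
    ChromSvRow,
    OverallScore,
    category_jaccard,
    chromosome_jaccard_rows,
    overall_concordance,
)

logger = logging.getLogger(__name__)

#: Canonical pair decomposition: label -> (role_a, role_b).
PAIR_ROLE_ORDER = (
    ("TvsX", "tumour", "pdx"),
    ("TvsO", "tumour", "pdo"),
    ("XvsO", "pdx", "pdo"),
)


@dataclass
class Config:
    """Run configuration: thresholds, tolerances and module toggles."""

    jaccard_threshold: float = 0.6   # S^c / classification cut, inclusive
    cn_tolerance: float = 0.25       # max |delta| of rescaled copy states
    elevated_min: float = 5.0        # clustered-rearrangement flag, both samples
    discordant_diff: float = 10.0    # event-count discordance flag
    bp_tolerance: int = 0            # SV breakpoint matching slack, bases
    ploidy_rel_tol: float = 0.1
    pass_only: bool = True
    snv_only: bool = False
    cn_denominator: str = "codefined"
    type_key: str = "MUT_TYPE"
    depth_key: str = "AD"
    run_ssm: bool = True
    run_sv: bool = True
    run_cnv: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "Config":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PairResult:
    """All statistics for one ordered sample pair; None = module not run."""

    sample_a: str
    sample_b: str
    ssm_rows: Optional[list[SsmJaccardRow]] = None
    ssm_all: Optional[SsmJaccardRow] = None
    sv_chrom_rows: Optional[list[ChromSvRow]] = None
    sv_category_rows: Optional[list[CategoryJaccardRow]] = None
    sv_overall: Optional[OverallScore] = None
    cn_genome: Optional[CnConcordance] = None
    cn_by_chrom: Optional[list[CnConcordance]] = None
    ploidy_flag: Optional[str] = None
    classifications: dict[str, str] = field(default_factory=dict)


@dataclass
class ConcordanceReport:
    patient_id: str
    cohort: str
    pair_results: dict[str, PairResult]
    provenance: dict = field(default_factory=dict)


def classify_score(score: Optional[float], threshold: float = 0.6) -> str:
    """Map a 0-1 concordance score to its label (threshold inclusive)."""
    if score is None:
        return "NA"
    return "concordant" if score >= threshold else "discordant"


def decompose_trio(entry: SampleManifest) -> list[tuple[str, str, str]]:
    """Ordered pairwise decomposition (TvsX, TvsO, XvsO), present roles only."""
    roles = set(entry.roles)
    if len(roles) < 2:
        raise ValueError(
            f"patient {entry.patient_id}: need at least two roles, got {sorted(roles)}"
        )
    return [
        (label, a, b)
        for label, a, b in PAIR_ROLE_ORDER
        if a in roles and b in roles
    ]


def _load_inputs(entry: SampleManifest, config: Config) -> dict[str, dict]:
    data: dict[str, dict] = {}
    for role in entry.roles:
        sample_id = entry.samples[role]
        kinds = entry.paths.get(role, {})
        loaded: dict = {"sample_id": sample_id}
        if config.run_ssm and "ssm" in kinds:
            loaded["ssm"] = read_ssm_vcf(
                kinds["ssm"], sample_id,
                type_key=config.type_key,
                depth_key=config.depth_key,
                pass_only=config.pass_only,
            )
        if config.run_sv and "sv" in kinds:
            loaded["sv"] = read_sv_bedpe(kinds["sv"], sample_id)
        if config.run_cnv and "cn" in kinds:
            segments, ploidy = read_cn_segments(
                kinds["cn"], sample_id, ploidy_path=kinds.get("ploidy"),
            )
            loaded["cn"] = segments
            loaded["ploidy"] = ploidy
        data[role] = loaded
    return data


def _score_pair(a: dict, b: dict, config: Config) -> PairResult:
    result = PairResult(sample_a=a["sample_id"], sample_b=b["sample_id"])
    if "ssm" in a and "ssm" in b:
        result.ssm_rows = jaccard_by_type(a["ssm"], b["ssm"], snv_only=config.snv_only)
        result.ssm_all = jaccard_all_mutations(a["ssm"], b["ssm"], snv_only=config.snv_only)
        result.classifications["ssm_all"] = classify_score(
            result.ssm_all.jaccard, config.jaccard_threshold
        )
    if "sv" in a and "sv" in b:
        result.sv_chrom_rows = chromosome_jaccard_rows(
            a["sv"], b["sv"],
            bp_tolerance=config.bp_tolerance,
            elevated_min=config.elevated_min,
            discordant_diff=config.discordant_diff,
        )
        result.sv_overall = overall_concordance(
            result.sv_chrom_rows, threshold=config.jaccard_threshold
        )
        rows = category_jaccard(a["sv"], b["sv"], "genome",
                                bp_tolerance=config.bp_tolerance)
        for row in result.sv_chrom_rows:
            rows.extend(
                category_jaccard(a["sv"], b["sv"], row.chrom,
                                 bp_tolerance=config.bp_tolerance)
            )
        result.sv_category_rows = rows
        result.classifications["sv_overall"] = classify_score(
            result.sv_overall.score, config.jaccard_threshold
        )
    if "cn" in a and "cn" in b:
        rescaled_a = rescale_by_ploidy(a["cn"], a["ploidy"])
        rescaled_b = rescale_by_ploidy(b["cn"], b["ploidy"])
        blocks = intersect_segments(rescaled_a, rescaled_b,
                                    tolerance=config.cn_tolerance)
        result.cn_genome = cn_concordance(
            blocks, tolerance=config.cn_tolerance,
            denominator=config.cn_denominator,
        )
        result.cn_by_chrom = cn_concordance_by_chromosome(
            blocks, tolerance=config.cn_tolerance,
            denominator=config.cn_denominator,
        )
        result.ploidy_flag = ploidy_qc(
            a["ploidy"], b["ploidy"], rel_tol=config.ploidy_rel_tol
        )
        result.classifications["cn_genome"] = classify_score(
            result.cn_genome.score, config.jaccard_threshold
        )
    return result


def run_patient(entry: SampleManifest, config: Optional[Config] = None) -> ConcordanceReport:
    """Score every requested analysis for every pair of one patient."""
    config = config or Config()
    data = _load_inputs(entry, config)
    pair_results = {
        label: _score_pair(data[role_a], data[role_b], config)
        for label, role_a, role_b in decompose_trio(entry)
    }
    provenance = {
        "tool_version": __version__,
        "config": config.to_dict(),
        "inputs": {role: dict(kinds) for role, kinds in entry.paths.items()},
    }
    return ConcordanceReport(
        patient_id=entry.patient_id,
        cohort=entry.cohort,
        pair_results=pair_results,
        provenance=provenance,
    )


def run_cohort(
    manifest_path: str,
    out_dir: str,
    config: Optional[Config] = None,
) -> dict[str, ConcordanceReport]:
    """Run every patient in a manifest; a failing patient is logged and skipped."""
    config = config or Config()
    reports: dict[str, ConcordanceReport] = {}
    for entry in read_manifest(manifest_path):
        try:
            report = run_patient(entry, config)
        except Exception:
            logger.exception("patient %s failed; continuing", entry.patient_id)
            continue
        reports[entry.patient_id] = report
        write_report(report, os.path.join(out_dir, entry.patient_id))
        logger.info("patient %s: %d pair(s) scored", entry.patient_id,
                    len(report.pair_results))
    return reports


def report_summary(report: ConcordanceReport) -> dict:
    """JSON-serializable summary of a report (lossless for all scores)."""
    return {
        "patient_id": report.patient_id,
        "cohort": report.cohort,
        "provenance": report.provenance,
        "pairs": {
            label: dataclasses.asdict(result)
            for label, result in report.pair_results.items()
        },
    }


def write_report(report: ConcordanceReport, out_dir: str) -> str:
    """Write the TSV matrices plus a machine-readable summary.json."""
    os.makedirs(out_dir, exist_ok=True)
    write_report_tables(report, out_dir)
    summary_path = os.path.join(out_dir, "summary.json")
    with open(summary_path, "w") as fh:
        json.dump(report_summary(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary_path
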