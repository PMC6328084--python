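"""Readers and writers for the external formats the pipeline touches.

All coordinate-convention conversion happens here and only here:

* VCF is 1-based; positions pass through unchanged.
* BEDPE is 0-based half-open; point breakpoints become 1-based on read
  (``pos = start + 1``) and are shifted back on write.
* Segment tables are 0-based half-open and stay that way internally.

Writers exist chiefly so the synthetic-data generator can emit files that
round-trip exactly through the readers.
"""

from __future__ import annotations

import csv
import logging
import os
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam
import yaml

from .model import (
    DEFAULT_CHROMOSOMES,
    CnSegment,
    SampleManifest,
    SamplePloidy,
    SvEvent,
    VariantCall,
    make_sv_event,
)

logger = logging.getLogger(__name__)

#: Caller-dialect labels accepted (case-insensitively) for SV categories.
SV_CATEGORY_SYNONYMS = {
    "del": "DEL",
    "deletion": "DEL",
    "dup": "DUP",
    "duplication": "DUP",
    "inv": "INV",
    "inversion": "INV",
    "tra": "TRA",
    "translocation": "TRA",
    "ctx": "TRA",
}

BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2", "svtype",
]


def normalize_sv_category(label: str) -> str:
    norm = SV_CATEGORY_SYNONYMS.get(label.strip().lower())
    if norm is None:
        raise ValueError(f"unknown SV category label {label!r}")
    return norm


# ---------------------------------------------------------------------------
# Simple somatic mutations (VCF)
# ---------------------------------------------------------------------------

def read_ssm_vcf(
    path: str,
    sample_id: str,
    *,
    type_key: str = "MUT_TYPE",
    depth_key: str = "AD",
    pass_only: bool = True,
) -> list[VariantCall]:
    """Read somatic SNV/indel calls from a VCF into :class:`VariantCall` s.

    Multi-allelic records are split into one call per ALT allele; each split
    call inherits the allele depths for its own allele. The annotation
    category is looked up in ``INFO[type_key]`` (scalar, or one value per
    ALT); calls with no annotation are kept as ``"Unannotated"`` with a
    warning. Symbolic ALTs (``<DEL>`` etc.) and spanning-deletion ``*``
    alleles are skipped.
    """
    calls: list[VariantCall] = []
    n_unannotated = 0
    with pysam.VariantFile(path) as vcf:
        vcf_samples = list(vcf.header.samples)
        for rec in vcf:
            if pass_only and rec.filter.keys() and "PASS" not in rec.filter.keys():
                continue
            alts = rec.alts or ()
            types = rec.info.get(type_key) if type_key in rec.info else None
            if isinstance(types, str):
                types = (types,) * len(alts)
            depths: Optional[Sequence[int]] = None
            if vcf_samples:
                col = sample_id if sample_id in vcf_samples else vcf_samples[0]
                sample_data = rec.samples[col]
                if depth_key in sample_data:
                    ad = sample_data[depth_key]
                    if ad is not None and all(v is not None for v in ad):
                        depths = list(ad)
            for i, alt in enumerate(alts):
                if alt is None or alt == "*" or alt.startswith("<"):
                    continue
                if types is not None and i < len(types) and types[i] is not None:
                    mutation_type = str(types[i])
                else:
                    mutation_type = "Unannotated"
                    n_unannotated += 1
                calls.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        mutation_type=mutation_type,
                        ref_depth=depths[0] if depths else None,
                        alt_depth=depths[1 + i] if depths and len(depths) > 1 + i else None,
                        sample_id=sample_id,
                    )
                )
    if n_unannotated:
        logger.warning(
            "%s: %d call(s) lacked INFO/%s; kept as 'Unannotated'",
            path, n_unannotated, type_key,
        )
    return calls


def write_ssm_vcf(
    calls: Iterable[VariantCall],
    path: str,
    sample_id: str,
    *,
    type_key: str = "MUT_TYPE",
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write calls as a minimal single-sample VCF 4.2 (one record per call)."""
    calls = sorted(calls, key=_variant_sort_key)
    contigs: dict[str, int] = dict(contig_lengths or {})
    for call in calls:
        contigs.setdefault(call.chrom, 300_000_000)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f'##INFO=<ID={type_key},Number=A,Type=String,'
                 'Description="Functional annotation category">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths (ref, alt)">\n')
        fh.write('##FILTER=<ID=PASS,Description="All filters passed">\n')
        for chrom in _sorted_chroms(contigs):
            fh.write(f"##contig=<ID={chrom},length={contigs[chrom]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample_id}\n")
        for call in calls:
            if call.ref_depth is not None and call.alt_depth is not None:
                fmt, geno = "GT:AD", f"0/1:{call.ref_depth},{call.alt_depth}"
            else:
                fmt, geno = "GT", "0/1"
            fh.write(
                f"{call.chrom}\t{call.pos}\t.\t{call.ref}\t{call.alt}\t.\tPASS\t"
                f"{type_key}={call.mutation_type}\t{fmt}\t{geno}\n"
            )


def _variant_sort_key(call: VariantCall):
    return (_chrom_rank(call.chrom), call.pos, call.ref, call.alt)


def _chrom_rank(chrom: str):
    try:
        return (0, DEFAULT_CHROMOSOMES.index(chrom), chrom)
    except ValueError:
        return (1, 0, chrom)


def _sorted_chroms(contigs: dict[str, int]) -> list[str]:
    return sorted(contigs, key=_chrom_rank)


# ---------------------------------------------------------------------------
# Structural variants (BEDPE)
# ---------------------------------------------------------------------------

def read_sv_bedpe(path: str, sample_id: str) -> list[SvEvent]:
    """Read point-breakpoint SVs from an 11-column BEDPE (svtype in column 11).

    BEDPE is 0-based half-open; breakpoints are taken as ``start + 1``.
    Intra-chromosomal events are reordered so ``pos_a < pos_b``; unknown
    category labels or a same-chromosome translocation are hard errors
    naming the offending line.
    """
    try:
        table = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype=str,
            names=BEDPE_COLUMNS, usecols=range(11),
        )
    except pd.errors.EmptyDataError:
        return []
    events: list[SvEvent] = []
    for idx, row in enumerate(table.itertuples(index=False), start=1):
        try:
            category = normalize_sv_category(row.svtype)
            events.append(
                make_sv_event(
                    row.chrom1, int(row.start1) + 1,
                    row.chrom2, int(row.start2) + 1,
                    category, sample_id,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: bad BEDPE record at data line {idx}: {exc}") from exc
    return events


def write_sv_bedpe(events: Iterable[SvEvent], path: str) -> None:
    """Write events as 11-column BEDPE with 1 bp breakpoint intervals."""
    events = sorted(
        events,
        key=lambda e: (_chrom_rank(e.chrom_a), e.pos_a, _chrom_rank(e.chrom_b),
                       e.pos_b, e.category),
    )
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(BEDPE_COLUMNS) + "\n")
        for ev in events:
            fh.write(
                f"{ev.chrom_a}\t{ev.pos_a - 1}\t{ev.pos_a}\t"
                f"{ev.chrom_b}\t{ev.pos_b - 1}\t{ev.pos_b}\t"
                f".\t.\t+\t-\t{ev.category}\n"
            )


# ---------------------------------------------------------------------------
# Copy-number segments and ploidy
# ---------------------------------------------------------------------------

def read_cn_segments(
    path: str,
    sample_id: str,
    *,
    ploidy: Optional[SamplePloidy] = None,
    ploidy_path: Optional[str] = None,
) -> tuple[list[CnSegment], SamplePloidy]:
    """Read a tab-separated segment table (chrom, start, end, imean).

    The per-sample ploidy scalar is mandatory (rescaling needs it) and may
    come from, in order of precedence: the ``ploidy`` argument, a side-car
    table given by ``ploidy_path``, or ``#ploidy=`` header comment lines in
    the segment file itself.

    Segments are sorted; overlapping segments within the sample are treated
    as an input defect and resolved deterministically by truncating the
    earlier segment at the later segment's start (logged).
    """
    header_meta: dict[str, str] = {}
    rows: list[CnSegment] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        columns: Optional[dict[str, int]] = None
        for raw in reader:
            if not raw or not raw[0].strip():
                continue
            if raw[0].startswith("#"):
                text = raw[0].lstrip("#").strip()
                if "=" in text:
                    key, _, value = text.partition("=")
                    header_meta[key.strip()] = value.strip()
                continue
            if columns is None:
                columns = {name.strip(): i for i, name in enumerate(raw)}
                for required in ("chrom", "start", "end", "imean"):
                    if required not in columns:
                        raise ValueError(f"{path}: segment table lacks column {required!r}")
                continue
            imean_text = raw[columns["imean"]].strip() if len(raw) > columns["imean"] else ""
            imean = None if imean_text in ("", "NA", "nan", ".") else float(imean_text)
            rows.append(
                CnSegment(
                    chrom=raw[columns["chrom"]],
                    start=int(raw[columns["start"]]),
                    end=int(raw[columns["end"]]),
                    imean=imean,
                    sample_id=sample_id,
                )
            )
    if ploidy is None and ploidy_path is not None:
        table = read_ploidy_table(ploidy_path)
        if sample_id not in table:
            raise ValueError(f"{ploidy_path}: no ploidy entry for sample {sample_id!r}")
        ploidy = table[sample_id]
    if ploidy is None and "ploidy" in header_meta:
        ploidy = SamplePloidy(
            sample_id=sample_id,
            ploidy=float(header_meta["ploidy"]),
            normal_fraction=_opt_float(header_meta.get("normal_fraction")),
            tumour_fraction=_opt_float(header_meta.get("tumour_fraction")),
        )
    if ploidy is None:
        raise ValueError(
            f"{path}: no ploidy available for sample {sample_id!r}; "
            "supply a #ploidy= header line or a side-car ploidy table"
        )
    return _resolve_segment_overlaps(rows, path), ploidy


def _opt_float(text: Optional[str]) -> Optional[float]:
    return None if text in (None, "", "NA") else float(text)


def _resolve_segment_overlaps(segments: list[CnSegment], path: str) -> list[CnSegment]:
    segments = sorted(segments, key=lambda s: (_chrom_rank(s.chrom), s.start, s.end))
    resolved: list[CnSegment] = []
    for seg in segments:
        while resolved and resolved[-1].chrom == seg.chrom and resolved[-1].end > seg.start:
            prev = resolved.pop()
            logger.warning(
                "%s: overlapping segments %s:[%d,%d) and [%d,%d); truncating the earlier",
                path, seg.chrom, prev.start, prev.end, seg.start, seg.end,
            )
            if prev.start < seg.start:
                resolved.append(
                    CnSegment(prev.chrom, prev.start, seg.start, prev.imean, prev.sample_id)
                )
                break
        resolved.append(seg)
    return resolved


def write_cn_segments(
    segments: Iterable[CnSegment],
    ploidy: SamplePloidy,
    path: str,
) -> None:
    """Write a segment table with the ploidy embedded as header comments."""
    segments = sorted(segments, key=lambda s: (_chrom_rank(s.chrom), s.start))
    with open(path, "w") as fh:
        fh.write(f"#sample_id={ploidy.sample_id}\n")
        fh.write(f"#ploidy={ploidy.ploidy:.6f}\n")
        if ploidy.normal_fraction is not None:
            fh.write(f"#normal_fraction={ploidy.normal_fraction:.6f}\n")
        if ploidy.tumour_fraction is not None:
            fh.write(f"#tumour_fraction={ploidy.tumour_fraction:.6f}\n")
        fh.write("chrom\tstart\tend\timean\n")
        for seg in segments:
            imean = "NA" if seg.imean is None else f"{seg.imean:.6f}"
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{imean}\n")


def read_ploidy_table(path: str) -> dict[str, SamplePloidy]:
    """Read a side-car ploidy TSV: sample_id, ploidy[, normal/tumour fractions]."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in table.columns or "ploidy" not in table.columns:
        raise ValueError(f"{path}: ploidy table needs 'sample_id' and 'ploidy' columns")
    out: dict[str, SamplePloidy] = {}
    for row in table.itertuples(index=False):
        out[row.sample_id] = SamplePloidy(
            sample_id=row.sample_id,
            ploidy=float(row.ploidy),
            normal_fraction=_opt_float(getattr(row, "normal_fraction", None)),
            tumour_fraction=_opt_float(getattr(row, "tumour_fraction", None)),
        )
    return out


def write_ploidy_table(ploidies: Iterable[SamplePloidy], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tploidy\tnormal_fraction\ttumour_fraction\n")
        for p in sorted(ploidies, key=lambda p: p.sample_id):
            nf = "NA" if p.normal_fraction is None else f"{p.normal_fraction:.6f}"
            tf = "NA" if p.tumour_fraction is None else f"{p.tumour_fraction:.6f}"
            fh.write(f"{p.sample_id}\t{p.ploidy:.6f}\t{nf}\t{tf}\n")


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def read_manifest(path: str) -> list[SampleManifest]:
    """Read a YAML manifest grouping samples into patient pairs/trios.

    Relative file paths are resolved against the manifest's directory.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    base = os.path.dirname(os.path.abspath(path))
    manifests = []
    for entry in doc.get("patients", []):
        paths = {
            role: {
                kind: p if os.path.isabs(p) else os.path.join(base, p)
                for kind, p in kinds.items()
            }
            for role, kinds in (entry.get("paths") or {}).items()
        }
        manifests.append(
            SampleManifest(
                patient_id=entry["patient_id"],
                samples=dict(entry["samples"]),
                paths=paths,
                cohort=entry.get("cohort", "primary"),
            )
        )
    return manifests


def write_manifest(manifests: Iterable[SampleManifest], path: str) -> None:
    doc = {
        "patients": [
            {
                "patient_id": m.patient_id,
                "cohort": m.cohort,
                "samples": dict(m.samples),
                "paths": {role: dict(kinds) for role, kinds in m.paths.items()},
            }
            for m in manifests
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def _fmt(value: Optional[float]) -> str:
    return "NA" if value is None else f"{value:.6f}"


def write_report_tables(report, out_dir: str) -> list[str]:
    """Serialize a :class:`~concord.orchestrator.ConcordanceReport` to TSVs.

    Emits one matrix per statistic family with one column per sample pair
    (``TvsX``/``TvsO``/``XvsO``): mutation-type Jaccard (with an
    "All Mutations" row), per-chromosome SV Jaccard (with an ``Sc`` row),
    per-chromosome SV flags, genome-wide SV category Jaccard, and
    per-chromosome + genome copy-number concordance. Undefined scores are
    written as ``NA``.
    """
    os.makedirs(out_dir, exist_ok=True)
    pair_labels = list(report.pair_results)
    written: list[str] = []

    def _write(name: str, frame: pd.DataFrame) -> None:
        out = os.path.join(out_dir, name)
        frame.to_csv(out, sep="\t", index_label=frame.index.name)
        written.append(out)

    ssm_types: list[str] = []
    for res in report.pair_results.values():
        for row in res.ssm_rows or []:
            if row.mutation_type not in ssm_types:
                ssm_types.append(row.mutation_type)
    if any(res.ssm_rows is not None for res in report.pair_results.values()):
        index = sorted(ssm_types) + ["All Mutations"]
        frame = pd.DataFrame("NA", index=pd.Index(index, name="mutation_type"),
                             columns=pair_labels)
        for label, res in report.pair_results.items():
            for row in res.ssm_rows or []:
                frame.loc[row.mutation_type, label] = _fmt(row.jaccard)
            if res.ssm_all is not None:
                frame.loc["All Mutations", label] = _fmt(res.ssm_all.jaccard)
        _write("ssm_jaccard.tsv", frame)

    if any(res.sv_chrom_rows is not None for res in report.pair_results.values()):
        chroms = list(DEFAULT_CHROMOSOMES)
        frame = pd.DataFrame("NA", index=pd.Index(chroms + ["Sc"], name="chrom"),
                             columns=pair_labels)
        flags = pd.DataFrame("NA", index=pd.Index(chroms, name="chrom"),
                             columns=[f"{p}_{flag}" for p in pair_labels
                                      for flag in ("elevated", "discordant_count")])
        for label, res in report.pair_results.items():
            for row in res.sv_chrom_rows or []:
                if row.chrom in frame.index:
                    frame.loc[row.chrom, label] = _fmt(row.jaccard)
                    flags.loc[row.chrom, f"{label}_elevated"] = str(row.elevated)
                    flags.loc[row.chrom, f"{label}_discordant_count"] = str(row.discordant_count)
            if res.sv_overall is not None:
                frame.loc["Sc", label] = _fmt(res.sv_overall.score)
        _write("sv_chromosome_jaccard.tsv", frame)
        _write("sv_chromosome_flags.tsv", flags)

        frame = pd.DataFrame("NA", index=pd.Index(["DEL", "DUP", "INV", "TRA"],
                                                  name="category"),
                             columns=pair_labels)
        for label, res in report.pair_results.items():
            for row in res.sv_category_rows or []:
                if row.scope == "genome":
                    frame.loc[row.category, label] = _fmt(row.jaccard)
        _write("sv_category_jaccard.tsv", frame)

    if any(res.cn_genome is not None for res in report.pair_results.values()):
        chroms = list(DEFAULT_CHROMOSOMES)
        frame = pd.DataFrame("NA", index=pd.Index(chroms + ["genome"], name="chrom"),
                             columns=pair_labels)
        for label, res in report.pair_results.items():
            for conc in res.cn_by_chrom or []:
                if conc.scope in frame.index:
                    frame.loc[conc.scope, label] = _fmt(conc.score)
            if res.cn_genome is not None:
                frame.loc["genome", label] = _fmt(res.cn_genome.score)
        _write("cn_concordance.tsv", frame)

    return written
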