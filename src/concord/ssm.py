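"""Mutation-set concordance between a donor tumour and a matched model.

Two calls are the same mutation iff they share chromosome, position and the
exact ref/alt substitution; annotation category and read depths never enter
identity. For each annotation category M the Jaccard index is

    J_M = C_M / (T_M + P_M - C_M)

with T_M and P_M the per-sample call counts in category M and C_M the count
of identical calls present in both. A category absent from both samples has
no defined Jaccard and is reported as NA, never 0: absence of a mutation
class is not discordance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .model import VariantCall

ALL_MUTATIONS = "All Mutations"

#: Default driver-gene panel for pancreatic ductal adenocarcinoma
#: (hg19 gene spans, 1-based inclusive).
DEFAULT_DRIVER_PANEL: dict[str, tuple[str, int, int]] = {
    "KRAS": ("chr12", 25_358_180, 25_403_854),
    "TP53": ("chr17", 7_571_720, 7_590_868),
    "CDKN2A": ("chr9", 21_967_751, 21_995_300),
    "SMAD4": ("chr18", 48_556_583, 48_611_411),
    "TGFB2": ("chr1", 218_518_675, 218_617_961),
    "MAP2K4": ("chr17", 11_924_141, 12_047_147),
    "RNF43": ("chr17", 56_429_861, 56_494_956),
    "KDM6A": ("chrX", 44_732_423, 44_971_866),
}


@dataclass(frozen=True)
class SsmJaccardRow:
    """Per-category concordance: counts and the Jaccard index (None = NA)."""

    mutation_type: str
    t_count: int
    m_count: int
    shared: int
    jaccard: Optional[float]


def variant_identity_key(call: VariantCall) -> tuple[str, int, str, str]:
    """Identity key of a call: (chrom, pos, ref, alt)."""
    return (call.chrom, call.pos, call.ref, call.alt)


def _key_sets_by_type(calls: Iterable[VariantCall], snv_only: bool) -> dict[str, set]:
    sets: dict[str, set] = {}
    for call in calls:
        if snv_only and not (len(call.ref) == 1 and len(call.alt) == 1):
            continue
        sets.setdefault(call.mutation_type, set()).add(variant_identity_key(call))
    return sets


def _row(mutation_type: str, t_keys: set, m_keys: set) -> SsmJaccardRow:
    shared = len(t_keys & m_keys)
    union = len(t_keys | m_keys)
    return SsmJaccardRow(
        mutation_type=mutation_type,
        t_count=len(t_keys),
        m_count=len(m_keys),
        shared=shared,
        jaccard=None if union == 0 else shared / union,
    )


def jaccard_by_type(
    tumour_calls: Iterable[VariantCall],
    model_calls: Iterable[VariantCall],
    *,
    snv_only: bool = False,
) -> list[SsmJaccardRow]:
    """Jaccard index per annotation category, one row per category present
    in either sample (duplicate identity keys within a sample collapse first).
    """
    t_sets = _key_sets_by_type(tumour_calls, snv_only)
    m_sets = _key_sets_by_type(model_calls, snv_only)
    categories = sorted(set(t_sets) | set(m_sets))
    return [
        _row(cat, t_sets.get(cat, set()), m_sets.get(cat, set()))
        for cat in categories
    ]


def jaccard_all_mutations(
    tumour_calls: Iterable[VariantCall],
    model_calls: Iterable[VariantCall],
    *,
    snv_only: bool = False,
) -> SsmJaccardRow:
    """Overall Jaccard over the union of all categories ("All Mutations")."""
    t_sets = _key_sets_by_type(tumour_calls, snv_only)
    m_sets = _key_sets_by_type(model_calls, snv_only)
    t_all = set().union(*t_sets.values()) if t_sets else set()
    m_all = set().union(*m_sets.values()) if m_sets else set()
    return _row(ALL_MUTATIONS, t_all, m_all)


def variant_allele_fraction(call: VariantCall) -> Optional[float]:
    """VAF = alt/(alt+ref) read depth; None when depths are missing or zero.

    Descriptive only — no concordance score consumes it.
    """
    if call.ref_depth is None or call.alt_depth is None:
        return None
    total = call.ref_depth + call.alt_depth
    if total == 0:
        return None
    return call.alt_depth / total


def driver_panel_summary(
    calls_by_sample: Mapping[str, Iterable[VariantCall]],
    gene_panel: Optional[Mapping[str, tuple[str, int, int]]] = None,
) -> pd.DataFrame:
    """Gene x sample table of mutation-type labels hit within each gene span.

    Panel intervals are 1-based inclusive on both ends; cells hold sorted
    lists of the mutation_type labels of calls inside the span (empty list
    when none).
    """
    panel = DEFAULT_DRIVER_PANEL if gene_panel is None else dict(gene_panel)
    for gene, (chrom, start, end) in panel.items():
        if start < 1 or start > end:
            raise ValueError(f"malformed interval for gene {gene}: {chrom}:{start}-{end}")
    samples = list(calls_by_sample)
    table = pd.DataFrame(
        [[[] for _ in samples] for _ in panel],
        index=pd.Index(list(panel), name="gene"),
        columns=samples,
    )
    for sample, calls in calls_by_sample.items():
        for call in calls:
            for gene, (chrom, start, end) in panel.items():
                if call.chrom == chrom and start <= call.pos <= end:
                    table.loc[gene, sample].append(call.mutation_type)
    for gene in table.index:
        for sample in samples:
            table.loc[gene, sample].sort()
    return table
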