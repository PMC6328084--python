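"""Ploidy-corrected copy-number concordance.

Segment values (imean, the average integer copy number) are divided by the
sample's ploidy so that genome-doubled models remain comparable to their
donor tumour. The two samples' segmentations are then intersected into
maximal constant-value blocks and scored base-weighted:

    G = I / (T + X - C)

with T / X the bases where the tumour / model has a defined rescaled value,
C the bases where either does, and I the bases where both are defined and
differ by at most the tolerance (0.25 by default). By inclusion-exclusion
T + X - C is exactly the co-defined footprint, so G as written is agreement
over bases where both samples report a value; ``denominator="union"``
switches to the conventional union-Jaccard I / C.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

from .model import CnSegment, SamplePloidy

DEFAULT_CN_TOLERANCE = 0.25
#: Relative tolerance for calling two ploidies "the same" or "doubled".
DEFAULT_PLOIDY_REL_TOL = 0.1


@dataclass(frozen=True)
class CnOverlapBlock:
    """A maximal interval on which each sample's rescaled value is constant."""

    chrom: str
    start: int
    end: int
    value_a: Optional[float]
    value_b: Optional[float]
    agrees: bool

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CnConcordance:
    scope: str  # "genome" or a chromosome name
    t_bases: int
    m_bases: int
    union_bases: int
    agree_bases: int
    score: Optional[float]


def rescale_by_ploidy(
    segments: Iterable[CnSegment],
    ploidy: Union[SamplePloidy, float],
) -> list[CnSegment]:
    """Divide every defined imean by the sample ploidy; coordinates untouched."""
    value = ploidy.ploidy if isinstance(ploidy, SamplePloidy) else float(ploidy)
    if value <= 0:
        raise ValueError(f"ploidy must be positive, got {value}")
    return [
        CnSegment(
            chrom=seg.chrom,
            start=seg.start,
            end=seg.end,
            imean=None if seg.imean is None else seg.imean / value,
            sample_id=seg.sample_id,
        )
        for seg in segments
    ]


def intersect_segments(
    a_segments: Sequence[CnSegment],
    b_segments: Sequence[CnSegment],
    *,
    tolerance: float = DEFAULT_CN_TOLERANCE,
) -> list[CnOverlapBlock]:
    """Partition each chromosome into maximal constant-value blocks.

    Expects per-sample segmentations that are sorted and non-overlapping
    (the reader guarantees this). Intervals covered by neither sample are
    omitted, so total block length per chromosome equals the length of the
    union of the two footprints. Adjacent blocks with identical value pairs
    are merged.
    """
    by_chrom_a: dict[str, list[CnSegment]] = {}
    by_chrom_b: dict[str, list[CnSegment]] = {}
    for seg in a_segments:
        by_chrom_a.setdefault(seg.chrom, []).append(seg)
    for seg in b_segments:
        by_chrom_b.setdefault(seg.chrom, []).append(seg)
    blocks: list[CnOverlapBlock] = []
    for chrom in sorted(set(by_chrom_a) | set(by_chrom_b)):
        blocks.extend(
            _intersect_one_chrom(
                chrom,
                sorted(by_chrom_a.get(chrom, []), key=lambda s: s.start),
                sorted(by_chrom_b.get(chrom, []), key=lambda s: s.start),
                tolerance,
            )
        )
    return blocks


def _value_at(segments: Sequence[CnSegment], idx: int, pos: int):
    """(advanced index, covering?, value) for position ``pos``."""
    while idx < len(segments) and segments[idx].end <= pos:
        idx += 1
    if idx < len(segments) and segments[idx].start <= pos:
        return idx, True, segments[idx].imean
    return idx, False, None


def _intersect_one_chrom(
    chrom: str,
    a_segs: Sequence[CnSegment],
    b_segs: Sequence[CnSegment],
    tolerance: float,
) -> list[CnOverlapBlock]:
    bounds = sorted({x for seg in list(a_segs) + list(b_segs) for x in (seg.start, seg.end)})
    blocks: list[CnOverlapBlock] = []
    ia = ib = 0
    for start, end in zip(bounds, bounds[1:]):
        ia, a_cov, a_val = _value_at(a_segs, ia, start)
        ib, b_cov, b_val = _value_at(b_segs, ib, start)
        if not a_cov and not b_cov:
            continue
        agrees = (
            a_val is not None and b_val is not None and abs(a_val - b_val) <= tolerance
        )
        prev = blocks[-1] if blocks else None
        if (
            prev is not None
            and prev.end == start
            and prev.value_a == a_val
            and prev.value_b == b_val
        ):
            blocks[-1] = CnOverlapBlock(chrom, prev.start, end, a_val, b_val, agrees)
        else:
            blocks.append(CnOverlapBlock(chrom, start, end, a_val, b_val, agrees))
    return blocks


def cn_concordance(
    blocks: Iterable[CnOverlapBlock],
    *,
    tolerance: float = DEFAULT_CN_TOLERANCE,
    scope: str = "genome",
    denominator: str = "codefined",
) -> CnConcordance:
    """Base-weighted agreement score over overlap blocks.

    ``scope`` restricts to one chromosome ("genome" aggregates all).
    Agreement is recomputed from block values with this call's tolerance.
    """
    if denominator not in ("codefined", "union"):
        raise ValueError("denominator must be 'codefined' or 'union'")
    t = x = c = i = 0
    for block in blocks:
        if scope != "genome" and block.chrom != scope:
            continue
        n = block.length
        a_def = block.value_a is not None
        b_def = block.value_b is not None
        if a_def:
            t += n
        if b_def:
            x += n
        if a_def or b_def:
            c += n
        if a_def and b_def and abs(block.value_a - block.value_b) <= tolerance:
            i += n
    denom = (t + x - c) if denominator == "codefined" else c
    return CnConcordance(
        scope=scope,
        t_bases=t,
        m_bases=x,
        union_bases=c,
        agree_bases=i,
        score=None if denom == 0 else i / denom,
    )


def cn_concordance_by_chromosome(
    blocks: Sequence[CnOverlapBlock],
    *,
    tolerance: float = DEFAULT_CN_TOLERANCE,
    denominator: str = "codefined",
) -> list[CnConcordance]:
    """One :class:`CnConcordance` per chromosome carrying any block."""
    chroms = sorted({block.chrom for block in blocks})
    return [
        cn_concordance(blocks, tolerance=tolerance, scope=chrom, denominator=denominator)
        for chrom in chroms
    ]


def ploidy_qc(
    t_ploidy: Union[SamplePloidy, float],
    m_ploidy: Union[SamplePloidy, float],
    *,
    rel_tol: float = DEFAULT_PLOIDY_REL_TOL,
) -> str:
    """Classify a ploidy pair: "comparable", "doubled", or "ambiguous".

    "doubled" means the larger ploidy is within ``rel_tol`` of twice the
    smaller (whole-genome doubling in one member of the pair); "comparable"
    means the two agree within ``rel_tol``. Analysis proceeds on rescaled
    values regardless; the flag is reporting only.
    """
    t = t_ploidy.ploidy if isinstance(t_ploidy, SamplePloidy) else float(t_ploidy)
    m = m_ploidy.ploidy if isinstance(m_ploidy, SamplePloidy) else float(m_ploidy)
    ratio = max(t, m) / min(t, m)
    if abs(ratio - 1.0) <= rel_tol:
        return "comparable"
    if abs(ratio - 2.0) <= 2.0 * rel_tol:
        return "doubled"
    return "ambiguous"
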