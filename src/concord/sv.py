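"""Structural-variant concordance between matched samples.

Scores are size-weighted Jaccard indices over breakpoint-identical events.
Intra-chromosomal events (DEL/DUP/INV) weigh in with the genomic span
between their breakpoints; a translocation counts as 1 base total and, in
chromosome-scoped sums, contributes that unit size to each of the two
chromosomes it joins. Event *counts* follow a different rule: 1 per
intra-chromosomal event, 0.5 to each chromosome involved in a
translocation.

Per chromosome V:        J_V = C_V / (T_V + P_V - C_V)
Per category K:          J_K = C_K / (T_K + P_K - C_K)
Overall:                 S^c = P / (P + N)

where T/P/C are base sums (tumour, model, shared) and P/N count
event-bearing chromosomes with J_V >= 0.6 / < 0.6. Chromosomes bearing no
event in either sample have no defined J_V and never enter S^c.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .model import SV_CATEGORIES, SvEvent

#: J_V at or above this value marks a chromosome as concordant in S^c.
DEFAULT_JACCARD_THRESHOLD = 0.6
#: >= this many (weighted) events in BOTH samples flags a chromosome as
#: carrying clustered rearrangements (chromothripsis-suggestive).
DEFAULT_ELEVATED_MIN = 5.0
#: A weighted event-count difference >= this flags count discordance.
DEFAULT_DISCORDANT_DIFF = 10.0


@dataclass(frozen=True)
class ChromSvRow:
    chrom: str
    t_bases: float
    m_bases: float
    shared_bases: float
    jaccard: Optional[float]
    t_events: float
    m_events: float
    elevated: bool
    discordant_count: bool


@dataclass(frozen=True)
class CategoryJaccardRow:
    category: str
    scope: str  # "genome" or a chromosome name
    t_bases: float
    m_bases: float
    shared_bases: float
    jaccard: Optional[float]


@dataclass(frozen=True)
class OverallScore:
    positives: int
    negatives: int
    score: Optional[float]


def sv_event_size(event: SvEvent) -> float:
    """Bases spanned by the breakpoints; translocations are fixed at 1."""
    if event.is_translocation:
        return 1.0
    return float(event.pos_b - event.pos_a)


def sv_identity_key(event: SvEvent) -> tuple:
    """Breakpoints plus category; the sample of origin is not identity."""
    return (event.chrom_a, event.pos_a, event.chrom_b, event.pos_b, event.category)


def _dedupe(events: Iterable[SvEvent]) -> list[SvEvent]:
    seen: dict[tuple, SvEvent] = {}
    for ev in events:
        seen.setdefault(sv_identity_key(ev), ev)
    return sorted(seen.values(), key=sv_identity_key)


def count_events_per_chromosome(events: Iterable[SvEvent]) -> dict[str, float]:
    """Weighted per-chromosome event counts (intra = 1, TRA = 0.5 + 0.5)."""
    counts: dict[str, float] = {}
    for ev in events:
        if ev.is_translocation:
            counts[ev.chrom_a] = counts.get(ev.chrom_a, 0.0) + 0.5
            counts[ev.chrom_b] = counts.get(ev.chrom_b, 0.0) + 0.5
        else:
            counts[ev.chrom_a] = counts.get(ev.chrom_a, 0.0) + 1.0
    return counts


def flag_chromosomes(
    t_counts: Mapping[str, float],
    m_counts: Mapping[str, float],
    *,
    elevated_min: float = DEFAULT_ELEVATED_MIN,
    discordant_diff: float = DEFAULT_DISCORDANT_DIFF,
) -> dict[str, tuple[bool, bool]]:
    """Per chromosome: (elevated, discordant_count) flags from weighted counts.

    ``elevated`` needs >= ``elevated_min`` events in *both* samples;
    ``discordant_count`` needs an absolute count difference >=
    ``discordant_diff``.
    """
    out: dict[str, tuple[bool, bool]] = {}
    for chrom in set(t_counts) | set(m_counts):
        t = t_counts.get(chrom, 0.0)
        m = m_counts.get(chrom, 0.0)
        out[chrom] = (t >= elevated_min and m >= elevated_min,
                      abs(t - m) >= discordant_diff)
    return out


def match_sv_events(
    t_events: Sequence[SvEvent],
    m_events: Sequence[SvEvent],
    *,
    bp_tolerance: int = 0,
) -> list[tuple[SvEvent, SvEvent]]:
    """Pair up events sharing category and both breakpoint positions.

    With the default tolerance of 0, matching is exact identity on
    (chrom_a, pos_a, chrom_b, pos_b, category). A positive tolerance allows
    each breakpoint to differ by up to that many bases; pairing is then
    greedy in position order and each event matches at most once.
    Within-sample duplicate events collapse before matching.
    """
    t_events = _dedupe(t_events)
    m_events = _dedupe(m_events)
    if bp_tolerance == 0:
        m_by_key = {sv_identity_key(ev): ev for ev in m_events}
        return [
            (ev, m_by_key[sv_identity_key(ev)])
            for ev in t_events
            if sv_identity_key(ev) in m_by_key
        ]
    pairs: list[tuple[SvEvent, SvEvent]] = []
    used = [False] * len(m_events)
    for t_ev in t_events:
        for j, m_ev in enumerate(m_events):
            if used[j]:
                continue
            if (
                t_ev.category == m_ev.category
                and t_ev.chrom_a == m_ev.chrom_a
                and t_ev.chrom_b == m_ev.chrom_b
                and abs(t_ev.pos_a - m_ev.pos_a) <= bp_tolerance
                and abs(t_ev.pos_b - m_ev.pos_b) <= bp_tolerance
            ):
                pairs.append((t_ev, m_ev))
                used[j] = True
                break
    return pairs


def _chrom_base_sum(events: Iterable[SvEvent], chrom: str) -> float:
    """Sum of event sizes attributed to one chromosome (TRA adds 1 to each side)."""
    return sum(sv_event_size(ev) for ev in events if chrom in ev.chromosomes)


def chromosome_jaccard(
    t_events: Sequence[SvEvent],
    m_events: Sequence[SvEvent],
    chrom: str,
    *,
    bp_tolerance: int = 0,
    elevated_min: float = DEFAULT_ELEVATED_MIN,
    discordant_diff: float = DEFAULT_DISCORDANT_DIFF,
) -> ChromSvRow:
    """Size-weighted Jaccard and count flags for one chromosome."""
    t_events = _dedupe(t_events)
    m_events = _dedupe(m_events)
    matched = [t for t, _ in match_sv_events(t_events, m_events, bp_tolerance=bp_tolerance)]
    t_bases = _chrom_base_sum(t_events, chrom)
    m_bases = _chrom_base_sum(m_events, chrom)
    shared = _chrom_base_sum(matched, chrom)
    denom = t_bases + m_bases - shared
    t_count = count_events_per_chromosome(t_events).get(chrom, 0.0)
    m_count = count_events_per_chromosome(m_events).get(chrom, 0.0)
    return ChromSvRow(
        chrom=chrom,
        t_bases=t_bases,
        m_bases=m_bases,
        shared_bases=shared,
        jaccard=None if denom == 0 else shared / denom,
        t_events=t_count,
        m_events=m_count,
        elevated=t_count >= elevated_min and m_count >= elevated_min,
        discordant_count=abs(t_count - m_count) >= discordant_diff,
    )


def chromosome_jaccard_rows(
    t_events: Sequence[SvEvent],
    m_events: Sequence[SvEvent],
    *,
    chromosomes: Optional[Sequence[str]] = None,
    bp_tolerance: int = 0,
    elevated_min: float = DEFAULT_ELEVATED_MIN,
    discordant_diff: float = DEFAULT_DISCORDANT_DIFF,
) -> list[ChromSvRow]:
    """Rows for every chromosome in ``chromosomes`` (default: all observed)."""
    if chromosomes is None:
        observed: list[str] = []
        for ev in list(t_events) + list(m_events):
            for chrom in ev.chromosomes:
                if chrom not in observed:
                    observed.append(chrom)
        chromosomes = sorted(observed)
    return [
        chromosome_jaccard(
            t_events, m_events, chrom,
            bp_tolerance=bp_tolerance,
            elevated_min=elevated_min,
            discordant_diff=discordant_diff,
        )
        for chrom in chromosomes
    ]


def overall_concordance(
    chrom_rows: Iterable[ChromSvRow],
    *,
    threshold: float = DEFAULT_JACCARD_THRESHOLD,
) -> OverallScore:
    """S^c: fraction of event-bearing chromosomes with J_V >= threshold."""
    positives = negatives = 0
    for row in chrom_rows:
        if row.jaccard is None:
            continue
        if row.jaccard >= threshold:
            positives += 1
        else:
            negatives += 1
    total = positives + negatives
    return OverallScore(positives, negatives, None if total == 0 else positives / total)


def category_jaccard(
    t_events: Sequence[SvEvent],
    m_events: Sequence[SvEvent],
    scope: str = "genome",
    *,
    bp_tolerance: int = 0,
) -> list[CategoryJaccardRow]:
    """Size-weighted Jaccard per SV category, genome-wide or per chromosome.

    Genome scope counts each event's size once (a TRA is 1 base total);
    chromosome scope restricts to events touching that chromosome.
    Categories with no event in either sample are omitted.
    """
    t_events = _dedupe(t_events)
    m_events = _dedupe(m_events)
    matched = [t for t, _ in match_sv_events(t_events, m_events, bp_tolerance=bp_tolerance)]

    def base_sum(events: Iterable[SvEvent], category: str) -> float:
        selected = (ev for ev in events if ev.category == category)
        if scope == "genome":
            return sum(sv_event_size(ev) for ev in selected)
        return _chrom_base_sum(selected, scope)

    rows: list[CategoryJaccardRow] = []
    for category in SV_CATEGORIES:
        t_bases = base_sum(t_events, category)
        m_bases = base_sum(m_events, category)
        shared = base_sum(matched, category)
        denom = t_bases + m_bases - shared
        if t_bases + m_bases == 0:
            continue
        rows.append(
            CategoryJaccardRow(
                category=category,
                scope=scope,
                t_bases=t_bases,
                m_bases=m_bases,
                shared_bases=shared,
                jaccard=None if denom == 0 else shared / denom,
            )
        )
    return rows
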