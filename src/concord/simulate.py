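"""Synthetic matched tumour / PDX / PDO call sets with known ground truth.

Real donor-model cohorts of this kind live behind controlled access, so the
generator emulates their structure instead: a tumour and a model share a
controlled number of identical somatic calls, carry private calls of their
own, share (or not) structural variants per chromosome — including
chromosomes with clustered rearrangements confined to a 5 Mb window, the
pattern chromothripsis leaves — and carry segment copy-number profiles whose
raw values can differ by a whole-genome-doubling factor while remaining
identical after ploidy rescaling.

Every generated bundle ships a *truth record*: the expected value of each
concordance statistic computed at generation time by straight-line set and
sum arithmetic over the realized call sets, deliberately independent of the
scoring modules, so pipeline tests are genuine oracle comparisons.

The organoid of a trio is derived by perturbing the xenograft, not the
tumour — matching how PDOs are established from PDX tissue — so
xenograft-organoid concordance exceeds tumour-organoid concordance by
construction.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .io_formats import (
    write_cn_segments,
    write_manifest,
    write_ssm_vcf,
    write_sv_bedpe,
)
from .model import (
    CnSegment,
    SampleManifest,
    SamplePloidy,
    SvEvent,
    VariantCall,
    make_sv_event,
)

#: Toy genome: 22 autosomes + chrX + chrY with roughly human-scale lengths.
DEFAULT_GENOME: dict[str, int] = {
    "chr1": 249_000_000, "chr2": 243_000_000, "chr3": 198_000_000,
    "chr4": 191_000_000, "chr5": 181_000_000, "chr6": 171_000_000,
    "chr7": 159_000_000, "chr8": 146_000_000, "chr9": 141_000_000,
    "chr10": 136_000_000, "chr11": 135_000_000, "chr12": 134_000_000,
    "chr13": 115_000_000, "chr14": 107_000_000, "chr15": 103_000_000,
    "chr16": 90_000_000, "chr17": 81_000_000, "chr18": 78_000_000,
    "chr19": 59_000_000, "chr20": 63_000_000, "chr21": 48_000_000,
    "chr22": 51_000_000, "chrX": 155_000_000, "chrY": 59_000_000,
}

#: Default annotation-category vocabulary: 12 functional and non-functional
#: mutation classes with genome-realistic weights (most somatic calls land in
#: intergenic and intronic space).
DEFAULT_MUTATION_TYPE_WEIGHTS: dict[str, float] = {
    "IGR": 0.35,
    "Intron": 0.30,
    "lincRNA": 0.08,
    "RNA": 0.02,
    "3'UTR": 0.04,
    "5'UTR": 0.01,
    "5'Flank": 0.05,
    "Missense_Mutation": 0.06,
    "Silent": 0.04,
    "Nonsense_Mutation": 0.01,
    "Splice_Site": 0.01,
    "Frame_Shift_Del": 0.03,
}

_BASES = ("A", "C", "G", "T")
_CLUSTER_WINDOW = 5_000_000  # clustered events confined to this span


@dataclass
class SsmScenario:
    n_shared: int = 700
    n_tumour_only: int = 300
    n_model_only: int = 300
    category_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MUTATION_TYPE_WEIGHTS)
    )
    mean_depth: float = 60.0
    true_vaf: float = 0.35

    def __post_init__(self) -> None:
        if min(self.n_shared, self.n_tumour_only, self.n_model_only) < 0:
            raise ValueError("SSM counts must be nonnegative")
        total = sum(self.category_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category weights must sum to 1, got {total}")


@dataclass
class SvChromSpec:
    """Intra-chromosomal SV plan for one chromosome."""

    n_shared: int = 0
    n_tumour_only: int = 0
    n_model_only: int = 0
    category_mix: dict[str, float] = field(
        default_factory=lambda: {"DEL": 0.5, "DUP": 0.25, "INV": 0.25}
    )
    clustered: bool = False


@dataclass
class SvScenario:
    chrom_specs: dict[str, SvChromSpec] = field(default_factory=dict)
    # Translocations join two random chromosomes, so they are planned
    # genome-wide rather than per chromosome.
    tra_shared: int = 1
    tra_tumour_only: int = 1
    tra_model_only: int = 0


@dataclass
class CnScenario:
    segments_per_chrom: int = 8
    states: Sequence[float] = (1.0, 2.0, 3.0, 4.0)
    state_weights: Sequence[float] = (0.15, 0.55, 0.2, 0.1)
    ploidy_factor: float = 1.0       # model ploidy = tumour ploidy x this
    jitter_sd: float = 0.0           # sd of rescaled-value jitter on concordant segments
    discordant_fraction: float = 0.0
    missing_fraction: float = 0.0    # segments with no fitted value, per sample
    tolerance: float = 0.25          # agreement tolerance the jitter must respect


@dataclass
class PairScenario:
    genome: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENOME))
    ssm: SsmScenario = field(default_factory=SsmScenario)
    sv: SvScenario = field(default_factory=SvScenario)
    cn: CnScenario = field(default_factory=CnScenario)
    hypermutator: bool = False       # MMR-like: 10x the SSM load
    hypermutator_factor: int = 10


@dataclass
class TrioPerturbation:
    """How the organoid is derived from the xenograft."""

    ssm_drop_fraction: float = 0.1
    ssm_new: int = 100
    sv_drop_fraction: float = 0.15
    sv_new: int = 2
    cn_discordant_fraction: float = 0.1
    cn_ploidy_factor: float = 1.0


def default_trio_scenario() -> PairScenario:
    """The default study conditions for a simulated trio.

    700 shared / 300 tumour-only / 300 model-only mutations; one clustered
    SV chromosome (chr8) shared by both samples plus a handful of mixed
    chromosomes; copy-number with 30% discordant segments and a
    whole-genome-doubled model (ploidy factor 2).
    """
    return PairScenario(
        sv=SvScenario(
            chrom_specs={
                "chr1": SvChromSpec(n_shared=3, n_tumour_only=1, n_model_only=1),
                "chr4": SvChromSpec(n_shared=2, n_tumour_only=1, n_model_only=1),
                "chr8": SvChromSpec(n_shared=6, clustered=True),
                "chr17": SvChromSpec(n_shared=1, n_tumour_only=2),
            },
            tra_shared=1,
            tra_tumour_only=1,
        ),
        cn=CnScenario(ploidy_factor=2.0, discordant_fraction=0.3, jitter_sd=0.02),
    )


def _rng(seed_or_rng: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# Independent truth arithmetic (the generation-time oracle)
# ---------------------------------------------------------------------------

def _jaccard_counts(t_keys: set, m_keys: set) -> dict:
    shared = len(t_keys & m_keys)
    union = len(t_keys) + len(m_keys) - shared
    return {
        "t_count": len(t_keys),
        "m_count": len(m_keys),
        "shared": shared,
        "jaccard": None if union == 0 else shared / union,
    }


def truth_ssm(t_calls: Sequence[VariantCall], m_calls: Sequence[VariantCall]) -> dict:
    """Expected per-category and overall mutation Jaccard, by set arithmetic."""
    t_by_type: dict[str, set] = {}
    m_by_type: dict[str, set] = {}
    for calls, sets in ((t_calls, t_by_type), (m_calls, m_by_type)):
        for c in calls:
            sets.setdefault(c.mutation_type, set()).add((c.chrom, c.pos, c.ref, c.alt))
    by_type = {
        cat: _jaccard_counts(t_by_type.get(cat, set()), m_by_type.get(cat, set()))
        for cat in sorted(set(t_by_type) | set(m_by_type))
    }
    t_all = {(c.chrom, c.pos, c.ref, c.alt) for c in t_calls}
    m_all = {(c.chrom, c.pos, c.ref, c.alt) for c in m_calls}
    return {"by_type": by_type, "all": _jaccard_counts(t_all, m_all)}


def _sv_key(ev: SvEvent) -> tuple:
    return (ev.chrom_a, ev.pos_a, ev.chrom_b, ev.pos_b, ev.category)


def _sv_size(key: tuple) -> float:
    chrom_a, pos_a, chrom_b, pos_b, category = key
    return 1.0 if category == "TRA" else float(pos_b - pos_a)


def truth_sv(
    t_events: Sequence[SvEvent],
    m_events: Sequence[SvEvent],
    *,
    threshold: float = 0.6,
    elevated_min: float = 5.0,
    discordant_diff: float = 10.0,
) -> dict:
    """Expected SV statistics by direct sum arithmetic over breakpoint keys."""
    t_keys = {_sv_key(ev) for ev in t_events}
    m_keys = {_sv_key(ev) for ev in m_events}
    shared_keys = t_keys & m_keys

    def chrom_sum(keys: set, chrom: str) -> float:
        total = 0.0
        for key in keys:
            chrom_a, _, chrom_b, _, category = key
            if category == "TRA":
                if chrom in (chrom_a, chrom_b):
                    total += 1.0
            elif chrom_a == chrom:
                total += _sv_size(key)
        return total

    def weighted_counts(keys: set) -> dict[str, float]:
        counts: dict[str, float] = {}
        for chrom_a, _, chrom_b, _, category in keys:
            if category == "TRA":
                counts[chrom_a] = counts.get(chrom_a, 0.0) + 0.5
                counts[chrom_b] = counts.get(chrom_b, 0.0) + 0.5
            else:
                counts[chrom_a] = counts.get(chrom_a, 0.0) + 1.0
        return counts

    chroms = sorted(
        {k[0] for k in t_keys | m_keys} | {k[2] for k in t_keys | m_keys}
    )
    t_counts = weighted_counts(t_keys)
    m_counts = weighted_counts(m_keys)
    by_chrom: dict[str, dict] = {}
    positives = negatives = 0
    for chrom in chroms:
        t_b = chrom_sum(t_keys, chrom)
        m_b = chrom_sum(m_keys, chrom)
        c_b = chrom_sum(shared_keys, chrom)
        denom = t_b + m_b - c_b
        jaccard = None if denom == 0 else c_b / denom
        if jaccard is not None:
            if jaccard >= threshold:
                positives += 1
            else:
                negatives += 1
        t_n = t_counts.get(chrom, 0.0)
        m_n = m_counts.get(chrom, 0.0)
        by_chrom[chrom] = {
            "t_bases": t_b, "m_bases": m_b, "shared_bases": c_b,
            "jaccard": jaccard,
            "t_events": t_n, "m_events": m_n,
            "elevated": t_n >= elevated_min and m_n >= elevated_min,
            "discordant_count": abs(t_n - m_n) >= discordant_diff,
        }
    total = positives + negatives
    by_category: dict[str, dict] = {}
    for category in ("DEL", "DUP", "INV", "TRA"):
        t_b = sum(_sv_size(k) for k in t_keys if k[4] == category)
        m_b = sum(_sv_size(k) for k in m_keys if k[4] == category)
        c_b = sum(_sv_size(k) for k in shared_keys if k[4] == category)
        if t_b + m_b == 0:
            continue
        denom = t_b + m_b - c_b
        by_category[category] = {
            "t_bases": t_b, "m_bases": m_b, "shared_bases": c_b,
            "jaccard": None if denom == 0 else c_b / denom,
        }
    return {
        "by_chrom": by_chrom,
        "by_category": by_category,
        "overall": {
            "positives": positives,
            "negatives": negatives,
            "score": None if total == 0 else positives / total,
        },
    }


def truth_cn(
    a_segments: Sequence[CnSegment],
    a_ploidy: SamplePloidy,
    b_segments: Sequence[CnSegment],
    b_ploidy: SamplePloidy,
    *,
    tolerance: float = 0.25,
) -> dict:
    """Expected G and per-chromosome G for two samples sharing one
    segmentation template (segment-aligned base arithmetic)."""
    a_sorted = sorted(a_segments, key=lambda s: (s.chrom, s.start))
    b_sorted = sorted(b_segments, key=lambda s: (s.chrom, s.start))
    if [(s.chrom, s.start, s.end) for s in a_sorted] != [
        (s.chrom, s.start, s.end) for s in b_sorted
    ]:
        raise ValueError("truth_cn requires segment-aligned samples")
    per_chrom: dict[str, dict[str, int]] = {}
    for sa, sb in zip(a_sorted, b_sorted):
        acc = per_chrom.setdefault(sa.chrom, {"t": 0, "x": 0, "c": 0, "i": 0})
        n = sa.end - sa.start
        va = None if sa.imean is None else sa.imean / a_ploidy.ploidy
        vb = None if sb.imean is None else sb.imean / b_ploidy.ploidy
        if va is not None:
            acc["t"] += n
        if vb is not None:
            acc["x"] += n
        if va is not None or vb is not None:
            acc["c"] += n
        if va is not None and vb is not None and abs(va - vb) <= tolerance:
            acc["i"] += n

    def score(acc: dict[str, int]) -> Optional[float]:
        denom = acc["t"] + acc["x"] - acc["c"]
        return None if denom == 0 else acc["i"] / denom

    genome = {"t": 0, "x": 0, "c": 0, "i": 0}
    for acc in per_chrom.values():
        for key in genome:
            genome[key] += acc[key]
    return {
        "by_chrom": {chrom: score(acc) for chrom, acc in sorted(per_chrom.items())},
        "genome": score(genome),
    }


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _draw_distinct_sites(
    genome: dict[str, int],
    n: int,
    rng: np.random.Generator,
    taken: Optional[set] = None,
) -> list[tuple[str, int]]:
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    sites: list[tuple[str, int]] = []
    seen = set(taken or ())
    attempts = 0
    while len(sites) < n:
        attempts += 1
        if attempts > 50 * n + 1000:
            raise ValueError("genome too small to host the requested distinct sites")
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        pos = int(rng.integers(1, genome[chrom] + 1))
        if (chrom, pos) in seen:
            continue
        seen.add((chrom, pos))
        sites.append((chrom, pos))
    return sites


def _draw_alleles(category: str, rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(0, 4)]
    if category == "Frame_Shift_Del":
        extra = "".join(_BASES[rng.integers(0, 4)] for _ in range(int(rng.integers(1, 4))))
        return ref + extra, ref
    alt = _BASES[rng.integers(0, 4)]
    while alt == ref:
        alt = _BASES[rng.integers(0, 4)]
    return ref, alt


def _with_depths(
    call: VariantCall, scenario: SsmScenario, rng: np.random.Generator
) -> VariantCall:
    depth = max(10, int(rng.poisson(scenario.mean_depth)))
    alt_depth = int(rng.binomial(depth, scenario.true_vaf))
    return VariantCall(
        chrom=call.chrom, pos=call.pos, ref=call.ref, alt=call.alt,
        mutation_type=call.mutation_type,
        ref_depth=depth - alt_depth, alt_depth=alt_depth,
        sample_id=call.sample_id,
    )


def simulate_pair_ssm(
    scenario: PairScenario,
    seed_or_rng: Union[int, np.random.Generator],
    tumour_id: str = "TUMOUR",
    model_id: str = "MODEL",
) -> tuple[list[VariantCall], list[VariantCall], dict]:
    """Matched mutation call sets with an exact shared/private breakdown."""
    rng = _rng(seed_or_rng)
    spec = scenario.ssm
    factor = scenario.hypermutator_factor if scenario.hypermutator else 1
    n_shared = spec.n_shared * factor
    n_t = spec.n_tumour_only * factor
    n_m = spec.n_model_only * factor
    sites = _draw_distinct_sites(scenario.genome, n_shared + n_t + n_m, rng)
    categories = list(spec.category_weights)
    weights = np.array([spec.category_weights[c] for c in categories])
    drawn = [categories[i] for i in rng.choice(len(categories), size=len(sites), p=weights)]
    templates = []
    for (chrom, pos), category in zip(sites, drawn):
        ref, alt = _draw_alleles(category, rng)
        templates.append(VariantCall(chrom, pos, ref, alt, category))
    shared = templates[:n_shared]
    t_only = templates[n_shared:n_shared + n_t]
    m_only = templates[n_shared + n_t:]

    def realize(template: VariantCall, sample_id: str) -> VariantCall:
        stamped = VariantCall(
            template.chrom, template.pos, template.ref, template.alt,
            template.mutation_type, sample_id=sample_id,
        )
        return _with_depths(stamped, spec, rng)

    t_calls = [realize(c, tumour_id) for c in shared + t_only]
    m_calls = [realize(c, model_id) for c in shared + m_only]
    return t_calls, m_calls, truth_ssm(t_calls, m_calls)


def _draw_intra_event(
    chrom: str,
    length: int,
    spec: SvChromSpec,
    rng: np.random.Generator,
    sample_id: str,
    window: Optional[tuple[int, int]],
) -> SvEvent:
    categories = list(spec.category_mix)
    weights = np.array([spec.category_mix[c] for c in categories], dtype=float)
    weights = weights / weights.sum()
    category = categories[rng.choice(len(categories), p=weights)]
    if window is not None:
        lo, hi = window
        pos_a = int(rng.integers(lo, hi - 50_000))
        pos_b = int(rng.integers(pos_a + 10_000, hi + 1))
    else:
        size = int(10 ** rng.uniform(4, np.log10(min(5_000_000, length // 4))))
        pos_a = int(rng.integers(1, length - size))
        pos_b = pos_a + size
    return make_sv_event(chrom, pos_a, chrom, pos_b, category, sample_id)


def simulate_pair_sv(
    scenario: PairScenario,
    seed_or_rng: Union[int, np.random.Generator],
    tumour_id: str = "TUMOUR",
    model_id: str = "MODEL",
) -> tuple[list[SvEvent], list[SvEvent], dict]:
    """Matched SV call sets.

    Shared events carry identical breakpoints in both samples. On
    chromosomes flagged ``clustered`` every event is confined to one 5 Mb
    window, so a clustered chromosome with >= 5 shared events is guaranteed
    to raise the elevated flag with a high per-chromosome Jaccard.
    """
    rng = _rng(seed_or_rng)
    sv_spec = scenario.sv
    t_events: list[SvEvent] = []
    m_events: list[SvEvent] = []
    seen: set = set()

    def add_events(chrom: str, spec: SvChromSpec, count: int, targets: list[list[SvEvent]],
                   window: Optional[tuple[int, int]]) -> None:
        length = scenario.genome[chrom]
        for _ in range(count):
            for _attempt in range(1000):
                ev = _draw_intra_event(chrom, length, spec, rng, "", window)
                if _sv_key(ev) not in seen:
                    seen.add(_sv_key(ev))
                    break
            else:
                raise ValueError(f"cannot place distinct SV events on {chrom}")
            for target, sample_id in zip(targets, (tumour_id, model_id)):
                target.append(
                    SvEvent(ev.chrom_a, ev.pos_a, ev.chrom_b, ev.pos_b,
                            ev.category, sample_id)
                )

    for chrom, spec in sv_spec.chrom_specs.items():
        if chrom not in scenario.genome:
            raise ValueError(f"SV scenario references unknown chromosome {chrom}")
        window = None
        if spec.clustered:
            start = int(rng.integers(1, scenario.genome[chrom] - _CLUSTER_WINDOW))
            window = (start, start + _CLUSTER_WINDOW)
        add_events(chrom, spec, spec.n_shared, [t_events, m_events], window)
        add_events(chrom, spec, spec.n_tumour_only, [t_events], window)
        add_events(chrom, spec, spec.n_model_only, [m_events], window)

    chroms = list(scenario.genome)

    def add_tra(count: int, targets: list[list[SvEvent]]) -> None:
        for _ in range(count):
            for _attempt in range(1000):
                ca, cb = rng.choice(len(chroms), size=2, replace=False)
                ev = make_sv_event(
                    chroms[ca], int(rng.integers(1, scenario.genome[chroms[ca]] + 1)),
                    chroms[cb], int(rng.integers(1, scenario.genome[chroms[cb]] + 1)),
                    "TRA",
                )
                if _sv_key(ev) not in seen:
                    seen.add(_sv_key(ev))
                    break
            else:
                raise ValueError("cannot place distinct translocations")
            for target, sample_id in zip(targets, (tumour_id, model_id)):
                target.append(
                    SvEvent(ev.chrom_a, ev.pos_a, ev.chrom_b, ev.pos_b,
                            ev.category, sample_id)
                )

    add_tra(sv_spec.tra_shared, [t_events, m_events])
    add_tra(sv_spec.tra_tumour_only, [t_events])
    add_tra(sv_spec.tra_model_only, [m_events])
    return t_events, m_events, truth_sv(t_events, m_events)


def simulate_pair_cn(
    scenario: PairScenario,
    seed_or_rng: Union[int, np.random.Generator],
    tumour_id: str = "TUMOUR",
    model_id: str = "MODEL",
) -> tuple[
    tuple[list[CnSegment], SamplePloidy],
    tuple[list[CnSegment], SamplePloidy],
    dict,
]:
    """Matched copy-number profiles sharing one segmentation template.

    The model's raw values equal the tumour's times ``ploidy_factor`` on
    concordant segments (plus jitter bounded by tolerance/2 in rescaled
    space), and are pushed beyond the tolerance on the designated
    discordant fraction; ploidies are set so rescaled concordant segments
    agree regardless of the factor.
    """
    rng = _rng(seed_or_rng)
    spec = scenario.cn
    if spec.jitter_sd > spec.tolerance / 4:
        raise ValueError(
            f"jitter_sd {spec.jitter_sd} too large to guarantee agreement "
            f"within tolerance {spec.tolerance}"
        )
    states = np.asarray(spec.states, dtype=float)
    state_w = np.asarray(spec.state_weights, dtype=float)
    state_w = state_w / state_w.sum()

    template: list[tuple[str, int, int]] = []
    t_values: list[float] = []
    for chrom, length in scenario.genome.items():
        cuts = np.sort(rng.choice(
            np.arange(1, length, 10_000), size=spec.segments_per_chrom - 1, replace=False,
        ))
        bounds = [0, *[int(c) for c in cuts], length]
        for start, end in zip(bounds, bounds[1:]):
            template.append((chrom, start, end))
            t_values.append(float(states[rng.choice(len(states), p=state_w)]))

    lengths = np.array([end - start for _, start, end in template], dtype=float)
    t_ploidy_value = float(np.average(t_values, weights=lengths))
    m_ploidy_value = t_ploidy_value * spec.ploidy_factor

    n_seg = len(template)
    n_discordant = int(round(spec.discordant_fraction * n_seg))
    discordant_idx = set(
        int(i) for i in rng.choice(n_seg, size=n_discordant, replace=False)
    )
    n_missing = int(round(spec.missing_fraction * n_seg))
    t_missing = {int(i) for i in rng.choice(n_seg, size=n_missing, replace=False)}
    m_missing = {int(i) for i in rng.choice(n_seg, size=n_missing, replace=False)}

    t_segments: list[CnSegment] = []
    m_segments: list[CnSegment] = []
    for idx, ((chrom, start, end), t_raw) in enumerate(zip(template, t_values)):
        rescaled_t = t_raw / t_ploidy_value
        if idx in discordant_idx:
            offset = 2.0 * spec.tolerance
            if rescaled_t >= offset and rng.random() < 0.5:
                offset = -offset
            rescaled_m = rescaled_t + offset
        else:
            jitter = float(rng.normal(0.0, spec.jitter_sd)) if spec.jitter_sd else 0.0
            jitter = float(np.clip(jitter, -spec.tolerance / 2, spec.tolerance / 2))
            rescaled_m = rescaled_t + jitter
        t_segments.append(
            CnSegment(chrom, start, end,
                      None if idx in t_missing else t_raw, tumour_id)
        )
        m_segments.append(
            CnSegment(chrom, start, end,
                      None if idx in m_missing else rescaled_m * m_ploidy_value,
                      model_id)
        )
    t_ploidy = SamplePloidy(tumour_id, t_ploidy_value)
    m_ploidy = SamplePloidy(model_id, m_ploidy_value)
    truth = truth_cn(t_segments, t_ploidy, m_segments, m_ploidy,
                     tolerance=spec.tolerance)
    return (t_segments, t_ploidy), (m_segments, m_ploidy), truth


# ---------------------------------------------------------------------------
# Trios
# ---------------------------------------------------------------------------

@dataclass
class SampleBundle:
    sample_id: str
    ssm: list[VariantCall]
    sv: list[SvEvent]
    cn_segments: list[CnSegment]
    ploidy: SamplePloidy


@dataclass
class TrioBundle:
    patient_id: str
    samples: dict[str, SampleBundle]  # role -> bundle
    truth: dict                       # pair label -> {"ssm", "sv", "cn"}


def simulate_trio(
    scenario: Optional[PairScenario] = None,
    seed: int = 0,
    perturbation: Optional[TrioPerturbation] = None,
    patient_id: str = "SIM_TRIO",
) -> TrioBundle:
    """Simulate a matched tumour / PDX / PDO trio.

    The tumour-PDX pair follows ``scenario``; the PDO is then derived by
    perturbing the PDX (dropping a fraction of its calls and adding fresh
    private ones), so PDX-PDO concordance exceeds tumour-PDO concordance.
    The truth record holds the expected statistics for all three pairs.
    """
    scenario = scenario or default_trio_scenario()
    perturbation = perturbation or TrioPerturbation()
    rng = np.random.default_rng(seed)
    t_id, x_id, o_id = (f"{patient_id}_T", f"{patient_id}_X", f"{patient_id}_O")

    t_ssm, x_ssm, _ = simulate_pair_ssm(scenario, rng, t_id, x_id)
    t_sv, x_sv, _ = simulate_pair_sv(scenario, rng, t_id, x_id)
    (t_cn, t_ploidy), (x_cn, x_ploidy), _ = simulate_pair_cn(scenario, rng, t_id, x_id)

    # Organoid mutations: keep most of the xenograft's, add fresh privates.
    n_drop = int(round(perturbation.ssm_drop_fraction * len(x_ssm)))
    keep = np.ones(len(x_ssm), dtype=bool)
    if n_drop:
        keep[rng.choice(len(x_ssm), size=n_drop, replace=False)] = False
    existing_sites = {(c.chrom, c.pos) for c in t_ssm} | {(c.chrom, c.pos) for c in x_ssm}
    new_sites = _draw_distinct_sites(scenario.genome, perturbation.ssm_new, rng,
                                     taken=existing_sites)
    categories = list(scenario.ssm.category_weights)
    weights = np.array([scenario.ssm.category_weights[c] for c in categories])
    o_ssm = [
        VariantCall(c.chrom, c.pos, c.ref, c.alt, c.mutation_type,
                    c.ref_depth, c.alt_depth, o_id)
        for c, kept in zip(x_ssm, keep) if kept
    ]
    for chrom, pos in new_sites:
        category = categories[rng.choice(len(categories), p=weights)]
        ref, alt = _draw_alleles(category, rng)
        o_ssm.append(_with_depths(
            VariantCall(chrom, pos, ref, alt, category, sample_id=o_id),
            scenario.ssm, rng,
        ))

    # Organoid SVs: same recipe.
    n_drop = int(round(perturbation.sv_drop_fraction * len(x_sv)))
    keep = np.ones(len(x_sv), dtype=bool)
    if n_drop:
        keep[rng.choice(len(x_sv), size=n_drop, replace=False)] = False
    o_sv = [
        SvEvent(e.chrom_a, e.pos_a, e.chrom_b, e.pos_b, e.category, o_id)
        for e, kept in zip(x_sv, keep) if kept
    ]
    seen = {_sv_key(e) for e in t_sv} | {_sv_key(e) for e in x_sv}
    chroms = list(scenario.genome)
    spec = SvChromSpec()
    for _ in range(perturbation.sv_new):
        for _attempt in range(1000):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            ev = _draw_intra_event(chrom, scenario.genome[chrom], spec, rng, o_id, None)
            if _sv_key(ev) not in seen:
                seen.add(_sv_key(ev))
                o_sv.append(ev)
                break
        else:
            raise ValueError("cannot place distinct organoid SV events")

    # Organoid copy number: the xenograft's profile with a fraction of
    # segments pushed out of tolerance (in rescaled space).
    tol = scenario.cn.tolerance
    o_ploidy = SamplePloidy(o_id, x_ploidy.ploidy * perturbation.cn_ploidy_factor)
    n_seg = len(x_cn)
    n_disc = int(round(perturbation.cn_discordant_fraction * n_seg))
    disc_idx = set(int(i) for i in rng.choice(n_seg, size=n_disc, replace=False))
    o_cn: list[CnSegment] = []
    for idx, seg in enumerate(x_cn):
        if seg.imean is None:
            o_cn.append(CnSegment(seg.chrom, seg.start, seg.end, None, o_id))
            continue
        rescaled_x = seg.imean / x_ploidy.ploidy
        if idx in disc_idx:
            offset = 2.0 * tol
            if rescaled_x >= offset and rng.random() < 0.5:
                offset = -offset
            rescaled_o = rescaled_x + offset
        else:
            rescaled_o = rescaled_x
        o_cn.append(
            CnSegment(seg.chrom, seg.start, seg.end,
                      rescaled_o * o_ploidy.ploidy, o_id)
        )

    samples = {
        "tumour": SampleBundle(t_id, t_ssm, t_sv, t_cn, t_ploidy),
        "pdx": SampleBundle(x_id, x_ssm, x_sv, x_cn, x_ploidy),
        "pdo": SampleBundle(o_id, o_ssm, o_sv, o_cn, o_ploidy),
    }
    pairs = {"TvsX": ("tumour", "pdx"), "TvsO": ("tumour", "pdo"),
             "XvsO": ("pdx", "pdo")}
    truth = {}
    for label, (role_a, role_b) in pairs.items():
        a, b = samples[role_a], samples[role_b]
        truth[label] = {
            "ssm": truth_ssm(a.ssm, b.ssm),
            "sv": truth_sv(a.sv, b.sv),
            "cn": truth_cn(a.cn_segments, a.ploidy, b.cn_segments, b.ploidy,
                           tolerance=tol),
        }
    return TrioBundle(patient_id=patient_id, samples=samples, truth=truth)


def write_trio(bundle: TrioBundle, out_dir: str) -> str:
    """Write a trio's files + manifest + truth record; returns manifest path.

    Emitted per sample: a single-sample VCF, an SV BEDPE, and a segment
    table with the ploidy embedded in its header. File paths in the
    manifest are relative to ``out_dir``.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, dict[str, str]] = {}
    for role, sample in bundle.samples.items():
        prefix = sample.sample_id
        ssm_name = f"{prefix}.ssm.vcf"
        sv_name = f"{prefix}.sv.bedpe"
        cn_name = f"{prefix}.cn.seg"
        write_ssm_vcf(sample.ssm, os.path.join(out_dir, ssm_name), sample.sample_id)
        write_sv_bedpe(sample.sv, os.path.join(out_dir, sv_name))
        write_cn_segments(sample.cn_segments, sample.ploidy,
                          os.path.join(out_dir, cn_name))
        paths[role] = {"ssm": ssm_name, "sv": sv_name, "cn": cn_name}
    manifest = SampleManifest(
        patient_id=bundle.patient_id,
        samples={role: s.sample_id for role, s in bundle.samples.items()},
        paths=paths,
    )
    manifest_path = os.path.join(out_dir, "manifest.yaml")
    write_manifest([manifest], manifest_path)
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(bundle.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest_path
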