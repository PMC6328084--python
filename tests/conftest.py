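"""Shared fixtures: factories for random matched call sets.

The random generators deliberately use tiny coordinate domains so that two
independently drawn samples share events by chance — the regime where set
statistics are actually exercised.
"""

from __future__ import annotations

import numpy as np
import pytest

from concord.model import CnSegment, SvEvent, VariantCall, make_sv_event

BASES = ("A", "C", "G", "T")
CATEGORIES = ("Missense_Mutation", "Silent", "Intron", "lincRNA")


def _random_call(rng: np.random.Generator, sample_id: str) -> VariantCall:
    chrom = f"chr{int(rng.integers(1, 4))}"
    pos = int(rng.integers(1, 200))
    ref = BASES[rng.integers(0, 4)]
    alt = BASES[rng.integers(0, 4)]
    while alt == ref:
        alt = BASES[rng.integers(0, 4)]
    return VariantCall(
        chrom, pos, ref, alt,
        mutation_type=CATEGORIES[rng.integers(0, len(CATEGORIES))],
        sample_id=sample_id,
    )


@pytest.fixture
def random_ssm_pair():
    """Factory: seeded pair of call lists over a tiny shared site domain."""

    def make(seed: int, max_calls: int = 100):
        rng = np.random.default_rng(seed)
        pool = [_random_call(rng, "") for _ in range(int(rng.integers(5, max_calls)))]
        t_n = int(rng.integers(0, max_calls))
        m_n = int(rng.integers(0, max_calls))
        t_calls = [pool[i] for i in rng.integers(0, len(pool), size=t_n)]
        m_calls = [pool[i] for i in rng.integers(0, len(pool), size=m_n)]
        return t_calls, m_calls

    return make


def _random_event(rng: np.random.Generator) -> SvEvent:
    chroms = ["chr1", "chr2", "chr3", "chr4"]
    if rng.random() < 0.25:
        ca, cb = rng.choice(len(chroms), size=2, replace=False)
        return make_sv_event(
            chroms[ca], int(rng.integers(1, 1000)),
            chroms[cb], int(rng.integers(1, 1000)),
            "TRA",
        )
    chrom = chroms[int(rng.integers(0, len(chroms)))]
    pos_a = int(rng.integers(1, 900))
    pos_b = pos_a + int(rng.integers(1, 100))
    category = ("DEL", "DUP", "INV")[rng.integers(0, 3)]
    return make_sv_event(chrom, pos_a, chrom, pos_b, category)


@pytest.fixture
def random_sv_pair():
    """Factory: seeded pair of SV event lists with chance-shared events."""

    def make(seed: int, max_events: int = 30):
        rng = np.random.default_rng(seed)
        pool = [_random_event(rng) for _ in range(int(rng.integers(3, max_events)))]
        t_n = int(rng.integers(0, max_events))
        m_n = int(rng.integers(0, max_events))
        t_events = [pool[i] for i in rng.integers(0, len(pool), size=t_n)]
        m_events = [pool[i] for i in rng.integers(0, len(pool), size=m_n)]
        return t_events, m_events

    return make


@pytest.fixture
def random_cn_pair():
    """Factory: seeded pair of segmentations over a 10 kb two-chromosome genome.

    Each sample covers random sub-intervals (gaps allowed), occasionally with
    a missing value; values sit on a grid straddling the 0.25 tolerance.
    """

    genome = {"chrA": 10_000, "chrB": 8_000}

    def make(seed: int):
        rng = np.random.default_rng(seed)

        def one_sample(sample_id: str) -> list[CnSegment]:
            segments = []
            for chrom, length in genome.items():
                n_cuts = int(rng.integers(2, 8))
                cuts = sorted(set(rng.integers(1, length, size=n_cuts).tolist()))
                bounds = [0, *cuts, length]
                for start, end in zip(bounds, bounds[1:]):
                    if start >= end or rng.random() < 0.2:  # leave gaps
                        continue
                    if rng.random() < 0.1:
                        value = None  # covered but unfitted
                    else:
                        value = float(rng.choice([0.5, 0.75, 0.9, 1.0, 1.1, 1.3, 2.0]))
                    segments.append(CnSegment(chrom, start, end, value, sample_id))
            return segments

        return one_sample("A"), one_sample("B")

    make.genome = genome
    return make
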