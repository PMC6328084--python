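"""Copy-number concordance: rescaling, interval partition, G statistics."""

import numpy as np
import pytest

from concord.cnv import (
    cn_concordance,
    cn_concordance_by_chromosome,
    intersect_segments,
    ploidy_qc,
    rescale_by_ploidy,
)
from concord.model import CnSegment, SamplePloidy


def seg(chrom, start, end, imean, sample=""):
    return CnSegment(chrom, start, end, imean, sample)


def per_base_concordance(a_segments, b_segments, genome, tolerance=0.25):
    """Independent oracle: literal per-base scan over value arrays."""
    scores = {}
    totals = {"t": 0, "x": 0, "c": 0, "i": 0}
    for chrom, length in genome.items():
        a = np.full(length, np.nan)
        b = np.full(length, np.nan)
        a_cov = np.zeros(length, dtype=bool)
        b_cov = np.zeros(length, dtype=bool)
        for s in a_segments:
            if s.chrom == chrom:
                a_cov[s.start:s.end] = True
                if s.imean is not None:
                    a[s.start:s.end] = s.imean
        for s in b_segments:
            if s.chrom == chrom:
                b_cov[s.start:s.end] = True
                if s.imean is not None:
                    b[s.start:s.end] = s.imean
        a_def = ~np.isnan(a)
        b_def = ~np.isnan(b)
        t = int(a_def.sum())
        x = int(b_def.sum())
        c = int((a_def | b_def).sum())
        both = a_def & b_def
        i = int((both & (np.abs(np.where(both, a - b, np.inf)) <= tolerance)).sum())
        denom = t + x - c
        scores[chrom] = None if denom == 0 else i / denom
        for key, val in zip(("t", "x", "c", "i"), (t, x, c, i)):
            totals[key] += val
    denom = totals["t"] + totals["x"] - totals["c"]
    genome_score = None if denom == 0 else totals["i"] / denom
    return genome_score, scores


class TestRescale:
    def test_division(self):
        (out,) = rescale_by_ploidy([seg("chr1", 0, 10, 4.0)], 3.8)
        assert out.imean == pytest.approx(4.0 / 3.8)

    def test_missing_stays_missing(self):
        (out,) = rescale_by_ploidy([seg("chr1", 0, 10, None)], 2.0)
        assert out.imean is None

    def test_coordinates_untouched(self):
        (out,) = rescale_by_ploidy([seg("chr1", 5, 10, 2.0)], 2.0)
        assert (out.start, out.end, out.imean) == (5, 10, 1.0)

    def test_nonpositive_ploidy_rejected(self):
        with pytest.raises(ValueError):
            rescale_by_ploidy([seg("chr1", 0, 10, 2.0)], 0.0)


class TestIntersect:
    def test_partial_overlap_partition(self):
        blocks = intersect_segments(
            [seg("chr1", 0, 100, 1.0)], [seg("chr1", 50, 150, 1.0)]
        )
        spans = [(b.start, b.end, b.value_a, b.value_b) for b in blocks]
        assert spans == [(0, 50, 1.0, None), (50, 100, 1.0, 1.0),
                         (100, 150, None, 1.0)]

    def test_identical_segmentations_reproduce_inputs(self):
        segments = [seg("chr1", 0, 100, 1.0), seg("chr1", 100, 300, 2.0)]
        blocks = intersect_segments(segments, segments)
        assert [(b.start, b.end) for b in blocks] == [(0, 100), (100, 300)]
        assert all(b.agrees for b in blocks)

    def test_uncovered_gap_omitted(self):
        blocks = intersect_segments(
            [seg("chr1", 0, 10, 1.0), seg("chr1", 90, 100, 1.0)],
            [seg("chr1", 0, 10, 1.0)],
        )
        assert sum(b.length for b in blocks) == 20

    def test_footprint_conserved(self, random_cn_pair):
        a, b = random_cn_pair(seed=5)
        blocks = intersect_segments(a, b)
        for chrom in random_cn_pair.genome:
            covered = np.zeros(random_cn_pair.genome[chrom], dtype=bool)
            for s in a + b:
                if s.chrom == chrom:
                    covered[s.start:s.end] = True
            block_len = sum(bl.length for bl in blocks if bl.chrom == chrom)
            assert block_len == int(covered.sum())


class TestConcordance:
    def test_identical_profiles_give_one(self):
        segments = [seg("chr1", 0, 1_000_000, 1.0)]
        blocks = intersect_segments(segments, segments)
        assert cn_concordance(blocks).score == 1.0

    def test_difference_beyond_tolerance_gives_zero(self):
        blocks = intersect_segments(
            [seg("chr1", 0, 1000, 1.0)], [seg("chr1", 0, 1000, 1.3)]
        )
        result = cn_concordance(blocks)
        assert result.agree_bases == 0
        assert result.score == 0.0

    def test_score_is_agreement_over_codefined_bases(self):
        # A on [0,200), B on [100,300), equal on the overlap:
        # T=200, X=200, C=300 -> G = 100/100 = 1.0
        blocks = intersect_segments(
            [seg("chr1", 0, 200, 1.0)], [seg("chr1", 100, 300, 1.0)]
        )
        result = cn_concordance(blocks)
        assert (result.t_bases, result.m_bases, result.union_bases) == (200, 200, 300)
        assert result.score == 1.0

    def test_union_denominator_option(self):
        blocks = intersect_segments(
            [seg("chr1", 0, 200, 1.0)], [seg("chr1", 100, 300, 1.0)]
        )
        result = cn_concordance(blocks, denominator="union")
        assert result.score == pytest.approx(100 / 300)

    def test_tolerance_boundary_inclusive(self):
        blocks = intersect_segments(
            [seg("chr1", 0, 100, 1.0)], [seg("chr1", 0, 100, 1.25)]
        )
        assert cn_concordance(blocks).score == 1.0

    def test_missing_values_excluded_from_defined_counts(self):
        blocks = intersect_segments(
            [seg("chr1", 0, 100, None)], [seg("chr1", 0, 100, 1.0)]
        )
        result = cn_concordance(blocks)
        assert (result.t_bases, result.m_bases, result.union_bases) == (0, 100, 100)
        assert result.score is None  # no co-defined bases

    def test_genome_aggregates_numerators_not_mean_of_chrom_scores(self):
        a = [seg("chr1", 0, 100, 1.0), seg("chr2", 0, 900, 1.0)]
        b = [seg("chr1", 0, 100, 1.0), seg("chr2", 0, 900, 2.0)]
        blocks = intersect_segments(a, b)
        genome = cn_concordance(blocks)
        per_chrom = {c.scope: c.score for c in cn_concordance_by_chromosome(blocks)}
        assert per_chrom == {"chr1": 1.0, "chr2": 0.0}
        assert genome.score == pytest.approx(100 / 1000)  # not 0.5

    def test_block_splitting_leaves_scores_unchanged(self):
        a = [seg("chr1", 0, 100, 1.0)]
        a_split = [seg("chr1", 0, 40, 1.0), seg("chr1", 40, 100, 1.0)]
        b = [seg("chr1", 0, 100, 1.1)]
        score = cn_concordance(intersect_segments(a, b)).score
        assert cn_concordance(intersect_segments(a_split, b)).score == score

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_base_oracle(self, random_cn_pair, seed):
        a, b = random_cn_pair(seed)
        blocks = intersect_segments(a, b)
        genome_score, chrom_scores = per_base_concordance(
            a, b, random_cn_pair.genome
        )
        assert cn_concordance(blocks).score == genome_score
        got = {c.scope: c.score for c in cn_concordance_by_chromosome(blocks)}
        for chrom, expected in chrom_scores.items():
            assert got.get(chrom) == expected

    def test_ploidy_scaling_invariance(self, random_cn_pair):
        a, b = random_cn_pair(seed=2)
        base = cn_concordance(intersect_segments(
            rescale_by_ploidy(a, 2.0), rescale_by_ploidy(b, 2.0)
        )).score
        doubled_b = [
            CnSegment(s.chrom, s.start, s.end,
                      None if s.imean is None else s.imean * 2, s.sample_id)
            for s in b
        ]
        rescored = cn_concordance(intersect_segments(
            rescale_by_ploidy(a, 2.0), rescale_by_ploidy(doubled_b, 4.0)
        )).score
        assert rescored == pytest.approx(base, abs=1e-12)


class TestPloidyQc:
    @pytest.mark.parametrize(
        "t,m,expected",
        [(1.9, 3.8, "doubled"), (2.0, 2.1, "comparable"), (2.0, 3.0, "ambiguous"),
         (3.8, 1.9, "doubled"), (2.0, 2.0, "comparable")],
    )
    def test_classification(self, t, m, expected):
        assert ploidy_qc(SamplePloidy("a", t), SamplePloidy("b", m)) == expected
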