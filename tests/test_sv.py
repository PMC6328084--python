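"""Structural-variant concordance: sizes, counts, flags, Jaccard, S^c."""

import pytest

from concord.model import SvEvent, make_sv_event
from concord.sv import (
    ChromSvRow,
    category_jaccard,
    chromosome_jaccard,
    chromosome_jaccard_rows,
    count_events_per_chromosome,
    flag_chromosomes,
    match_sv_events,
    overall_concordance,
    sv_event_size,
)


def ev(chrom="chr8", pos_a=100, pos_b=500, category="DEL", sample=""):
    return SvEvent(chrom, pos_a, chrom, pos_b, category, sample)


def tra(chrom_a="chr1", pos_a=1000, chrom_b="chr9", pos_b=2000):
    return make_sv_event(chrom_a, pos_a, chrom_b, pos_b, "TRA")


class TestEventSize:
    def test_intra_is_breakpoint_span(self):
        assert sv_event_size(ev(pos_a=100, pos_b=500)) == 400.0

    def test_translocation_is_unit(self):
        assert sv_event_size(tra()) == 1.0

    def test_minimal_inversion(self):
        assert sv_event_size(ev(pos_a=100, pos_b=101, category="INV")) == 1.0


class TestWeightedCounts:
    def test_intra_one_tra_half(self):
        events = [ev("chr4", 10 * i, 10 * i + 5) for i in range(1, 4)]
        events.append(tra("chr4", 999, "chr7", 50))
        counts = count_events_per_chromosome(events)
        assert counts == {"chr4": 3.5, "chr7": 0.5}

    def test_empty_is_empty(self):
        assert count_events_per_chromosome([]) == {}

    @pytest.mark.parametrize("seed", range(10))
    def test_conservation(self, random_sv_pair, seed):
        events, _ = random_sv_pair(seed)
        n_intra = sum(1 for e in events if not e.is_translocation)
        n_tra = sum(1 for e in events if e.is_translocation)
        assert sum(count_events_per_chromosome(events).values()) == n_intra + n_tra


class TestFlags:
    @pytest.mark.parametrize(
        "t,m,elevated,discordant",
        [(6, 5, True, False), (15, 4, False, True), (4.5, 5, False, False),
         (5, 5, True, False), (14.5, 4.5, False, True)],
    )
    def test_thresholds(self, t, m, elevated, discordant):
        flags = flag_chromosomes({"chr1": t}, {"chr1": m})
        assert flags["chr1"] == (elevated, discordant)


class TestMatching:
    def test_identical_events_match(self):
        event = ev()
        assert len(match_sv_events([event], [event])) == 1

    def test_category_is_part_of_identity(self):
        assert match_sv_events([ev(category="DEL")], [ev(category="DUP")]) == []

    def test_tolerance_contract(self):
        a = ev(pos_a=100, pos_b=500)
        b = ev(pos_a=105, pos_b=495)
        assert match_sv_events([a], [b]) == []
        assert len(match_sv_events([a], [b], bp_tolerance=10)) == 1

    def test_each_event_matches_at_most_once(self):
        a = ev(pos_a=100, pos_b=500)
        near1 = ev(pos_a=102, pos_b=500)
        near2 = ev(pos_a=104, pos_b=500)
        pairs = match_sv_events([a], [near1, near2], bp_tolerance=5)
        assert len(pairs) == 1
        pairs = match_sv_events([near1, near2], [a], bp_tolerance=5)
        assert len(pairs) == 1


class TestChromosomeJaccard:
    def test_identical_single_event(self):
        event = ev(pos_a=100, pos_b=500)
        row = chromosome_jaccard([event], [event], "chr8")
        assert row.jaccard == 1.0
        assert row.t_bases == row.m_bases == row.shared_bases == 400.0

    def test_formula_with_private_event(self):
        t = [ev(pos_a=100, pos_b=200), ev(pos_a=300, pos_b=400)]
        m = [ev(pos_a=100, pos_b=200)]
        row = chromosome_jaccard(t, m, "chr8")
        assert row.jaccard == pytest.approx(100 / 200)

    def test_no_events_is_undefined(self):
        row = chromosome_jaccard([ev()], [ev()], "chr21")
        assert row.jaccard is None

    def test_shared_tra_contributes_unit_to_both_chromosomes(self):
        event = tra("chr1", 1000, "chr9", 2000)
        for chrom in ("chr1", "chr9"):
            row = chromosome_jaccard([event], [event], chrom)
            assert (row.t_bases, row.m_bases, row.shared_bases) == (1.0, 1.0, 1.0)
            assert row.jaccard == 1.0

    def test_self_comparison_is_one_everywhere(self, random_sv_pair):
        events, _ = random_sv_pair(seed=3)
        rows = chromosome_jaccard_rows(events, list(events))
        assert rows  # populated
        for row in rows:
            assert row.jaccard == 1.0

    def test_removing_shared_event_never_increases_jaccard(self):
        shared = [ev(pos_a=100, pos_b=200), ev(pos_a=300, pos_b=400)]
        private = [ev(pos_a=500, pos_b=600)]
        before = chromosome_jaccard(shared + private, shared, "chr8").jaccard
        after = chromosome_jaccard(shared[1:] + private, shared, "chr8").jaccard
        assert after <= before

    def test_adding_private_event_never_increases_jaccard(self):
        shared = [ev(pos_a=100, pos_b=200)]
        before = chromosome_jaccard(shared, shared, "chr8").jaccard
        after = chromosome_jaccard(shared + [ev(pos_a=500, pos_b=600)], shared,
                                   "chr8").jaccard
        assert after <= before


class TestOverallScore:
    @staticmethod
    def rows(jaccards):
        return [
            ChromSvRow(f"chr{i}", 1, 1, 1, j, 1, 1, False, False)
            for i, j in enumerate(jaccards, start=1)
        ]

    def test_all_at_or_above_threshold(self):
        score = overall_concordance(self.rows([1.0, 0.9, 0.7, 0.6]))
        assert score.score == 1.0

    def test_half_below(self):
        score = overall_concordance(self.rows([0.8, 0.7, 0.5, 0.2]))
        assert (score.positives, score.negatives) == (2, 2)
        assert score.score == 0.5

    def test_undefined_rows_excluded(self):
        score = overall_concordance(self.rows([None, None, 1.0]))
        assert (score.positives, score.negatives) == (1, 0)
        assert score.score == 1.0

    def test_no_event_bearing_chromosomes_is_undefined(self):
        assert overall_concordance(self.rows([None])).score is None


class TestCategoryJaccard:
    def test_identical_categories_all_one(self):
        events = [ev(category="DEL"), ev(pos_a=700, pos_b=900, category="DUP"),
                  ev(pos_a=50, pos_b=60, category="INV"), tra()]
        rows = category_jaccard(events, list(events))
        assert {r.category for r in rows} == {"DEL", "DUP", "INV", "TRA"}
        assert all(r.jaccard == 1.0 for r in rows)

    def test_disjoint_del_only(self):
        t = [ev(pos_a=100, pos_b=200)]
        m = [ev(pos_a=300, pos_b=400)]
        rows = category_jaccard(t, m)
        assert [(r.category, r.jaccard) for r in rows] == [("DEL", 0.0)]

    def test_genome_tra_counts_once(self):
        event = tra()
        (row,) = category_jaccard([event], [event], "genome")
        assert row.t_bases == 1.0  # one base total, not one per chromosome

    def test_chromosome_scope_restricts(self):
        on8 = ev(pos_a=100, pos_b=200)
        on5 = ev(chrom="chr5", pos_a=100, pos_b=300)
        rows = category_jaccard([on8, on5], [on8, on5], "chr8")
        assert [(r.category, r.t_bases) for r in rows] == [("DEL", 100.0)]

    def test_shared_bases_sum_over_categories_matches_unstratified(self,
                                                                   random_sv_pair):
        t, m = random_sv_pair(seed=11)
        rows = category_jaccard(t, m, "genome")
        by_cat = sum(r.shared_bases for r in rows)
        matched = match_sv_events(t, m)
        unstratified = sum(sv_event_size(a) for a, _ in matched)
        assert by_cat == unstratified
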