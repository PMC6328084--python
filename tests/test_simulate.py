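"""Synthetic-data generator: construction guarantees, truth records, determinism."""

import filecmp
import os

import pytest

from concord.simulate import (
    CnScenario,
    PairScenario,
    SsmScenario,
    SvChromSpec,
    SvScenario,
    default_trio_scenario,
    simulate_pair_cn,
    simulate_pair_ssm,
    simulate_pair_sv,
    simulate_trio,
    write_trio,
)


class TestSsmGeneration:
    def test_constructed_overall_jaccard(self):
        scenario = PairScenario()
        t, m, truth = simulate_pair_ssm(scenario, 42)
        assert len(t) == 1000 and len(m) == 1000
        assert truth["all"]["jaccard"] == pytest.approx(700 / 1300)

    def test_no_shared_calls_gives_zero(self):
        scenario = PairScenario(ssm=SsmScenario(n_shared=0, n_tumour_only=20,
                                                n_model_only=20))
        _, _, truth = simulate_pair_ssm(scenario, 1)
        assert truth["all"]["jaccard"] == 0.0

    def test_hypermutator_scales_load(self):
        scenario = PairScenario(
            ssm=SsmScenario(n_shared=10, n_tumour_only=5, n_model_only=5),
            hypermutator=True,
        )
        t, m, truth = simulate_pair_ssm(scenario, 1)
        assert len(t) == 150 and len(m) == 150
        assert truth["all"]["jaccard"] == pytest.approx(100 / 200)

    def test_per_category_truth_sums_to_totals(self):
        _, _, truth = simulate_pair_ssm(PairScenario(), 3)
        assert sum(v["shared"] for v in truth["by_type"].values()) == 700

    def test_tiny_genome_rejected(self):
        scenario = PairScenario(genome={"chr1": 10},
                                ssm=SsmScenario(n_shared=50, n_tumour_only=0,
                                                n_model_only=0))
        with pytest.raises(ValueError, match="too small"):
            simulate_pair_ssm(scenario, 1)


class TestSvGeneration:
    def test_clustered_chromosome_shared_is_concordant_and_elevated(self):
        scenario = PairScenario(sv=SvScenario(
            chrom_specs={"chr8": SvChromSpec(n_shared=6, clustered=True)},
            tra_shared=0, tra_tumour_only=0, tra_model_only=0,
        ))
        t, m, truth = simulate_pair_sv(scenario, 5)
        row = truth["by_chrom"]["chr8"]
        assert row["jaccard"] == 1.0
        assert row["elevated"] is True
        window = max(e.pos_b for e in t) - min(e.pos_a for e in t)
        assert window <= 5_000_000

    def test_threshold_arithmetic_four_of_ten(self):
        specs = {f"chr{i}": SvChromSpec(n_shared=2) for i in range(1, 5)}
        specs.update({f"chr{i}": SvChromSpec(n_tumour_only=1, n_model_only=1)
                      for i in range(5, 11)})
        scenario = PairScenario(sv=SvScenario(chrom_specs=specs, tra_shared=0,
                                              tra_tumour_only=0))
        _, _, truth = simulate_pair_sv(scenario, 9)
        assert truth["overall"]["score"] == pytest.approx(0.4)

    def test_model_only_cluster_is_discordant(self):
        # chromothripsis-like cluster present only in the model
        scenario = PairScenario(sv=SvScenario(
            chrom_specs={"chr22": SvChromSpec(n_model_only=12, clustered=True)},
            tra_shared=0, tra_tumour_only=0,
        ))
        _, m, truth = simulate_pair_sv(scenario, 5)
        row = truth["by_chrom"]["chr22"]
        assert row["jaccard"] == 0.0
        assert row["discordant_count"] is True
        assert row["elevated"] is False


class TestCnGeneration:
    def test_ploidy_factor_two_without_discordance_is_fully_concordant(self):
        scenario = PairScenario(cn=CnScenario(ploidy_factor=2.0,
                                              discordant_fraction=0.0))
        (_, t_ploidy), (_, m_ploidy), truth = simulate_pair_cn(scenario, 4)
        assert m_ploidy.ploidy == pytest.approx(2 * t_ploidy.ploidy)
        assert truth["genome"] == 1.0

    def test_raw_values_differ_when_ploidy_doubled(self):
        scenario = PairScenario(cn=CnScenario(ploidy_factor=2.0, jitter_sd=0.0,
                                              discordant_fraction=0.0))
        (t_segments, _), (m_segments, _), _ = simulate_pair_cn(scenario, 4)
        for ts, ms in zip(t_segments, m_segments):
            assert ms.imean == pytest.approx(2 * ts.imean)

    def test_discordant_fraction_reflected_in_truth(self):
        scenario = PairScenario(cn=CnScenario(discordant_fraction=0.3,
                                              segments_per_chrom=10))
        _, _, truth = simulate_pair_cn(scenario, 8)
        # base-weighted score is near (not exactly) 0.7: segments have
        # random lengths but the discordant count is exact
        assert 0.5 < truth["genome"] < 0.9

    def test_unit_factor_zero_jitter_identical_profiles(self):
        scenario = PairScenario(cn=CnScenario(ploidy_factor=1.0, jitter_sd=0.0,
                                              discordant_fraction=0.0))
        (t_segments, _), (m_segments, _), truth = simulate_pair_cn(scenario, 4)
        assert [s.imean for s in m_segments] == pytest.approx(
            [s.imean for s in t_segments]
        )
        assert truth["genome"] == 1.0

    def test_incompatible_jitter_rejected(self):
        scenario = PairScenario(cn=CnScenario(jitter_sd=0.2, tolerance=0.25))
        with pytest.raises(ValueError, match="jitter"):
            simulate_pair_cn(scenario, 1)


class TestTrio:
    def test_zero_perturbation_makes_organoid_identical_to_xenograft(self):
        from concord.simulate import TrioPerturbation

        bundle = simulate_trio(
            seed=2,
            perturbation=TrioPerturbation(ssm_drop_fraction=0.0, ssm_new=0,
                                          sv_drop_fraction=0.0, sv_new=0,
                                          cn_discordant_fraction=0.0),
        )
        truth = bundle.truth["XvsO"]
        assert truth["ssm"]["all"]["jaccard"] == 1.0
        assert truth["sv"]["overall"]["score"] == 1.0
        assert truth["cn"]["genome"] == 1.0

    def test_derivation_order_reflected_in_concordance(self):
        bundle = simulate_trio(seed=6)
        assert (bundle.truth["XvsO"]["ssm"]["all"]["jaccard"]
                >= bundle.truth["TvsO"]["ssm"]["all"]["jaccard"])

    def test_same_seed_identical_file_trees(self, tmp_path):
        dirs = []
        for name in ("a", "b"):
            out = tmp_path / name
            write_trio(simulate_trio(default_trio_scenario(), seed=99), str(out))
            dirs.append(out)
        files = sorted(os.listdir(dirs[0]))
        assert files == sorted(os.listdir(dirs[1]))
        match, mismatch, errors = filecmp.cmpfiles(dirs[0], dirs[1], files,
                                                   shallow=False)
        assert mismatch == [] and errors == []

    def test_different_seeds_differ(self):
        a = simulate_trio(seed=1)
        b = simulate_trio(seed=2)
        assert a.truth != b.truth
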