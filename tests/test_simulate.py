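import numpy as np
import pandas as pd
import pytest

from cnvrpop.annotate import GeneIndex, read_gff3
from cnvrpop.callset import filter_calls, read_calls
from cnvrpop.genotype_vst import compute_vst
from cnvrpop.simulate import (
    LocusSpec,
    SimulationConfig,
    config_from_yaml,
    config_to_yaml,
    default_config,
    depth_track,
    emit_callset,
    emit_genes,
    expected_vst,
    generate_truth,
    planted_classes,
)


def locus(dist, chrom="chr1", start=10_001, end=15_000):
    return LocusSpec(chrom=chrom, start=start, end=end, dist=dist)


def one_locus_config(dist, groups=(("A", 1),), **kwargs):
    return SimulationConfig(
        chromosomes=(("chr1", 1_000_000),),
        groups=groups,
        loci=(locus(dist),),
        **kwargs,
    )


class TestConfigValidation:
    def test_bad_probabilities_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            one_locus_config({"A": {0.5: 0.6, 1.0: 0.6}})

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError, match="negative CN"):
            one_locus_config({"A": {-0.5: 1.0}})

    def test_locus_outside_chromosome_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            SimulationConfig(
                chromosomes=(("chr1", 10_000),),
                groups=(("A", 1),),
                loci=(locus({"A": {1.0: 1.0}}),),
            )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="sample count"):
            one_locus_config({"A": {1.0: 1.0}}, groups=(("A", 0),))

    def test_missing_group_distribution_rejected(self):
        with pytest.raises(ValueError, match="no distribution"):
            one_locus_config({"A": {1.0: 1.0}}, groups=(("A", 1), ("B", 1)))


class TestGenerateTruth:
    def test_degenerate_distribution_is_constant(self):
        config = one_locus_config(
            {"A": {1.0: 1.0}, "B": {1.0: 1.0}}, groups=(("A", 3), ("B", 3))
        )
        truth = generate_truth(config)
        assert (truth.cn.to_numpy() == 1.0).all()

    def test_group_specific_constants(self):
        config = one_locus_config(
            {"A": {0.5: 1.0}, "B": {1.5: 1.0}}, groups=(("A", 3), ("B", 3))
        )
        truth = generate_truth(config)
        for sample in config.samples:
            expected = 0.5 if sample.startswith("A") else 1.5
            assert truth.cn.at[config.loci[0].id, sample] == expected

    def test_law_of_large_numbers(self):
        config = one_locus_config(
            {"A": {0.5: 0.5, 1.0: 0.5}}, groups=(("A", 10_000),), seed=3
        )
        truth = generate_truth(config)
        values = truth.cn.iloc[0].to_numpy()
        se = np.std(values, ddof=1) / np.sqrt(len(values))
        assert abs(values.mean() - 0.75) < 3 * se

    def test_seed_reproducibility(self):
        config = default_config(seed=5)
        a = generate_truth(config).cn
        b = generate_truth(config).cn
        pd.testing.assert_frame_equal(a, b)


class TestEmitCallset:
    def test_all_diploid_yields_empty_callset(self, tmp_path):
        config = one_locus_config(
            {"A": {1.0: 1.0}}, groups=(("A", 2),), junk_call_rate=0.0
        )
        paths = emit_callset(generate_truth(config), tmp_path)
        for sample in config.samples:
            assert read_calls(paths["calls_dir"] / f"{sample}.cnv.tsv", sample) == []

    def test_single_deletion_noiseless(self, tmp_path):
        config = one_locus_config(
            {"A": {0.5: 1.0}}, groups=(("A", 1),), rd_noise_sd=0.0, junk_call_rate=0.0
        )
        paths = emit_callset(generate_truth(config), tmp_path)
        (call,) = read_calls(paths["calls_dir"] / "A_1.cnv.tsv", "A_1")
        assert call.cnv_type == "deletion"
        assert call.normalized_rd == pytest.approx(0.5)
        assert (call.start, call.end) == (10_001, 15_000)

    def test_junk_calls_fail_filter_and_match_sidecar(self, cohort):
        sidecar = pd.read_csv(cohort["sidecar"], sep="\t")
        kept = filter_calls(cohort["calls"])
        n_junk = (sidecar["kind"] == "junk").sum()
        assert n_junk > 0
        assert len(cohort["calls"]) - len(kept) == n_junk

    def test_coordinates_round_trip(self, cohort):
        sidecar = pd.read_csv(cohort["sidecar"], sep="\t")
        emitted = sorted(
            zip(sidecar.sample_id, sidecar.chrom, sidecar.start, sidecar.end)
        )
        parsed = sorted(
            (c.sample_id, c.chrom, c.start, c.end) for c in cohort["calls"]
        )
        assert emitted == parsed

    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        config = default_config(seed=9)
        for d in ("run1", "run2"):
            emit_callset(generate_truth(config), tmp_path / d)
        for f1 in sorted((tmp_path / "run1" / "calls").iterdir()):
            f2 = tmp_path / "run2" / "calls" / f1.name
            assert f1.read_bytes() == f2.read_bytes()


class TestEmitDepth:
    def test_poisson_moments_diploid_and_duplicated(self):
        config = SimulationConfig(
            chromosomes=(("chr1", 1_000_000),),
            groups=(("A", 1),),
            loci=(
                LocusSpec("chr1", 500_001, 600_000, {"A": {2.0: 1.0}}),
                LocusSpec("chr1", 700_001, 800_000, {"A": {0.0: 1.0}}),
            ),
            mean_coverage=20.0,
            seed=4,
        )
        track = depth_track(generate_truth(config), "A_1")
        diploid = track[track.bin_start < 500_000]["depth"]
        dup = track[(track.bin_start >= 500_000) & (track.bin_start < 600_000)]["depth"]
        zero = track[(track.bin_start >= 700_000) & (track.bin_start < 800_000)]["depth"]
        for values, mean in ((diploid, 20.0), (dup, 40.0)):
            se = np.sqrt(mean / len(values))  # Poisson variance = mean
            assert abs(values.mean() - mean) < 3 * se
        assert (zero == 0).all()


class TestEmitGenes:
    def test_gff_round_trips(self, cohort):
        models = read_gff3(cohort["gff3"])
        assert models, "toy annotation should contain genes"
        for g in models:
            assert g.exons[0][0] >= g.start and g.exons[-1][1] <= g.end

    def test_minus_strand_upstream_lies_above_gene_end(self, cohort):
        config = cohort["config"]
        models = {g.gene_id: g for g in read_gff3(cohort["gff3"])}
        classes = planted_classes(config)
        index = GeneIndex(list(models.values()), flank_bp=1900)
        upstream_minus = [
            l
            for i, l in enumerate(config.loci)
            if classes[l.id] == "upstream" and i % 2 == 1
        ]
        assert upstream_minus
        for l in upstream_minus:
            assert index.classify(l.chrom, l.start, l.end) == "upstream"
            # the gene serving this locus sits below it on the chromosome
            nearby = [
                g
                for g in models.values()
                if g.chrom == l.chrom and abs(g.end - l.start) < 5000
            ]
            assert nearby and all(g.end < l.start for g in nearby)

    def test_every_region_class_planted(self, demo_config):
        assert set(planted_classes(demo_config).values()) == {
            "exonic",
            "intronic",
            "upstream",
            "downstream",
            "intergenic",
        }

    def test_gene_overflow_rejected(self, tmp_path):
        config = SimulationConfig(
            chromosomes=(("chr1", 10_200),),
            groups=(("A", 1),),
            loci=(LocusSpec("chr1", 10_001, 10_150, {"A": {1.0: 1.0}}),),
        )
        with pytest.raises(ValueError, match="overflow"):
            emit_genes(config, tmp_path)


class TestExpectedVst:
    def test_identical_distributions_give_zero(self):
        l = locus({"A": {0.5: 0.5, 1.0: 0.5}, "B": {0.5: 0.5, 1.0: 0.5}})
        assert expected_vst(l, {"A": 4, "B": 4}) == 0.0

    def test_disjoint_constants_give_one(self):
        l = locus({"A": {0.5: 1.0}, "B": {1.0: 1.0}})
        assert expected_vst(l, {"A": 4, "B": 4}) == pytest.approx(1.0)

    def test_half_mixture_against_brute_force(self):
        # Var_A = 0.0625, Var_B = 0, pooled variance 0.046875, V_S = 0.03125
        l = locus({"A": {0.5: 0.5, 1.0: 0.5}, "B": {1.0: 1.0}})
        assert expected_vst(l, {"A": 4, "B": 4}) == pytest.approx(1 / 3)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            expected_vst(locus({"A": {1.0: 1.0}}), {"A": 4})

    def test_sampling_consistency(self):
        """Empirical Vst from generated truth converges to the analytic value."""
        dist = {"A": {0.5: 0.5, 1.0: 0.5}, "B": {1.0: 0.7, 2.0: 0.3}}
        spacing = 10_000
        loci = tuple(
            LocusSpec("chr1", 1 + i * spacing, spacing + i * spacing, dist)
            for i in range(20)
        )
        config = SimulationConfig(
            chromosomes=(("chr1", 20 * spacing),),
            groups=(("A", 100), ("B", 100)),
            loci=loci,
            seed=13,
        )
        truth = generate_truth(config)
        labels = [config.group_map[s] for s in config.samples]
        expected = expected_vst(loci[0], {"A": 100, "B": 100})
        errors = [
            abs(compute_vst(truth.cn.loc[l.id], labels).vst - expected)
            for l in loci
        ]
        assert np.mean(errors) < 0.05


def test_config_yaml_round_trip(tmp_path, demo_config):
    path = tmp_path / "sim.yaml"
    config_to_yaml(demo_config, path)
    back = config_from_yaml(path)
    assert back == demo_config
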