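import math
import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cnvrpop.cnvr import merge_calls
from cnvrpop.genotype_vst import (
    VstRecord,
    build_cn_matrix,
    classify_cn,
    compute_vst,
    ddct_quantity,
    genotype_from_calls,
    genotype_from_depth,
    select_top,
    vst_scan,
)

from conftest import make_call


def vst_oracle(values, labels):
    """Independent two-pass population-variance implementation."""

    def popvar(xs):
        m = sum(xs) / len(xs)
        return sum((x - m) ** 2 for x in xs) / len(xs)

    groups = {}
    for v, l in zip(values, labels):
        groups.setdefault(l, []).append(v)
    v_t = popvar(list(values))
    v_s = sum(len(xs) * popvar(xs) for xs in groups.values()) / len(values)
    return 0.0 if v_t == 0 else (v_t - v_s) / v_t


class TestClassify:
    @pytest.mark.parametrize(
        "cn,expected",
        [
            (0.0, "deleted"),
            (0.39, "deleted"),
            (0.4, "conserved"),
            (1.0, "conserved"),
            (1.6, "conserved"),
            (1.61, "duplicated"),
            (3.0, "duplicated"),
        ],
    )
    def test_redon_boundaries(self, cn, expected):
        assert classify_cn(cn) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_cn(-0.1)

    def test_partitions_nonnegative_reals(self):
        rng = np.random.default_rng(0)
        for cn in rng.uniform(0, 5, size=200):
            assert classify_cn(cn) in ("deleted", "conserved", "duplicated")


class TestGenotype:
    def _cnvr(self, start=1001, end=2000):
        (region,) = merge_calls([make_call(start=start, end=end)])
        return region

    def test_full_cover_returns_call_rd(self):
        region = self._cnvr()
        call = make_call(start=1001, end=2000, rd=0.5)
        assert genotype_from_calls(region, [call]) == pytest.approx(0.5)

    def test_half_cover_blends_with_diploid(self):
        region = self._cnvr()
        call = make_call(start=1001, end=1500, rd=0.5)
        assert genotype_from_calls(region, [call]) == pytest.approx(0.75)

    def test_no_evidence_is_diploid(self):
        assert genotype_from_calls(self._cnvr(), []) == pytest.approx(1.0)

    def test_overlapping_same_sample_calls_counted_once(self):
        # shared bases are weighted once, by the call that sorts first in
        # (start, end) order; here the deletion covers only 1601..2000
        region = self._cnvr()
        calls = [
            make_call(start=1001, end=1600, rd=0.5),
            make_call(start=1401, end=2000, rd=1.5),
        ]
        assert genotype_from_calls(region, calls) == pytest.approx(
            (0.5 * 600 + 1.5 * 400) / 1000
        )

    def test_depth_mode_flat_track_is_diploid(self):
        region = self._cnvr(start=101, end=300)
        depth = pd.DataFrame(
            {"chrom": "chr1", "bin_start": np.arange(0, 1000, 100), "depth": 20}
        )
        assert genotype_from_depth(region, depth) == pytest.approx(1.0)

    def test_depth_mode_halved_region(self):
        region = self._cnvr(start=101, end=300)
        depth = pd.DataFrame(
            {"chrom": "chr1", "bin_start": np.arange(0, 1000, 100), "depth": 20}
        )
        depth.loc[(depth.bin_start >= 100) & (depth.bin_start < 300), "depth"] = 10
        # region bins average 10; genome-wide mean is (8*20 + 2*10)/10 = 18
        assert genotype_from_depth(region, depth) == pytest.approx(10 / 18, rel=1e-6)

    def test_depth_mode_outside_extent_raises(self):
        region = self._cnvr(start=5_000_001, end=5_001_000)
        depth = pd.DataFrame({"chrom": ["chr1"], "bin_start": [0], "depth": [20]})
        with pytest.raises(ValueError, match="outside"):
            genotype_from_depth(region, depth)

    def test_matrix_complete_with_diploid_default(self):
        calls = [make_call(sample="a", rd=0.5)]
        cnvrs = merge_calls(calls)
        matrix = build_cn_matrix(cnvrs, calls, ["a", "b"])
        assert matrix.shape == (1, 2)
        assert matrix.iloc[0]["a"] == pytest.approx(0.5)
        assert matrix.iloc[0]["b"] == 1.0


class TestComputeVst:
    def test_all_equal_is_zero_by_convention(self):
        rec = compute_vst([1.0, 1.0, 1.0, 1.0], ["A", "A", "B", "B"])
        assert rec.vst == 0.0 and rec.v_total == 0.0

    def test_constant_groups_with_different_means_is_one(self):
        rec = compute_vst([1.0, 1.0, 2.0, 2.0], ["A", "A", "B", "B"])
        assert rec.vst == pytest.approx(1.0)

    def test_worked_example(self):
        rec = compute_vst([1, 1, 2, 2, 2, 2, 3, 3], ["A"] * 4 + ["B"] * 4)
        assert rec.v_total == pytest.approx(0.5)
        assert rec.v_within == pytest.approx(0.25)
        assert rec.vst == pytest.approx(0.5)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compute_vst([1.0, 2.0], ["A", "A"])

    def test_sample_convention_switchable(self):
        values = [1, 1, 2, 2, 2, 2, 3, 3]
        labels = ["A"] * 4 + ["B"] * 4
        pop = compute_vst(values, labels).vst
        samp = compute_vst(values, labels, convention="sample").vst
        assert pop != samp
        # sample convention: V_T = var(ddof=1), V_S weighted by n_i - 1
        v_t = np.var(values, ddof=1)
        v_s = (3 * np.var(values[:4], ddof=1) + 3 * np.var(values[4:], ddof=1)) / 6
        assert samp == pytest.approx((v_t - v_s) / v_t)

    def test_agrees_with_brute_force_oracle(self):
        rng = random.Random(42)
        for _ in range(200):
            n = rng.randrange(4, 11)
            labels = [rng.choice("AB") for _ in range(n)]
            if len(set(labels)) < 2:
                labels[0], labels[1] = "A", "B"
            values = [rng.uniform(0, 3) for _ in range(n)]
            rec = compute_vst(values, labels)
            assert rec.vst == pytest.approx(vst_oracle(values, labels), abs=1e-12)

    @given(
        st.lists(st.floats(0, 4, allow_nan=False), min_size=6, max_size=12),
        st.floats(-5, 5, allow_nan=False),
        st.floats(0.1, 10, allow_nan=False),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_invariant_under_affine_transform(self, values, shift, scale):
        from hypothesis import assume

        labels = ["A", "B", "C"] * (len(values) // 3) + ["A"] * (len(values) % 3)
        rec = compute_vst(values, labels)
        assume(rec.v_total > 1e-6)  # near-constant input is numerically wild
        moved = compute_vst([scale * v + shift for v in values], labels).vst
        assert moved == pytest.approx(rec.vst, abs=1e-9)

    def test_never_exceeds_one(self):
        rng = random.Random(7)
        for _ in range(100):
            values = [rng.gauss(1, 0.5) for _ in range(8)]
            labels = ["A"] * 4 + ["B"] * 4
            assert compute_vst(values, labels).vst <= 1.0

    def test_negative_vst_reported_unclamped(self):
        # with population variances V_T = V_S + between-group variance, so
        # Vst >= 0; the sample convention can dip below zero and must not
        # be clamped (clamping would distort the top-quantile scan)
        rec = compute_vst(
            [0.0, 2.0, 1.0, 1.0], ["A", "A", "B", "B"], convention="sample"
        )
        assert rec.vst == pytest.approx(-0.5)


class TestSelectTop:
    def test_distinct_values_give_single_candidate(self):
        records = [
            VstRecord(f"r{i}", "all", 1, 1, (4, 4), vst=i / 100) for i in range(100)
        ]
        candidates, threshold = select_top(records, 0.01)
        assert len(candidates) == 1
        assert candidates[0].vst == pytest.approx(0.99)
        assert threshold == pytest.approx(0.99)

    def test_ties_at_threshold_all_included(self):
        records = [VstRecord(f"r{i}", "all", 1, 1, (4,), vst=0.5) for i in range(50)]
        candidates, _ = select_top(records, 0.01)
        assert len(candidates) == 50

    def test_fraction_validated(self):
        records = [VstRecord("r", "all", 1, 1, (4,), vst=0.5)]
        for bad in (0.0, 1.0, -0.5):
            with pytest.raises(ValueError):
                select_top(records, bad)
        with pytest.raises(ValueError):
            select_top([], 0.01)

    def test_candidates_sorted_descending(self):
        rng = random.Random(9)
        records = [
            VstRecord(f"r{i}", "all", 1, 1, (4,), vst=rng.random()) for i in range(200)
        ]
        candidates, threshold = select_top(records, 0.05)
        vsts = [c.vst for c in candidates]
        assert vsts == sorted(vsts, reverse=True)
        assert all(v >= threshold for v in vsts)


class TestScan:
    def test_contrast_restricts_samples(self):
        matrix = pd.DataFrame(
            [[0.5, 0.5, 1.5, 1.5, 1.0, 1.0]],
            index=["chr1:1-100"],
            columns=[f"s{i}" for i in range(6)],
        )
        gm = {"s0": "A", "s1": "A", "s2": "B", "s3": "B", "s4": "C", "s5": "C"}
        (rec,) = vst_scan(matrix, gm, ({"A"}, {"B"}), contrast_name="AvB")
        assert rec.vst == pytest.approx(1.0)
        assert rec.contrast == "AvB"
        assert rec.n_i == (2, 2)

    def test_overlapping_contrast_sides_rejected(self):
        matrix = pd.DataFrame([[1.0, 2.0]], index=["r"], columns=["s0", "s1"])
        with pytest.raises(ValueError):
            vst_scan(matrix, {"s0": "A", "s1": "B"}, ({"A"}, {"A", "B"}))


@pytest.mark.parametrize(
    "ddct,expected", [(0.0, 1.0), (1.0, 0.5), (-2.0, 4.0)]
)
def test_ddct_relative_quantity(ddct, expected):
    # put the whole difference on the test sample's target gene
    assert ddct_quantity(20.0 + ddct, 20.0, 20.0, 20.0) == pytest.approx(expected)
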