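"""Boundary segmentation, segment classification, HWE and filters."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cnvresp.hmm import CnvCall
from cnvresp.segments import (
    SegmentMatrix,
    carrier_frequency,
    classify_segment,
    deletion_carrier_frequency,
    filter_segments,
    hwe_chi2_p,
    hwe_exact_p,
    hwe_test,
    segment_cnvs,
    segments_to_calls,
)

from _oracles import hwe_exact_enumeration


def _call(sample, start, end, cn=1, chrom="1"):
    return CnvCall(sample, chrom, start, end, cn, 5)


class TestSegmentCnvs:
    def test_published_three_segment_geometry(self, table1_calls):
        """Boundaries at 129,457,798 / 129,458,197 / 129,459,141 / 129,461,606
        split the merged deletion region into 0.4-, 0.9- and 2.5-kb segments."""
        m = segment_cnvs(table1_calls, ["A", "B", "C"])
        lengths_kb = [round(s.length / 1000, 1) for s in m.segments]
        assert lengths_kb == [0.4, 0.9, 2.5]
        assert round(sum(s.length for s in m.segments) / 1000, 1) == 3.8
        assert all(s.n_supporting_boundaries == 4 for s in m.segments)

    def test_single_call_yields_identical_segment(self):
        m = segment_cnvs([_call("A", 100, 200)], ["A"])
        (seg,) = m.segments
        assert (seg.start, seg.end) == (100, 200)
        assert list(seg.copy_numbers) == [1]

    def test_partial_overlap_hand_enumeration(self):
        """sampleA 100-200 and sampleB 150-250 split at cuts {100,150,201,251}."""
        calls = [_call("A", 100, 200), _call("B", 150, 250)]
        m = segment_cnvs(calls, ["A", "B"])
        got = [(s.start, s.end, tuple(s.copy_numbers)) for s in m.segments]
        assert got == [
            (100, 149, (1, 2)),
            (150, 200, (1, 1)),
            (201, 250, (2, 1)),
        ]

    def test_conflicting_same_sample_overlap_rejected(self):
        calls = [_call("A", 100, 200, cn=1), _call("A", 150, 250, cn=3)]
        with pytest.raises(ValueError, match="sample A"):
            segment_cnvs(calls, ["A"])

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValueError, match="not in sample_ids"):
            segment_cnvs([_call("X", 100, 200)], ["A"])

    def test_disjoint_calls_produce_no_gap_segments(self):
        calls = [_call("A", 100, 200), _call("A", 1000, 1100)]
        m = segment_cnvs(calls, ["A"])
        assert [(s.start, s.end) for s in m.segments] == [(100, 200), (1000, 1100)]
        assert m.n_regions() == 2


# strategy: same-sample non-overlapping integer calls on one chromosome
@st.composite
def call_sets(draw):
    n_samples = draw(st.integers(1, 4))
    samples = [f"S{i}" for i in range(n_samples)]
    calls = []
    for s in samples:
        pos = 1
        for _ in range(draw(st.integers(0, 4))):
            start = pos + draw(st.integers(0, 30))
            end = start + draw(st.integers(0, 40))
            calls.append(_call(s, start, end, cn=draw(st.sampled_from([0, 1, 3, 4]))))
            pos = end + 2  # keep same-sample calls disjoint
    return samples, calls


class TestSegmentationProperties:
    @given(call_sets())
    def test_partition_tiles_union_footprint(self, samples_calls):
        samples, calls = samples_calls
        m = segment_cnvs(calls, samples)
        covered = set()
        for c in calls:
            covered.update(range(c.start, c.end + 1))
        tiled = []
        for seg in m.segments:
            tiled.extend(range(seg.start, seg.end + 1))
        assert len(tiled) == len(set(tiled)), "segments overlap"
        assert set(tiled) == covered, "segments do not tile the call footprint"

    @given(call_sets())
    def test_every_call_is_union_of_whole_segments(self, samples_calls):
        samples, calls = samples_calls
        m = segment_cnvs(calls, samples)
        bounds = {(s.start, s.end) for s in m.segments}
        for c in calls:
            inside = sorted(
                (s.start, s.end) for s in m.segments if s.start >= c.start and s.end <= c.end
            )
            assert inside, "call lost during segmentation"
            assert inside[0][0] == c.start and inside[-1][1] == c.end
            for (a_s, a_e), (b_s, b_e) in zip(inside[:-1], inside[1:]):
                assert b_s == a_e + 1
            # no segment straddles the call's boundary
            for s in m.segments:
                if s.start <= c.end and s.end >= c.start:
                    assert s.start >= c.start and s.end <= c.end

    @given(call_sets())
    def test_idempotent_when_segments_are_resegmented(self, samples_calls):
        samples, calls = samples_calls
        m = segment_cnvs(calls, samples)
        again = segment_cnvs(segments_to_calls(m), samples)
        assert [(s.start, s.end) for s in again.segments] == [
            (s.start, s.end) for s in m.segments
        ]
        assert all(
            np.array_equal(a.copy_numbers, b.copy_numbers)
            for a, b in zip(again.segments, m.segments)
        )

    @given(call_sets(), st.integers(0, 1000))
    def test_adding_a_call_never_reduces_segment_count(self, samples_calls, seed):
        samples, calls = samples_calls
        rng = np.random.default_rng(seed)
        start = int(rng.integers(1, 400))
        extra = _call("EXTRA", start, start + int(rng.integers(0, 50)), cn=1)
        before = len(segment_cnvs(calls, samples).segments)
        after = len(segment_cnvs(calls + [extra], samples + ["EXTRA"]).segments)
        assert after >= before


class TestClassification:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ([1, 2, 2], "deletion_only"),
            ([1, 2, 3], "multi_class"),
            ([3, 4, 2], "duplication_only"),
            ([0, 1, 2], "deletion_only"),
        ],
    )
    def test_classes(self, column, expected):
        assert classify_segment(np.array(column)) == expected

    def test_all_diploid_rejected(self):
        with pytest.raises(ValueError, match="no abnormal"):
            classify_segment(np.array([2, 2]))

    def test_carrier_frequency_from_published_counts(self):
        """20 deletion carriers and one duplication carrier among 357."""
        col = np.array([1] * 20 + [3] * 1 + [2] * 336)
        assert carrier_frequency(col) == pytest.approx(21 / 357)
        assert deletion_carrier_frequency(col) == pytest.approx(20 / 357)

    def test_carrier_frequency_extremes(self):
        assert carrier_frequency(np.array([2, 2, 2])) == 0.0
        assert carrier_frequency(np.array([1, 1])) == 1.0


class TestHwe:
    def test_chi2_is_exact_hwe_proportions(self):
        # q = 0.1, n = 100: expected genotype counts exactly (81, 18, 1)
        assert hwe_chi2_p(18, 1, 81) == pytest.approx(1.0)

    def test_extreme_het_deficit_is_tiny(self):
        assert hwe_exact_p(0, 25, 25) < 1e-12

    def test_published_deletion_counts_pass_hwe(self):
        """20 hemizygotes, no homozygotes among 357 is HWE-consistent."""
        assert hwe_exact_p(20, 0, 337) > 0.05

    def test_monomorphic_is_one(self):
        assert hwe_exact_p(0, 0, 50) == 1.0

    @given(
        n_het=st.integers(0, 25), n_rare=st.integers(0, 12), n_common=st.integers(0, 30)
    )
    def test_exact_method_matches_rational_enumeration(self, n_het, n_rare, n_common):
        got = hwe_exact_p(n_het, n_rare, n_common)
        want = hwe_exact_enumeration(n_het, n_rare, n_common)
        assert got == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_cn_to_genotype_mapping(self):
        col = np.array([2] * 81 + [1] * 18 + [0] * 1)
        res = hwe_test(col, "deletion_only", method="chi2")
        assert (res.n_hom_ref, res.n_het, res.n_hom_alt) == (81, 18, 1)
        dup = np.array([2] * 10 + [3] * 4 + [4] * 1)
        res2 = hwe_test(dup, "duplication_only")
        assert (res2.n_hom_ref, res2.n_het, res2.n_hom_alt) == (10, 4, 1)

    def test_multi_class_not_applicable_unless_requested(self):
        col = np.array([1, 3, 2, 2])
        assert hwe_test(col, "multi_class") is None
        res = hwe_test(col, "multi_class", multi_class_mode="deletion")
        assert res is not None and res.n_het == 1 and res.n_hom_ref == 2


class TestFilterSegments:
    @staticmethod
    def _matrix(columns: dict[str, np.ndarray], n: int) -> SegmentMatrix:
        from cnvresp.segments import CnvSegment

        segs = [
            CnvSegment("1", 1000 * (i + 1), 1000 * (i + 1) + 99, col)
            for i, col in enumerate(columns.values())
        ]
        return SegmentMatrix(sample_ids=[f"S{j}" for j in range(n)], segments=segs)

    def test_carrier_frequency_boundary(self):
        n = 1000
        below = np.array([1] * 49 + [2] * (n - 49))
        at = np.array([1] * 50 + [2] * (n - 50))
        m = self._matrix({"below": below, "at": at}, n)
        kept, decisions = filter_segments(m, min_carrier_freq=0.05)
        assert len(kept.segments) == 1
        assert decisions["kept"].tolist() == [False, True]

    def test_hwe_boundary_excludes_p_equal_alpha(self):
        # (AA=25, Aa=0, aa=25) has exact p << 0.05 -> dropped; a clean HWE
        # column is kept; a multi-class column with the same imbalance is
        # exempt from the HWE screen
        n = 50
        out_of_hwe = np.array([2] * 25 + [0] * 25)
        multi = np.array([2] * 24 + [0] * 25 + [3])
        in_hwe = np.array([2] * 32 + [1] * 16 + [0] * 2)
        m = self._matrix({"bad": out_of_hwe, "multi": multi, "ok": in_hwe}, n)
        kept, decisions = filter_segments(m)
        assert decisions["kept"].tolist() == [False, True, True]
        assert "hwe_p" in decisions.loc[decisions.index[0], "reason"]

    def test_exact_alpha_boundary_dropped(self):
        """A single-class segment with p exactly at alpha is excluded."""
        col = np.array([2] * 25 + [0] * 25)
        p = hwe_exact_p(0, 25, 25)
        m = self._matrix({"seg": col}, 50)
        m.annotate()
        kept, _ = filter_segments(m, hwe_alpha=p)  # alpha set to the attained p
        assert len(kept.segments) == 0
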