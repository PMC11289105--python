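"""Consensus ROI construction, reciprocal overlap and database filters."""

import numpy as np
import pytest

from twindiscord.cnv import (
    CnvCall,
    DatabaseCnvRecord,
    ROI,
    build_rois,
    filter_common_cnvs,
    filter_single_caller_rois,
    identify_discordant_cnvs,
    reciprocal_overlap,
    rescue_pathogenic,
    screen_risk_cnvs,
)
from twindiscord.types import Cohort, TwinPair


def interval(start, end, chrom="chr1"):
    return DatabaseCnvRecord(chrom=chrom, start=start, end=end)


class TestReciprocalOverlap:
    def test_half_overlap(self):
        assert reciprocal_overlap(interval(0, 100), interval(50, 150)) == (0.5, 0.5)

    def test_nested_asymmetric(self):
        fa, fb = reciprocal_overlap(interval(0, 1000), interval(400, 600))
        assert (fa, fb) == (0.2, 1.0)

    def test_different_chrom_is_zero(self):
        assert reciprocal_overlap(
            interval(0, 100), interval(0, 100, chrom="chr2")
        ) == (0.0, 0.0)

    def test_symmetry_and_base_counting_oracle(self):
        """1000 random pairs: fractions equal per-base membership counts."""
        rng = np.random.default_rng(11)
        for _ in range(1000):
            s1, s2 = rng.integers(0, 500, size=2)
            a = interval(int(s1), int(s1) + int(rng.integers(1, 200)))
            b = interval(int(s2), int(s2) + int(rng.integers(1, 200)))
            fa, fb = reciprocal_overlap(a, b)
            assert (fb, fa) == reciprocal_overlap(b, a)
            bases_a = set(range(a.start, a.end))
            bases_b = set(range(b.start, b.end))
            shared = len(bases_a & bases_b)
            assert fa == pytest.approx(shared / len(bases_a))
            assert fb == pytest.approx(shared / len(bases_b))


@pytest.fixture
def pair():
    return TwinPair("T01", "T01_A", "T01_U", affected_id="T01_A",
                    diagnoses={"T01_A": "SCZ", "T01_U": "None"})


class TestBuildRois:
    def test_identical_calls_merge_with_support(self, pair):
        calls = [
            CnvCall("chr1", 100, 200, "DEL", "c1", "T01_A"),
            CnvCall("chr1", 100, 200, "DEL", "c2", "T01_A"),
        ]
        (roi,) = build_rois(calls, pair)
        assert (roi.start, roi.end) == (100, 200)
        assert roi.support["T01_A"] == {"c1", "c2"}
        assert roi.present_in == {"T01_A"}

    def test_overlapping_calls_union_merge(self, pair):
        calls = [
            CnvCall("chr1", 0, 100, "DEL", "cA", "T01_A"),
            CnvCall("chr1", 90, 200, "DEL", "cB", "T01_U"),
        ]
        (roi,) = build_rois(calls, pair)
        assert (roi.start, roi.end) == (0, 200)
        assert roi.present_in == {"T01_A", "T01_U"}

    def test_del_and_dup_never_merge(self, pair):
        calls = [
            CnvCall("chr1", 0, 100, "DEL", "c1", "T01_A"),
            CnvCall("chr1", 0, 100, "DUP", "c1", "T01_A"),
        ]
        assert len(build_rois(calls, pair)) == 2

    def test_abutting_intervals_do_not_merge(self, pair):
        # half-open [0,100) and [100,200) share no base
        calls = [
            CnvCall("chr1", 0, 100, "DEL", "c1", "T01_A"),
            CnvCall("chr1", 100, 200, "DEL", "c2", "T01_A"),
        ]
        assert len(build_rois(calls, pair)) == 2

    def test_merge_idempotent(self, pair):
        rng = np.random.default_rng(3)
        calls = [
            CnvCall("chr1", int(s), int(s) + int(rng.integers(10, 100)),
                    "DEL", f"c{rng.integers(3)}", "T01_A")
            for s in rng.integers(0, 1000, size=40)
        ]
        rois = build_rois(calls, pair)
        as_calls = [
            CnvCall(r.chrom, r.start, r.end, r.type, "merged", "T01_A")
            for r in rois
        ]
        again = build_rois(as_calls, pair)
        assert [(r.chrom, r.start, r.end, r.type) for r in rois] == [
            (r.chrom, r.start, r.end, r.type) for r in again
        ]


class TestSingleCallerFilter:
    @pytest.mark.parametrize(
        "support,kept",
        [
            ({"T01_A": {"c1"}}, False),                      # 1 sample, 1 caller
            ({"T01_A": {"c1", "c2"}}, True),                 # 1 sample, 2 callers
            ({"T01_A": {"c1"}, "T01_U": {"c1"}}, True),      # both samples
            ({"T01_A": {"c1"}, "T01_U": {"c2"}}, True),      # rule is conjunctive
        ],
    )
    def test_rule_enumeration(self, support, kept):
        roi = ROI("chr1", 0, 100, "DEL", "T01",
                  support={s: frozenset(v) for s, v in support.items()})
        assert bool(filter_single_caller_rois([roi])) is kept


def _roi(start, end, pair_id="T01", support=None, chrom="chr1", rtype="DEL"):
    return ROI(chrom, start, end, rtype, pair_id,
               support=support or {"T01_A": frozenset({"c1", "c2"})})


class TestCommonFilter:
    def test_exact_match_removed(self):
        db = [DatabaseCnvRecord("chr1", 0, 100, frequency=0.02)]
        assert filter_common_cnvs([_roi(0, 100)], [db]) == []

    def test_one_sided_overlap_retained(self):
        # 40%/90% overlap fails the reciprocal requirement
        db = [DatabaseCnvRecord("chr1", 0, 450, frequency=0.02)]
        roi = _roi(270, 1270)  # overlap 180: 18% of roi, 40% of record
        assert filter_common_cnvs([roi], [db]) == [roi]

    def test_rare_record_ignored(self):
        db = [DatabaseCnvRecord("chr1", 0, 100, frequency=0.002)]
        roi = _roi(0, 100)
        with pytest.warns(UserWarning):  # nothing common remains in the db
            assert filter_common_cnvs([roi], [db]) == [roi]

    def test_empty_database_warns_and_keeps(self):
        roi = _roi(0, 100)
        with pytest.warns(UserWarning):
            assert filter_common_cnvs([roi], [[]]) == [roi]

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(5)
        rois = [
            _roi(int(s), int(s) + int(rng.integers(50, 400)))
            for s in rng.integers(0, 5000, size=60)
        ]
        db = [
            DatabaseCnvRecord("chr1", int(s), int(s) + int(rng.integers(50, 400)),
                              frequency=float(rng.uniform(0, 0.1)))
            for s in rng.integers(0, 5000, size=60)
        ]
        kept = filter_common_cnvs(rois, [db])

        def brute(roi):
            for rec in db:
                if rec.frequency < 0.01:
                    continue
                ov = min(roi.end, rec.end) - max(roi.start, rec.start)
                if ov <= 0:
                    continue
                if ov / roi.length >= 0.5 and ov / (rec.end - rec.start) >= 0.5:
                    return False
            return True

        assert kept == [r for r in rois if brute(r)]


class TestPathogenicRescue:
    def test_phenotype_gate(self):
        roi = _roi(0, 100)
        neuro = DatabaseCnvRecord("chr1", 0, 100, label="pathogenic",
                                  phenotype_tags=frozenset({"neurodevelopmental"}))
        cardiac = DatabaseCnvRecord("chr1", 0, 100, label="pathogenic",
                                    phenotype_tags=frozenset({"cardiac"}))
        assert [r.pathogenic for r in rescue_pathogenic([roi], [neuro])] == [True]
        assert rescue_pathogenic([roi], [cardiac]) == []

    def test_type_is_ignored(self):
        dup_roi = _roi(0, 100, rtype="DUP")
        del_record = DatabaseCnvRecord("chr1", 0, 100, type="DEL", label="pathogenic",
                                       phenotype_tags=frozenset({"psychiatric"}))
        assert rescue_pathogenic([dup_roi], [del_record])


class TestScreenAndDiscordant:
    @pytest.fixture
    def cohort(self, pair):
        return Cohort([pair])

    def test_both_twins_classification(self, cohort):
        roi = _roi(0, 100, support={"T01_A": frozenset({"c1"}),
                                    "T01_U": frozenset({"c1"})})
        risk = [DatabaseCnvRecord("chr1", 0, 100, type="DEL")]
        report = screen_risk_cnvs([roi], risk, cohort)
        assert list(report["status"]) == ["both_twins"]

    def test_affected_only_and_no_match(self, cohort):
        roi = _roi(0, 100)
        risk = [DatabaseCnvRecord("chr1", 0, 100)]
        assert list(screen_risk_cnvs([roi], risk, cohort)["status"]) == ["affected_only"]
        far = [DatabaseCnvRecord("chr2", 0, 100)]
        assert screen_risk_cnvs([roi], far, cohort).empty

    def test_discordant_requires_exactly_one_sample(self, cohort):
        single = _roi(0, 100)
        both = _roi(200, 300, support={"T01_A": frozenset({"c1"}),
                                       "T01_U": frozenset({"c2"})})
        unaffected = _roi(400, 500, support={"T01_U": frozenset({"c1", "c2"})})
        result = identify_discordant_cnvs([single, both, unaffected], cohort)
        assert [(r.start, carrier, affected) for r, carrier, affected in result] == [
            (0, "T01_A", True),
            (400, "T01_U", False),
        ]


def test_length_is_end_minus_start():
    assert CnvCall("chr3", 195940567, 197638156, "DUP", "c", "s").length == 1_697_589
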