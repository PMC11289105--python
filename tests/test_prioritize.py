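"""Coding cascade, privacy filter and regulatory route semantics."""

import numpy as np
import pytest

from twindiscord.discordance import alt_copy_count, detect_discordant_cohort
from twindiscord.prioritize import (
    PrioritizationConfig,
    cohort_privacy_filter,
    filter_coding_deleterious,
    filter_regulatory,
    prioritize_coding,
)
from twindiscord.types import AlleleAnnotation, DiscordantCall

from conftest import make_variant

PASSING = dict(
    gene="FOXN1", impact="MODERATE", csq_class="missense_variant",
    sift_class="deleterious", polyphen_class="probably_damaging",
)


def make_call(cohort_or_pair, carrier="S1_A", pos=100, ref="A", alt="G",
              extra_genotypes=None, **ann_kwargs):
    ann = AlleleAnnotation(**{**PASSING, **ann_kwargs})
    genotypes = {"S1_A": (0, 0), "S1_U": (0, 0)}
    if extra_genotypes:
        genotypes.update(extra_genotypes)
    genotypes[carrier] = (0, 1)
    v = make_variant(pos=pos, ref=ref, alt=(alt,), genotypes=genotypes, ann=(ann,))
    return DiscordantCall(variant=v, pair_id="S1", carrier_id=carrier,
                          carrier_affected=carrier.endswith("_A"))


class TestCodingCascade:
    def test_fully_passing_missense_retained(self):
        call = make_call(None)
        assert filter_coding_deleterious([call]) == [call]

    @pytest.mark.parametrize(
        "ann,reason",
        [
            (dict(csq_class="intron_variant"), "non-coding"),
            (dict(impact="LOW"), "impact"),
            (dict(sift_class="tolerated", polyphen_class="benign"), "predictions"),
            (dict(af_gnomad=0.05), "gnomAD frequency"),
            (dict(af_1kg=0.02), "1KG frequency"),
            (dict(sift_class=None, polyphen_class=None), "both scores missing"),
        ],
    )
    def test_single_violations_removed(self, ann, reason):
        assert filter_coding_deleterious([make_call(None, **ann)]) == []

    def test_sift_polyphen_or_semantics(self):
        # tolerated SIFT is rescued by a damaging PolyPhen and vice versa,
        # including the single-letter annotation dialect
        for ann in (
            dict(sift_class="tolerated", polyphen_class="damaging"),
            dict(sift_class="T", polyphen_class="D"),
            dict(sift_class="deleterious", polyphen_class="benign"),
            dict(sift_class="D", polyphen_class="B"),
        ):
            assert filter_coding_deleterious([make_call(None, **ann)]), ann

    def test_af_boundary_and_missing(self):
        cfg = PrioritizationConfig()
        assert not filter_coding_deleterious([make_call(None, af_gnomad=0.01)], cfg)
        assert filter_coding_deleterious([make_call(None, af_gnomad=0.009)], cfg)
        # absent frequency passes ("rare or absent")
        assert filter_coding_deleterious(
            [make_call(None, af_gnomad=None, af_1kg=None)], cfg
        )

    def test_indels_excluded(self):
        call = make_call(None, ref="CT", alt="C")
        assert filter_coding_deleterious([call]) == []

    def test_unaffected_carrier_removed_by_default_kept_when_disabled(self):
        call = make_call(None, carrier="S1_U")
        assert filter_coding_deleterious([call]) == []
        cfg = PrioritizationConfig(affected_only=False)
        assert filter_coding_deleterious([call], cfg) == [call]

    def test_filters_commute(self):
        """(i)-(iv) are pure predicates: subsetting in any order agrees."""
        anns = [
            {}, dict(csq_class="intron_variant"), dict(impact="LOW"),
            dict(sift_class="tolerated", polyphen_class="benign"),
            dict(af_gnomad=0.05), dict(af_1kg=0.5, af_gnomad=0.5),
        ]
        calls = [make_call(None, pos=i + 1, **a) for i, a in enumerate(anns)]
        cfg = PrioritizationConfig()
        reference = filter_coding_deleterious(calls, cfg)
        # applying twice (idempotence) and shuffling input order
        assert filter_coding_deleterious(reference, cfg) == reference
        shuffled = calls[::-1]
        assert set(map(id, filter_coding_deleterious(shuffled, cfg))) == set(
            map(id, reference)
        )


class TestPrivacyFilter:
    def test_private_variant_retained(self, two_pair_cohort):
        call = make_call(None, extra_genotypes={"S2_A": (0, 0), "S2_U": (0, 0)})
        assert cohort_privacy_filter([call], two_pair_cohort) == [call]

    def test_concordant_presence_in_other_pair_removes(self, two_pair_cohort):
        call = make_call(None, extra_genotypes={"S2_A": (0, 1), "S2_U": (0, 1)})
        assert cohort_privacy_filter([call], two_pair_cohort) == []

    def test_matches_brute_force_scan(self, two_pair_cohort):
        """Random cohort: retained set equals an all-samples occurrence scan."""
        rng = np.random.default_rng(7)
        gts = [(0, 0), (0, 1), (1, 1)]
        variants = []
        for pos in range(1, 300):
            genotypes = {
                s: gts[rng.integers(3)] for s in two_pair_cohort.sample_ids
            }
            variants.append(make_variant(pos=pos, genotypes=genotypes,
                                         ann=(AlleleAnnotation(**PASSING),)))
        calls = detect_discordant_cohort(variants, two_pair_cohort)
        kept = cohort_privacy_filter(calls, two_pair_cohort)

        def brute_force_private(call):
            others = [
                s for s in two_pair_cohort.sample_ids
                if s not in two_pair_cohort.pair(call.pair_id).sample_ids
            ]
            return all(
                (alt_copy_count(call.variant.calls[s]) or 0) == 0 for s in others
            )

        assert kept == [c for c in calls if brute_force_private(c)]


class TestRegulatoryRoute:
    @pytest.mark.parametrize(
        "cadd,rank,kept",
        [
            (21.0, 2, True),
            (20.0, 1, False),  # strictly greater than threshold required
            (25.0, 3, False),
            (None, 1, False),
            (30.0, None, False),
        ],
    )
    def test_thresholds(self, cadd, rank, kept):
        call = make_call(None, cadd_phred=cadd, regdb_rank=rank)
        assert bool(filter_regulatory([call])) is kept

    def test_unaffected_carrier_still_reported(self):
        call = make_call(None, carrier="S1_U", cadd_phred=24.0, regdb_rank=1)
        (kept,) = filter_regulatory([call])
        assert kept.carrier_affected is False


def test_cascade_monotone_and_trace_accounts_for_everything(two_pair_cohort):
    calls = [
        make_call(None, pos=1),
        make_call(None, pos=2, impact="LOW"),
        make_call(None, pos=3, extra_genotypes={"S2_A": (0, 1), "S2_U": (0, 1)}),
    ]
    res = prioritize_coding(calls, two_pair_cohort)
    assert set(map(id, res.retained)) <= set(map(id, calls))
    assert len(res.retained) + len(res.trace) == len(calls)
    reasons = {c.variant.pos: fails for c, fails in res.trace}
    assert reasons[2] == ["impact"]
    assert reasons[3] == ["private_to_pair"]
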