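"""Synthetic cohort generator: determinism, truth conservation, scaling."""

import numpy as np
import pytest

from twindiscord.discordance import alt_copy_count
from twindiscord.simulate import (
    CohortConfig,
    generate_cnv_callsets,
    generate_snv_cohort,
    generate_tracks_and_repeats,
    make_cohort,
)
from twindiscord.vcf_io import split_multiallelic

QUIET_PROFILE = dict(
    coding=0.05, regulatory=0.1, deleterious_given_coding=0.3,
    multiallelic_fraction=0.0, n_prioritizable=0, n_regulatory_hits=0,
)


def small_config(**kwargs):
    defaults = dict(n_pairs=3, n_shared_variants=400, seed=5)
    defaults.update(kwargs)
    return CohortConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(discordant_fraction=1.5),
            dict(genotype_error_rate=-0.1),
            dict(n_pairs=0),
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            small_config(**kwargs)

    def test_cnv_needs_two_callers(self):
        with pytest.raises(ValueError, match="n_callers"):
            generate_cnv_callsets(small_config(), n_callers=1)


class TestDeterminism:
    def test_snv_outputs_byte_identical(self, tmp_path):
        cfg = small_config()
        generate_snv_cohort(cfg, tmp_path / "a")
        generate_snv_cohort(cfg, tmp_path / "b")
        for name in ("cohort.vcf", "pairs.tsv", "truth_discordant.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_cnv_and_track_outputs_byte_identical(self, tmp_path):
        cfg = small_config()
        for sub in ("a", "b"):
            generate_cnv_callsets(cfg, out_dir=tmp_path / sub)
            generate_tracks_and_repeats(cfg, out_dir=tmp_path / sub)
        for name in ("cnv_calls.tsv", "cnv_common_db.tsv", "repeats.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()


class TestGroundTruth:
    def test_no_discordance_no_error_means_identical_twins(self):
        cfg = small_config(discordant_fraction=0.0, genotype_error_rate=0.0)
        sim = generate_snv_cohort(cfg)
        assert sim.truth.discordant.empty
        for v in sim.variants:
            for pair in sim.cohort:
                g1 = v.calls[pair.twin1_id].allele_indices
                g2 = v.calls[pair.twin2_id].allele_indices
                assert g1 == g2

    def test_planted_count_is_reproducible_binomial(self):
        cfg = CohortConfig(n_pairs=2, n_shared_variants=1000,
                           discordant_fraction=0.01, seed=7)
        counts = []
        for _ in range(2):
            sim = generate_snv_cohort(cfg)
            per_sample = sim.truth.discordant.groupby("carrier").size()
            counts.append(tuple(per_sample))
        assert counts[0] == counts[1]  # same seed, same draws
        # Binomial(1000, 0.01): expect about 10 per sample, within 3 SD
        sd = np.sqrt(1000 * 0.01 * 0.99)
        assert len(counts[0]) == 4
        for c in counts[0]:
            assert abs(c - 10) <= 3 * sd

    def test_truth_conservation_without_errors(self):
        """With zero genotype error, truth rows coincide exactly with the
        emitted sites at which twins differ by one alternate copy."""
        cfg = small_config(genotype_error_rate=0.0)
        sim = generate_snv_cohort(cfg)
        emitted = set()
        for v in sim.variants:
            for rec in split_multiallelic(v):
                for pair in sim.cohort:
                    n1 = alt_copy_count(rec.calls[pair.twin1_id])
                    n2 = alt_copy_count(rec.calls[pair.twin2_id])
                    if n1 is None or n2 is None or abs(n1 - n2) != 1:
                        continue
                    carrier = pair.twin1_id if n1 > n2 else pair.twin2_id
                    emitted.add((carrier, rec.chrom, rec.pos, rec.alt[0]))
        truth = {
            (r.carrier, r.chrom, int(r.pos), str(r.alt))
            for r in sim.truth.discordant.itertuples(index=False)
        }
        assert emitted == truth

    def test_discordant_fraction_converges(self):
        cfg = CohortConfig(n_pairs=2, n_shared_variants=10_000,
                           discordant_fraction=0.01, seed=13,
                           annotation_profile=dict(QUIET_PROFILE))
        sim = generate_snv_cohort(cfg)
        sd = np.sqrt(10_000 * 0.01 * 0.99)
        per_sample = sim.truth.discordant.groupby("carrier").size()
        assert len(per_sample) == 4
        for count in per_sample:
            assert abs(count - 100) <= 3 * sd


class TestCnvGenerator:
    def test_no_jitter_no_dropout_identical_across_callers(self):
        cfg = small_config(cnv_jitter_sd=0.0, cnv_dropout=0.0,
                           cnv_false_positives_per_caller=0)
        sim = generate_cnv_callsets(cfg, n_callers=3)
        for row in sim.truth.cnvs.itertuples(index=False):
            matching = [
                c for calls in sim.calls_by_pair.values() for c in calls
                if (c.chrom, c.start, c.end) == (row.chrom, row.start, row.end)
            ]
            n_samples = 1 if row.discordant else 2
            assert len(matching) == 3 * n_samples
            assert {c.caller_id for c in matching} == {"caller1", "caller2", "caller3"}

    def test_single_caller_truth_marks(self):
        cfg = small_config(n_pairs=6, cnv_dropout=0.45, seed=23)
        sim = generate_cnv_callsets(cfg)
        marked = sim.truth.cnvs.query("expected == 'removed_single_caller'")
        for row in marked.itertuples(index=False):
            assert row.n_support_samples == 1
            assert row.n_support_calls == 1

    def test_database_decoys_straddle_threshold(self):
        sim = generate_cnv_callsets(small_config(n_pairs=6, seed=3))
        assert (sim.truth.cnvs["expected"] == "removed_common").any() or (
            sim.truth.cnvs["expected"] == "rescued_pathogenic"
        ).any()
        assert any(r.is_common for r in sim.common_db)
        assert any(r.label == "pathogenic" for r in sim.pathogenic_db)


class TestTracksAndRepeats:
    def test_default_counts(self, tmp_path):
        sim = generate_tracks_and_repeats(small_config(), out_dir=tmp_path)
        assert len(sim.tracks) == 8
        assert len(sim.thresholds) == 16
        assert len(list((tmp_path / "tracks").glob("*.bed"))) == 8
        # default cohort has no above-threshold repeat counts
        assert sim.truth.repeat_flags.empty
        for g in sim.repeat_genotypes:
            assert g.max_count < sim.thresholds[g.locus_id]

    def test_empty_track_request(self, tmp_path):
        sim = generate_tracks_and_repeats(small_config(n_tracks=0), out_dir=tmp_path)
        assert sim.tracks == []
        assert list((tmp_path / "tracks").glob("*.bed")) == []

    def test_forced_expansion_flagged_exactly(self):
        cfg = small_config()
        cohort = make_cohort(cfg)
        sample = cohort.pairs[0].twin1_id
        sim = generate_tracks_and_repeats(
            cfg, cohort=cohort, forced_expansions=[(sample, "HTT")]
        )
        flags = sim.truth.repeat_flags
        assert len(flags) == 1
        assert (flags.iloc[0]["sample"], flags.iloc[0]["locus"]) == (sample, "HTT")
        flagged = [
            g for g in sim.repeat_genotypes
            if g.max_count > sim.thresholds[g.locus_id]
        ]
        assert [(g.sample_id, g.locus_id) for g in flagged] == [(sample, "HTT")]
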