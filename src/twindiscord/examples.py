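"""Worked-example cohorts with known expected output.

Two small, fully deterministic input bundles exercise the whole
pipeline end to end:

* :func:`snv_example` — a joint VCF in which six known discordant,
  rare, predicted-deleterious missense SNVs (three FOXN1 variants in
  one carrier, one FLOT2, one NUTM2G, one KRTAP10-6) are planted as
  affected-carrier discordant calls, alongside decoy records that each
  violate exactly one cascade filter (non-coding; LOW impact;
  tolerated+benign; common allele frequency; shared with a second pair;
  indel) plus a low-QUAL site and a homozygous-difference site.
  Running QC -> discordance -> coding cascade must retain exactly the
  six variants across four genes.

* :func:`cnv_example` — multi-caller CNV call tables in which four
  known rare CNVs (a large pathogenic 3q29-region duplication and three
  small deletions) are present in affected samples only with two-caller
  support, alongside decoys (present in both twins; >= 50% reciprocal
  overlap with a 2%-frequency database record; single-caller/
  single-sample) and a risk-locus duplication carried by both twins of
  one pair.  The consensus pipeline must report exactly the four
  discordant rare CNVs with their exact lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .cnv import CnvCall, DatabaseCnvRecord
from .types import (
    AlleleAnnotation,
    AnnotatedVariant,
    Cohort,
    GenotypeCall,
    TwinPair,
)
from .vcf_io import write_annotated_vcf


def example_cohort() -> Cohort:
    """Eight twin pairs covering every carrier in the worked examples."""
    layout = [
        ("T01", "T01_A1", "SCZ", "None"),
        ("T02", "T02_A", "SAD", "None"),
        ("T07", "T07_A", "BD", "None"),
        ("T09", "T09_A", "BD", "None"),
        ("T10", "T10_A", "SCZ", "None"),
        ("T13", "T13_A1", "SCZ", "MDD"),
        ("T16", "T16_A", "BD", "None"),
        ("T17", "T17_A", "BD", "None"),
    ]
    pairs = []
    for pid, affected, dx, co_dx in layout:
        co = f"{pid}_U"
        pairs.append(
            TwinPair(
                pair_id=pid,
                twin1_id=affected,
                twin2_id=co,
                affected_id=affected,
                diagnoses={affected: dx, co: co_dx},
            )
        )
    return Cohort(pairs)


#: the six expected prioritized missense SNVs:
#: (chrom, pos, rsid, ref, alt, carrier, gene, hgvsp, sift, polyphen)
EXPECTED_SNVS = (
    ("chr9", 96932219, "rs112610837", "C", "T", "T13_A1", "NUTM2G", "P172S", "tolerated", "damaging"),
    ("chr17", 28530789, "rs1385768054", "A", "C", "T07_A", "FOXN1", "S291R", "deleterious", "damaging"),
    ("chr17", 28530791, "rs371766542", "C", "A", "T07_A", "FOXN1", "S291R", "deleterious", "damaging"),
    ("chr17", 28530802, "rs1220808552", "G", "C", "T07_A", "FOXN1", "S295T", "deleterious", "damaging"),
    ("chr17", 28881251, None, "C", "T", "T09_A", "FLOT2", "A347T", "deleterious", "damaging"),
    ("chr22", 44592351, "rs367621282", "G", "C", "T10_A", "KRTAP10-6", "P45R", "deleterious", "damaging"),
)

EXPECTED_GENES = ("FOXN1", "FLOT2", "NUTM2G", "KRTAP10-6")


def _variant(
    cohort: Cohort,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    carrier: str,
    ann: AlleleAnnotation,
    qual: float = 500.0,
    gq: int = 99,
    dp: int = 35,
    extra_het: tuple[str, ...] = (),
    carrier_gt: tuple[int, int] = (0, 1),
) -> AnnotatedVariant:
    calls = {}
    for s in cohort.sample_ids:
        if s == carrier:
            gt = carrier_gt
        elif s in extra_het:
            gt = (0, 1)
        else:
            gt = (0, 0)
        calls[s] = GenotypeCall(s, gt, gq=gq, dp=dp)
    return AnnotatedVariant(
        chrom=chrom, pos=pos, ref=ref, alt=(alt,), qual=qual, calls=calls,
        annotations=(ann,),
    )


@dataclass
class SnvExample:
    cohort: Cohort
    variants: list[AnnotatedVariant]
    vcf_path: Optional[Path] = None
    pairs_path: Optional[Path] = None


def snv_example(out_dir: Optional[str | Path] = None) -> SnvExample:
    """Build the SNV worked example; optionally write VCF + pairs table."""
    cohort = example_cohort()
    variants: list[AnnotatedVariant] = []

    for chrom, pos, rsid, ref, alt, carrier, gene, hgvsp, sift, polyphen in EXPECTED_SNVS:
        variants.append(
            _variant(
                cohort, chrom, pos, ref, alt, carrier,
                AlleleAnnotation(
                    gene=gene, impact="MODERATE", csq_class="missense_variant",
                    sift_class=sift, polyphen_class=polyphen, hgvsp=hgvsp, rsid=rsid,
                ),
            )
        )

    deleterious = dict(
        impact="MODERATE", csq_class="missense_variant",
        sift_class="deleterious", polyphen_class="probably_damaging",
    )
    decoys = [
        # non-coding consequence, everything else passing
        _variant(cohort, "chr1", 1_000_100, "A", "G", "T13_A1",
                 AlleleAnnotation(**{**deleterious, "gene": "DECOY1",
                                     "csq_class": "regulatory_region_variant"})),
        # LOW impact
        _variant(cohort, "chr1", 1_000_200, "C", "T", "T10_A",
                 AlleleAnnotation(**{**deleterious, "gene": "DECOY2", "impact": "LOW",
                                     "csq_class": "synonymous_variant"})),
        # tolerated + benign
        _variant(cohort, "chr1", 1_000_300, "G", "A", "T07_A",
                 AlleleAnnotation(**{**deleterious, "gene": "DECOY3",
                                     "sift_class": "tolerated", "polyphen_class": "benign"})),
        # common allele frequency
        _variant(cohort, "chr1", 1_000_400, "T", "C", "T09_A",
                 AlleleAnnotation(**{**deleterious, "gene": "DECOY4", "af_gnomad": 0.05})),
        # observed concordantly in a second pair
        _variant(cohort, "chr1", 1_000_500, "A", "C", "T13_A1",
                 AlleleAnnotation(**{**deleterious, "gene": "DECOY5"}),
                 extra_het=("T16_A", "T16_U")),
        # indel (no SIFT/PolyPhen applicability)
        AnnotatedVariant(
            chrom="chr1", pos=1_000_600, ref="CT", alt=("C",), qual=500.0,
            calls={
                s: GenotypeCall(s, (0, 1) if s == "T02_A" else (0, 0), gq=99, dp=35)
                for s in cohort.sample_ids
            },
            annotations=(AlleleAnnotation(**{**deleterious, "gene": "DECOY6",
                                             "csq_class": "inframe_deletion"}),),
        ),
        # below the site QUAL threshold: removed before discordance
        _variant(cohort, "chr1", 1_000_700, "G", "T", "T01_A1",
                 AlleleAnnotation(**{**deleterious, "gene": "DECOY7"}), qual=50.0),
        # homozygous difference (copy delta 2): not a discordant call
        _variant(cohort, "chr1", 1_000_800, "C", "G", "T01_A1",
                 AlleleAnnotation(**{**deleterious, "gene": "DECOY8"}),
                 carrier_gt=(1, 1)),
    ]
    variants.extend(decoys)
    variants.sort(key=lambda v: (v.chrom, v.pos))

    ex = SnvExample(cohort=cohort, variants=variants)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ex.vcf_path = out_dir / "example_cohort.vcf"
        ex.pairs_path = out_dir / "example_pairs.tsv"
        write_annotated_vcf(ex.vcf_path, variants, cohort.sample_ids)
        cohort.to_tsv(ex.pairs_path)
    return ex


#: the four expected rare discordant CNVs:
#: (chrom, start, end, type, pair, carrier, pathogenic)
EXPECTED_CNVS = (
    ("chr3", 195940567, 197638156, "DUP", "T17", "T17_A", True),
    ("chr10", 92847856, 92849207, "DEL", "T02", "T02_A", False),
    ("chr12", 120201498, 120204299, "DEL", "T16", "T16_A", False),
    ("chr19", 11261852, 11262999, "DEL", "T01", "T01_A1", False),
)

EXPECTED_CNV_LENGTHS = (1_697_589, 1_351, 2_801, 1_147)


@dataclass
class CnvExample:
    cohort: Cohort
    calls_by_pair: dict[str, list[CnvCall]]
    common_db: list[DatabaseCnvRecord]
    pathogenic_db: list[DatabaseCnvRecord]
    risk_list: list[DatabaseCnvRecord]


def cnv_example() -> CnvExample:
    """Build the CNV worked example (calls, databases, risk list)."""
    cohort = example_cohort()
    calls: dict[str, list[CnvCall]] = {p.pair_id: [] for p in cohort}

    for chrom, start, end, ctype, pair_id, carrier, _path in EXPECTED_CNVS:
        for caller in ("caller1", "caller2"):
            calls[pair_id].append(CnvCall(chrom, start, end, ctype, caller, carrier))

    # decoy: present in both twins of T07 (two callers each)
    for s in cohort.pair("T07").sample_ids:
        for caller in ("caller1", "caller2"):
            calls["T07"].append(CnvCall("chr5", 1_000_000, 1_050_000, "DEL", caller, s))
    # decoy: affected-only two-caller CNV fully matching a 2%-frequency record
    for caller in ("caller1", "caller3"):
        calls["T10"].append(CnvCall("chr6", 2_000_000, 2_080_000, "DUP", caller, "T10_A"))
    # decoy: single caller, single sample
    calls["T09"].append(CnvCall("chr7", 3_000_000, 3_020_000, "DEL", "caller4", "T09_A"))
    # risk-locus duplication carried by both twins of T09
    for s in cohort.pair("T09").sample_ids:
        for caller in ("caller1", "caller2"):
            calls["T09"].append(CnvCall("chr13", 20_200_000, 20_420_000, "DUP", caller, s))

    common_db = [
        DatabaseCnvRecord("chr6", 2_000_000, 2_080_000, type="DUP", frequency=0.02, label="common"),
        # near-miss: only ~40% reciprocal overlap with the chr12 deletion
        DatabaseCnvRecord("chr12", 120_203_179, 120_205_980, type="DEL", frequency=0.05, label="common"),
    ]
    pathogenic_db = [
        DatabaseCnvRecord(
            "chr3", 195_900_000, 197_700_000, label="pathogenic",
            phenotype_tags=frozenset({"neurodevelopmental", "autism"}),
        ),
        DatabaseCnvRecord(
            "chr1", 10_000_000, 10_100_000, label="pathogenic",
            phenotype_tags=frozenset({"cardiac"}),
        ),
    ]
    risk_list = [
        DatabaseCnvRecord("chr13", 20_200_000, 20_420_000, type="DUP", label="other"),
    ]
    return CnvExample(cohort, calls, common_db, pathogenic_db, risk_list)
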