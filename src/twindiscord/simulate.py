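"""Synthetic twin-cohort generator with known ground truth.

Emulates the statistical structure of a jointly-genotyped MZ twin
cohort at desk scale: twins share germline genotypes drawn at
population allele frequencies; a small fraction of per-sample variants
(default 1%, the discordance level reported for blood WGS of MZ twins)
is planted as post-zygotic discordant sites where one twin carries
exactly one extra alternate-allele copy; genotypes are perturbed by a
0.1% per-genotype error process mimicking short-read sequencing error;
QUAL/GQ/DP fields span the quality-filter thresholds so the QC stage
has real work to do.  Companion generators emit multi-caller CNV call
sets with breakpoint jitter and caller dropout plus database tables
exercising the 50% reciprocal-overlap rule on both sides of the
threshold, regulatory feature tracks, and repeat-count tables.

Every generator is deterministic given its config seed, and returns a
truth table recording what was planted and what the analysis is
expected to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .burden import FeatureTrack
from .cnv import CnvCall, DatabaseCnvRecord
from .repeats import DEFAULT_THRESHOLDS, RepeatGenotype
from .types import (
    AlleleAnnotation,
    AnnotatedVariant,
    Cohort,
    GenotypeCall,
    TwinPair,
)
from .vcf_io import write_annotated_vcf

#: synthetic reference: three desk-scale contigs
CONTIGS: dict[str, int] = {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000}

_BASES = np.array(["A", "C", "G", "T"])

TRACK_NAMES = (
    "promoter",
    "enhancer",
    "dnase",
    "tf_binding",
    "ctcf",
    "h3k27ac",
    "open_chromatin",
    "brain_enhancer",
)


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the twin-study setting: 17 pairs, ~1% of per-sample
    variants discordant, 0.1% genotype error.  ``n_shared_variants`` is
    the per-pair germline variant count, kept at desk scale.
    """

    n_pairs: int = 17
    n_shared_variants: int = 2000
    discordant_fraction: float = 0.01
    genotype_error_rate: float = 0.001
    qual_distribution: dict = field(
        default_factory=lambda: {"low_fraction": 0.05, "low": (20.0, 99.0), "high": (100.0, 3000.0)}
    )
    gq_dp_distribution: dict = field(
        default_factory=lambda: {
            "low_gq_fraction": 0.02,
            "gq": (40, 99),
            "gq_low": (0, 19),
            "dp_mean": 30,
            "low_dp_fraction": 0.02,
        }
    )
    annotation_profile: dict = field(
        default_factory=lambda: {
            "coding": 0.05,
            "regulatory": 0.10,
            "deleterious_given_coding": 0.3,
            "multiallelic_fraction": 0.02,
            "n_prioritizable": 4,
            "n_regulatory_hits": 1,
        }
    )
    seed: int = 0
    broad_fraction: float = 0.3  # co-twin has MDD (broad discordance class)
    # CNV generator conditions
    n_cnvs_per_pair: int = 3
    cnv_discordant_fraction: float = 0.5
    cnv_jitter_sd: float = 50.0
    cnv_dropout: float = 0.25
    cnv_false_positives_per_caller: int = 2
    # track / repeat generator conditions
    n_tracks: int = 8
    n_repeat_loci: int = 16

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        _check_prob("discordant_fraction", self.discordant_fraction)
        _check_prob("genotype_error_rate", self.genotype_error_rate)
        _check_prob("broad_fraction", self.broad_fraction)
        _check_prob("cnv_discordant_fraction", self.cnv_discordant_fraction)
        _check_prob("cnv_dropout", self.cnv_dropout)
        _check_prob("qual low_fraction", self.qual_distribution.get("low_fraction", 0.0))
        for k in ("coding", "regulatory", "deleterious_given_coding", "multiallelic_fraction"):
            _check_prob(f"annotation_profile[{k}]", self.annotation_profile.get(k, 0.0))


@dataclass
class TruthTable:
    """Ground truth for one generated cohort.

    ``discordant`` rows are keyed by (carrier sample, chrom, pos, alt);
    ``expected_cascade`` marks variants planted to survive the coding or
    regulatory prioritization route.  ``cnvs`` carries the expected fate
    of every planted CNV under the consensus rules; ``repeat_flags``
    lists forced above-threshold repeat genotypes.
    """

    discordant: pd.DataFrame = field(default_factory=pd.DataFrame)
    cnvs: pd.DataFrame = field(default_factory=pd.DataFrame)
    repeat_flags: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if len(self.discordant.columns):
            self.discordant.to_csv(out_dir / "truth_discordant.tsv", sep="\t", index=False)
        if len(self.cnvs.columns):
            self.cnvs.to_csv(out_dir / "truth_cnvs.tsv", sep="\t", index=False)
        if len(self.repeat_flags.columns):
            self.repeat_flags.to_csv(out_dir / "truth_repeats.tsv", sep="\t", index=False)


def make_cohort(config: CohortConfig) -> Cohort:
    """Build the synthetic pair structure (ids T01.., affected twin _A)."""
    rng = np.random.default_rng([config.seed, 101])
    pairs = []
    for i in range(1, config.n_pairs + 1):
        pid = f"T{i:02d}"
        affected_dx = str(rng.choice(["SCZ", "SAD", "BD"]))
        co_dx = "MDD" if rng.random() < config.broad_fraction else "None"
        a, u = f"{pid}_A", f"{pid}_U"
        pairs.append(
            TwinPair(
                pair_id=pid,
                twin1_id=a,
                twin2_id=u,
                affected_id=a,
                diagnoses={a: affected_dx, u: co_dx},
            )
        )
    return Cohort(pairs)


@dataclass
class SnvCohortSim:
    variants: list[AnnotatedVariant]
    cohort: Cohort
    truth: TruthTable
    vcf_path: Optional[Path] = None


def _chrom_order(chrom: str) -> int:
    return list(CONTIGS).index(chrom)


def _draw_sites(rng: np.random.Generator, n: int, used: set) -> list[tuple[str, int]]:
    """Draw n unique (chrom, pos) not colliding with ``used``."""
    sites = []
    chroms = list(CONTIGS)
    while len(sites) < n:
        c = chroms[int(rng.integers(len(chroms)))]
        p = int(rng.integers(1, CONTIGS[c]))
        if (c, p) in used:
            continue
        used.add((c, p))
        sites.append((c, p))
    return sites


def _neutral_annotation(rng: np.random.Generator, profile: dict) -> AlleleAnnotation:
    """Annotation bundle for a background (shared or unplanted) allele."""
    u = rng.random()
    coding_p = profile.get("coding", 0.05)
    reg_p = profile.get("regulatory", 0.10)
    if u < coding_p:
        deleterious = rng.random() < profile.get("deleterious_given_coding", 0.3)
        return AlleleAnnotation(
            gene=f"GENE{int(rng.integers(1, 500)):03d}",
            impact="MODERATE" if deleterious else "LOW",
            csq_class="missense_variant" if deleterious else "synonymous_variant",
            sift_class="deleterious" if deleterious else "tolerated",
            polyphen_class="probably_damaging" if deleterious else "benign",
        )
    if u < coding_p + reg_p:
        return AlleleAnnotation(
            impact="MODIFIER",
            csq_class="regulatory_region_variant",
            cadd_phred=float(np.round(rng.uniform(0.1, 35.0), 2)),
            regdb_rank=int(rng.integers(1, 8)),
        )
    return AlleleAnnotation(
        impact="MODIFIER",
        csq_class="intron_variant",
        cadd_phred=float(np.round(rng.uniform(0.1, 15.0), 2)),
    )


def generate_snv_cohort(
    config: CohortConfig, out_dir: Optional[str | Path] = None
) -> SnvCohortSim:
    """Generate the jointly-called multi-sample VCF and its truth table.

    Twins share germline genotypes at every shared site; each pair
    additionally receives ``Binomial(n_shared_variants,
    discordant_fraction)`` planted discordant sites at which the carrier
    twin holds exactly one extra alternate copy.  Genotype errors flip
    one allele copy with probability ``genotype_error_rate`` per written
    genotype.  Planted discordant sites are emitted with passing
    QUAL/GQ/DP so that, absent genotype errors, the detector's recovery
    of the truth table is exact; shared sites span the QC thresholds.

    When ``out_dir`` is given, writes ``cohort.vcf``, ``pairs.tsv`` and
    the truth tables there.
    """
    rng = np.random.default_rng([config.seed, 202])
    cohort = make_cohort(config)
    samples = cohort.sample_ids
    profile = config.annotation_profile
    qd = config.qual_distribution
    gd = config.gq_dp_distribution

    used_sites: set[tuple[str, int]] = set()
    pool_size = max(1, math.ceil(config.n_shared_variants * 1.5))
    pool_sites = _draw_sites(rng, pool_size, used_sites)

    pool = []
    for (chrom, pos) in pool_sites:
        ref = str(_BASES[int(rng.integers(4))])
        others = [b for b in _BASES if b != ref]
        multi = rng.random() < profile.get("multiallelic_fraction", 0.0)
        n_alt = 2 if multi else 1
        alts = tuple(rng.choice(others, size=n_alt, replace=False))
        af = float(np.round(np.clip(rng.beta(0.5, 2.0), 0.001, 0.999), 4))
        anns = tuple(
            AlleleAnnotation(
                **{
                    **_neutral_annotation(rng, profile).__dict__,
                    "af_1kg": af,
                    "af_gnomad": float(np.round(np.clip(af * rng.uniform(0.8, 1.2), 0.0001, 0.9999), 4)),
                }
            )
            for _ in alts
        )
        pool.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alts, "af": af, "ann": anns})

    # pair -> germline genotype per selected pool site (twins identical)
    genotypes: dict[int, dict[str, tuple[int, int]]] = {i: {} for i in range(len(pool))}
    for pair in cohort:
        chosen = rng.choice(len(pool), size=min(config.n_shared_variants, len(pool)), replace=False)
        for i in chosen:
            site = pool[int(i)]
            alt_idx = 1 + int(rng.integers(len(site["alt"])))
            q = site["af"]
            p_het = 2 * (1 - q) / (2 * (1 - q) + q)  # HWE conditioned on non-ref
            gt = (0, alt_idx) if rng.random() < p_het else (alt_idx, alt_idx)
            genotypes[int(i)][pair.pair_id] = gt

    # planted discordant variants
    truth_rows = []
    planted = []
    n_prior = int(profile.get("n_prioritizable", 0))
    n_reg = int(profile.get("n_regulatory_hits", 0))
    special: list[tuple[str, str]] = []  # (pair_id, cascade) assignments
    for k, pair in enumerate(cohort.pairs):
        if k < n_prior:
            special.append((pair.pair_id, "coding"))
        elif k < n_prior + n_reg:
            special.append((pair.pair_id, "regulatory"))
    special_map = dict(special)

    for pair in cohort:
        # per-twin planting: each sample's discordant-variant count is
        # Binomial(n_shared_variants, discordant_fraction), so the
        # per-sample discordance level matches discordant_fraction
        per_twin = {
            s: int(rng.binomial(config.n_shared_variants, config.discordant_fraction))
            for s in pair.sample_ids
        }
        cascade_left = [special_map[pair.pair_id]] if pair.pair_id in special_map else []
        if cascade_left and config.discordant_fraction > 0:
            cascade_carrier = (
                pair.affected_id if cascade_left[0] == "coding" else pair.twin1_id
            )
            per_twin[cascade_carrier] = max(1, per_twin[cascade_carrier])
        carriers = [s for s, n in per_twin.items() for _ in range(n)]
        sites = _draw_sites(rng, len(carriers), used_sites)
        for (chrom, pos), carrier in zip(sites, carriers):
            ref = str(_BASES[int(rng.integers(4))])
            alt = str(rng.choice([b for b in _BASES if b != ref]))
            cascade = ""
            if cascade_left:
                wants = (
                    pair.affected_id if cascade_left[0] == "coding" else pair.twin1_id
                )
                if carrier == wants:
                    cascade = cascade_left.pop(0)
            if cascade == "coding":
                ann = AlleleAnnotation(
                    gene=f"PZGENE_{pair.pair_id}",
                    impact="MODERATE",
                    csq_class="missense_variant",
                    sift_class="deleterious",
                    polyphen_class="probably_damaging",
                )
            elif cascade == "regulatory":
                ann = AlleleAnnotation(
                    impact="MODIFIER",
                    csq_class="regulatory_region_variant",
                    cadd_phred=float(np.round(rng.uniform(22.0, 35.0), 2)),
                    regdb_rank=int(rng.integers(1, 3)),
                )
            else:
                ann = _neutral_annotation(rng, profile)
            planted.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "pair_id": pair.pair_id,
                    "carrier": carrier,
                    "ann": ann,
                }
            )
            truth_rows.append(
                {
                    "pair_id": pair.pair_id,
                    "carrier": carrier,
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "expected_cascade": cascade,
                }
            )

    # assemble records with quality fields, then apply the error process
    def qual_value(passing: bool) -> float:
        if passing or rng.random() >= qd.get("low_fraction", 0.0):
            lo, hi = qd.get("high", (100.0, 3000.0))
        else:
            lo, hi = qd.get("low", (20.0, 99.0))
        return float(np.round(rng.uniform(lo, hi), 1))

    def gq_dp(passing: bool) -> tuple[int, int]:
        if passing:
            return int(rng.integers(50, 100)), int(rng.integers(20, 41))
        if rng.random() < gd.get("low_gq_fraction", 0.0):
            gq = int(rng.integers(*gd.get("gq_low", (0, 19))))
        else:
            gq = int(rng.integers(*gd.get("gq", (40, 99))))
        if rng.random() < gd.get("low_dp_fraction", 0.0):
            dp = int(rng.integers(0, 10))
        else:
            dp = int(rng.poisson(gd.get("dp_mean", 30))) + 1
        return gq, dp

    def maybe_flip(gt: tuple[int, int]) -> tuple[int, int]:
        if config.genotype_error_rate > 0 and rng.random() < config.genotype_error_rate:
            slot = int(rng.integers(2))
            lst = list(gt)
            lst[slot] = 1 - lst[slot] if lst[slot] in (0, 1) else 0
            return (lst[0], lst[1])
        return gt

    records: list[AnnotatedVariant] = []
    for i, site in enumerate(pool):
        calls = {}
        for pair in cohort:
            base = genotypes[i].get(pair.pair_id, (0, 0))
            for s in pair.sample_ids:
                gq, dp = gq_dp(False)
                calls[s] = GenotypeCall(s, maybe_flip(base), gq=gq, dp=dp)
        records.append(
            AnnotatedVariant(
                chrom=site["chrom"],
                pos=site["pos"],
                ref=site["ref"],
                alt=site["alt"],
                qual=qual_value(False),
                calls=calls,
                annotations=site["ann"],
            )
        )
    for pv in planted:
        calls = {}
        for s in samples:
            base = (0, 1) if s == pv["carrier"] else (0, 0)
            gq, dp = gq_dp(True)
            calls[s] = GenotypeCall(s, maybe_flip(base), gq=gq, dp=dp)
        records.append(
            AnnotatedVariant(
                chrom=pv["chrom"],
                pos=pv["pos"],
                ref=pv["ref"],
                alt=(pv["alt"],),
                qual=qual_value(True),
                calls=calls,
                annotations=(pv["ann"],),
            )
        )

    records.sort(key=lambda v: (_chrom_order(v.chrom), v.pos))
    truth = TruthTable(
        discordant=pd.DataFrame(
            truth_rows,
            columns=["pair_id", "carrier", "chrom", "pos", "ref", "alt", "expected_cascade"],
        )
    )
    sim = SnvCohortSim(variants=records, cohort=cohort, truth=truth)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        sim.vcf_path = out_dir / "cohort.vcf"
        write_annotated_vcf(sim.vcf_path, records, samples, contigs=CONTIGS)
        cohort.to_tsv(out_dir / "pairs.tsv")
        truth.write(out_dir)
    return sim


# ---------------------------------------------------------------------------
# CNV call sets

@dataclass
class CnvSim:
    calls_by_pair: dict[str, list[CnvCall]]
    common_db: list[DatabaseCnvRecord]
    pathogenic_db: list[DatabaseCnvRecord]
    truth: TruthTable
    cohort: Cohort


def generate_cnv_callsets(
    config: CohortConfig,
    n_callers: int = 4,
    out_dir: Optional[str | Path] = None,
    cohort: Optional[Cohort] = None,
) -> CnvSim:
    """Generate per-caller CNV call tables plus database tables.

    Each planted CNV is observed by each caller in each carrying sample
    with probability ``1 - cnv_dropout`` and breakpoints jittered by a
    normal(0, cnv_jitter_sd) offset.  Per caller and pair, false-positive
    single-sample calls are injected.  The common-CNV table contains a
    2%-frequency record fully covering one planted discordant CNV per
    third pair (expected removed), a ~40%-reciprocal decoy record near a
    retained CNV, and unrelated records; the pathogenic table rescues
    one of the common-matched CNVs with a neurodevelopmental phenotype
    and includes a non-matching (cardiac) decoy.

    Planted CNVs are placed in disjoint 1 Mb slots so ROIs never merge
    across distinct planted events.
    """
    if n_callers < 2:
        raise ValueError("n_callers must be >= 2")
    rng = np.random.default_rng([config.seed, 303])
    cohort = cohort or make_cohort(config)
    callers = [f"caller{i + 1}" for i in range(n_callers)]

    slot_size = 1_000_000
    slots = [
        (chrom, s)
        for chrom in CONTIGS
        for s in range(0, CONTIGS[chrom] - slot_size + 1, slot_size)
    ]

    calls_by_pair: dict[str, list[CnvCall]] = {p.pair_id: [] for p in cohort}
    events = []  # classified against the final global databases below
    common_db: list[DatabaseCnvRecord] = []
    pathogenic_db: list[DatabaseCnvRecord] = []

    for pi, pair in enumerate(cohort):
        n_events = config.n_cnvs_per_pair
        n_fp = config.cnv_false_positives_per_caller * n_callers
        slot_idx = rng.choice(len(slots), size=min(n_events + n_fp, len(slots)), replace=False)
        event_slots = [slots[int(i)] for i in slot_idx[:n_events]]
        fp_slots = [slots[int(i)] for i in slot_idx[n_events:]]

        # 1 kb slot margins keep jittered calls inside their own slot
        for ei, (chrom, slot_start) in enumerate(event_slots):
            length = int(rng.integers(20_000, 400_000))
            start = slot_start + 1_000 + int(rng.integers(0, slot_size - length - 2_000))
            end = start + length
            ctype = str(rng.choice(["DEL", "DUP"]))
            discordant = rng.random() < config.cnv_discordant_fraction
            if discordant:
                carrier = pair.affected_id if rng.random() < 0.7 else pair.unaffected_id
                carriers = [carrier]
            else:
                carriers = list(pair.sample_ids)

            support: dict[str, list[str]] = {}
            for s in carriers:
                for caller in callers:
                    if rng.random() < config.cnv_dropout:
                        continue
                    jitter = rng.normal(0, config.cnv_jitter_sd, size=2)
                    js = max(0, start + int(round(jitter[0])))
                    je = max(js + 1, end + int(round(jitter[1])))
                    calls_by_pair[pair.pair_id].append(
                        CnvCall(chrom, js, je, ctype, caller, s)
                    )
                    support.setdefault(s, []).append(caller)

            # database decoys keyed to planted events (every third pair)
            if ei == 0 and pi % 3 == 0 and discordant:
                common_db.append(
                    DatabaseCnvRecord(chrom, start, end, type=ctype, frequency=0.02, label="common")
                )
                if pi % 6 == 0:
                    pathogenic_db.append(
                        DatabaseCnvRecord(
                            chrom, start, end, type=None, label="pathogenic",
                            phenotype_tags=frozenset({"neurodevelopmental"}),
                        )
                    )
            elif ei == 1 and pi % 3 == 1:
                # 40% reciprocal decoy: overlaps 40% of the event, same length
                off = int(0.6 * length)
                common_db.append(
                    DatabaseCnvRecord(
                        chrom, start + off, end + off, type=ctype, frequency=0.02, label="common"
                    )
                )

            events.append(
                {
                    "pair_id": pair.pair_id,
                    "carrier": carriers[0] if discordant else "both",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "type": ctype,
                    "discordant": discordant,
                    "n_support_samples": len(support),
                    "n_support_calls": sum(len(v) for v in support.values()),
                }
            )

        # pure false positives: one caller, one sample, own slot
        for fi, (chrom, slot_start) in enumerate(fp_slots):
            length = int(rng.integers(5_000, 50_000))
            start = slot_start + 1_000 + int(rng.integers(0, slot_size - length - 2_000))
            caller = callers[fi % n_callers]
            sample = str(rng.choice(list(pair.sample_ids)))
            calls_by_pair[pair.pair_id].append(
                CnvCall(chrom, start, start + length, "DEL", caller, sample)
            )

    # unrelated database records in untouched territory (chr3 tail is roomy)
    for _ in range(10):
        chrom = str(rng.choice(list(CONTIGS)))
        start = int(rng.integers(0, CONTIGS[chrom] - 10_000))
        common_db.append(
            DatabaseCnvRecord(chrom, start, start + int(rng.integers(1_000, 10_000)),
                              frequency=float(np.round(rng.uniform(0.01, 0.2), 3)), label="common")
        )
    pathogenic_db.append(
        DatabaseCnvRecord("chr1", 50_000, 60_000, label="pathogenic",
                          phenotype_tags=frozenset({"cardiac"}))
    )

    # expected fate under the consensus rules, evaluated against the
    # complete databases (records built for one pair can overlap another
    # pair's event when slots collide across pairs)
    def _ro_hit(ev, rec) -> bool:
        if ev["chrom"] != rec.chrom:
            return False
        ov = min(ev["end"], rec.end) - max(ev["start"], rec.start)
        return (
            ov > 0
            and ov / (ev["end"] - ev["start"]) >= 0.5
            and ov / (rec.end - rec.start) >= 0.5
        )

    truth_rows = []
    for ev in events:
        common_hit = any(_ro_hit(ev, rec) for rec in common_db if rec.is_common)
        rescued = any(
            _ro_hit(ev, rec)
            for rec in pathogenic_db
            if rec.label == "pathogenic"
            and rec.phenotype_tags & {"psychiatric", "neurodevelopmental"}
        )
        if ev["n_support_calls"] == 0:
            expected = "dropped_out"
        elif ev["n_support_samples"] == 1 and ev["n_support_calls"] == 1:
            expected = "removed_single_caller"
        elif common_hit and rescued:
            expected = "rescued_pathogenic"
        elif common_hit:
            expected = "removed_common"
        elif ev["discordant"]:
            expected = "retained_discordant"
        else:
            expected = "concordant"
        truth_rows.append({**ev, "expected": expected})

    truth = TruthTable(
        cnvs=pd.DataFrame(
            truth_rows,
            columns=["pair_id", "carrier", "chrom", "start", "end", "type", "discordant",
                     "n_support_samples", "n_support_calls", "expected"],
        )
    )
    sim = CnvSim(calls_by_pair, common_db, pathogenic_db, truth, cohort)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = [
            {"chrom": c.chrom, "start": c.start, "end": c.end, "type": c.type,
             "caller": c.caller_id, "sample": c.sample_id, "pair_id": pid}
            for pid, calls in calls_by_pair.items()
            for c in calls
        ]
        pd.DataFrame(rows).to_csv(out_dir / "cnv_calls.tsv", sep="\t", index=False)
        _write_db(out_dir / "cnv_common_db.tsv", common_db)
        _write_db(out_dir / "cnv_pathogenic_db.tsv", pathogenic_db)
        truth.write(out_dir)
    return sim


def _write_db(path: Path, records: Sequence[DatabaseCnvRecord]) -> None:
    rows = [
        {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "type": r.type or ".",
            "freq": "" if r.frequency is None else r.frequency,
            "label": r.label,
            "phenotype": ",".join(sorted(r.phenotype_tags)) or ".",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "type", "freq", "label", "phenotype"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# regulatory tracks and repeat tables

@dataclass
class TracksRepeatsSim:
    tracks: list[FeatureTrack]
    repeat_genotypes: list[RepeatGenotype]
    thresholds: dict[str, int]
    truth: TruthTable
    cohort: Cohort


def generate_tracks_and_repeats(
    config: CohortConfig,
    out_dir: Optional[str | Path] = None,
    cohort: Optional[Cohort] = None,
    forced_expansions: Sequence[tuple[str, str]] = (),
) -> TracksRepeatsSim:
    """Generate regulatory feature tracks and a repeat-count table.

    Tracks are non-overlapping intervals laid out on a coarse grid per
    contig; defaults produce eight named regulatory features.  Repeat
    counts are drawn below each locus threshold, with small within-pair
    jitter producing benign discordances; ``forced_expansions`` pushes
    specific (sample, locus) genotypes strictly above threshold and
    records them in the truth table.
    """
    rng = np.random.default_rng([config.seed, 404])
    cohort = cohort or make_cohort(config)

    names = list(TRACK_NAMES[: config.n_tracks])
    for i in range(len(names), config.n_tracks):
        names.append(f"feature_{i + 1}")
    tracks = []
    for name in names:
        intervals = []
        for chrom, length in CONTIGS.items():
            grid = np.arange(0, length - 5_000, 5_000)
            starts = rng.choice(grid, size=60, replace=False)
            for s in np.sort(starts):
                width = int(rng.integers(200, 2_000))
                intervals.append((chrom, int(s), int(s) + width))
        tracks.append(FeatureTrack(name, intervals))

    loci = list(DEFAULT_THRESHOLDS)[: config.n_repeat_loci]
    for i in range(len(loci), config.n_repeat_loci):
        loci.append(f"LOCUS{i + 1}")
    thresholds = {
        l: DEFAULT_THRESHOLDS.get(l, 50) for l in loci
    }
    forced = set(forced_expansions)
    genotypes: list[RepeatGenotype] = []
    flag_rows = []
    for pair in cohort:
        for locus in loci:
            thr = thresholds[locus]
            base = int(rng.integers(max(1, thr // 5), max(2, int(thr * 0.6))))
            a2 = int(np.clip(base + rng.integers(-2, 3), 1, thr - 1))
            for s in pair.sample_ids:
                jitter = int(rng.poisson(0.3))
                a1 = int(np.clip(base + jitter, 1, thr - 1))
                b2 = int(np.clip(a2 + int(rng.poisson(0.2)), 1, thr - 1))
                if (s, locus) in forced:
                    a1 = thr + int(rng.integers(1, 10))
                    flag_rows.append({"sample": s, "locus": locus, "count": a1, "threshold": thr})
                genotypes.append(RepeatGenotype(s, locus, a1, b2))

    truth = TruthTable(
        repeat_flags=pd.DataFrame(flag_rows, columns=["sample", "locus", "count", "threshold"])
    )
    sim = TracksRepeatsSim(tracks, genotypes, thresholds, truth, cohort)
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "tracks").mkdir(parents=True, exist_ok=True)
        for name, track in zip(names, tracks):
            with open(out_dir / "tracks" / f"{name}.bed", "w") as fh:
                for chrom in CONTIGS:
                    tree = track._trees.get(chrom)
                    if tree is None:
                        continue
                    for iv in sorted(tree):
                        fh.write(f"{chrom}\t{iv.begin}\t{iv.end}\n")
        pd.DataFrame(
            [{"sample": g.sample_id, "locus": g.locus_id,
              "allele1": g.allele1_count, "allele2": g.allele2_count}
             for g in genotypes]
        ).to_csv(out_dir / "repeats.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"locus": l, "threshold": t} for l, t in thresholds.items()]
        ).to_csv(out_dir / "repeat_thresholds.tsv", sep="\t", index=False)
        truth.write(out_dir)
    return sim
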