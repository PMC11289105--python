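"""Within-pair discordant-variant detection (reverse-pairwise analysis).

A site is discordant within a monozygotic twin pair when one twin carries
exactly one more copy of the alternate allele than the co-twin — the
genotype signature expected of a heterozygous post-zygotic mutation.
Detection is symmetric in the twins: carriers are identified regardless
of affectation status, and downstream filters decide whether to restrict
to affected carriers.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .types import AnnotatedVariant, Cohort, DiscordantCall, GenotypeCall, TwinPair


def alt_copy_count(call: GenotypeCall) -> Optional[int]:
    """Number of alternate-allele copies in a biallelic genotype (0/1/2).

    Missing calls return ``None``.  Phase is irrelevant.
    """
    if call.is_missing:
        return None
    return sum(1 for a in call.allele_indices if a == 1)


def detect_discordant(
    variants: Iterable[AnnotatedVariant],
    pair: TwinPair,
    cohort: Optional[Cohort] = None,
) -> list[DiscordantCall]:
    """Emit a :class:`DiscordantCall` for every biallelic site where the
    twins' alternate-copy counts differ by exactly one.

    Sites with any missing twin genotype are skipped (a missing call
    cannot establish a copy delta), as are deltas of 0 or 2.  The carrier
    is the twin with the larger count.
    """
    out: list[DiscordantCall] = []
    for v in variants:
        if not v.is_biallelic:
            raise ValueError(
                f"{v.chrom}:{v.pos}: detect_discordant requires biallelic records; "
                "run split_multiallelic first"
            )
        try:
            c1 = v.calls[pair.twin1_id]
            c2 = v.calls[pair.twin2_id]
        except KeyError as exc:
            raise ValueError(
                f"sample {exc.args[0]} of pair {pair.pair_id} absent from variant file"
            ) from None
        n1, n2 = alt_copy_count(c1), alt_copy_count(c2)
        if n1 is None or n2 is None:
            continue
        if abs(n1 - n2) != 1:
            continue
        carrier = pair.twin1_id if n1 > n2 else pair.twin2_id
        affected = None if pair.affected_id is None else carrier == pair.affected_id
        out.append(
            DiscordantCall(
                variant=v,
                pair_id=pair.pair_id,
                carrier_id=carrier,
                carrier_affected=affected,
            )
        )
    return out


def detect_discordant_cohort(
    variants: Iterable[AnnotatedVariant], cohort: Cohort
) -> list[DiscordantCall]:
    """Run detection for every pair over one pass of the variant stream."""
    variants = list(variants)
    calls: list[DiscordantCall] = []
    for pair in cohort:
        calls.extend(detect_discordant(variants, pair))
    return calls


def summarize_discordance(
    calls: Iterable[DiscordantCall], cohort: Cohort
) -> tuple[pd.DataFrame, dict]:
    """Per-sample discordant-carrier counts plus cohort summary statistics.

    Returns ``(per_sample, summary)`` where ``per_sample`` has one row per
    cohort sample (zero counts included) and ``summary`` holds mean, sample
    standard deviation (n-1 denominator), median, min and max.
    """
    counts = {s: 0 for s in cohort.sample_ids}
    for c in calls:
        if c.carrier_id in counts:
            counts[c.carrier_id] += 1
    per_sample = pd.DataFrame(
        {
            "sample": list(counts),
            "pair_id": [cohort.pair_of(s).pair_id for s in counts],
            "n_discordant": list(counts.values()),
        }
    )
    x = per_sample["n_discordant"].to_numpy(dtype=float)
    summary = {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        "median": float(np.median(x)),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "n_samples": int(len(x)),
    }
    return per_sample, summary


def calls_to_frame(calls: Iterable[DiscordantCall]) -> pd.DataFrame:
    """Tabulate discordant calls (one row per call, annotation columns)."""
    rows = []
    for c in calls:
        a = c.annotation
        rows.append(
            {
                "chrom": c.variant.chrom,
                "pos": c.variant.pos,
                "rsid": a.rsid or ".",
                "ref": c.variant.ref,
                "alt": c.variant.alt[0],
                "pair_id": c.pair_id,
                "carrier": c.carrier_id,
                "carrier_affected": c.carrier_affected,
                "gene": a.gene or ".",
                "impact": a.impact or ".",
                "csq_class": a.csq_class or ".",
                "sift": a.sift_class or ".",
                "polyphen": a.polyphen_class or ".",
                "af_1kg": a.af_1kg,
                "af_gnomad": a.af_gnomad,
                "cadd_phred": a.cadd_phred,
                "regdb_rank": a.regdb_rank,
                "hgvsp": a.hgvsp or ".",
            }
        )
    cols = [
        "chrom", "pos", "rsid", "ref", "alt", "pair_id", "carrier",
        "carrier_affected", "gene", "impact", "csq_class", "sift",
        "polyphen", "af_1kg", "af_gnomad", "cadd_phred", "regdb_rank",
        "hgvsp",
    ]
    return pd.DataFrame(rows, columns=cols)
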