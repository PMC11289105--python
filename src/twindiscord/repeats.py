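"""Repeat-expansion threshold screening.

Per-sample repeat-unit counts (as produced by a short-read repeat
genotyper) are screened against per-locus pathogenic thresholds for the
classic repeat-expansion disorders.  A sample is flagged at a locus when
its larger allele count strictly exceeds the locus threshold.  Within
each twin pair we also list loci where the twins' larger allele counts
differ — sub-threshold discordances worth manual review even when
nothing is flagged.

Shipped thresholds are commonly cited full-mutation repeat counts for 16
disorder loci; they are defaults, not clinical cutoffs, and callers
should supply their own table where it matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .types import Cohort

#: default pathogenic (full-mutation) repeat-count thresholds, by locus.
#: User-overridable placeholders based on commonly cited values.
DEFAULT_THRESHOLDS: dict[str, int] = {
    "HTT": 39,        # Huntington disease
    "FMR1": 200,      # fragile X syndrome
    "DMPK": 50,       # myotonic dystrophy type 1
    "CNBP": 75,       # myotonic dystrophy type 2
    "ATXN1": 44,      # SCA1
    "ATXN2": 34,      # SCA2
    "ATXN3": 60,      # SCA3
    "CACNA1A": 20,    # SCA6
    "ATXN7": 36,      # SCA7
    "ATXN8OS": 80,    # SCA8
    "ATXN10": 800,    # SCA10
    "PPP2R2B": 51,    # SCA12
    "TBP": 49,        # SCA17
    "ATN1": 48,       # DRPLA
    "AR": 38,         # spinal and bulbar muscular atrophy
    "C9orf72": 30,    # C9orf72 ALS/FTD
}


@dataclass(frozen=True)
class RepeatGenotype:
    """One sample's repeat-unit counts at one disorder locus."""

    sample_id: str
    locus_id: str
    allele1_count: int
    allele2_count: int

    def __post_init__(self) -> None:
        if self.allele1_count < 0 or self.allele2_count < 0:
            raise ValueError("repeat counts must be >= 0")

    @property
    def max_count(self) -> int:
        return max(self.allele1_count, self.allele2_count)


@dataclass
class RepeatScreenReport:
    flags: pd.DataFrame        # samples exceeding a locus threshold
    discordances: pd.DataFrame  # within-pair differing max counts


def read_repeat_table(path: str | Path) -> list[RepeatGenotype]:
    """Read a repeat-count table: columns sample locus allele1 allele2."""
    df = pd.read_csv(path, sep="\t")
    return [
        RepeatGenotype(r.sample, r.locus, int(r.allele1), int(r.allele2))
        for r in df.itertuples(index=False)
    ]


def read_thresholds(path: str | Path) -> dict[str, int]:
    """Read a thresholds table: columns locus threshold."""
    df = pd.read_csv(path, sep="\t")
    out = {str(r.locus): int(r.threshold) for r in df.itertuples(index=False)}
    if any(t <= 0 for t in out.values()):
        raise ValueError("thresholds must be positive")
    return out


def screen_repeats(
    genotypes: Iterable[RepeatGenotype],
    cohort: Cohort,
    thresholds: Optional[Mapping[str, int]] = None,
) -> RepeatScreenReport:
    """Flag (sample, locus) with max allele count strictly above threshold
    and list within-pair max-count discordances.

    A genotype at a locus with no threshold is an error: silently
    skipping a disorder locus would invalidate the negative result.
    """
    thresholds = dict(thresholds) if thresholds is not None else dict(DEFAULT_THRESHOLDS)
    genotypes = list(genotypes)
    by_sample_locus: dict[tuple[str, str], RepeatGenotype] = {}
    flag_rows = []
    for g in genotypes:
        if g.locus_id not in thresholds:
            raise ValueError(f"no threshold for locus {g.locus_id}")
        by_sample_locus[(g.sample_id, g.locus_id)] = g
        thr = thresholds[g.locus_id]
        if g.max_count > thr:
            flag_rows.append(
                {
                    "sample": g.sample_id,
                    "locus": g.locus_id,
                    "max_count": g.max_count,
                    "threshold": thr,
                }
            )
    disc_rows = []
    loci = sorted({g.locus_id for g in genotypes})
    for pair in cohort:
        for locus in loci:
            g1 = by_sample_locus.get((pair.twin1_id, locus))
            g2 = by_sample_locus.get((pair.twin2_id, locus))
            if g1 is None or g2 is None:
                continue
            if g1.max_count != g2.max_count:
                disc_rows.append(
                    {
                        "pair_id": pair.pair_id,
                        "locus": locus,
                        "twin1_max": g1.max_count,
                        "twin2_max": g2.max_count,
                        "threshold": thresholds[locus],
                    }
                )
    return RepeatScreenReport(
        flags=pd.DataFrame(flag_rows, columns=["sample", "locus", "max_count", "threshold"]),
        discordances=pd.DataFrame(
            disc_rows,
            columns=["pair_id", "locus", "twin1_max", "twin2_max", "threshold"],
        ),
    )
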