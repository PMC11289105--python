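"""Regulatory-feature burden analysis for discordant variants.

Discordant calls are intersected with regulatory feature tracks (BED
intervals: promoters, enhancers, open chromatin, brain-specific marks,
...).  For each track we count, per twin, the discordant variants whose
carrier is that twin and whose position falls inside the track, then
test whether affected twins systematically carry more (or fewer) such
variants than their unaffected co-twins with a paired Wilcoxon
signed-rank test.

Overlap uses the variant's start position (point overlap) for SNVs and
the reference span for indels; a variant overlapping several intervals
of the same track is counted once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .stats import WilcoxonResult, wilcoxon_signed_rank
from .types import Cohort, DiscordantCall


class FeatureTrack:
    """A named set of genomic intervals (0-based half-open)."""

    def __init__(self, name: str, intervals: Iterable[tuple[str, int, int]]):
        self.name = name
        self._trees: dict[str, IntervalTree] = {}
        n = 0
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(f"{name}: end must exceed start at {chrom}:{start}-{end}")
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)
            n += 1
        self.n_intervals = n

    @classmethod
    def from_bed(cls, path: str | Path, name: Optional[str] = None) -> "FeatureTrack":
        path = Path(path)
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                intervals.append((fields[0], int(fields[1]), int(fields[2])))
        return cls(name or path.stem, intervals)

    def contains(self, chrom: str, start: int, end: Optional[int] = None) -> bool:
        """Whether [start, end) (or the point ``start``) hits any interval."""
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        if end is None or end <= start + 1:
            return bool(tree.at(start))
        return bool(tree.overlap(start, end))

    @property
    def chroms(self) -> set[str]:
        return set(self._trees)


@dataclass(frozen=True)
class PairedCounts:
    """Per-pair (affected, unaffected) overlap counts for one feature."""

    feature: str
    pairs: tuple[tuple[str, int, int], ...]  # (pair_id, affected_count, unaffected_count)

    @property
    def differences(self) -> list[int]:
        return [a - u for _, a, u in self.pairs]


def count_track_overlaps(
    calls: Iterable[DiscordantCall],
    track: FeatureTrack,
    cohort: Cohort,
    known_chroms: Optional[set[str]] = None,
) -> PairedCounts:
    """Count discordant variants overlapping a track, per twin, per pair.

    The affected column counts calls carried by the affected twin, the
    unaffected column calls carried by the co-twin.  Pairs without an
    assigned affected twin are skipped.
    """
    if known_chroms is not None:
        unknown = track.chroms - known_chroms
        if unknown:
            warnings.warn(
                f"track {track.name}: ignoring intervals on unknown contigs "
                f"{sorted(unknown)}"
            )
    counts: dict[str, int] = {s: 0 for s in cohort.sample_ids}
    for c in calls:
        v = c.variant
        start0 = v.pos - 1  # VCF 1-based -> 0-based
        span_end = start0 + len(v.ref)  # reference span; length 1 for SNVs
        if track.contains(v.chrom, start0, span_end if len(v.ref) > 1 else None):
            counts[c.carrier_id] = counts.get(c.carrier_id, 0) + 1
    rows = []
    for pair in cohort:
        if pair.affected_id is None:
            continue
        rows.append(
            (pair.pair_id, counts.get(pair.affected_id, 0), counts.get(pair.unaffected_id, 0))
        )
    return PairedCounts(feature=track.name, pairs=tuple(rows))


def burden_test(
    counts: PairedCounts, zero_method: str = "wilcox"
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on the per-pair count differences."""
    return wilcoxon_signed_rank(counts.differences, zero_method=zero_method)


def burden_table(
    calls: Sequence[DiscordantCall],
    tracks: Sequence[FeatureTrack],
    cohort: Cohort,
    zero_method: str = "wilcox",
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-feature burden table: counts, test statistic and p-value."""
    rows = []
    for track in tracks:
        pc = count_track_overlaps(calls, track, cohort)
        res = burden_test(pc, zero_method=zero_method)
        affected_total = sum(a for _, a, _ in pc.pairs)
        unaffected_total = sum(u for _, _, u in pc.pairs)
        rows.append(
            {
                "feature": track.name,
                "affected_total": affected_total,
                "unaffected_total": unaffected_total,
                "n_effective": res.n_effective,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "method": res.method,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["feature", "affected_total", "unaffected_total",
                 "n_effective", "statistic", "p_value", "method"],
    )
    if bonferroni and len(df):
        df["p_bonferroni"] = (df["p_value"] * len(df)).clip(upper=1.0)
    return df
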