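"""Family-aware consensus CNV calling and prioritization.

Per twin pair, raw calls from multiple CNV callers (both twins pooled)
are union-merged by type into Regions of Interest (ROIs).  ROIs seen in
only one sample by only one caller are discarded as likely artifacts.
Surviving ROIs are filtered against common-CNV databases (gnomAD-SV /
DDD / DGV style tables) at 50% reciprocal overlap; ROIs matching a
"Pathogenic" entry of a ClinGen-style table with a psychiatric or
neurodevelopmental phenotype are rescued regardless of population
frequency (and regardless of DEL/DUP type, since aggregated pathogenic
databases mix calling conventions).  Finally, ROIs present in exactly
one twin are reported as discordant, and all samples are screened
against a user-supplied list of known psychosis-risk CNV loci.

Coordinates are 0-based half-open throughout, so ``length = end - start``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import Cohort, TwinPair

CNV_TYPES = ("DEL", "DUP")


@dataclass(frozen=True)
class CnvCall:
    """One interval from one caller in one sample."""

    chrom: str
    start: int
    end: int
    type: str
    caller_id: str
    sample_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end must exceed start ({self.chrom}:{self.start}-{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ROI:
    """A merged Region of Interest for one pair.

    ``support`` maps each sample that contributed calls to the set of
    callers that called it there; ``present_in`` is its key set.
    """

    chrom: str
    start: int
    end: int
    type: str
    pair_id: str
    support: dict[str, frozenset[str]] = field(default_factory=dict)
    pathogenic: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def present_in(self) -> frozenset[str]:
        return frozenset(s for s, callers in self.support.items() if callers)


@dataclass(frozen=True)
class DatabaseCnvRecord:
    """External CNV database entry (frequency and/or pathogenicity)."""

    chrom: str
    start: int
    end: int
    type: Optional[str] = None
    frequency: Optional[float] = None
    label: str = "other"  # common / pathogenic / benign / other
    phenotype_tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")

    @property
    def is_common(self) -> bool:
        return self.label == "common" or (
            self.frequency is not None and self.frequency >= 0.01
        )


def reciprocal_overlap(a, b) -> tuple[float, float]:
    """Overlap of two intervals as a fraction of each interval's length.

    Returns ``(fraction_of_a, fraction_of_b)``; zero on different
    chromosomes.  Both intervals are 0-based half-open objects with
    ``chrom``/``start``/``end``.
    """
    if a.chrom != b.chrom:
        return (0.0, 0.0)
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return (0.0, 0.0)
    return (ov / (a.end - a.start), ov / (b.end - b.start))


def _passes_reciprocal(a, b, threshold: float) -> bool:
    fa, fb = reciprocal_overlap(a, b)
    return fa >= threshold and fb >= threshold


def build_rois(calls: Sequence[CnvCall], pair: TwinPair) -> list[ROI]:
    """Union-merge a pair's calls (all callers, both twins) into ROIs.

    Calls of the same chromosome and type that overlap by at least 1 bp
    are merged into a single ROI spanning their union, iterated to a
    fixpoint; DEL and DUP never merge.  Support sets record which caller
    saw the region in which sample.
    """
    valid = set(pair.sample_ids)
    for c in calls:
        if c.sample_id not in valid:
            raise ValueError(f"call sample {c.sample_id} not in pair {pair.pair_id}")
    rois: list[ROI] = []
    groups: dict[tuple[str, str], list[CnvCall]] = {}
    for c in calls:
        groups.setdefault((c.chrom, c.type), []).append(c)
    for (chrom, ctype), members in sorted(groups.items()):
        members = sorted(members, key=lambda c: (c.start, c.end))
        cluster: list[CnvCall] = []
        cur_end = None
        for c in members:
            if cur_end is not None and c.start < cur_end:
                cluster.append(c)
                cur_end = max(cur_end, c.end)
            else:
                if cluster:
                    rois.append(_cluster_to_roi(cluster, pair))
                cluster = [c]
                cur_end = c.end
        if cluster:
            rois.append(_cluster_to_roi(cluster, pair))
    return rois


def _cluster_to_roi(cluster: list[CnvCall], pair: TwinPair) -> ROI:
    support: dict[str, set[str]] = {}
    for c in cluster:
        support.setdefault(c.sample_id, set()).add(c.caller_id)
    return ROI(
        chrom=cluster[0].chrom,
        start=min(c.start for c in cluster),
        end=max(c.end for c in cluster),
        type=cluster[0].type,
        pair_id=pair.pair_id,
        support={s: frozenset(v) for s, v in support.items()},
    )


def filter_single_caller_rois(rois: Iterable[ROI]) -> list[ROI]:
    """Drop ROIs found in one sample only *and* by one caller only.

    The rule is conjunctive: a single-sample ROI with two callers, or a
    both-samples ROI with one caller each, is retained.
    """
    out = []
    for r in rois:
        present = r.present_in
        if len(present) == 1 and len(r.support[next(iter(present))]) == 1:
            continue
        out.append(r)
    return out


def filter_common_cnvs(
    rois: Iterable[ROI],
    databases: Sequence[Sequence[DatabaseCnvRecord]],
    threshold: float = 0.5,
    match_type: bool = False,
) -> list[ROI]:
    """Drop ROIs with >= ``threshold`` reciprocal overlap with any common
    database record (frequency >= 1% or labelled common).

    ``match_type`` optionally requires the DEL/DUP type to agree; the
    default matches type-agnostically, consistent with how aggregated
    databases mix calling conventions.
    """
    records = [rec for db in databases for rec in db if rec.is_common]
    if not records:
        warnings.warn("no common-CNV records supplied; common filter is a no-op")
        return list(rois)
    out = []
    for r in rois:
        hit = any(
            (not match_type or rec.type is None or rec.type == r.type)
            and _passes_reciprocal(r, rec, threshold)
            for rec in records
        )
        if not hit:
            out.append(r)
    return out


def rescue_pathogenic(
    rois: Iterable[ROI],
    clingen: Sequence[DatabaseCnvRecord],
    phenotype_filter: frozenset[str] = frozenset({"psychiatric", "neurodevelopmental"}),
    threshold: float = 0.5,
) -> list[ROI]:
    """Flag ROIs with >= 50% reciprocal overlap with a pathogenic record
    whose phenotype tags intersect ``phenotype_filter``.

    DEL/DUP type is deliberately ignored.  Returns the matching ROIs
    with ``pathogenic=True``.
    """
    pathogenic = [r for r in clingen if r.label == "pathogenic"]
    out = []
    for r in rois:
        hit = any(
            rec.phenotype_tags & phenotype_filter and _passes_reciprocal(r, rec, threshold)
            for rec in pathogenic
        )
        if hit:
            out.append(replace(r, pathogenic=True))
    return out


def screen_risk_cnvs(
    rois: Iterable[ROI],
    risk_list: Sequence[DatabaseCnvRecord],
    cohort: Cohort,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Screen every pair's ROIs against known psychosis-risk CNV loci.

    For each (risk locus, pair) with at least one matching ROI, reports
    which twins carry it: ``both_twins``, ``affected_only`` or
    ``unaffected_only``.
    """
    rows = []
    rois = list(rois)
    for rec in risk_list:
        for pair in cohort:
            carriers: set[str] = set()
            for r in rois:
                if r.pair_id != pair.pair_id:
                    continue
                if _passes_reciprocal(r, rec, threshold):
                    carriers |= r.present_in
            if not carriers:
                continue
            if carriers == set(pair.sample_ids):
                status = "both_twins"
            elif pair.affected_id is not None and carriers == {pair.affected_id}:
                status = "affected_only"
            else:
                status = "unaffected_only"
            rows.append(
                {
                    "locus": f"{rec.chrom}:{rec.start}-{rec.end}",
                    "type": rec.type or ".",
                    "pair_id": pair.pair_id,
                    "carriers": ",".join(sorted(carriers)),
                    "status": status,
                }
            )
    return pd.DataFrame(rows, columns=["locus", "type", "pair_id", "carriers", "status"])


def identify_discordant_cnvs(
    rois: Iterable[ROI], cohort: Cohort
) -> list[tuple[ROI, str, Optional[bool]]]:
    """ROIs present in exactly one twin: ``(roi, carrier, carrier_affected)``."""
    out = []
    for r in rois:
        present = r.present_in
        if len(present) != 1:
            continue
        carrier = next(iter(present))
        pair = cohort.pair(r.pair_id)
        affected = None if pair.affected_id is None else carrier == pair.affected_id
        out.append((r, carrier, affected))
    return out


def consensus_pipeline(
    calls_by_pair: dict[str, Sequence[CnvCall]],
    cohort: Cohort,
    common_dbs: Sequence[Sequence[DatabaseCnvRecord]],
    clingen: Sequence[DatabaseCnvRecord] = (),
    threshold: float = 0.5,
    match_type: bool = False,
    phenotype_filter: frozenset[str] = frozenset({"psychiatric", "neurodevelopmental"}),
) -> list[ROI]:
    """Consensus + filtering for the whole cohort.

    Returns high-confidence rare ROIs: union-merged, single-caller/
    single-sample removed, common-database filtered, with pathogenic
    rescues re-added (flagged) even when they match a common record.
    """
    common_records = [rec for db in common_dbs for rec in db if rec.is_common]
    pathogenic_records = [r for r in clingen if r.label == "pathogenic"]
    final: list[ROI] = []
    for pair in cohort:
        calls = calls_by_pair.get(pair.pair_id, ())
        rois = build_rois(list(calls), pair)
        rois = filter_single_caller_rois(rois)
        for r in rois:
            path_hit = any(
                rec.phenotype_tags & phenotype_filter
                and _passes_reciprocal(r, rec, threshold)
                for rec in pathogenic_records
            )
            common_hit = any(
                (not match_type or rec.type is None or rec.type == r.type)
                and _passes_reciprocal(r, rec, threshold)
                for rec in common_records
            )
            if common_hit and not path_hit:
                continue
            final.append(replace(r, pathogenic=path_hit) if path_hit else r)
    return final


# ---------------------------------------------------------------------------
# table I/O (0-based half-open TSVs)

def read_cnv_calls(path: str | Path) -> list[CnvCall]:
    """Read a caller table: columns chrom start end type caller sample."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        CnvCall(
            chrom=r.chrom, start=int(r.start), end=int(r.end),
            type=r.type, caller_id=r.caller, sample_id=r.sample,
        )
        for r in df.itertuples(index=False)
    ]


def read_cnv_database(path: str | Path, one_based: bool = False) -> list[DatabaseCnvRecord]:
    """Read a database table: chrom start end type freq label phenotype.

    ``phenotype`` is a comma-separated tag list; ``one_based`` shifts
    starts down by one for inclusive 1-based inputs.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    shift = 1 if one_based else 0
    out = []
    for r in df.itertuples(index=False):
        tags = getattr(r, "phenotype", "")
        tags = frozenset(t for t in str(tags).split(",") if t and t != "nan" and t != ".")
        freq = getattr(r, "freq", None)
        ctype = getattr(r, "type", None)
        out.append(
            DatabaseCnvRecord(
                chrom=r.chrom,
                start=int(r.start) - shift,
                end=int(r.end),
                type=None if ctype in (None, ".", "nan") or pd.isna(ctype) else ctype,
                frequency=None if freq is None or pd.isna(freq) else float(freq),
                label=str(getattr(r, "label", "other")),
                phenotype_tags=tags,
            )
        )
    return out


def rois_to_frame(
    discordant: Sequence[tuple[ROI, str, Optional[bool]]], cohort: Cohort
) -> pd.DataFrame:
    """Tabulate discordant ROIs in the rare-CNV report layout."""
    rows = []
    for roi, carrier, affected in discordant:
        pair = cohort.pair(roi.pair_id)
        rows.append(
            {
                "chrom": roi.chrom,
                "start": roi.start,
                "end": roi.end,
                "length": roi.length,
                "type": roi.type,
                "sample": carrier,
                "phenotype": pair.diagnoses.get(carrier, "None"),
                "carrier_affected": affected,
                "pathogenic": "Y" if roi.pathogenic else "",
                "callers": ";".join(sorted(roi.support.get(carrier, frozenset()))),
            }
        )
    cols = ["chrom", "start", "end", "length", "type", "sample", "phenotype",
            "carrier_affected", "pathogenic", "callers"]
    return pd.DataFrame(rows, columns=cols)
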