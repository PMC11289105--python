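"""Prioritization cascades for discordant SNVs.

Two routes are applied to the discordant call set:

* **Coding cascade** — retain variants that (i) fall in the coding
  sequence of a protein-coding gene, (ii) have MODERATE or HIGH impact,
  (iii) are called deleterious by SIFT *or* damaging by PolyPhen,
  (iv) have population allele frequency < 1% or absent in both the 1000
  Genomes and gnomAD columns, and (v) are not observed in any other twin
  pair of the cohort (the cohort "privacy" filter).  Only SNVs enter the
  cascade; indels carry no SIFT/PolyPhen scores.  By default only calls
  whose carrier is the affected twin are kept.

* **Regulatory route** — retain discordant variants with a CADD Phred
  score strictly above 20 (top 1% of predicted-deleterious variants
  genome-wide) and a RegulomeDB rank of 1 or 2 (strong regulatory
  evidence).  Carriers are not restricted to affected twins here; the
  report records ``carrier_affected`` instead.

Missing-annotation policy: missing SIFT *and* missing PolyPhen cannot
satisfy (iii) and the call is removed; a missing allele frequency counts
as "absent" and passes (iv); missing CADD or RegulomeDB removes the call
from the regulatory route.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .discordance import alt_copy_count
from .types import Cohort, DiscordantCall, polyphen_is_damaging, sift_is_deleterious


@dataclass(frozen=True)
class PrioritizationConfig:
    """Thresholds for both prioritization routes.

    ``af_max`` applies to each population AF column independently;
    ``cadd_min`` is a strict lower bound; ``regdb_max_rank`` an inclusive
    upper bound on the 1 (best) .. 7 (worst) rank scale.
    """

    af_max: float = 0.01
    cadd_min: float = 20.0
    regdb_max_rank: int = 2
    impact_classes: frozenset[str] = frozenset({"MODERATE", "HIGH"})
    affected_only: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.af_max <= 1):
            raise ValueError("af_max must be in (0, 1]")
        if self.cadd_min < 0:
            raise ValueError("cadd_min must be >= 0")
        if self.regdb_max_rank not in range(1, 8):
            raise ValueError("regdb_max_rank must be in 1..7")


#: filter labels used in the audit trace
F_SNV = "snv_only"
F_CODING = "coding"
F_IMPACT = "impact"
F_DELETERIOUS = "sift_polyphen"
F_FREQUENCY = "allele_frequency"
F_PRIVATE = "private_to_pair"
F_AFFECTED = "affected_carrier"
F_CADD = "cadd"
F_REGDB = "regulomedb"


def _coding_failures(call: DiscordantCall, cfg: PrioritizationConfig) -> list[str]:
    a = call.annotation
    fails = []
    if not call.variant.is_snv:
        fails.append(F_SNV)
    if not a.coding:
        fails.append(F_CODING)
    if a.impact not in cfg.impact_classes:
        fails.append(F_IMPACT)
    if not (sift_is_deleterious(a.sift_class) or polyphen_is_damaging(a.polyphen_class)):
        fails.append(F_DELETERIOUS)
    if (a.af_1kg is not None and a.af_1kg >= cfg.af_max) or (
        a.af_gnomad is not None and a.af_gnomad >= cfg.af_max
    ):
        fails.append(F_FREQUENCY)
    if cfg.affected_only and call.carrier_affected is not True:
        fails.append(F_AFFECTED)
    return fails


def filter_coding_deleterious(
    calls: Iterable[DiscordantCall],
    cfg: PrioritizationConfig = PrioritizationConfig(),
) -> list[DiscordantCall]:
    """Apply cascade filters (i)-(iv) plus the affected-carrier restriction.

    Each filter is a pure per-call predicate, so application order cannot
    change the retained set.
    """
    return [c for c in calls if not _coding_failures(c, cfg)]


def observed_in_other_pair(call: DiscordantCall, cohort: Cohort) -> bool:
    """True if the call's allele is carried by any sample outside its pair.

    Uses the post-masking genotypes stored on the variant itself: any
    sample of another pair with >= 1 alternate copy counts as an
    observation.
    """
    own = set(cohort.pair(call.pair_id).sample_ids)
    for sample_id, gcall in call.variant.calls.items():
        if sample_id in own:
            continue
        n = alt_copy_count(gcall)
        if n is not None and n >= 1:
            return True
    return False


def cohort_privacy_filter(
    calls: Iterable[DiscordantCall], cohort: Cohort
) -> list[DiscordantCall]:
    """Cascade filter (v): drop calls whose allele appears in another pair."""
    return [c for c in calls if not observed_in_other_pair(c, cohort)]


def _regulatory_failures(call: DiscordantCall, cfg: PrioritizationConfig) -> list[str]:
    a = call.annotation
    fails = []
    if a.cadd_phred is None or not a.cadd_phred > cfg.cadd_min:
        fails.append(F_CADD)
    if a.regdb_rank is None or a.regdb_rank > cfg.regdb_max_rank:
        fails.append(F_REGDB)
    return fails


def filter_regulatory(
    calls: Iterable[DiscordantCall],
    cfg: PrioritizationConfig = PrioritizationConfig(),
) -> list[DiscordantCall]:
    """Regulatory route: CADD strictly above threshold and RegulomeDB rank
    within bound; a missing score on either axis removes the call."""
    return [c for c in calls if not _regulatory_failures(c, cfg)]


@dataclass
class CascadeResult:
    """Retained calls plus a per-rejected-call audit trace."""

    retained: list[DiscordantCall]
    trace: list[tuple[DiscordantCall, list[str]]] = field(default_factory=list)

    @property
    def removed(self) -> list[DiscordantCall]:
        return [c for c, _ in self.trace]


def prioritize_coding(
    calls: Sequence[DiscordantCall],
    cohort: Cohort,
    cfg: PrioritizationConfig = PrioritizationConfig(),
) -> CascadeResult:
    """Full coding cascade (i)-(v) with an audit trace of removals."""
    retained, trace = [], []
    for c in calls:
        fails = _coding_failures(c, cfg)
        if not fails and observed_in_other_pair(c, cohort):
            fails = [F_PRIVATE]
        if fails:
            trace.append((c, fails))
        else:
            retained.append(c)
    return CascadeResult(retained=retained, trace=trace)


def prioritize_regulatory(
    calls: Sequence[DiscordantCall],
    cfg: PrioritizationConfig = PrioritizationConfig(),
) -> CascadeResult:
    """Regulatory route with audit trace; carriers are not restricted."""
    retained, trace = [], []
    for c in calls:
        fails = _regulatory_failures(c, cfg)
        (trace if fails else retained).append((c, fails) if fails else c)
    return CascadeResult(retained=retained, trace=trace)
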