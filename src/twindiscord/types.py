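"""Core domain types for the twin discordant-variant pipeline.

The analysis operates on monozygotic (MZ) twin pairs discordant for a
psychotic disorder.  Twins share their germline genome, so any site where
one twin carries exactly one more copy of an allele than the co-twin is a
candidate post-zygotic (de novo, post-fertilization) event.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

DIAGNOSES = ("SCZ", "SAD", "BD", "MDD", "None")

#: consequence classes counted as protein-coding sequence changes
CODING_CLASSES = frozenset(
    {
        "missense_variant",
        "synonymous_variant",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift_variant",
        "inframe_insertion",
        "inframe_deletion",
        "protein_altering_variant",
        "coding_sequence_variant",
        "incomplete_terminal_codon_variant",
        "stop_retained_variant",
    }
)

_SIFT_DELETERIOUS = {"deleterious", "deleterious_low_confidence", "d"}
_POLYPHEN_DAMAGING = {"probably_damaging", "possibly_damaging", "damaging", "d"}


def sift_is_deleterious(label: Optional[str]) -> bool:
    """True if a SIFT class string denotes a deleterious call.

    Accepts full class names and the single-letter dialect (``D``/``T``),
    case-insensitively.
    """
    if label is None:
        return False
    return label.strip().lower() in _SIFT_DELETERIOUS


def polyphen_is_damaging(label: Optional[str]) -> bool:
    """True if a PolyPhen class string denotes a damaging call
    (probably/possibly damaging, or the single-letter ``D`` dialect)."""
    if label is None:
        return False
    return label.strip().lower() in _POLYPHEN_DAMAGING


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's diploid genotype at a site, with its quality metrics.

    ``allele_indices`` is a pair of allele indices into [ref] + alts, or
    ``None`` for a missing call.  Phase is discarded: ``0|1`` and ``0/1``
    are the same call.
    """

    sample_id: str
    allele_indices: Optional[tuple[int, int]] = None
    gq: Optional[float] = None
    dp: Optional[int] = None

    @property
    def is_missing(self) -> bool:
        return self.allele_indices is None

    def masked(self) -> "GenotypeCall":
        """Return the same call with the genotype set to missing."""
        return replace(self, allele_indices=None)


@dataclass(frozen=True)
class AlleleAnnotation:
    """Functional annotation bundle for one alternate allele.

    Fields mirror what a VEP-style annotator provides: gene symbol,
    impact class, consequence class, SIFT/PolyPhen deleteriousness,
    population allele frequencies, CADD Phred score and RegulomeDB rank.
    Any field may be missing (``None``).
    """

    gene: Optional[str] = None
    impact: Optional[str] = None  # HIGH / MODERATE / LOW / MODIFIER
    csq_class: Optional[str] = None
    sift_class: Optional[str] = None
    polyphen_class: Optional[str] = None
    af_1kg: Optional[float] = None
    af_gnomad: Optional[float] = None
    cadd_phred: Optional[float] = None
    regdb_rank: Optional[int] = None  # 1..7, 1-2 = strong regulatory evidence
    hgvsp: Optional[str] = None
    rsid: Optional[str] = None

    @property
    def coding(self) -> bool:
        return self.csq_class in CODING_CLASSES


@dataclass(frozen=True)
class AnnotatedVariant:
    """One site from a jointly-genotyped multi-sample variant file.

    ``pos`` is 1-based.  ``annotations`` is keyed per alternate allele
    (``annotations[i]`` describes ``alt[i]``).
    """

    chrom: str
    pos: int
    ref: str
    alt: tuple[str, ...]
    qual: Optional[float]
    calls: dict[str, GenotypeCall]
    annotations: tuple[AlleleAnnotation, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt) == 1

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """(chrom, pos, ref, alt) identity key; biallelic records only."""
        if not self.is_biallelic:
            raise ValueError("key is defined for biallelic records only")
        return (self.chrom, self.pos, self.ref, self.alt[0])


@dataclass(frozen=True)
class TwinPair:
    """A monozygotic twin pair with affectation labels.

    ``discordance_class`` is 'broad' when the co-twin also carries a
    diagnosis (MDD, treated as unaffected for the psychosis phenotype)
    and 'narrow' when the co-twin has none.
    """

    pair_id: str
    twin1_id: str
    twin2_id: str
    affected_id: Optional[str] = None
    diagnoses: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.twin1_id == self.twin2_id:
            raise ValueError(f"pair {self.pair_id}: twins must have distinct ids")
        if self.affected_id is not None and self.affected_id not in (
            self.twin1_id,
            self.twin2_id,
        ):
            raise ValueError(
                f"pair {self.pair_id}: affected_id {self.affected_id!r} not in pair"
            )

    @property
    def sample_ids(self) -> tuple[str, str]:
        return (self.twin1_id, self.twin2_id)

    @property
    def unaffected_id(self) -> Optional[str]:
        if self.affected_id is None:
            return None
        return self.twin2_id if self.affected_id == self.twin1_id else self.twin1_id

    @property
    def discordance_class(self) -> Optional[str]:
        co = self.unaffected_id
        if co is None:
            return None
        return "broad" if self.diagnoses.get(co, "None") == "MDD" else "narrow"

    def co_twin(self, sample_id: str) -> str:
        if sample_id == self.twin1_id:
            return self.twin2_id
        if sample_id == self.twin2_id:
            return self.twin1_id
        raise KeyError(f"{sample_id} not in pair {self.pair_id}")


class Cohort:
    """An ordered collection of twin pairs with sample->pair lookup."""

    def __init__(self, pairs: Iterable[TwinPair]):
        self.pairs: list[TwinPair] = list(pairs)
        if not self.pairs:
            raise ValueError("cohort must contain at least one pair")
        self._by_sample: dict[str, TwinPair] = {}
        self._by_id: dict[str, TwinPair] = {}
        for p in self.pairs:
            if p.pair_id in self._by_id:
                raise ValueError(f"duplicate pair id {p.pair_id}")
            self._by_id[p.pair_id] = p
            for s in p.sample_ids:
                if s in self._by_sample:
                    raise ValueError(f"sample {s} appears in more than one pair")
                self._by_sample[s] = p

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def sample_ids(self) -> list[str]:
        return [s for p in self.pairs for s in p.sample_ids]

    def pair_of(self, sample_id: str) -> TwinPair:
        return self._by_sample[sample_id]

    def pair(self, pair_id: str) -> TwinPair:
        return self._by_id[pair_id]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Cohort":
        """Load a cohort from a pairs table.

        Expected columns: pair_id, twin1, twin2, affected, twin1_dx,
        twin2_dx (dx columns optional).
        """
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"pair_id", "twin1", "twin2"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"pairs table missing columns: {sorted(missing)}")
        pairs = []
        for row in df.itertuples(index=False):
            dx = {}
            if hasattr(row, "twin1_dx") and isinstance(row.twin1_dx, str):
                dx[row.twin1] = row.twin1_dx
            if hasattr(row, "twin2_dx") and isinstance(row.twin2_dx, str):
                dx[row.twin2] = row.twin2_dx
            affected = getattr(row, "affected", None)
            if not isinstance(affected, str) or not affected:
                affected = None
            pairs.append(
                TwinPair(
                    pair_id=row.pair_id,
                    twin1_id=row.twin1,
                    twin2_id=row.twin2,
                    affected_id=affected,
                    diagnoses=dx,
                )
            )
        return cls(pairs)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for p in self.pairs:
            rows.append(
                {
                    "pair_id": p.pair_id,
                    "twin1": p.twin1_id,
                    "twin2": p.twin2_id,
                    "affected": p.affected_id or "",
                    "twin1_dx": p.diagnoses.get(p.twin1_id, "None"),
                    "twin2_dx": p.diagnoses.get(p.twin2_id, "None"),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class DiscordantCall:
    """A biallelic variant discordant within one twin pair.

    The carrier holds exactly one more copy of the alternate allele than
    the co-twin (copy_delta is always 1 by construction).
    """

    variant: AnnotatedVariant
    pair_id: str
    carrier_id: str
    carrier_affected: Optional[bool]
    copy_delta: int = 1

    def __post_init__(self) -> None:
        if self.copy_delta != 1:
            raise ValueError("copy_delta must be 1")

    @property
    def annotation(self) -> AlleleAnnotation:
        return self.variant.annotations[0]

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.variant.key
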