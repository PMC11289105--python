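"""Reading, quality filtering and normalization of annotated variant files.

Input is a jointly-genotyped multi-sample VCF carrying a flat per-allele
annotation schema in INFO (GENE, IMPACT, CSQ_CLASS, SIFT, POLYPHEN,
AF_1KG, AF_GNOMAD, CADD_PHRED, REGDB_RANK).  A shim for the VEP
pipe-delimited CSQ string is provided for real-world files.

Quality control follows the twin-study protocol:

* sites with QUAL < 100 are removed entirely;
* any genotype with GQ < 20 or DP < 10 is set to missing (the site is
  kept even if every genotype is masked);
* multi-allelic sites are split into biallelic records so each alternate
  allele can be filtered on its own annotations.

Missing QUAL/GQ/DP are treated as failing their filter (conservative).
"""

from __future__ import annotations

import re
from dataclasses import replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from cyvcf2 import VCF

from .types import AlleleAnnotation, AnnotatedVariant, GenotypeCall

ANNOTATION_INFO_KEYS = (
    "GENE",
    "IMPACT",
    "CSQ_CLASS",
    "SIFT",
    "POLYPHEN",
    "AF_1KG",
    "AF_GNOMAD",
    "CADD_PHRED",
    "REGDB_RANK",
    "HGVSP",
)


class VcfParseError(ValueError):
    pass


def _split_per_allele(raw, n_alt: int) -> list[Optional[str]]:
    """Normalize an INFO value into one string slot per alternate allele."""
    if raw is None:
        return [None] * n_alt
    if isinstance(raw, (tuple, list)):
        vals = [None if v is None else str(v) for v in raw]
    else:
        vals = str(raw).split(",")
    vals = [None if v in (None, "", ".") else v for v in vals]
    if len(vals) == 1 and n_alt > 1:
        vals = vals * n_alt
    if len(vals) < n_alt:
        vals = vals + [None] * (n_alt - len(vals))
    return vals[:n_alt]


def _opt_float(v: Optional[str]) -> Optional[float]:
    if v is None:
        return None
    try:
        return float(v)
    except ValueError:
        return None


def _opt_int(v: Optional[str]) -> Optional[int]:
    f = _opt_float(v)
    return None if f is None else int(f)


def read_annotated_vcf(path: str | Path) -> Iterator[AnnotatedVariant]:
    """Yield :class:`AnnotatedVariant` records from a VCF in file order.

    Missing annotation keys become missing fields rather than errors.
    A file without a GT FORMAT declaration is rejected outright.
    """
    path = str(path)
    vcf = VCF(path, gts012=False)
    if 'ID=GT' not in vcf.raw_header:
        raise VcfParseError(f"{path}: no GT FORMAT declared in header")
    samples = list(vcf.samples)
    for lineno, v in enumerate(vcf, start=1):
        try:
            yield _convert_record(v, samples)
        except VcfParseError:
            raise
        except Exception as exc:  # noqa: BLE001 - surface line context
            raise VcfParseError(f"{path}: malformed record #{lineno} "
                                f"({v.CHROM}:{v.POS}): {exc}") from exc
    vcf.close()


def _convert_record(v, samples: Sequence[str]) -> AnnotatedVariant:
    n_alt = len(v.ALT)
    if n_alt == 0:
        raise VcfParseError("record has no alternate allele")
    gq = v.format("GQ")
    dp = v.format("DP")
    calls: dict[str, GenotypeCall] = {}
    for i, s in enumerate(samples):
        g = v.genotypes[i]
        # cyvcf2 genotype row: [allele1, allele2, phased]; -1 marks missing
        if len(g) < 3 or g[0] < 0 or g[1] < 0:
            alleles = None
        else:
            alleles = (int(g[0]), int(g[1]))
        gq_i = None
        if gq is not None:
            val = float(gq[i][0]) if gq[i] is not None else None
            gq_i = val if val is not None and val >= 0 else None
        dp_i = None
        if dp is not None:
            val = int(dp[i][0]) if dp[i] is not None else None
            dp_i = val if val is not None and val >= 0 else None
        calls[s] = GenotypeCall(sample_id=s, allele_indices=alleles, gq=gq_i, dp=dp_i)

    info = {k: _split_per_allele(v.INFO.get(k), n_alt) for k in ANNOTATION_INFO_KEYS}
    rsid = v.ID if v.ID not in (None, ".") else None
    annotations = tuple(
        AlleleAnnotation(
            gene=info["GENE"][k],
            impact=info["IMPACT"][k],
            csq_class=info["CSQ_CLASS"][k],
            sift_class=info["SIFT"][k],
            polyphen_class=info["POLYPHEN"][k],
            af_1kg=_opt_float(info["AF_1KG"][k]),
            af_gnomad=_opt_float(info["AF_GNOMAD"][k]),
            cadd_phred=_opt_float(info["CADD_PHRED"][k]),
            regdb_rank=_opt_int(info["REGDB_RANK"][k]),
            hgvsp=info["HGVSP"][k],
            rsid=rsid,
        )
        for k in range(n_alt)
    )
    return AnnotatedVariant(
        chrom=v.CHROM,
        pos=v.POS,
        ref=v.REF,
        alt=tuple(v.ALT),
        qual=None if v.QUAL is None else float(v.QUAL),
        calls=calls,
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# quality filters

def apply_site_quality_filter(
    variants: Iterable[AnnotatedVariant], qual_min: float = 100.0
) -> Iterator[AnnotatedVariant]:
    """Drop whole sites with QUAL below ``qual_min`` (missing QUAL fails).

    Order-preserving; QUAL exactly at the threshold is retained since the
    removal rule is a strict ``QUAL < qual_min``.
    """
    if qual_min < 0:
        raise ValueError("qual_min must be >= 0")
    for v in variants:
        if v.qual is not None and v.qual >= qual_min:
            yield v


def mask_low_confidence_genotypes(
    variant: AnnotatedVariant, gq_min: float = 20.0, dp_min: float = 10.0
) -> AnnotatedVariant:
    """Set genotypes with GQ < gq_min or DP < dp_min to missing.

    A missing GQ or DP counts as failing.  The site itself is retained
    even when every genotype ends up masked.
    """
    if gq_min < 0 or dp_min < 0:
        raise ValueError("thresholds must be >= 0")
    new_calls = {}
    for s, c in variant.calls.items():
        if c.is_missing:
            new_calls[s] = c
            continue
        fails = (c.gq is None or c.gq < gq_min) or (c.dp is None or c.dp < dp_min)
        new_calls[s] = c.masked() if fails else c
    return replace(variant, calls=new_calls)


def split_multiallelic(variant: AnnotatedVariant) -> list[AnnotatedVariant]:
    """Split a site into one biallelic record per alternate allele.

    Genotypes are recoded against {ref, that alt}: allele indices for any
    other alternate allele contribute 0 copies of the split allele.  The
    total alternate-allele copy count over the split records equals the
    number of non-reference copies in the original.  Biallelic input is
    returned unchanged.
    """
    if variant.is_biallelic:
        return [variant]
    out = []
    for k, alt in enumerate(variant.alt):
        alt_idx = k + 1
        calls = {}
        for s, c in variant.calls.items():
            if c.is_missing:
                calls[s] = c
            else:
                a, b = c.allele_indices
                calls[s] = replace(
                    c,
                    allele_indices=(1 if a == alt_idx else 0, 1 if b == alt_idx else 0),
                )
        out.append(
            replace(
                variant,
                alt=(alt,),
                calls=calls,
                annotations=(variant.annotations[k],),
            )
        )
    return out


def qc_pipeline(
    variants: Iterable[AnnotatedVariant],
    qual_min: float = 100.0,
    gq_min: float = 20.0,
    dp_min: float = 10.0,
) -> Iterator[AnnotatedVariant]:
    """Site QUAL filter -> genotype masking -> multi-allelic split."""
    for v in apply_site_quality_filter(variants, qual_min):
        yield from split_multiallelic(mask_low_confidence_genotypes(v, gq_min, dp_min))


# ---------------------------------------------------------------------------
# VCF writing (used by the synthetic generator and worked examples)

VCF_HEADER_TEMPLATE = """\
##fileformat=VCFv4.2
{contigs}##INFO=<ID=GENE,Number=A,Type=String,Description="Gene symbol">
##INFO=<ID=IMPACT,Number=A,Type=String,Description="Predicted impact class (HIGH/MODERATE/LOW/MODIFIER)">
##INFO=<ID=CSQ_CLASS,Number=A,Type=String,Description="Consequence class (sequence ontology term)">
##INFO=<ID=SIFT,Number=A,Type=String,Description="SIFT class">
##INFO=<ID=POLYPHEN,Number=A,Type=String,Description="PolyPhen class">
##INFO=<ID=AF_1KG,Number=A,Type=Float,Description="1000 Genomes allele frequency">
##INFO=<ID=AF_GNOMAD,Number=A,Type=Float,Description="gnomAD allele frequency">
##INFO=<ID=CADD_PHRED,Number=A,Type=Float,Description="CADD Phred-scaled score">
##INFO=<ID=REGDB_RANK,Number=A,Type=Integer,Description="RegulomeDB rank (1-7)">
##INFO=<ID=HGVSP,Number=A,Type=String,Description="Protein change">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def _fmt_num(x, kind=float) -> str:
    if x is None:
        return "."
    if kind is int:
        return str(int(x))
    return f"{x:.6g}"


def _info_field(variants_ann: Sequence[AlleleAnnotation]) -> str:
    def col(get, kind=None):
        vals = []
        for a in variants_ann:
            v = get(a)
            if v is None:
                vals.append(".")
            elif kind:
                vals.append(_fmt_num(v, kind))
            else:
                vals.append(str(v))
        return ",".join(vals)

    parts = []
    for key, get, kind in (
        ("GENE", lambda a: a.gene, None),
        ("IMPACT", lambda a: a.impact, None),
        ("CSQ_CLASS", lambda a: a.csq_class, None),
        ("SIFT", lambda a: a.sift_class, None),
        ("POLYPHEN", lambda a: a.polyphen_class, None),
        ("AF_1KG", lambda a: a.af_1kg, float),
        ("AF_GNOMAD", lambda a: a.af_gnomad, float),
        ("CADD_PHRED", lambda a: a.cadd_phred, float),
        ("REGDB_RANK", lambda a: a.regdb_rank, int),
        ("HGVSP", lambda a: a.hgvsp, None),
    ):
        val = col(get, kind)
        if set(val.split(",")) != {"."}:
            parts.append(f"{key}={val}")
    return ";".join(parts) if parts else "."


def write_annotated_vcf(
    path: str | Path,
    variants: Sequence[AnnotatedVariant],
    sample_ids: Sequence[str],
    contigs: Optional[dict[str, int]] = None,
) -> None:
    """Serialize records to a plain-text VCF v4.2 with the flat INFO schema."""
    contig_lines = ""
    if contigs:
        contig_lines = "".join(
            f"##contig=<ID={c},length={l}>\n" for c, l in contigs.items()
        )
    header = VCF_HEADER_TEMPLATE.format(
        contigs=contig_lines, samples="\t".join(sample_ids)
    )
    with open(path, "w") as fh:
        fh.write(header)
        for v in variants:
            rsid = v.annotations[0].rsid or "."
            gts = []
            for s in sample_ids:
                c = v.calls[s]
                gt = "./." if c.is_missing else f"{c.allele_indices[0]}/{c.allele_indices[1]}"
                gts.append(
                    f"{gt}:{_fmt_num(c.gq, int)}:{_fmt_num(c.dp, int)}"
                )
            fh.write(
                "\t".join(
                    [
                        v.chrom,
                        str(v.pos),
                        rsid,
                        v.ref,
                        ",".join(v.alt),
                        _fmt_num(v.qual),
                        "PASS",
                        _info_field(v.annotations),
                        "GT:GQ:DP",
                    ]
                    + gts
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VEP CSQ shim

_SCORE_PAREN = re.compile(r"\(([-0-9.eE]+)\)")


def annotations_from_csq(
    csq_value: str,
    csq_format: Sequence[str],
    alt_alleles: Sequence[str],
) -> tuple[AlleleAnnotation, ...]:
    """Build annotation bundles from a VEP pipe-delimited CSQ string.

    ``csq_format`` is the field list from the CSQ header Description
    (e.g. ``["Allele", "Consequence", "IMPACT", "SYMBOL", "SIFT",
    "PolyPhen", "AF", "gnomAD_AF"]``).  The first transcript block
    matching each alternate allele is used; SIFT/PolyPhen values like
    ``deleterious(0.01)`` are stripped to their class.
    """
    idx = {name: i for i, name in enumerate(csq_format)}
    blocks = [b.split("|") for b in csq_value.split(",")]

    def field(block, name):
        i = idx.get(name)
        if i is None or i >= len(block):
            return None
        v = block[i].strip()
        return v or None

    def strip_score(v):
        if v is None:
            return None
        return _SCORE_PAREN.sub("", v) or None

    out = []
    for alt in alt_alleles:
        chosen = None
        for b in blocks:
            if field(b, "Allele") == alt:
                chosen = b
                break
        if chosen is None:
            out.append(AlleleAnnotation())
            continue
        csq = field(chosen, "Consequence")
        out.append(
            AlleleAnnotation(
                gene=field(chosen, "SYMBOL") or field(chosen, "Gene"),
                impact=field(chosen, "IMPACT"),
                csq_class=csq.split("&")[0] if csq else None,
                sift_class=strip_score(field(chosen, "SIFT")),
                polyphen_class=strip_score(field(chosen, "PolyPhen")),
                af_1kg=_opt_float(field(chosen, "AF")),
                af_gnomad=_opt_float(field(chosen, "gnomAD_AF")),
                cadd_phred=_opt_float(field(chosen, "CADD_PHRED")),
                regdb_rank=_opt_int(field(chosen, "RegulomeDB")),
                hgvsp=field(chosen, "HGVSp"),
            )
        )
    return tuple(out)
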