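"""End-to-end pipeline orchestration and report writing.

Stage order follows the analysis protocol: quality control ->
within-pair discordance -> coding prioritization -> regulatory
prioritization -> CNV consensus/filtering/screening -> regulatory
burden testing -> repeat screening.  Every stage is also callable on
its own through the library API or the ``discord`` CLI subcommands.

Outputs are TSV reports: a prioritized-SNV table (chrom, pos, rsid,
ref, alt, sample, phenotype, gene, HGVSp, SIFT, PolyPhen), a rare
discordant CNV table (positions, length = end - start, type, sample,
phenotype, pathogenic flag), the per-sample discordance summary, the
per-feature burden table, the risk-CNV screen and the repeat screen,
plus an audit log of which filter removed each rejected call and a
manifest with input checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import burden as burden_mod
from . import cnv as cnv_mod
from . import repeats as repeats_mod
from .discordance import detect_discordant_cohort, summarize_discordance
from .prioritize import PrioritizationConfig, prioritize_coding, prioritize_regulatory
from .types import Cohort
from .vcf_io import qc_pipeline, read_annotated_vcf


class PipelineError(RuntimeError):
    """A stage failed; the message is tagged with the stage name."""


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run.

    Only the VCF + pairs inputs are mandatory; CNV, track and repeat
    stages run when their inputs are supplied.
    """

    vcf: Optional[str] = None
    pairs: Optional[str] = None
    cnv_calls: Optional[str] = None
    common_dbs: list[str] = field(default_factory=list)
    pathogenic_db: Optional[str] = None
    risk_list: Optional[str] = None
    tracks_dir: Optional[str] = None
    repeats: Optional[str] = None
    repeat_thresholds: Optional[str] = None
    out_dir: str = "discord_out"
    qual_min: float = 100.0
    gq_min: float = 20.0
    dp_min: float = 10.0
    af_max: float = 0.01
    cadd_min: float = 20.0
    regdb_max_rank: int = 2
    cnv_overlap_threshold: float = 0.5
    cnv_match_type: bool = False
    phenotype_filter: tuple[str, ...] = ("psychiatric", "neurodevelopmental")
    zero_method: str = "wilcox"
    bonferroni: bool = False
    markdown: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    discordance_per_sample: Optional[pd.DataFrame] = None
    discordance_summary: Optional[dict] = None
    snv_report: Optional[pd.DataFrame] = None
    regulatory_report: Optional[pd.DataFrame] = None
    filter_trace: Optional[pd.DataFrame] = None
    cnv_report: Optional[pd.DataFrame] = None
    risk_screen: Optional[pd.DataFrame] = None
    burden: Optional[pd.DataFrame] = None
    repeat_flags: Optional[pd.DataFrame] = None
    repeat_discordances: Optional[pd.DataFrame] = None
    manifest: dict = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"[{name}] {exc}") from exc
        return wrapped
    return deco


def _snv_report_frame(calls, cohort: Cohort) -> pd.DataFrame:
    rows = []
    for c in calls:
        a = c.annotation
        pair = cohort.pair(c.pair_id)
        rows.append(
            {
                "chrom": c.variant.chrom,
                "pos": c.variant.pos,
                "rsid": a.rsid or "-",
                "ref": c.variant.ref,
                "alt": c.variant.alt[0],
                "sample": c.carrier_id,
                "phenotype": pair.diagnoses.get(c.carrier_id, "None"),
                "gene": a.gene or ".",
                "hgvsp": a.hgvsp or ".",
                "sift": a.sift_class or ".",
                "polyphen": a.polyphen_class or ".",
                "carrier_affected": c.carrier_affected,
            }
        )
    cols = ["chrom", "pos", "rsid", "ref", "alt", "sample", "phenotype",
            "gene", "hgvsp", "sift", "polyphen", "carrier_affected"]
    return pd.DataFrame(rows, columns=cols)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all configured stages and write reports under ``out_dir``."""
    if config.vcf is None or config.pairs is None:
        raise PipelineError("[config] vcf and pairs inputs are required")
    for p in [config.vcf, config.pairs, config.cnv_calls, config.pathogenic_db,
              config.risk_list, config.repeats, config.repeat_thresholds,
              *config.common_dbs]:
        if p is not None and not Path(p).exists():
            raise PipelineError(f"[config] input not found: {p}")

    result = PipelineResult()
    inputs = [config.vcf, config.pairs, *config.common_dbs]
    for p in (config.cnv_calls, config.pathogenic_db, config.risk_list,
              config.repeats, config.repeat_thresholds):
        if p:
            inputs.append(p)
    result.manifest = {
        "inputs": {str(p): _sha256(p) for p in inputs},
        "seed": config.seed,
    }

    cohort = _stage("pairs")(Cohort.from_tsv)(config.pairs)
    prio_cfg = PrioritizationConfig(
        af_max=config.af_max, cadd_min=config.cadd_min,
        regdb_max_rank=config.regdb_max_rank,
    )

    # QC -> discordance -> prioritization
    @_stage("qc+discordance")
    def _detect():
        variants = qc_pipeline(
            read_annotated_vcf(config.vcf),
            qual_min=config.qual_min, gq_min=config.gq_min, dp_min=config.dp_min,
        )
        return detect_discordant_cohort(variants, cohort)

    calls = _detect()
    per_sample, summary = summarize_discordance(calls, cohort)
    result.discordance_per_sample = per_sample
    result.discordance_summary = summary

    coding = _stage("coding-prioritization")(prioritize_coding)(calls, cohort, prio_cfg)
    result.snv_report = _snv_report_frame(coding.retained, cohort)
    trace_rows = [
        {"chrom": c.variant.chrom, "pos": c.variant.pos, "alt": c.variant.alt[0],
         "pair_id": c.pair_id, "carrier": c.carrier_id,
         "filter_trace": ";".join(fails)}
        for c, fails in coding.trace
    ]
    result.filter_trace = pd.DataFrame(
        trace_rows, columns=["chrom", "pos", "alt", "pair_id", "carrier", "filter_trace"]
    )

    regulatory = _stage("regulatory-prioritization")(prioritize_regulatory)(calls, prio_cfg)
    result.regulatory_report = _snv_report_frame(regulatory.retained, cohort)

    # CNV consensus
    if config.cnv_calls:
        @_stage("cnv-consensus")
        def _cnv():
            all_calls = cnv_mod.read_cnv_calls(config.cnv_calls)
            by_pair: dict[str, list] = {}
            for c in all_calls:
                by_pair.setdefault(cohort.pair_of(c.sample_id).pair_id, []).append(c)
            common = [cnv_mod.read_cnv_database(p) for p in config.common_dbs]
            clingen = (
                cnv_mod.read_cnv_database(config.pathogenic_db)
                if config.pathogenic_db else []
            )
            rois = cnv_mod.consensus_pipeline(
                by_pair, cohort, common, clingen,
                threshold=config.cnv_overlap_threshold,
                match_type=config.cnv_match_type,
                phenotype_filter=frozenset(config.phenotype_filter),
            )
            discordant = cnv_mod.identify_discordant_cnvs(rois, cohort)
            report = cnv_mod.rois_to_frame(discordant, cohort)
            screen = None
            if config.risk_list:
                risk = cnv_mod.read_cnv_database(config.risk_list)
                screen = cnv_mod.screen_risk_cnvs(
                    rois, risk, cohort, threshold=config.cnv_overlap_threshold
                )
            return report, screen

        result.cnv_report, result.risk_screen = _cnv()

    # regulatory burden
    if config.tracks_dir:
        @_stage("burden")
        def _burden():
            tracks = [
                burden_mod.FeatureTrack.from_bed(p)
                for p in sorted(Path(config.tracks_dir).glob("*.bed"))
            ]
            return burden_mod.burden_table(
                calls, tracks, cohort,
                zero_method=config.zero_method, bonferroni=config.bonferroni,
            )

        result.burden = _burden()

    # repeat screen
    if config.repeats:
        @_stage("repeat-screen")
        def _repeats():
            genotypes = repeats_mod.read_repeat_table(config.repeats)
            thresholds = (
                repeats_mod.read_thresholds(config.repeat_thresholds)
                if config.repeat_thresholds else None
            )
            return repeats_mod.screen_repeats(genotypes, cohort, thresholds)

        rep = _repeats()
        result.repeat_flags = rep.flags
        result.repeat_discordances = rep.discordances

    write_reports(result, config)
    return result


def write_reports(result: PipelineResult, config: PipelineConfig) -> list[Path]:
    """Write all available result tables as TSV (plus optional markdown)."""
    out = Path(config.out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise PipelineError(f"[reports] output dir not writable: {exc}") from exc

    written: list[Path] = []

    def emit(df: Optional[pd.DataFrame], name: str):
        if df is None:
            return
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    emit(result.discordance_per_sample, "discordance_per_sample.tsv")
    emit(result.snv_report, "snv_report.tsv")
    emit(result.regulatory_report, "regulatory_snv_report.tsv")
    emit(result.filter_trace, "filter_trace.tsv")
    emit(result.cnv_report, "cnv_report.tsv")
    emit(result.risk_screen, "risk_cnv_screen.tsv")
    emit(result.burden, "regulatory_burden.tsv")
    emit(result.repeat_flags, "repeat_flags.tsv")
    emit(result.repeat_discordances, "repeat_discordances.tsv")

    if result.discordance_summary is not None:
        path = out / "discordance_summary.tsv"
        pd.DataFrame([result.discordance_summary]).to_csv(path, sep="\t", index=False)
        written.append(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    written.append(out / "manifest.json")

    if config.markdown:
        md = ["# Discordant-variant pipeline summary", ""]
        if result.discordance_summary:
            s = result.discordance_summary
            md += [
                "## Discordance",
                f"- mean discordant variants per sample: {s['mean']:.1f} "
                f"(sd {s['sd']:.1f}, median {s['median']:.1f}, "
                f"range {s['min']:.0f}-{s['max']:.0f})",
                "",
            ]
        if result.snv_report is not None:
            genes = sorted(set(result.snv_report["gene"]) - {"."})
            md += [
                "## Prioritized coding SNVs",
                f"- {len(result.snv_report)} variants across {len(genes)} genes "
                f"({', '.join(genes)})",
                "",
            ]
        if result.cnv_report is not None:
            md += [
                "## Rare discordant CNVs",
                f"- {len(result.cnv_report)} regions",
                "",
            ]
        (out / "summary.md").write_text("\n".join(md))
        written.append(out / "summary.md")
    return written
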