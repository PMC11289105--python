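# twindiscord

Discordant-variant analysis for monozygotic (MZ) twin cohorts.

MZ twins are often treated as genetically identical, but mutations arising
after fertilization (post-zygotic, early-embryonic events) can be present in
one twin and absent from the co-twin. In a **case co-twin design** — one twin
affected by a psychotic disorder (schizophrenia, schizoaffective disorder or
bipolar disorder), the co-twin unaffected — such discordant variants are
candidate contributors to the phenotypic discordance, with shared genetic
background and much of the environment controlled by design. `twindiscord`
implements the full analysis for jointly-genotyped whole-genome data:

* **Quality control** of a multi-sample VCF: sites with `QUAL < 100` are
  removed; genotypes with `GQ < 20` or `DP < 10` are set to missing;
  multi-allelic sites are split to biallelic records.
* **Reverse-pairwise discordance detection**: for each twin pair, a biallelic
  site is discordant when both genotypes are called and one twin carries
  *exactly one more copy* of the alternate allele than the co-twin
  (|c₁ − c₂| = 1) — the signature of a heterozygous post-zygotic mutation.
  Homozygous differences (Δ = 2) and sites with a missing twin genotype are
  excluded. Detection is symmetric; the carrier's affectation status is
  recorded, not filtered on.
* **Coding prioritization cascade** on discordant SNVs: (i) in the coding
  sequence of a protein-coding gene; (ii) predicted impact MODERATE or HIGH;
  (iii) SIFT deleterious **or** PolyPhen damaging; (iv) population allele
  frequency < 1% or absent (1000 Genomes and gnomAD); (v) not observed in any
  other twin pair of the cohort; carrier is the affected twin.
* **Regulatory prioritization**: discordant variants with CADD Phred > 20 and
  RegulomeDB rank 1–2, carriers unrestricted.
* **Family-aware consensus CNV calling**: per pair, calls from multiple CNV
  callers (both twins pooled) are union-merged by type into Regions of
  Interest (ROIs); ROIs supported by a single caller in a single sample are
  removed; ROIs with ≥ 50% *reciprocal* overlap with a common CNV
  (frequency ≥ 1% in gnomAD-SV / DDD / DGV-style tables) are removed, except
  that ROIs matching a ClinGen-style "Pathogenic" record with a psychiatric or
  neurodevelopmental phenotype are retained (type-agnostically) and flagged.
  ROIs present in exactly one twin are reported as discordant; all samples are
  also screened against a user-supplied list of known psychosis-risk CNV loci.
* **Paired regulatory burden**: per regulatory feature track, discordant
  variants overlapping the track are counted per twin and tested
  affected-vs-unaffected with an exact Wilcoxon signed-rank test
  (zeros dropped, midranks for ties, statistic `min(W⁺, W⁻)`, two-sided
  p by full sign enumeration for n ≤ 25).
* **Repeat-expansion screen**: per-sample repeat-unit counts are flagged when
  the larger allele strictly exceeds the locus threshold; sub-threshold
  within-pair discordances are listed for review.

A bundled synthetic-cohort generator (`twindiscord.simulate`) produces
jointly-called VCFs, multi-caller CNV tables, database tables, feature tracks
and repeat tables with known ground truth: 17 twin pairs by default, ~1% of
per-sample variants planted as discordant and a 0.1% per-genotype error
process, matching the discordance and error levels reported for short-read
WGS of MZ twin blood samples.

## Worked example

The package ships a deterministic worked example
(`twindiscord.examples`): a cohort VCF encoding six known discordant,
rare, predicted-deleterious missense SNVs plus decoys that each violate
exactly one cascade filter, and CNV call sets encoding four known rare
discordant CNVs plus consensus/database decoys.

```python
import twindiscord as td
from twindiscord.examples import snv_example, cnv_example
from twindiscord.cnv import rois_to_frame
from twindiscord.pipeline import _snv_report_frame

ex = snv_example()
calls = td.detect_discordant_cohort(td.qc_pipeline(ex.variants), ex.cohort)
res = td.prioritize_coding(calls, ex.cohort)
print(_snv_report_frame(res.retained, ex.cohort).to_string(index=False))
```

```
chrom      pos         rsid ref alt sample phenotype      gene hgvsp        sift polyphen  carrier_affected
chr17 28530789 rs1385768054   A   C  T07_A        BD     FOXN1 S291R deleterious damaging              True
chr17 28530791  rs371766542   C   A  T07_A        BD     FOXN1 S291R deleterious damaging              True
chr17 28530802 rs1220808552   G   C  T07_A        BD     FOXN1 S295T deleterious damaging              True
chr17 28881251            -   C   T  T09_A        BD     FLOT2 A347T deleterious damaging              True
chr22 44592351  rs367621282   G   C  T10_A       SCZ KRTAP10-6  P45R deleterious damaging              True
 chr9 96932219  rs112610837   C   T T13_A1       SCZ    NUTM2G P172S   tolerated damaging              True
```

Six variants survive the cascade, spanning four genes (FOXN1, FLOT2,
NUTM2G, KRTAP10-6); every decoy is removed by exactly the filter it was
built to violate (the audit is in `res.trace`). The NUTM2G row shows the
OR semantics of filter (iii): SIFT tolerated is rescued by a damaging
PolyPhen call.

```python
cx = cnv_example()
rois = td.consensus_pipeline(cx.calls_by_pair, cx.cohort, [cx.common_db], cx.pathogenic_db)
print(rois_to_frame(td.identify_discordant_cnvs(rois, cx.cohort), cx.cohort).to_string(index=False))
```

```
chrom     start       end  length type sample phenotype  carrier_affected pathogenic         callers
chr19  11261852  11262999    1147  DEL T01_A1       SCZ              True            caller1;caller2
chr10  92847856  92849207    1351  DEL  T02_A       SAD              True            caller1;caller2
chr12 120201498 120204299    2801  DEL  T16_A        BD              True            caller1;caller2
 chr3 195940567 197638156 1697589  DUP  T17_A        BD              True          Y caller1;caller2
```

Four rare discordant CNVs, all carried by affected twins, with lengths
computed as `end − start`; the 1.7 Mb 3q29-region duplication is flagged
pathogenic via the neurodevelopmental ClinGen-style record.

The same analysis runs from the shell on synthetic data:

```bash
discord simulate --out demo --n-pairs 17 --n-variants 2000 --seed 1
discord run-all --vcf demo/cohort.vcf --pairs demo/pairs.tsv --out demo_out
# done: 16 prioritized coding SNVs; mean discordant per sample 24.7
```

(24.7 discordant variants per sample ≈ 1.2% of the 2,000 simulated
per-sample variants: the planted 1% post-zygotic rate plus the 0.1%
genotype-error process, minus QC losses.)

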