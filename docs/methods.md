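# Methods

## The design and the discordance model

The analysis targets post-zygotic mutations in monozygotic (MZ) twin
pairs discordant for a psychotic disorder. Both twins inherit the same
germline genome, so after joint genotyping any site where the twins'
genotypes differ is either a post-zygotic event or an artifact. A true
early-embryonic mutation is expected to be heterozygous in the carrier
and absent in the co-twin, i.e. the carrier holds exactly one extra
copy of the alternate allele. Detection therefore emits a discordant
call only when both twin genotypes are present and the alternate-copy
difference is exactly one; homozygous differences (Δ = 2) are far more
likely to be genotyping errors at germline-variable sites and are
excluded, and a missing genotype on either side cannot establish a copy
delta, so the site is skipped rather than counted. Detection is
deliberately symmetric in the twins ("reverse-pairwise"): carriers are
found regardless of affectation, and the carrier-affected flag is
consumed downstream by the prioritization filters, not by the detector.
This keeps unaffected-carrier variants visible — the regulatory route
reports them explicitly.

## Quality control

Three filters precede detection, in this order: site-level
`QUAL ≥ 100` (strict removal below), per-genotype masking at `GQ < 20`
or `DP < 10`, and multi-allelic splitting. Missing QUAL, GQ or DP is
treated as failing its filter — a conservative reading, since a metric
that was not emitted cannot certify the call. Splitting recodes each
alternate allele against {ref, that alt}; allele indices belonging to
other alternates contribute zero copies of the split allele, which
preserves the total non-reference copy count across the split records
(a property-tested invariant). Sites are kept even when every genotype
is masked, and all filters preserve record order and are idempotent.
Phase is discarded: `0|1` and `0/1` are the same call.

## Prioritization

The coding cascade applies five conditions, all pure per-call
predicates so their order is immaterial: coding consequence in a
protein-coding gene; MODERATE/HIGH impact; SIFT deleterious **or**
PolyPhen damaging; each population allele frequency below 1% *or
absent*; and privacy within the cohort — the exact
(chrom, pos, ref, alt) allele must not be carried (≥ 1 alternate copy,
post-masking genotypes) by any sample of another pair. Only SNVs enter
the cascade because SIFT/PolyPhen do not score indels. Annotation
dialects vary across tools, so SIFT classes
{deleterious, deleterious_low_confidence, D} and PolyPhen classes
{probably_damaging, possibly_damaging, damaging, D} are matched
case-insensitively; a call with *both* scores missing cannot satisfy
the OR and is removed, while a missing allele frequency counts as
"absent" and passes. By default only affected-twin carriers are
retained (`affected_only=False` disables this).

The regulatory route keeps discordant variants with CADD Phred
strictly above 20 and RegulomeDB rank ≤ 2; a missing score on either
axis removes the call. Carriers are not restricted to affected twins.

## CNV consensus

Raw calls from ≥ 2 callers over both twins of a pair are grouped by
chromosome and type and union-merged: intervals overlapping by at least
one base merge into a Region of Interest spanning their union, iterated
to a fixpoint. Union-merging is the simplest rule consistent with
pooling all of a pair's calls; the overlap requirement is a
configuration point (`--merge-min-overlap` semantics are covered by the
`threshold` arguments on the filtering steps) and DEL/DUP never merge.
Support sets record which caller saw the region in which sample, and
the artifact filter removes exactly the ROIs seen in one sample by one
caller — the conjunctive reading, so a single-sample/two-caller ROI and
a both-samples/one-caller-each ROI both survive.

Database filtering uses 50% *reciprocal* overlap: the shared length
must be at least half of the ROI **and** half of the database record.
Records with frequency ≥ 1% (or labelled common) remove matching ROIs.
Pathogenic rescue re-admits, regardless of frequency, ROIs matching a
"Pathogenic" record whose phenotype tags intersect
{psychiatric, neurodevelopmental}; DEL/DUP type is ignored here because
aggregated clinical databases mix calling conventions, and the common
filter follows the same type-agnostic default (a `match_type` flag
restores strict matching). Coordinates are 0-based half-open
throughout, so reported lengths are `end − start`; 1-based inclusive
database tables can be shifted on read.

## Wilcoxon signed-rank test

Cohorts of ~17 pairs are deep in the small-sample regime, so the
paired burden test computes exact p-values. Zero differences are
dropped before ranking (the classic Wilcoxon policy; Pratt handling is
available as an option), ties in |d| receive midranks, the statistic is
min(W⁺, W⁻), and the two-sided p-value is
min(1, 2·P(W⁺ ≤ min(W⁺, W⁻))) under the null in which each rank joins
W⁺ independently with probability ½. The null distribution is computed
by dynamic programming over doubled midranks (midranks are multiples of
½, so doubling makes them integers); this is algebraically identical to
enumerating all 2ⁿ sign vectors and is what the test suite checks
against a literal enumeration oracle. Above 25 effective pairs a normal
approximation takes over, with the tie-robust variance
Var(W⁺) = Σrᵢ²/4 and a 0.5 continuity correction. With no nonzero
differences the result is flagged degenerate with p = 1. Burden counts
use point overlap at the variant's start for SNVs and the reference
span for indels, counting a variant once per track however many of the
track's intervals it touches. No multiple-testing correction is applied
across features by default (per-feature results are reported);
Bonferroni is available via a flag.

## Repeat screen

A sample is flagged at a locus when its larger allele count strictly
exceeds the locus threshold ("above" the threshold; premutation ranges
are not modeled). Twin pairs whose larger counts differ below threshold
are listed as benign discordances. The shipped thresholds are commonly
cited full-mutation counts for 16 classic repeat-expansion disorder
loci; they are placeholders for the user's own clinically curated
table, and a locus appearing in the data without a threshold is an
error rather than a silent skip.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
at desk scale:

* **Cohort**: 17 pairs by default, one affected twin each (diagnoses
  drawn from SCZ/SAD/BD; 30% of co-twins carry MDD, giving the broad
  discordance class).
* **Shared variation**: a pool of 1.5× `n_shared_variants` sites on
  three synthetic 10 Mb contigs, with population allele frequencies
  drawn from Beta(0.5, 2); each pair selects `n_shared_variants` sites
  (default 2,000) and draws one germline genotype per site from
  Hardy–Weinberg conditioned on carrying the variant, identical in both
  twins. Because pairs sample from a common pool, most shared sites
  recur across pairs, which is what gives the cohort privacy filter
  real work.
* **Planted discordance**: each *sample* receives
  Binomial(`n_shared_variants`, `discordant_fraction`) discordant sites
  (default fraction 0.01, the ~1% per-sample discordance level observed
  in short-read WGS of MZ twin blood), each a unique site where the
  carrier is 0/1 and everyone else 0/0. A configurable handful are
  annotated to survive the coding cascade (affected carrier, missense,
  deleterious, frequency absent) or the regulatory route (CADD > 20,
  RegulomeDB 1–2) and are so marked in the truth table.
* **Noise**: every written genotype is perturbed with probability
  `genotype_error_rate` (default 0.001, the short-read per-genotype
  error level) by flipping one uniformly chosen allele copy — the
  simplest error model consistent with a per-genotype error rate.
  Shared-site QUAL/GQ/DP are drawn so configurable fractions fall below
  the QC thresholds; planted sites are emitted with passing quality so
  that, at zero error rate, truth-table recovery is exact by
  construction — this is what makes the recovery invariant a sharp test
  of the detector rather than of the quality simulator.
* **CNVs**: per pair, events of 20–400 kb are placed in disjoint 1 Mb
  slots (1 kb margins keep jittered breakpoints inside their slot, so
  distinct events never merge); each carrying sample × caller observes
  an event with probability 1 − dropout, with Normal(0, 50 bp)
  breakpoint jitter. Caller-specific false positives (single sample,
  single caller) are injected in separate slots. Database decoys are
  built on both sides of the 50% reciprocal-overlap threshold: exact
  2%-frequency matches over some discordant events, 40%-overlap
  near-misses, a neurodevelopmental pathogenic rescue, and a cardiac
  pathogenic non-rescue. Because slots are drawn independently per
  pair, a record built for one pair can collide with another pair's
  event; expected fates in the truth table are therefore classified
  against the *final global* databases.
* **Tracks and repeats**: eight named regulatory feature tracks of
  non-overlapping intervals on a 5 kb grid, and repeat counts for the
  16 default loci drawn below threshold with small within-pair jitter
  (benign discordances); forced expansions can be planted and are
  recorded in the truth table.

Everything is deterministic given the config seed (byte-identical
output files), with independent substreams for the SNV, CNV and
track/repeat generators.

What the generator does **not** emulate: linkage disequilibrium and
recombination, realistic site-frequency spectra, read-level error
correlation (errors are independent across genotypes), somatic mosaic
allele fractions, hemizygosity (sex chromosomes would be emitted
diploid), trio structure, and realistic CNV size/frequency
distributions. Passing tests on synthetic data therefore demonstrate
the correctness of the filtering, detection and testing logic under the
stated statistical assumptions — not calibration against real WGS
artifacts such as alignment-induced clustered errors, which is exactly
why the worked examples pin their expected outputs explicitly.

## Numerical and interface choices

* Problem sizes: tests and the acceptance script run cohorts of 2–17
  pairs with 300–10,000 variants per pair and Monte-Carlo loops of
  400–2,000 replicates — sizes chosen so the whole suite completes in
  well under a minute while keeping binomial/Monte-Carlo bands (±3 SD)
  tight enough to detect real defects.
* The per-pair consensus and all database filters are brute-force
  scans; at realistic call-set sizes (hundreds of calls per pair) this
  is faster and simpler than interval indexing, which is reserved for
  the burden counter (interval trees per track).
* The pipeline runner records input SHA-256 checksums in a manifest and
  is deterministic given inputs; stage failures abort with a
  stage-tagged error.
* The CLI follows click conventions for exit codes (2 for usage and
  data errors, 1 for unexpected failures).

## Known limitations

* The discordance summary counts post-split biallelic records; a
  pipeline that counts pre-split sites would report slightly lower
  numbers at multi-allelic loci.
* The privacy filter uses post-masking genotypes; a variant carried in
  another pair only by a masked low-quality genotype does not count as
  "observed" there.
* Genome-build conversion (liftOver) is out of scope: CNV databases
  must be supplied on the working build.
* The regulatory burden test reports per-feature results without
  cross-feature correction by default, mirroring per-feature reporting
  practice; use `bonferroni=True` where a family-wise claim is needed.
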