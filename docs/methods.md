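# Methods

This note documents the models behind each pipeline stage, the defaults
that matter, the design choices made where the design was genuinely open,
and what the synthetic data can and cannot show.  Coordinates are 1-based
inclusive everywhere in memory (matching ISCN `g.start_end` notation);
BED-dialect files (cytoBand, BEDPE) are converted on read and write.

## Read-depth CNV model

**Windows and normalization.** The unit of analysis is the non-overlapping
5-kb window count of uniquely aligned fragments.  Copy ratios are counts
divided by the autosomal median count, so a disomic autosome sits at ratio
1.0 and a single-copy male sex chromosome at 0.5.  Optional corrections:
per-window division by a reference-panel mean (sensible only for
sex-matched panels) and a quadratic GC fit on autosomal windows, both off
by default.  Zero-count windows are kept with ratio 0.  Sample sex is
inferred from the chrX mean ratio (< 0.75 → male).

**Candidate scan.** A sliding window of 50 kb advances in 5-kb increments;
a candidate is a maximal run of at least 3 consecutive sliding positions
whose mean ratio deviates from the chromosome baseline by more than 0.2
(half the heterozygous-deletion effect — robust at 30×-equivalent window
noise; runs separated by less than one scan window are merged).
Chromosome-wide deviations beyond 0.05 are emitted as chromosome-level
candidates; this is the entry point for mosaic aneuploidy, and local
candidates on such a chromosome are absorbed into the whole-chromosome
call.

**Breakpoint refinement.** For each candidate edge the coverage-step
statistic — the absolute difference of mean ratio over the 10 windows on
either side of a putative boundary — is maximised within 10 windows of the
scan edge.  On noise-free data with edges on the grid this recovers the
boundary exactly; with default noise the error is at most the grid
resolution (5 kb) in essentially all cases.  Refinement cannot resolve
below the window size: a deletion whose true edges fall inside windows is
reported at the enclosing window boundaries, so reported sizes are
grid-quantized (the worked 751.9-kb deletion is called as 760 kb on the
grid; exact sizes follow once base-pair breakpoints are known,
`size_kb = (end − start + 1)/1000` to one decimal, half-up).

**Event typing and mosaicism.** With baseline ratio `b` (1.0 autosome, 0.5
single-copy sex chromosome) the mean segment ratio `r` is typed by nearest
state: loss with `r < 0.25 b` → homozygous deletion (event ratio 0),
other losses → heterozygous deletion (event `b/2`; single-copy
chromosomes always use event 0), gains with `r > 1.75 b` → triplication
(event `2b`), else duplication (event `1.5b`).  The mosaic cell fraction
is the mixture solution `f = (b − r)/(b − event)`, clamped to [0, 1].  A
fraction in [0.1, 0.9] is reported as mosaic; outside that band the call
is reported as constitutional — the band is a reporting choice motivated
by the ~20–30% mosaicism floor of array platforms.

**Rarity screen.** The p-value is a two-sided Mann–Whitney test of the
case's per-window ratios in the region against the pooled panel ratios
over the same windows (exact enumeration when both samples are ≤ 20
values and tie-free, normal approximation with tie correction otherwise);
events are kept at `p < 10⁻⁴`.  Pooling alone cannot reject a polymorphic
CNV segregating in the panel — with carriers in half the panel the pooled
distribution is bimodal but the case windows still rank low, and the test
stays significant for any region of realistic length.  The screen is
therefore two-part: an event is additionally dropped as a polymorphism
when at least 2 panel samples, and at least 5% of the panel, shift their
regional mean in the case's direction by half the case effect or more.
No multiple-testing correction is applied; the threshold is a fixed
screen, not an error-rate guarantee.  Whether the population comparison
should be region-wise (chosen here) or per-window across the cohort was
left open by the source description; region-wise is implemented because it
is the form the pooled rank-sum statistic supports directly.  Minimum
reportable event size defaults to 25 kb (5 windows).

## Chimeric-pair SV model

**Joining type.** A junction fuses one side of each breakpoint.  The
convention (isolated in one place so it can be swapped): a read on the
`+` strand points into the junction from upstream, so the retained
segment lies to its left (side L); a `−` read retains the downstream side
(R).  A cluster's joining type is the canonical strand pair of its
members.  Consequences: inversions produce the complementary `++`/`−−`
pair at the same breakpoints, reciprocal translocations `+−`/`−+`, and a
forward insertion links the receptor's left edge to the source start
(side R) and its right edge to the source end (side L).

**Clustering.** Pairs are canonically ordered (lower chromosome/coordinate
first) and grouped by chromosome pair and joining type; within a group,
labels are refined by alternately splitting at coordinate gaps larger
than the clustering window (1,000 bp ≈ two insert-size SDs above the
maximum insert) on each footprint until stable.  The result is
independent of input order.

**Filter cascade** (order fixed: systematic → random → typing):

* *Systematic*: a cluster is dropped when a control cluster with the same
  chromosome pair and joining type overlaps it reciprocally ≥ 50% on both
  footprints, after padding each footprint by 500 bp (roughly one insert
  size) — two read clusters supporting the same junction need not tile
  the same bases, so unpadded reciprocal overlap under-matches.
* *Random*: the property vector must pass every threshold — ≥ 4
  supporting pairs, footprint spans ≤ 1,500 bp, strand consistency 1.0,
  median mapping quality ≥ 30.  The thresholds stand in for the property
  matrix of the upstream method, whose exact values are not public; all
  are exposed as parameters.
* *Typing*: clusters within 1 Mb on both footprints form a locus group.
  Two same-chromosome clusters with `++`/`−−` types and matching
  footprints → inversion; two interchromosomal clusters with
  complementary types, both footprints narrow (≤ 10 kb) → translocation;
  ≥ 2 interchromosomal clusters pinned to one narrow receptor footprint
  and flanking a spread source interval → insertion, with fragments
  reconstructed by pairing source-side entry (R) and exit (L) endpoints
  in coordinate order and uncovered sub-intervals reported as lost
  segments.  Interleaved or inverted multi-fragment layouts beyond this
  fall back to a single spanning fragment; anything else is
  complex/unresolved with a reason.

Breakpoints are estimated from the junction-facing footprint edge, which
is inside the true breakpoint by roughly the smallest read offset
(tens of bp at typical support).  Base-pair precision requires split
reads or Sanger sequencing of the junction, which is out of scope;
`characterize_junction` instead takes a sequenced junction plus the two
reference flanks and reports the non-templated insertion (gap between the
maximal flank matches) or microhomology (their overlap), the two being
mutually exclusive.

## Variant triage

Retention: previously reported (ClinVar P/LP or HGMD DM), or all of —
MAF ≤ 0.05, coding/exon–intron-junction location, damaging or
splice-altering calls from ≥ 2 of the 5 predictors (SIFT, PolyPhen-2,
MutationTaster, Human Splicing Finder, MaxEntScan; "multiple algorithms"
is read as ≥ 2, configurable), and an OMIM disease-gene annotation.
Missing annotations fail their own criterion, so a variant can still be
retained through the others.  Each retained row carries the criterion
numbers that fired.

Trio logic: both parents reference → de novo; one carrier → that parent;
both → biparental; a missing parent → unknown.  For recessive genes,
variants from both parents are a confirmed-trans compound heterozygote,
all from one parent are cis, unphased multiples are suspected, and a lone
heterozygote is a (non-diagnostic) single carrier.

Classification is an ordered first-match rule table shipped as YAML
(`data/classification_rules.yaml`): known + phenotype match →
pathogenic; novel truncating in a dominant gene with de-novo status or
phenotype match → likely pathogenic; de-novo dominant missense with
phenotype match → likely pathogenic; biallelic recessive with phenotype
match → likely pathogenic; everything else VOUS.  Phenotype consistency
is an input flag — correlating ultrasound findings with a gene's reported
phenotype is expert judgment, not computable here.  Independently of the
table, the engine caps any recessive-gene variant without a biallelic
state (homozygous, hemizygous, or confirmed-trans) at VOUS; a full ACMG
evidence-code calculus (PVS/PS/PM/PP arithmetic) is deliberately reduced
to this explicit table.

## Reporting and statistics

Findings rank pathogenic < likely pathogenic < potentially pathogenic <
VOUS < polymorphism/likely benign < benign, then by decreasing size and
position; a case is diagnostic only on a pathogenic or likely pathogenic
finding (an SV graded "potentially pathogenic" is reportable but not
counted as a diagnosis).  SV interpretation, lacking consensus
guidelines, uses a three-step rule: OMIM-gene disruption at a breakpoint
→ potentially pathogenic; TAD/regulatory disruption only → VOUS; neither
→ polymorphism.

Diagnostic yields carry Clopper–Pearson exact binomial 95% intervals
(beta-quantile form), reported in percent to one decimal, half-up — the
exact method is fixed because it reproduces the printed intervals for
both 8/50 (7.2–29.1) and 16/50 (19.5–46.7), which Wilson intervals do
not.  Group comparisons use the chi-square test without continuity
correction when every 2×2 expected count is ≥ 5 and Fisher's exact test
otherwise; this selection rule is inferred from the printed p-values
(0.144 and 0.061 chi-square, 0.433 Fisher) and flagged as inferred.
Comparisons of two methods on the same cases are computed unpaired, which
matches the printed values; a paired (McNemar) test would be the stricter
choice and is noted as a caveat.  qPCR copy number is `2^−ΔΔCt` with
`ΔΔCt = (Ct_target − Ct_reference)_case − (Ct_target − Ct_reference)_control`,
replicate standard errors propagated onto the ratio scale; the ratio is
invariant to any constant shift of all Ct values.

The ISCN output is a constrained dialect — `del`/`dup`/`trp` segments
with band labels, mosaic sex-chromosome counts (`(X)x1,(Y)x0∼1`), the
bracketed insertion form and simple inversions — not a full ISCN 2016
grammar.  Band labels come from a `GenomeSpec`; the built-in
`nomenclature_band_map()` is a coarse, synthetic approximation of
hg19-scale band boundaries, adequate for rendering and round-tripping the
worked examples, while a real UCSC cytoBand.txt can be loaded for
production use.

## Synthetic data: what it emulates, and what it does not

The generators target the statistics of a 30× paired-end run after
alignment, not the run itself (no reads, FASTQ or alignments are
simulated).  Defaults: 750 expected fragments per 5-kb window at copy
number 2 (≈ 30× with ~400-bp fragments), negative-binomial counts with
shape 200 (window CV ≈ 8.5%; Poisson and noise-free variants available —
no empirical dispersion for 30× windowed counts was available, so the
default is flagged as tunable), optional quadratic GC bias (off by
default), insert sizes N(350, 50) bp inside the assay's 300–500-bp
fragment band, 2,000 uniform random chimeric pairs per genome, 5
systematic artifact junctions planted at identical coordinates in case
and control, and a reduced five-chromosome genome (three autosomes plus X
and Y, 10–60 Mb) in place of full hg19.  Mosaic events contribute the
ploidy mixture `f·event + (1−f)·base` to the expected count, and window
means scale linearly with local copy number (checked by regression:
slope = baseline/2 within 2% in the noise-free model).

Variant-table decoys each violate exactly one retention criterion, so
exact truth recovery is a meaningful test.  Cohort tables reproduce
requested marginals exactly; microarray positives are drawn from the
CNV-positive sequencing cases, reflecting that the array sees CNVs only
and the sequencing calls are a superset.  qPCR plates put one extra
target copy at exactly one cycle at 100% efficiency, with configurable
efficiency in the 95–105% validation band.

What passing these tests does **not** show: performance on real data with
mappability artifacts, GC waves beyond a quadratic, reference biases,
segmental duplications or repeat-mediated breakpoints (the upstream
study's own limitation for small-insert libraries), incomplete or wrong
annotations, or phenotype judgment.  The per-case variant discoveries of
any particular cohort are not reproducible without its raw sequencing;
printed annotations are covered as classification worked-examples only.

## Problem sizes and numerical choices in the test suite

The suite runs entirely on synthetic data at desk scale: 200 simulated
deletions ≥ 100 kb (50 replicates × 4 events on a 20-Mb chromosome) for
recall ≥ 0.95 and median breakpoint error ≤ 5 kb; 50 seeds × 20 planted
SVs for cascade recall ≥ 0.9 with ≤ 1 false event per genome (planted at
separated loci — events whose clusters legitimately merge into one locus
group are a truth-placement artifact, not a caller property); 50 seeds
for the 40% mosaic chromosome-Y recovery (±5 points per seed, ±2 on the
mean); exact enumeration oracles for the rank-sum test (region ≤ 8
windows, panel ≤ 3 samples, tie-free) and Fisher's test (all 2×2 tables
with n ≤ 20); 100 seeded decoy tables for exact prioritizer recovery;
and parse/emit round-trips for every worked nomenclature string.
Deterministic seeds throughout; Hypothesis profiles are derandomized.
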