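# Methods

## Scope and model

`mtrnahet` quantifies mitochondrial RNA heteroplasmy — the fraction of
transcripts at a position carrying a non-consensus base — in paired
oocyte–cumulus RNA-seq studies, and aggregates it across a three-age-group
mouse cohort. The pipeline consumes aligned reads (or per-position base
counts); upstream alignment, duplicate removal and library chemistry are out
of scope. mtRNA variants conflate two biological sources the assay cannot
separate: true mtDNA heteroplasmy and post-transcriptional modifications
that cause reverse-transcription miscalls. The cohort logic is designed
around that ambiguity (within-mouse recurrence, cumulus-based maternal
classification, paired deltas, and a lookup of catalogued rRNA modification
sites).

## Pileup

A read contributes nothing if unmapped, duplicate-flagged, or mapping
quality < 20; an aligned base contributes only with base quality ≥ 30.
Insertions, deletions and soft-clipped segments contribute no counts, and
`N` never counts. Depth everywhere downstream is this quality-filtered
depth: the analysis needs one consistent denominator for h, and the filtered
depth is the number of observations actually used. Raising either threshold
can only remove counts (monotonicity), and the pileup is independent of read
order.

## Variant calling

A transparent threshold caller, deliberately without priors, strand-bias
terms or genotype likelihoods: at positions with depth ≥ 100, every
non-consensus base with allele fraction ≥ 1% becomes one call with
h = alt_count/depth. Both boundaries are inclusive. Multi-allelic positions
yield one record per alternate base; indels and multi-nucleotide haplotypes
are not called. The consensus defaults to the supplied reference base;
`consensus_from_tables` optionally recomputes it as the study-wide majority
base, which matches the word "consensus" at the cost of depending on the
sample set. Calls serialize to minimal VCF 4.2 (DP/AD/AF) and a flat TSV;
both round-trip losslessly.

## Cohort aggregation

* **Recurrence.** A (position, alt) is recurrent for a mouse when detected
  (h ≥ the 1% detection threshold, which reuses the calling threshold) in
  ≥ 2 of that mouse's samples. Detection never crosses mice. The same
  position with two alternates is two variants.
* **Maternal origin.** Default rule: detected in ≥ 2 cumulus samples of the
  mouse (`maternal_min_cumulus=2`). A mouse with a single complex cannot
  satisfy it; setting `maternal_min_cumulus=1` admits such mice at the cost
  of letting any single cumulus detection count as maternal. Both readings
  are exposed because the strict rule is the literal one while the relaxed
  rule is the only one applicable to single-OCC mice.
* **Paired deltas.** delta = h_oocyte − h_cumulus per complex, one row per
  variant seen in either member (the absent member contributes 0). Per
  variant, `avg_A` averages over all complete complexes (zeros included) and
  `avg_B` only over complexes where the variant was seen.
* **Bins.** h is partitioned into [1%, 10%) / [10%, 50%] / (50%, 100%].
  Calls at exactly the 1% floor exist, so the first bin is closed on the
  left; 10% and 50% both fall in the middle bin.
* **Synonymy summary.** Each coding recurrent variant counts once per cell
  type in which it is detected, at that cell type's maximum h; non-coding
  variants appear in a companion per-region-class summary.
* **Top variants.** Two rankings, since "highest average level" and
  "greatest oocyte–cumulus change" select different sets: `mean_h` (mean of
  detected per-sample levels) and `mean_abs_delta` (mean |delta| over
  complexes where present). Ties break by (position, alt).

## Reference and synonymy

Coordinates are 1-based inclusive on the heavy strand. The packaged feature
map follows the mouse mitochondrial layout (16,299 bp; 12S rRNA gene
containing positions 179/233/729; tRNA-Glu containing 14,131; mt-Nd5
containing 12,216; D-loop at 15,443–16,299). The packaged *sequence* is a
deterministic synthetic stand-in — adequate for simulation and for testing
the synonymy machinery (implementation and oracle see the same sequence),
not for interpreting real mouse variants.

Feature lookup returns all overlapping features; the primary region class
uses the priority protein_coding > tRNA > rRNA > D_loop (a deterministic
convention — annotations do not state how to attribute overlaps).
Substitutions are classified under NCBI translation table 2; a change is
non-synonymous if it alters the amino acid (stop included) in **any**
overlapping coding gene — the conservative choice for overlapping reading
frames. Positions in a trailing partial codon (incomplete stop completed by
polyadenylation: mt-Co3, mt-Nd4, mt-Cytb in this layout) are classified
non-coding with a warning, since no complete codon exists to compare.
Stop-gain/loss changes fold into non-synonymous (only the binary split is
used downstream). The genetic code id is configurable only via the feature
file header.

The known rRNA-modification catalogue shipped with the package is a
synthetic stand-in (see its header): canonical modification classes (Psi,
m5U, m1A, m4C, m5C, m62A, Gm, Um) at representative 12S/16S positions, used
to exercise the overlap-report machinery.

## Statistics

Sample standard deviations (n−1) and two-sided p-values throughout; F and t
distributions via scipy. Holm–Šidák is implemented from its definition
(sort ascending, adjusted_(i) = 1 − (1 − p_(i))^(m−i+1), running maximum,
clip at 1) and cross-checked against statsmodels in the tests. The ANOVA
compares pooled per-variant h values by age group, separately per cell type;
one correction family = the omnibus plus all pairwise age comparisons of one
cell type, recorded explicitly in the report. Sister-sample CV: for each
mouse with ≥ 2 samples of a cell type, each variant detected in ≥ 2 sisters
contributes sd/mean of h across all sisters (zeros included for undetected
sisters); per-mouse value = mean over variants, per-age value = mean over
mice. Degenerate inputs (all values equal, all paired differences zero,
constant x) raise rather than returning a statistic; a constant response in
the linear fit returns slope 0, R² = 0 by convention. Closed-form checks in
the tests use 1e−10 tolerances (1e−12 for the step-down formula).

## Synthetic study generator

The generator is the package's test bed: it emulates the *structure* the
analysis assumes, not sequencing chemistry.

* **Design**: 3 age groups × 4 mice × 2 OCCs (one mouse with 1 OCC, one
  with 3, mirroring collection accidents), each OCC giving one oocyte and
  one cumulus sample — 48 samples.
* **Maternal variants**: per mouse, Poisson(6) variants at uniform positions
  with founder levels from Beta(1.5, 15) truncated to [0.05, 0.90] — right-
  skewed so most variants sit below ~10–15%, while staying above the 5%
  floor at which recovery through the 1% detection threshold is essentially
  deterministic at the simulated depths.
* **Within-mouse segregation**: each sample redraws its level from
  Beta(c·h₀, c·(1−h₀)) with concentration c = 300. Sister samples of one
  mouse share the post-bottleneck maternal pool, so their dispersion
  reflects sampling from that pool, not the full germline bottleneck; c=300
  gives sister CVs of a few percent to ~20%, comparable to what paired
  designs report. Cumulus expected levels are scaled ×1.5 (capped at 0.97),
  reproducing the observed cumulus-elevated pattern.
* **Modification artifacts**: fixed apparent alternate fractions per cell
  type at four sites — three cumulus-elevated (two in the 12S rRNA gene, one
  in tRNA-Glu at 14,131, rate 0.23 in cumulus vs 0.005 in oocytes) and one
  oocyte-elevated (position 233, 0.12 vs 0.02). The rates are descriptive
  placeholders on the reported scale (tens of percent in the elevated cell
  type); no study-measured values exist to plug in.
* **Counts**: per-position depth ~ Poisson with feature-class means
  (6,000 coding / 8,000 rRNA / 4,000 tRNA / 2,200 D-loop and intergenic for
  oocytes — the control region is transcribed at comparatively low levels),
  ×3 for cumulus samples; base counts are multinomial with a 0.001 per-base
  miscall spread uniformly over the three other bases.
* **Determinism**: one seeded generator, consumed in a fixed documented
  order; identical config + seed gives byte-identical output.

What the generator does **not** model: expression structure beyond the
class-level depth profile, correlated or quality-dependent errors,
alignment artifacts, mouse-to-mouse modification-rate variation, and any
age effect (the default study is null by construction with respect to age).
Passing recovery tests therefore show the pipeline's logic is correct under
binomial sampling at realistic depths — not that real data are this clean.

`emit_alignments` decomposes any base-count table into contiguous
single-base runs emitted as SAM records with passing qualities, so
pileup ∘ emit is the identity; it exercises the SAM path, it does not
simulate reads.

## Problem sizes and verification

The default study (48 samples × 16,299 positions) simulates and analyses in
a few seconds. The test suite verifies the synonymy classifier exhaustively
(every coding position × 3 alternates, ~34,000 cases, against a whole-gene
translation oracle), the caller against a per-site brute-force oracle, the
estimator at 1,000 binomial sites (depths 1,000–10,000), and end-to-end
recovery/precision/classification against the planted truth on the default
study. `scripts/acceptance.py` recomputes the headline quantities from a
fresh simulation at a user-supplied seed.

## Known limitations

* The packaged sequence is synthetic; real-data use requires the user's
  reference FASTA and feature table.
* The caller implements exactly four thresholds; it will not match callers
  with internal priors (e.g. haplotype-based tools) call-for-call.
* Maternal classification is within-mouse only; cross-study sharing is out
  of scope.
* The paired design gives no way to separate mtDNA heteroplasmy from
  modification artifacts at a single site; the package reports the evidence
  (recurrence pattern, delta sign, catalogue overlap) without deciding.
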