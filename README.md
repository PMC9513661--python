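# mtrnahet

Mitochondrial RNA heteroplasmy analysis for paired oocyte–cumulus RNA-seq
studies.

Developing eggs (oocytes) and their surrounding cumulus cells share a mother
cell, so comparing the mitochondrial transcripts of the two tissues within
one oocyte–cumulus complex (OCC) separates inherited mtDNA heteroplasmy from
cell-type-specific artifacts such as post-transcriptional RNA modifications
that disturb base calling. `mtrnahet` implements that analysis for studies
of mouse oocytes across age groups, from aligned reads to paired statistics,
and ships a synthetic study generator with a known truth table so every
stage can be validated without sequencing data.

## The method

For each sample, reads on the mitochondrial contig are piled up into
quality-filtered base counts (mapping quality ≥ 20, base quality ≥ 30;
duplicates, indels, clipped bases and `N` excluded). At every position with
filtered depth ≥ 100, each non-consensus base with allele fraction ≥ 1% is
emitted as a single-nucleotide variant with heteroplasmy level

    h = alt_count / depth

Cohort logic then follows the paired design:

* **recurrence** — a variant (position, alt) is kept for a mouse only when
  detected (h ≥ 1%) in at least two of that mouse's samples;
* **maternal origin** — a recurrent variant is maternal when found in more
  than one cumulus sample of the mouse (cumulus cells are somatic, so
  sharing implies inheritance rather than a de novo germline event), with an
  `oocyte_detected` / `cumulus_only` split;
* **paired deltas** — per complex, `delta = h_oocyte − h_cumulus` (negative
  when the cumulus level is higher);
* **annotation** — variants are assigned to protein-coding/tRNA/rRNA/D-loop
  features of the mouse mitochondrial gene map and coding substitutions are
  classified synonymous/non-synonymous under the vertebrate mitochondrial
  genetic code (translation table 2);
* **statistics** — one-way ANOVA across age groups with Holm–Šidák-corrected
  pairwise comparisons, per-site paired t-tests, OLS fit of cumulus on
  oocyte levels with R², sister-sample coefficients of variation, and
  cumulative D-loop variant curves.

The packaged reference uses the mouse mitochondrial coordinate layout
(16,299 bp, D-loop at 15,443–16,299) with a deterministic *synthetic*
sequence; supply your own FASTA + feature TSV for real data.

## Worked example

```
python examples/02_recurrence_and_origin.py
```

prints, for the default synthetic study (3 age groups × 4 mice, paired
oocyte/cumulus samples, seed 7):

```
504 raw calls -> 136 recurrent variants
  maternal origin: 127 (93%)
  detected in cumulus only: 15

against the planted truth: recall 1.000, precision 1.000, maternal agreement 1.000
```

504 per-sample calls collapse to 136 within-mouse recurrent variants; 93%
are classified maternal, and every planted heteroplasmy is recovered with no
spurious recurrent calls (recall = precision = 1 at these depths). The other
examples cover calling (`01`), paired statistics and top-variant ranking
(`03`), and gene-map/synonymy queries (`04`).

The same pipeline is available from the shell:

```
mtrnahet run-all --seed 7 --outdir results/run7
mtrnahet simulate / pileup / call / analyze   # individual stages
```

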