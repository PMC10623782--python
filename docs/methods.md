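# Methods

## The problem and the procedure

Constitutive heterochromatin marks — H3K9me3 and DNA methylation — usually
co-occupy CpG-poor sequence, but a distinct set of CpG-rich regions carries
both marks stably. This package identifies such co-marked CpG-rich regions
(CHMs) across multiple developmental processes and characterizes what sets
them apart from CpG-rich regions that escape the marks.

The procedure, per developmental process with stages *s = 1..n*:

1. **Bin lattice.** Each chromosome is tiled with fixed 1-kb bins
   (0-based half-open coordinates; a CG dinucleotide belongs to the bin
   containing its C). Bins with **more than 30 CpGs** are CpG-rich.
2. **Per-stage candidate calling.** On CpG-rich bins, with mean bin RPM
   *h* and mean per-CpG methylation *m*:
   - CHM: *h* ≥ h_high and *m* ≥ m_high
   - CH-nonM: *h* ≥ h_high and *m* ≤ m_low
   - CM-nonH: *h* ≤ h_low and *m* ≥ m_high

   Defaults: h_high = 2× the genome-wide mean bin RPM of that stage,
   h_low = the genome-wide mean, m_high = 0.5, m_low = 0.2. These rules
   re-specify the candidate definitions explicitly (the original analyses
   used an external caller whose internal thresholds are not published);
   every threshold is configurable, and inequalities are inclusive at the
   boundary. The three classes are mutually exclusive whenever
   h_low < h_high and m_low < m_high.
3. **Stability.** A bin is a process-level call when it is a candidate in
   **strictly more than 2/3** of the process's stages ("more than" read
   literally; a `rule="gte"` switch exists for sensitivity analysis).
   Stable CHM bins are fused and regions within 2 kb (inclusive,
   edge-to-edge) are merged.
4. **Cross-process classes.** Region identity across processes is resolved
   on the bin lattice: the 2-kb-merged cover of the union of all
   processes' CHMs is intersected with each process's calls. A region
   present in all processes is a **universal CHM**, in exactly one a
   **process-specific CHM**, otherwise non-universal. CH-nonM / CM-nonH
   universal sets are the bin-level intersections across processes.
   **CpG-rich nonCHMs** are CpG-rich bins with no CHM candidate (pooled
   over every stage of every process) within 2 kb.

Downstream characterization:

- **DNAme amount** (browser-track style): per 1-kb window sliding at
  10 bp, mean per-CpG methylation × window CpG count, emitted at the
  window center; zero-CpG windows emit 0 so the track is dense.
- **Compartment consistency** over 5 cell-type A/B maps: a region's
  per-cell-type label is the compartment with the larger overlapped
  length (exact tie → neither); A-in-all-5 / B-in-all-5 /
  neither-in-all-5 ("other") / anything else ("inconsistent"). The four
  labels partition any region set.
- **Enrichment score** = log2(observed/expected) with observed =
  overlap bp / region bp and expected = feature bp / genome bp, both on
  merged covers; score ≥ 1 is "enriched"; zero overlap reports a −∞
  sentinel. For repeat element parts the fraction of the part's elements
  intersected by ≥ 1 region ("overlap ratio", element-count based) is
  reported, and parts with score ≥ 1 and ratio > 10% are called out.
- **Targets.** Genes whose strand-aware TSS lies within 10 kb of a
  region (distance = min |TSS − q| over region positions, 0 inside;
  boundary inclusive); TEs require ≥ 1 bp of true overlap. Expression is
  log2(TPM+1) averaged over stages, classes compared by a two-sided
  Mann–Whitney test (the underlying studies do not name their test);
  stars at p < 0.05/0.01/0.001/0.0001.
- **k-mers.** All k-mers for 1 ≤ k ≤ 6 keyed by canonical form
  (lexicographic min of k-mer and reverse complement; 2,772 keys), with
  frequency = occurrences / valid positions (positions touching N are
  dropped from both numerator and denominator). Per-k-mer class AUC is
  the normalized Mann–Whitney U (ties half credit), hence deterministic
  and reverse-complement invariant; rank ties in the top-10 list break
  lexicographically.
- **ZFP57 motifs.** "TGCmCGC" is read as the hexamer TGCCGC with the
  methyl mark on its internal CpG; both strands are scanned (a
  minus-strand hit appears as GCGGCA on the forward strand) and a hit is
  methylated when its CpG has level ≥ 0.5 in strictly more than 2/3 of
  stages. Motif CpGs missing from the track are excluded and tallied.

## The synthetic-data generator

The generator is first-class, tested code: it emits a genome (FASTA),
per-stage methylation and H3K9me3 tracks (bedGraph), annotations (BED),
compartment maps, gene models and a TPM table, with planted ground-truth
regions of five classes (universal CHM, process-specific CHM, CH-nonM,
CM-nonH, CpG-rich nonCHM). Defaults define the study conditions: a 10-Mb
genome on 2 chromosomes, 6 processes with 4–6 stages, 50/12/30/30/40
planted 2-kb regions at least 5 kb apart, CpG-rich bins with 35–45 CpGs/kb
against a Poisson(8)/kb background, methylation means 0.85/0.15 (clipped
Gaussian noise, sd 0.05, background CpGs at 0.75 as in somatic tissue),
and Gamma-distributed RPM with marked bins at 5× background.

Choices worth flagging:

- **H3K9me3 depletion in unmarked CpG-rich bins.** CM-nonH and CpG-rich
  nonCHM bins draw RPM at 0.3× background, not at background. With h_low
  defaulting to the genome-wide mean, bins sitting exactly at background
  straddle the threshold and no caller could classify them consistently;
  depletion is also what an unbound CpG island looks like in ChIP pileup,
  where signal concentrates in peaks. This is part of the study
  conditions, fixed in the generator defaults.
- **Sequence construction is exact.** Filler bases are drawn, every CG in
  the filler is destroyed, then CpGs (and, in universal-CHM bins, three
  TGCCGC motifs) are planted at non-colliding positions — so per-bin CpG
  counts are exact by construction, and the planted classes carry real
  compositional signal (G/T-biased filler in CHM-like regions, A/C-biased
  in unmarked CpG-rich regions) for the k-mer analyses to find.
- **Planted effects.** A young-LTR subfamily ("sIAPEz-int", family ERVK)
  overlaps 90% of universal CHMs with a few members elsewhere, and draws
  lower conservation (mean 0.08 vs 0.5) than three older LTR subfamilies;
  each planted region gets a gene with TSS 3 kb away (CHM-target genes
  from a lower log-normal TPM than nonCHM-target genes) and one 20 kb
  away; compartment maps share a block pattern across 5 cell types with
  independent 10% A/B flips.

What the generator does **not** emulate: read-level noise and mapping
artifacts, copy-number and mappability biases, fractional bisulfite
conversion, CpG-density gradients (CpG-island shores), overlapping or
nested repeat structure, and realistic genome-wide methylation topology.
Passing recovery tests therefore demonstrate that the calling and
classification logic is correct under its stated signal model — not that
the thresholds are tuned for any real ChIP/WGBS dataset.

By the literal definition, CpG-rich regions marked by one mark only are
also "CpG-rich nonCHMs" (no CHM candidate nearby). The recovery scorer
respects the mutually exclusive planted taxonomy by subtracting the
universal CH-nonM/CM-nonH bin sets from the literal nonCHM set before
computing F1.

## Numerical and design choices

- "Within 2 kb" is inclusive (≤ 2,000 bp edge-to-edge) for merging,
  nonCHM exclusion and nearby-candidate queries.
- Interval arithmetic is done with small sorted-sweep primitives on
  numpy arrays, each validated against brute-force per-base oracles in
  the test suite.
- Methylation level of a bin/window is the mean of fractional per-CpG
  levels (equal to the methylated/total count ratio when levels are
  binary). Bins without CpGs have undefined methylation (NaN) — such bins
  can never be CpG-rich, so the caller is unaffected.
- Spearman (not Pearson) correlation for the CpG-class analysis, robust
  to the heavy-tailed RPM distribution; class bounds default to ≤ 10 /
  11–30 / > 30 CpGs per bin and are configurable.
- The pipeline is a pure function of (config, seed); repeated runs are
  byte-identical. No stage caching is implemented: at package scale a
  full run takes seconds, so caching would add failure modes without
  benefit.
- Problem sizes throughout (10-Mb genome, tens of planted regions,
  hundreds of 1-kb sequences in the k-mer analyses) are chosen so the
  full pipeline completes in well under a minute on one CPU while every
  class keeps enough bins for stable rank statistics.

## Known limitations

- Caller thresholds are defined on genome-wide mean RPM, not local
  background; broad enrichment domains would inflate h_high.
- Cross-process identity by bin-lattice overlap means a single merged
  region can absorb adjacent planted regions if they sit within 2 kb
  (avoided by construction in the generator, possible on real data).
- The published atlas's headline counts (20,313 CHMs, 2,677 universal,
  etc.) derive from genome-scale public ChIP-seq/WGBS accessions; this
  package recomputes their internal count/percentage arithmetic
  (`pipeline.verify_printed_ratios`) but does not reproduce the counts
  themselves at desk scale.
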