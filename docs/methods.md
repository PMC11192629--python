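# Methods

## The model

A *nullomer* of a genome is a k-mer that occurs nowhere in it, on
either strand. Somatic mutations can create previously absent k-mers:
each edited base can change up to k overlapping windows, and any of
those windows that is absent from the reference has *emerged*. Because
emerged nullomers are sequence-specific and recur at driver loci across
patients, their occurrence counts in cell-free RNA act as a cancer
signal, which the package classifies with an L1-regularized logistic
model under a repeated cross-validation protocol.

The pipeline has four stages, each usable on its own:

1. **Presence index** (`nullorna.index`). All k-mers of the genome and
   its reverse complement are recorded in a flat bit-array of 4^k bits
   (code = base-4 value of the sequence, A=0 C=1 G=2 T=3). Membership
   is O(1); k is capped at 16 (512 MiB worst case). Windows containing
   any non-ACGT character are skipped, not expanded; lowercase
   (soft-masked) bases are uppercased, since masking is irrelevant to
   absence. Indexing both strands makes the presence set closed under
   reverse complement, so the lexicographically smaller of a k-mer and
   its reverse complement (the *canonical form*) is a well-defined
   representative used for all deduplication.

2. **Emergence** (`nullorna.emergence`). For each variant the local
   mutated window is rebuilt: up to k−1 reference bases of flank on
   each side of the edited span (truncated at contig ends), with the
   reference allele replaced by the alternate. Insertions follow the
   MAF convention (inserted between `Start_Position` and the next
   base); coordinates are 1-based inclusive externally and 0-based
   half-open internally. Every k-mer of the window is tested against
   the index; this is provably identical to testing only
   edit-overlapping windows, because any window lying wholly in
   unedited flank is a reference substring and fails the membership
   test. Emerged nullomers are reported in canonical form; a variant
   is "nullomer emerging" iff it creates at least one. Variants whose
   stated reference allele disagrees with the genome, or whose window
   contains an ambiguous base, are skipped with a logged warning.
   Overlapping variants in one sample are applied independently to the
   unmutated reference (no phasing); germline subtraction is assumed
   done upstream.

3. **Channels** (`nullorna.channels`). SNVs are typed on the
   pyrimidine strand by their trinucleotide context ("A[C>T]G"; 6
   substitutions x 16 contexts = 96 channels). Indels are typed by the
   83-channel scheme: 1-bp events by affected base (pyrimidine strand)
   and the reference homopolymer run length (deletions 1..6+,
   insertions 0..5+), longer events by length (2,3,4,5+) and
   adjacent tandem-repeat copy number (deletions count the deleted
   copy, 1..6+; insertions count reference copies only, 0..5+), and
   non-repeat deletions by breakpoint microhomology (2:1, 3:1–2,
   4:1–3, 5+:1–5). Labels print the observed run/copy count directly
   ("1:Del:T:6" for a deletion inside a 6-homopolymer). Multi-base
   substitutions (DNP/TNP/ONP) pass through the emergence machinery
   but receive no channel label.

4. **cfRNA classification** (`nullorna.cfrna`, `nullorna.classify`).
   Reads are scanned directly for a fixed nullomer panel; a window
   matches if it equals a panel sequence or its reverse complement,
   overlapping occurrences all count, and a palindromic match counts
   once. The sample x nullomer count matrix is then processed in a
   fixed order: entries ≤ 2 are zeroed (false-positive suppression),
   nullomer columns with total count < 10 are dropped, and each row is
   scaled to counts-per-million. The classifier is a lasso logistic
   regression tuned over 20 penalty values evenly spaced in
   [0.05, 1.0] (glmnet-style lambda; fitted via liblinear with
   C = 1/lambda and per-fold feature standardization) by mean
   out-of-fold ROC AUC over stratified 10-fold CV repeated `n_repeats`
   times (default 100); AUC ties resolve toward the larger, sparser
   penalty, and a fold whose predictions are constant scores chance
   (0.5). Out-of-fold probabilities at the chosen penalty, pooled
   across repeats, give the ROC/PR curves, AUCs and the Brier score.
   Features with non-zero coefficients in more than 90% of the
   folds x repeats refits are reported as *stable*; these refits reuse
   the tuning partitions, so exactly n_folds x n_repeats models are
   tracked.

### Calibration

Calibration is summarized by the intercept and slope of a
maximum-likelihood logistic regression of outcomes on
logit(probability) (probabilities clipped to [1e−6, 1−1e−6]); a
perfectly calibrated model gives (0, 1) and logit-inflated
(overconfident) probabilities give slope ≈ 1/inflation. When the slope
departs from 1 by more than 0.2 — a deterministic surrogate for
judging a sigmoidal reliability curve by eye — Platt scaling (the same
ML sigmoid, applied as a correction) recalibrates the pooled
probabilities. Platt scaling is monotone, so ranking metrics (ROC/PR
AUC) are unchanged, and as an ML fit it cannot increase log-loss on
the data it was fitted to.

## Synthetic data: what it emulates and what it does not

The generator (`nullorna.simulate`) produces the three inputs the
analysis consumes, at toy scale, deterministically per seed.

**Genome**: a single contig of i.i.d. bases (default 10 kb, GC 0.41,
human-like). At this size the nullomer space at k = 8–10 is non-trivial
while the index stays tiny; the same code paths support the real-scale
k = 12–16 on gigabase genomes but tests do not exercise them.

**Cohort**: 4 cancer types x 12 patients, per-patient mutation counts
Poisson(30), 85% SNVs / 5% insertions / 10% deletions (a typical WES
somatic call composition), indels 1–3 bp, reference alleles read from
the genome, depth ~ Poisson(80) and VAF ~ Beta(2, 6) (mean 0.25). An
optional hypermutator multiplies one patient's count, emulating
extreme-burden tumors.

**Reads**: 30 cases and 30 controls, 1000 error-free reads of 75 bp
per sample. A read is a random genome substring; with the group's
per-read spike probability (cases 0.05, controls 0.005 — a 10x ratio)
one panel nullomer is embedded at a random offset. With
`n_case_specific` set (the default study condition uses 10 of a
20-nullomer panel), case spikes draw only from the tumor-associated
subpanel and control background from the rest, emulating the
compositional structure of the real assay: tumor-derived fragments
carry recurrent tumor nullomers while healthy background hits other
sequences. This structure matters because CPM normalization removes
total-abundance differences by construction, and the count-zeroing
threshold is designed to absorb sporadic background — the read depth
is chosen so control contamination per nullomer (mean 0.25) stays
below that threshold while case counts (mean ~5 per tumor-associated
nullomer) sit well above it. Spiked reads are re-drawn in the rare
event that the embedding junction creates an extra panel occurrence,
so the recorded truth table is exact. Optional uniform substitution
errors can be applied outside embedded spans.

What the generator does *not* model: mutational-signature structure,
transcript abundance and expression (reads are genomic substrings, not
transcripts), sequencing-quality profiles, adapter/contaminant
content, and alignment artifacts. Passing tests therefore demonstrate
the correctness of the computation and the behavior of the protocol
under its assumptions — not the clinical performance of nullomer
panels on real cfRNA, where upstream read processing, library
composition and biological variability dominate.

## Numerical and design choices

- **Tie-breaks**: recurrence ranking orders by distinct-patient count,
  then lexicographically by nullomer; gene density by density then
  gene symbol; penalty ties toward the larger lambda. All outputs are
  order-independent of input shuffles.
- **Degenerate inputs**: empty read sets give all-zero counts with a
  warning; all-zero count rows pass CPM unscaled; constant
  probabilities make the calibration slope undefined (rejected);
  constant out-of-fold predictions score AUC 0.5; classes smaller than
  the fold count reduce the fold count with a warning.
- **Determinism**: every stochastic step takes an explicit seed
  (NumPy `default_rng`; CV fold assignment via scikit-learn's seeded
  `RepeatedStratifiedKFold`; liblinear seeded), so fixed seed + fixed
  inputs reproduce results bit-for-bit.
- **Serialization**: the index persists as a 4-byte magic, k, a
  genome identifier, the popcount (verified on load), and the raw
  little-endian bit-array. Tables are TSV, UTF-8, '.' for missing,
  floats at 6 significant digits.
- **Scale used in tests**: brute-force oracles run on genomes ≤ 5 kb
  with k ≤ 8, where exhaustive substring sets are cheap; the
  classifier protocol runs at 10-fold x 10 repeats in the analysis
  script (the 100-repeat default remains the library default). These
  sizes are the package's chosen study conditions for its own checks.

## Known limitations

- k ≤ 16 and a dense bit-array only; no succinct structures, so
  k = 16 on any genome costs 512 MiB of index.
- Read scanning counts occurrences in reads directly; the original
  assay counted k-mers in aligned, deduplicated, contaminant-filtered
  reads, so absolute counts are not comparable between the two — only
  the downstream protocol is.
- The 28-channel indel and doublet-substitution channel taxonomies are
  not implemented; multi-nucleotide substitutions emerge nullomers but
  are unlabelled.
- Cancer-type-specific nullomer sets use exact presence/absence across
  cohorts and are therefore sensitive to cohort size; no significance
  is attached to them.
- Cross-assembly reconciliation (index built on one reference, reads
  derived from another) is the user's responsibility: one genome per
  run.
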