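# Methods

This note documents the models, parameter choices and numerical details
behind each stage of the pipeline, plus what the synthetic-data tests do
and do not demonstrate about real resequencing data.

## Synthetic data model

The generator emulates a diploid sample diverged from a haploid
reference, positionally rather than at read level:

* **Reference**: i.i.d. bases with symmetric AT/GC pair probabilities,
  so the expected G+C fraction equals the `gc` parameter (default 0.35,
  a typical plant-genome value).
* **Small variants**: homozygous SNPs are placed on both haplotypes,
  heterozygous SNPs on one (chosen at random); indels (1–10 bp, half
  insertions) are split evenly hom/het. Inside forced-homozygosity
  blocks only homozygous SNPs occur. Variants are never placed inside
  implanted large deletions or copy-0 segments, where they would be
  unobservable.
* **Depth**: each haplotype contributes Poisson(coverage/2 × copies)
  reads per position; CNV segments assign the extra copy to haplotype 1,
  large deletions zero one (het) or both (hom) haplotypes. The default
  per-sample coverage is 30× and the reference-side simulated track is
  40× — the re-sequencing depths the study design uses. Simulating the
  reference side directly as a Poisson track (rather than simulating and
  re-aligning reads) preserves its statistical role — damping shared
  coverage artifacts in the ratio — without an aligner dependency.
* **Allele observations**: binomial splits of the site depth by
  haplotype, with symmetric substitution errors at `error_rate`
  (default 0.005, i.e. Q23-equivalent); errors at non-variant sites are
  multinomial over the three non-reference bases. No quality scores are
  modelled: every downstream filter acts on counts only.
* **Read pairs**: fragments drawn uniformly per haplotype with
  insert ~ N(500, 50²) bp and 100-bp reads, mapped back to reference
  coordinates through the deletion map, so a fragment spanning a
  deletion of length L maps at distance ≈ insert − read_len + L. Pairs
  overlapping declared repeat regions are emitted non-unique.

The expected number of pairs spanning a deletion breakpoint is
`pair_depth × (insert_mean − 2·read_len)`; recovery experiments use
`pair_depth = 0.05` so each implanted deletion has ≈ 15 expected
supporting pairs.

What this generator deliberately does **not** model: GC-bias and
mappability variation, overdispersed coverage, indel sequencing errors,
base-quality structure, and linked variation (LD). Passing recovery
tests therefore demonstrate the callers' correctness under their own
model assumptions, not their performance on real Illumina data, where
coverage heterogeneity and alignment artifacts dominate error budgets.

## Variant calling

Coverage statistics (mean μ, SD σ) are computed over positions covered
by ≥ 3 reads; that floor defines "covered" for all density denominators
but is not itself a call filter. A call requires, as a pure conjunction
(each filter independently toggleable):

| filter | default | note |
|---|---|---|
| depth ≥ μ | on | conservative: drops sub-average-coverage regions |
| alt count ≥ μ/2 | on | `--support-base site` switches the denominator to the site depth |
| allele freq ≥ 0.2 | on | screens somatic/mosaic signal |
| p ≤ 0.05 | on | one-sided exact binomial tail, error rate 0.01 (Fisher variant behind a flag) |
| depth ≤ μ + 6σ | on | collapsed-repeat guard, read as mean plus six SDs |

Zygosity: allele frequency ≥ 0.75 → homozygous (the conventional
genotyper default; no value is published for this pipeline).
Multi-allelic sites keep the single most-supported alternate.

A structural consequence of the depth ≥ μ rule under uniform
(Poisson-distributed) coverage: about half of all sites fall below the
mean, and at heterozygous sites the support rule alt ≥ μ/2 is a further
coin flip against Binomial(depth, ½). Measured on a 1-Mb genome at 40×
with error 0.005, recall against the full truth set is ≈ 0.43 overall
(hom ≈ 0.47, het ≈ 0.33) at precision 1.00. This is the filter set
working as designed — it trades recall for precision — and the recovery
suite records it rather than hiding it.

## Digital-CGH segmentation

Window means (500 bp, final short window kept and flagged) are
normalized by each track's genome-wide mean depth, then
log₂((t + c)/(r + c)) with pseudocount c = 0.5 on the window mean;
zero-flag (target raw depth 0, reference covered) uses pre-pseudocount
depths. Because the normalizer is the genome-wide mean, implants
covering a non-trivial genome fraction shift all ratios slightly; with
the recovery experiment's ≈ 10% CNV content the bias is < 0.02 log₂
units.

CBS: the statistic is the standardized difference of means between an
arc of windows and its complement, maximized over all arcs (exhaustive
O(n²) search). A split is accepted when its permutation p-value
(1 + #exceedances)/(1 + n_perm) ≤ α, with n_perm = 1000 and α = 0.01 by
default. The permutation stream for a segment is seeded from
(seed, segment offset, segment length), which makes results independent
of recursion order and acceptance decisions monotone in α; evaluation
stops early once the exceedance count guarantees p > α. No post-hoc
segment merging ("undo") is performed. On ≤ 50-window profiles the
accepted changepoints are verified identical to an independent
exhaustive-search oracle sharing the permutation protocol.

Classification: gain if mean log₂ ratio ≥ +0.58, loss if ≤ −0.58
(1.5-fold change, the conventional single-copy cut at diploid baseline;
the published analysis states only "significant" shifts, so the cut is
config-exposed). PAV — ≥ 1 kb of consecutive zero-flagged windows — is
a loss subtype. Segments shorter than 1 kb are not retained as events.
Recovery experiments pass explicit cuts of ±0.3 instead of the ±0.58
defaults: ±0.58 equals log₂(3/2) exactly, i.e. it sits *on* the copy-3
class boundary, so the midpoint between the copy-2 and copy-1/3
expectations is the correct decision threshold when single-copy changes
must be classified.

## Large deletions

Non-unique pairs are removed first (a duplicated region maps its pairs
ambiguously — without this, intra-chromosomal duplications masquerade as
deletions). Discordant = mapped distance in [10 kb, 1 Mb]. Each pair's
implied deleted interval is [pos1 + read_len, pos2 − insert_mean];
clusters are single-linkage chains of overlapping implied intervals, and
clusters with ≥ 3 pairs emit a call whose interval is the intersection
of implied intervals (median endpoints as fallback). Exact breakpoints
are not claimed: endpoint accuracy is bounded by the insert size.

## Runs of homozygosity

Windows of 500 consecutive SNPs slide one SNP at a time; a window is
homozygous when it contains ≤ 1 heterozygous-or-missing call. Each SNP
scores the fraction of spanning windows that are homozygous, and a SNP
qualifies when its score ≥ 0.05 — the scanning convention and default of
the standard ROH tool (a SNP belongs to a run as soon as a twentieth of
its windows is clean; the window, not the single SNP, carries the
evidence). Maximal runs of qualifying SNPs spanning ≥ 50 kb become
ROHs, with boundaries at the first/last SNP (not extended into flanking
SNP-free sequence). ROHs overlapping loss/PAV segments by ≥ 1 bp are
excluded — hemizygous regions mimic homozygosity — but flagged rather
than silently dropped. In single-sample mode only het calls count
toward the allowance; a cohort's missing-genotype positions can be
supplied explicitly.

The ROH recovery experiment implants a 200-kb block in a background of
hom 3.5×10⁻³ + het 2×10⁻³ SNPs/bp — the hom/het proportions of the most
homozygous cultivar in the published per-cultivar densities — because a
200-kb block must hold comfortably more than one 500-SNP window for the
scan to see it.

## Genic impact and selection

Variants are projected strand-aware onto CDS/UTR intervals; alternate
alleles are complemented for minus-strand codon logic, and SNPs sharing
a codon are applied jointly before translation. Premature stop = an
internal codon becoming TAA/TAG/TGA; lost stop = the terminal stop
destroyed, with the next in-frame stop located within 3 kb downstream.
Frameshift iff the CDS-overlapping net indel length is not a multiple of
three. A gene is a putative pseudogene when it carries ≥ 1 premature
stop in ≥ 1 sample; cross-sample sharing is partitioned
specific-to-one / shared-by-all / intermediate.

dN/dS uses NG86 counting with these conventions (shared by the
brute-force test oracle): synonymous site fractions are averaged between
the two sequences; mutations creating a stop count as nonsynonymous;
codons that are stops (or carry N) in either sequence are skipped;
multi-substitution codons average Sd/Nd over all substitution orderings,
excluding pathways through stop codons unless all are blocked. Rates
are Jukes–Cantor corrected, d = −(3/4)·ln(1 − 4p/3), undefined (flagged)
for p ≥ 3/4 or dS = 0. Significance is a Fisher exact test on the
rounded (Nd, N−Nd; Sd, S−Sd) table; purifying/diversifying labels
require p < 0.05. The published analysis used a maximum-likelihood
dN/dS estimator; NG86 was chosen here because it is fully specifiable
and oracle-checkable, and class labels at |dN/dS − 1| ≫ 0 are robust to
the estimator. The method name is recorded in the output.

Heterozygous alternate alleles are included when building the alternate
CDS (phasing is unavailable; "more than five SNPs" is the published
inclusion rule, implemented as > 5 CDS SNPs). Transcripts with CDS
indels are excluded from dN/dS so the codon alignment stays gap-free.

## Cohort summaries

Densities are 10⁶ × count / covered bases, ratios het/hom, both printed
half-up at one decimal (raw values retained); ΔGC is
100 × [GC fraction of alt alleles − GC fraction of ref alleles] over SNP
sites. Region sharing uses any-overlap by default (no reciprocal
threshold is published; a `reciprocal` fraction is available), and the
bp-level partition is exact interval algebra that conserves each
sample's merged total. The genome track is 20-kb windows of mean depth
over covered positions, normalized to the genome-wide covered mean.

## Problem sizes

The recovery suite runs on 1–2 Mb genomes: 1 Mb at 40× for variant
calling (~3000 implanted SNPs), 2 Mb at 30× for CNV recovery (10
segments, copy 0/1/3/4, 2–50 kb), 2 Mb for deletions (15 kb and 200 kb),
1 Mb for ROH (one 200-kb block), plus 100 pure-noise 200-window profiles
for the CBS null rate and 10 random 300-codon pairs for the dN/dS
oracle. These sizes give every statistic a comfortable expected-count
margin while keeping the full suite and the acceptance script to a
couple of minutes each on one CPU.

## Known limitations

* Coverage is the only CNV evidence; absolute copy number is not
  inferred, and no GC/mappability correction is applied.
* The deletion caller reports no zygosity and no split-read refinement.
* ROH detection cannot distinguish inbreeding from mosaic structural
  variation beyond the loss-overlap exclusion.
* The binomial significance model assumes independent errors at a fixed
  rate; real base-quality structure is not used.
* dN/dS on unphased pooled alternate alleles can mix haplotypes within
  a codon.
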