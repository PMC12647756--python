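# Methods

## Model of the experiment

The pipeline targets a pooled-germline design: a perturbation is applied
transiently to meiotic nuclei, embryos derived from those nuclei are pooled,
and DNA from the pool is long-read sequenced at moderate coverage. Under the
assumption that de novo rearrangements arise independently in each nucleus,
the pool is a mixture of thousands of haplotypes, each carrying a private
set of SVs. At coverage *C* over *n* nuclei, the expected number of reads
supporting any one private SV is ≈ *C*/*n* — for *C* = 30 and *n* in the
thousands, far below 1. Consequently:

* a captured SV is supported by one read, occasionally two — hence the
  rare-variant filter keeps calls with support ∈ {1, 2} and discards
  higher-support calls (those are either shared variants or artifacts);
* the expected number of *captured* events of a type is
  (events per nucleus) × (coverage), independent of read length — this
  identity sizes every synthetic study below;
* the comparison between conditions is a count comparison, valid only after
  the two libraries are made exchangeable (resampling, below).

## Synthetic data generator

**Reference.** I.i.d. uniform bases, chromosomes named `LGI`, `LGII`, …
Uniform composition is deliberate: it is the correct null for the
flanking-repeat scan, which asks whether breakpoints co-locate with repeats
beyond chance.

**Events.** Per nucleus and type, counts are Poisson with configurable
rates; positions uniform over the genome; lengths log-uniform on a
configurable range (default 1–100 kb, matching the three reported size
classes 1–10, 10–50, 50–100 kb); events of one nucleus are redrawn until
non-overlapping, with an explicit `PlacementError` if the density is
infeasible. Translocation (BND) mates are always placed on a different
chromosome: an intra-chromosomal "translocation" is geometrically a
deletion- or duplication-like junction and would be (correctly) classified
as such by any split-read caller.

**Reads.** Lengths are log-normal (default mean-log 9.0, sd-log 0.5 ≈ 10-kb
mean, a typical genomic nanopore library); each read's donor nucleus is
uniform. Reads are emitted pre-aligned: mapping is not the subject of the
pipeline, and bypassing an aligner keeps runs self-contained and exactly
ground-truthed. A read is traced through its donor's derived genome and may
chain through any number of junctions: in-CIGAR `D`/`I` for deletions (≤100
bp always; larger ones split-pair with probability 0.5, so callers must
handle both evidence classes) and insertions that fit within the read;
split segments with a strand flip for inversions (entering *and* leaving,
so a read traversing a whole inversion yields both junction signatures);
re-covering segments for tandem-duplication junctions; cross-chromosome
segments for BNDs. A breakpoint is "captured" when it lies ≥ 100 bp
(`margin`) inside the available read span; the generator records exactly
which (event, read) pairs it encoded, which is what oracle tests score
against. Multi-junction chaining matters: an earlier single-split-per-read
shortcut made dense arms lose captures to event competition and biased the
recovered folds downward.

**Noise.** The dominant nanopore artifact is modeled: spurious indel events
at a per-bp rate (default 5 × 10⁻⁵, ~0.5 events per 10-kb read), each an
insertion or deletion of length uniform on [1, 50] bp spliced into matched
segments with query length conserved. Base-level realism (homopolymer bias,
quality strings, mismatches in emitted sequence) is out of scope — SEQ is
`*`; nothing downstream reads base identities from the SAM.

**What passing tests do not show.** The generator has perfect mapping, no
repeat-induced ambiguity, no chimeric artifacts, no coverage biases, and
haploid nuclei (no dosage). Results on it validate the statistics and the
bookkeeping, not robustness to alignment artifacts in real libraries; real
callsets can enter via the VCF boundary instead.

## Caller

Signatures per primary read: merged `D`/`I` runs ≥ 30 bp (runs of the same
type separated by ≤ 100 bp of matches are merged, as aligners fragment
single events); split-pair geometry classified by chromosome, strand and
overlap (gap → DEL, re-coverage → DUP, strand flip → INV with the interval
delimited by the junction, cross-chromosome → BND keyed on the
lexicographically smaller breakend). Supplementary segments' own CIGARs are
also scanned so chained reads lose no evidence. Clustering is
single-linkage within (type, chromosome): starts within 500 bp and length
ratio ≥ 0.7 (BNDs: both breakends within the window). Call coordinates are
medians over member signatures with ties to the lower coordinate
(determinism); support counts distinct reads. The 30-bp signature floor is
deliberately far below the 1000-bp analysis filter so that the error-filter
test is a real test of the filter, not of the caller.

## Resampling

Both libraries are binned on read length (default 20 log-spaced bins from
500 bp to the pooled 99.9th percentile, plus an overflow bin) and each bin
is subsampled without replacement to min(count_A, count_B). This is the
strongest reading of "eliminate bias": binned length distributions become
identical and totals equal by construction, at the cost of discarding reads
(reported per bin, with before/after KS distance). Resampling happens at
the read level *before* calling so support counts reflect matched depth; a
post-call support-subsampling mode exists for external VCFs where reads are
no longer available.

## Burden statistics

* Length filter strict (svlen > 1000 bp); bin edges half-open with 1000
  inclusive — the two thresholds are independently configurable.
* BND calls have no length; they bypass the length filter and appear only
  in per-type overall counts, not in bins or windows.
* Fold = raw count ratio; a pseudocount (default 1) enters only when the
  control cell is zero and such cells are flagged. No normalization beyond
  resampling — counts are compared raw by design.
* Windows: 300-kb non-overlapping tiles, a call assigned by its start
  coordinate. Per window and type, a pooled two-proportion z test of window
  count against the genome-wide type total in each condition; Holm–Šídák
  step-down adjustment across the windows of each type; degenerate windows
  (both counts zero) get p = 1. The z test was chosen as the simplest
  calibrated proportion test; its Monte-Carlo calibration is part of the
  test suite (empirical size 0.03–0.07 at nominal 0.05, and null
  family-wise error at the nominal level over 200 replicate pipelines).
* `cliffs_delta` and `holm_sidak` are implemented from their definitions and
  cross-checked against brute force and statsmodels; standard tests (the z
  test, KS) are delegated to statsmodels/scipy.

## Breakpoint repeat scan

Flanks of length 200 bp (default) left of `start` and right of `end`;
longest shared substring exact-match DP, direct and inverted (reverse
complement), ties to the leftmost occurrence in the left flank;
microhomology as the standard deletion walk (identical bases reading right
from both breakends), capped at 25 bp; "notable" report threshold 10 bp.
Exact matching keeps the null clean and the scan deterministic; fuzzy and
repeat-family annotation are out of scope. The null is the same scan after
moving each call to a uniform random breakpoint of equal length; observed
vs null distributions are compared by a two-sample KS test (asymptotic —
the statistics are small discrete integers with heavy ties).

## Desk-scale study sizes

The canned studies (`raresv.study`, used by the acceptance script and
tests) run on a 2-Mb genome rather than a ~100-Mb animal genome. Because
captured events per type ≈ rate × coverage, observing ≥ 500 events per
type per arm at 5000 nuclei and 30× forces ~20 planted events per nucleus
per type. On 2 Mb, per-nucleus non-overlap packing then requires smaller
events than the 1–100 kb default: the enrichment-recovery design uses
log-uniform 1–20 kb (DEL/DUP/INV) and 1–8 kb (INS; an insertion longer
than the read minus flanks cannot appear as an `I` operation at all).
These sizes are a property of the scaled-down genome, chosen from that
packing arithmetic, not from the comparison's outcome. Event density this
high also means measurable read-level interference between events (query
spent re-traversing duplications, occasional cluster collisions), which
biases recovered folds a few percent toward 1 — visible in the acceptance
numbers (DEL ≈ 1.8 for a planted 2.0) and absent in the equal-rate null.
The null-calibration design (300 nuclei, 2 × 600 kb, 15×, rate 10) keeps
~37 expected counts per 300-kb window so the z test's normal approximation
is comfortable at the Holm–Šídák-adjusted tail.

## Numerical and degenerate-input choices

Coordinates 0-based half-open internally; SAM/VCF emitted 1-based, negative
SVLEN for deletions on output and either sign accepted on input. All
randomness flows through per-stage seeds derived from one global seed and a
stage label (CRC-mixed, < 2³¹), so every artifact is byte-reproducible and
recorded in a checksum manifest. Median ties resolve low; empty callsets,
empty libraries-within-a-bin, and single p-values all take their defined
degenerate paths rather than erroring. Known limitations: haploid nuclei
(no heterozygosity or dosage), perfect mapping, exact-match repeat scan,
no base-level error realism, and BND handling limited to reciprocal-free
single junctions.
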