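# raresv

Rare structural-variant (SV) burden comparison for pooled-nucleus long-read
libraries.

## The problem

When a perturbation acts transiently on a germline, each affected meiotic
nucleus can acquire its own private de novo rearrangements. Sequencing DNA
pooled from many thousands of resulting embryos at ~30× coverage means any
single de novo SV is sampled by at most one or two reads — far below the
support thresholds ordinary SV pipelines use. The signal of interest is not
any individual call but the *excess burden*: are deletions, duplications,
insertions, inversions or translocations more frequent in the treated pool
than in the control pool?

`raresv` implements this comparison end to end for people analyzing such
pooled designs (and for validating the statistics on synthetic data):

1. **simulate** — generate a reference, plant per-nucleus Poisson-rate SV
   events (non-overlapping within a nucleus), and emit pre-aligned
   nanopore-like reads (SAM) whose CIGARs and split alignments carry the
   expected SV signatures plus short spurious indels;
2. **call** — extract in-CIGAR (`I`/`D` runs) and split-read signatures and
   single-linkage cluster them into typed calls with per-call supporting-read
   counts;
3. **resample** — subsample both libraries to the per-length-bin minimum so
   read counts and length spectra match exactly before any comparison;
4. **burden** — keep rare (support ∈ {1, 2}) large (svlen > 1000 bp) calls,
   tabulate counts per type and size bin (1–10 kb, 10–50 kb, 50–100 kb),
   report fold enrichment treatment/control, and test non-overlapping 300-kb
   windows genome-wide with a two-proportion z test, Holm–Šídák corrected
   per type (Cliff's delta is provided for effect sizes on continuous
   measures);
5. **repeats** — scan breakpoint flanks for direct/inverted repeats and
   junction microhomology, against a permuted-breakpoint null.

## The statistic at the core

For condition *t* (treatment) and *c* (control), after resampling and
filtering, per SV type and size bin:

    fold = n_t / n_c            (pseudocount only when n_c = 0, marked)

and per 300-kb window *w* of type *k*, a two-proportion z test of
(n_{t,w,k}, N_{t,k}) vs (n_{c,w,k}, N_{c,k}) with step-down Šídák
adjustment over the windows of that type:

    p_adj(k) = max_{j<=k} [ 1 - (1 - p_(j))^(m - j + 1) ]

## Worked example

```python
from raresv.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    mode="synthetic", seed=11, out_dir="demo_run",
    chrom_lengths=(600_000, 600_000), n_nuclei=500, coverage=20,
    control_rates={"DEL": 5, "DUP": 5, "INS": 5, "INV": 5, "BND": 0.3},
    treatment_multipliers={"DEL": 2.0, "DUP": 3.0},
    size_model={"min_len": 1_000, "max_len": 20_000},
    ins_size_model={"min_len": 1_000, "max_len": 8_000},
)
run_pipeline(cfg)
print(open("demo_run/summary.txt").read())
```

prints

```
Rare large-SV burden comparison
==================================
filter: svlen > 1000 bp, support in [1, 2]
  DEL:   168 vs    85  fold = 1.98
  DUP:   292 vs    87  fold = 3.36
  INS:    49 vs    54  fold = 0.91
  INV:    87 vs    92  fold = 0.95
  BND:     2 vs     4  fold = 0.50
windows (300000 bp): 1 significant at alpha = 0.05
```

Reading: the treatment arm was simulated with deletion rates doubled and
duplication rates tripled; after resampling and rare-large filtering the
pipeline recovers folds of ~2 and ~3.4 for DEL and DUP while the untouched
types sit near 1. Counts are rare-variant calls (each typically supported by
a single read); `demo_run/` also contains the SAMs, VCFs, per-bin fold
table, window tests, repeat scan, and a checksum manifest — rerunning the
same config and seed reproduces every data artifact byte for byte.

The same analysis is available from the shell:

```bash
raresv run --config sim.yaml --seed 11 --out-dir demo_run
raresv burden treat.vcf ctrl.vcf --genome ref.fa.fai --min-len 1000 --support 1,2
raresv repeats calls.vcf --ref ref.fa --flank 200 --out repeats.tsv
```

Real data enter either as SAM alignments (`mode: sam`) or as externally
called SV VCFs (`mode: vcf`; SUPPORT/RE/DV tags are mapped onto support).

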