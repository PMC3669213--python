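# Methods

## Model and assumptions

The caller treats a ChIP-seq experiment as a per-base signal track:
deduplicated single-end reads extended to the mean fragment length
(150 bp) and piled up, then scaled so the genome-wide mass equals
10⁹ bp. Differential calling assumes (i) the two samples are on this
common scale, (ii) 100-bp bin means are locally exchangeable, so a
paired *t*-test on positionally matched bins is a meaningful test of a
local shift, and (iii) deduplicated read starts approximate a Poisson
process, so local enrichment can be judged against a Poisson upper
tail. No input/IgG channel, replicate structure or mappability model is
used; thresholds are applied raw, with no multiple-testing correction,
matching the procedure's published operating point.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `ext_len` | 150 | bp | fragment-length read extension |
| `target_total` | 1e9 | bp | normalized genome-wide signal mass |
| `bin_size` | 100 | bp | scan bin width |
| `seed_bins` / `max_bins` | 5 / 50 | bins | seed width / accumulated-region cap |
| `scan_alpha` | 0.01 | — | per-window *t*-test threshold |
| `min_fold` | 2.0 | — | fold-change criterion |
| `pseudocount` | 1.0 | normalized units | stabilises the fold ratio at near-zero means |
| `merge_gap` | 1000 | bp | regions closer than this merge |
| `background_extent` | 10 000 | bp | local-background window |
| `enrich_window` / `enrich_step` | 100 / 1 | bp | Poisson scan geometry |
| `enrich_alpha` | 1e-5 / 1e-3 | — | punctate / broad mark thresholds |
| promoter flank | 2000 | bp | TSS ± flank defines the promoter |

Mark-specific thresholds are selected by a `mark_class` label
(punctate: promoter-focused marks such as H3K4me3/H3K9ac; broad:
domain-scale marks such as H3K27me3/H3K9me3) rather than by mark-name
matching, so the tool generalises to other marks.

## Design choices

**Seed extension semantics.** Two readings of "slide a significant
seed window in 1-bin steps until p > 0.01 or fifty bins" are
implemented. The default (`extend_mode="slide"`) keeps the window at
its seed width, slides it one bin per step, re-tests at each step, and
accumulates the region swept while every step stays significant. The
alternative (`extend_mode="grow"`) re-tests the whole growing window.
Slide is the default because whole-window re-testing lets a long
window remain significant on the strength of its earliest bins: on
simulated 2-kb differential regions it drags boundaries 3–5 kb
downstream, diluting the region means that feed the fold-change
criterion and destroying recall, whereas the sliding window stops
within a few bins of the true edge.

**Per-seed union instead of skip-ahead scanning.** Every bin is
evaluated as a potential seed and overlapping per-seed stretches are
unioned. Resuming the scan after an emitted region would be marginally
cheaper but can miss territory a seed interior to an emitted region
would have reached; the union is, by construction, identical to the
exhaustive all-start reference and still near-linear in practice
because stretch extension is O(1) per step on prefix sums.

**Degenerate *t* statistics.** Zero-variance differences give p = 1
when the mean difference is zero and p = 0 otherwise — the limits of
the *t* statistic. This makes `call_dhmrs(a, a)` exactly empty.

**Poisson testing on read starts.** Window enrichment uses counts of
deduplicated read 5′ starts, not per-base extended coverage: extended
coverage is serially correlated over the 150-bp fragment and grossly
overdispersed relative to Poisson, while read starts are the closest
observable realisation of the underlying sampling process. λ is
estimated per sample from read starts in a 10-kb window centred on the
region (widened to the region itself when the region exceeds 10 kb,
clipped at chromosome ends); the window deliberately includes the
region, making the background conservative for enriched regions.

**Keep-if-any enrichment.** A region is retained when at least one
sample contains an enriched window. A genuine gain or loss is usually
enriched only on its high side, so requiring both samples would
discard exactly the events of interest; a strict-both mode exists
(`enrich_mode="both"`) for sensitivity analysis.

**Fold-change re-check after merging.** Merging two fold-passing
regions across a < 1-kb gap can pull the merged region's recomputed
fold below 2; the filter is re-applied to merged regions so every
emitted record satisfies the published criterion. Merging ignores
direction; a merged region's direction is recomputed from its overall
means.

**DHMG direction.** When a promoter overlaps DHMRs of mixed direction
the gene takes the direction of the DHMR with the largest promoter
overlap, ties broken by larger |m̄_b − m̄_a|. Genes with several
transcripts contribute one promoter per distinct (gene, TSS) pair and
are reported at the gene level.

**Reversal and disappearance.** "Reciprocal" requires strict direction
opposition between the two comparisons. DHMR disappearance is ≥ 1-bp
interval overlap absence, the simplest reading of a Venn construction.
The promoter z-test is the unpaired large-sample form
z = (m̄_x − m̄_y)/√(s²_x/n_x + s²_y/n_y) with a two-sided normal
p-value; both-samples-zero variance is reported as a degenerate-input
error.

## Synthetic data: what it does and does not emulate

The generator reproduces the features the caller's statistics rely on:
uniform-rate Poisson read starts (an optional Gamma-mixed
overdispersion knob defaults off), rectangular rate bumps with known
fold, direction and position — half centred on promoters of generated
genes so gene-level recovery is measurable — a third condition equal to
the control at a configurable share of spikes and to the treated
condition elsewhere, Bernoulli(½) strands, SE50 reads and 20% PCR
duplication. Defaults are one 10-Mb chromosome, 0.05 read starts/bp
(≈ 500 k reads, matching genome-wide ChIP depth per Mb), 100 spikes of
2 kb at 4-fold, and 80% drug reversal — a mid-to-high operating point
chosen once as a realistic degree of drug-mediated epigenetic
restoration in this three-condition design.

It does **not** emulate sequence content, alignment or mappability
artefacts, fragment-length variation, chromatin-state-dependent
backgrounds, copy-number variation, or the smooth shoulders of real
peaks (spikes are rectangular so truth boundaries are unambiguous for
scoring). Passing recovery tests therefore demonstrates correctness of
the statistical machinery under its own assumptions, not performance
on real libraries, where overdispersion and mappability structure
lower both recall and precision.

Scoring: a spike counts as recovered when a called region covers at
least half of it; a called region is a false positive when it overlaps
no spike at all.

## Numerical choices

- All coordinates are 0-based half-open internally; GTF (1-based
  closed) is converted at the I/O boundary only.
- Window *t* statistics use prefix sums of the per-bin differences and
  their squares (O(1) per window); tiny negative variances from
  cancellation are clamped to the degenerate branch. Significance
  during extension compares |t| to the inverted critical value
  `stdtrit(df, 1 − α/2)` so no CDF is evaluated per step.
- Poisson window calls precompute the smallest enriched count k_min
  with P(X ≥ k | λ) < α once per region, so the 1-bp sliding scan is a
  vectorised threshold comparison; clipped terminal windows are tested
  exactly.
- bedGraph output merges equal-value runs, omits zero runs and prints
  floats at full precision (`%.17g`), so a write/read round trip is
  exact per base.
- Metagene portions use floored linspace edges; portions outside the
  chromosome contribute NaN and gene averaging is NaN-aware; genes
  shorter than the body portion count are skipped and counted.
- The pipeline is deterministic: the only random source is the
  simulator's seed, every derived stream comes from a
  `SeedSequence`, and the CLI `--threads` flag is accepted for
  interface compatibility while execution stays single-threaded per
  chromosome, so thread count cannot change results.

## Problem sizes in the test suite

The suite exercises the default 10-Mb / 100-spike conditions for
end-to-end recovery, reversal-logic extremes (reversal fractions 1 and
0 for one punctate and one broad mark) and record-level contracts;
scan/oracle agreement runs on 25 seeded 2 000-bin track pairs; unit
tests use 200-kb smoke fixtures and 10-kb toy chromosomes. The
acceptance script runs the default conditions once, end to end.

## Known limitations

- No input-subtraction, replicate statistics, FDR control or HMM-based
  broad-domain segmentation; the caller reproduces a specific
  published three-criterion procedure.
- The paired 5-bin *t*-test has only 4 degrees of freedom; its p-values
  are approximate for non-Gaussian bin noise, and the 0.01 seed
  threshold is an operating point, not a calibrated error rate.
- Fold change with ψ = 1 normalized unit is scale-dependent at very
  low coverage.
- Single-end reads only; paired-end fragments should be reduced to
  fragment intervals upstream.
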