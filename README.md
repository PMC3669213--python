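# dhmscan

Differential histone modification analysis for ChIP-seq across a
three-condition drug-reversal design.

`dhmscan` is for epigenomics analysts who have aligned single-end
ChIP-seq reads for histone marks (e.g. H3K4me3, H3K9ac, H3K27me3,
H3K9me3) in a control condition, a treated condition, and a
treated-plus-drug condition, and want to know **which genomic regions
changed, which genes those changes sit on, and how much of the change
the drug reverses**.

## Method

**Signal tracks.** Uniquely mapped reads are deduplicated by mapping
position (chrom, start, strand), extended to 150 bp in the fragment
direction, and piled into per-base coverage. Each track is scaled so the
genome-wide signal mass is 10⁹ bp, making samples of different depth
comparable.

**DHMR calling.** Differential histone modification regions between two
tracks are called with three criteria:

1. *Seed-and-extend t-test scan.* The genome is cut into 100-bp bins of
   mean signal. A 5-bin window with a two-sided paired *t*-test
   p < 0.01 on the per-bin condition differences seeds a region; the
   window slides downstream one bin at a time, re-testing at each step,
   until p > 0.01 or the region reaches 50 bins.
2. *Fold change + merging.* Regions must show ≥ 2-fold change in mean
   normalized signal, fc = max((m̄_b+ψ)/(m̄_a+ψ), (m̄_a+ψ)/(m̄_b+ψ))
   with pseudocount ψ = 1; survivors separated by < 1 kb merge.
3. *Poisson enrichment.* Per sample, a local background rate λ is the
   read-start rate of a 10-kb window covering the region; 100-bp
   windows slide in 1-bp steps and a window is enriched when
   P(X ≥ k | Poisson(100λ)) beats 10⁻⁵ (punctate marks) or 10⁻³
   (broad marks). Regions enriched in neither sample are dropped.

**Gene-level reversal.** A gene whose promoter (TSS ± 2 kb) overlaps a
DHMR is a differential histone modification gene (DHMG). Cross-matching
the control-vs-treated DHMG set with the control-vs-treated+drug set
classifies each gene as *reciprocal* (direction flips), *specific* to
the treated comparison, or retained; reciprocal + treated-specific
genes are the drug-**reversed** set. Metagene profiles (25/100/25
portions over 5-kb flanks and the gene body) and a promoter-level
two-sample z-test summarise global signal redistribution.

A seeded synthetic-data module simulates the whole design — Poisson
read starts, rectangular differential spikes with known direction and
fold, PCR duplicates, a drug condition that reverts a chosen share of
spikes — so every stage is testable against ground truth without any
external data.

## Worked example

```python
from dhmscan import (SimConfig, generate_experiment, make_track,
                     analyze_mark)

cfg = SimConfig(chrom_sizes={"chrSim": 1_000_000}, n_genes=40,
                n_spikes=10, reversal_fraction=0.8, seed=17)
exp = generate_experiment(cfg)                 # 3 conditions + truth
tracks = {c: make_track(r, cfg.chrom_sizes) for c, r in exp["reads"].items()}
res = analyze_mark(tracks, "punctate", exp["genes"])
print(res["ct"].summary())
print("disappeared fraction:", res["disappeared_fraction"])
print("reversed fraction:   ", res["reversal"].reversed_fraction)
```

prints

```
Differential Histone Modification Regions
=========================================================
mark class:          punctate (enrichment alpha 1e-05)
scan:                5-bin seed, 50-bin cap, p < 0.01
fold change:         >= 2 (pseudocount 1)
merge gap:           < 1000 bp
---------------------------------------------------------
stage survivors:
  candidates              244
  fold_pass                42
  merged                   37
  enriched                 10
---------------------------------------------------------
DHMRs:               10 (6 up, 4 down)
median width:        2200 bp
median fold change:  3.33
disappeared fraction: 0.8
reversed fraction:    0.8
```

The per-stage survivor counts show the three criteria at work: 244
scan candidates shrink to 42 after the 2-fold filter and to the 10
truly spiked regions after Poisson enrichment. All ten 2-kb spikes are
recovered; 8 of 10 spikes were simulated as drug-reversed, and the
measured DHMR disappearance and DHMG reversal fractions are both 0.8.

The same analysis is available from the shell:

```sh
dhmscan simulate --preset smoke --seed 17 --out fix/
dhmscan signal --reads fix/reads_H3K4me3_c1.bed --chrom-sizes fix/chrom.sizes --out c1.bedgraph
dhmscan call --reads-a fix/reads_H3K4me3_c1.bed --reads-b fix/reads_H3K4me3_c2.bed \
             --chrom-sizes fix/chrom.sizes --mark-class punctate --out dhmrs.bed
dhmscan annotate --dhmrs dhmrs.bed --genes fix/genes.gtf --out dhmgs.tsv
dhmscan compare --ct dhmgs_ct.tsv --cts dhmgs_cts.tsv --out reversal.tsv
dhmscan run-all --config run.yaml
```

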