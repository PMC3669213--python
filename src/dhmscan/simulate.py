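"""Seeded synthetic ChIP-seq with ground truth.

Emulates the three-condition study design (control, treated,
treated+drug) for one histone mark: read starts form a Poisson process
with a uniform background rate, rectangular rate bumps ("spikes") mark
differential regions with known fold and direction, and the third
condition matches the control at reversed spikes and the treated
condition elsewhere. PCR duplicates are injected by re-emitting reads.
Strands are Bernoulli(1/2); reads are SE50 single-end.

Gain spikes are elevated in the treated condition, loss spikes in the
control, so both directions of change occur. A configurable share of
spikes is centred on promoters of the generated genes, making DHMG
recovery testable. Spike edges are kept >= 2 x merge-gap apart so truth
regions can never merge during calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coverage import AlignedRead

TRUTH_COLUMNS = ["chrom", "start", "end", "direction", "fold", "reversed"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic experiment.

    Defaults: one 10-Mb chromosome, background 0.05 read starts/bp,
    100 spikes of 2 kb at 4-fold, 50-bp reads, 20% PCR duplication,
    80% of spikes reversed by the drug condition.
    """

    chrom_sizes: dict = field(default_factory=lambda: {"chrSim": 10_000_000})
    n_genes: int = 200
    gene_length_range: tuple = (2000, 20_000)
    read_length: int = 50
    background_rate: float = 0.05
    n_spikes: int = 100
    spike_width: int = 2000
    spike_fold: float = 4.0
    gain_fraction: float = 0.5
    reversal_fraction: float = 0.8
    promoter_fraction: float = 0.5
    promoter_flank: int = 2000
    duplicate_rate: float = 0.2
    overdispersion: float = 0.0   # Gamma-mixed rate; 0 = pure Poisson
    min_spike_gap: int = 2000     # 2 x merge gap
    seed: int = 17

    def __post_init__(self):
        if not 0 <= self.reversal_fraction <= 1:
            raise ValueError("reversal_fraction must lie in [0, 1]")
        for name in ("background_rate", "duplicate_rate", "spike_fold",
                     "overdispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _rng(config: SimConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, *stream]))


def plan_genes(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Non-overlapping gene spans: chromosomes are cut into equal slots,
    one gene per slot at a random in-slot offset, random strand."""
    rng = rng or _rng(config, 0)
    total = sum(config.chrom_sizes.values())
    rows = []
    gi = 0
    for chrom, clen in config.chrom_sizes.items():
        n_c = max(1, round(config.n_genes * clen / total))
        slot = clen // n_c
        lo, hi = config.gene_length_range
        for j in range(n_c):
            glen = int(rng.integers(lo, hi + 1))
            glen = min(glen, slot - 1)
            offset = int(rng.integers(0, max(1, slot - glen)))
            start = j * slot + offset
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"gene{gi:05d}", chrom, strand, start, start + glen))
            gi += 1
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end"])


def plan_spikes(config: SimConfig, genes: pd.DataFrame | None = None,
                rng: np.random.Generator | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place the differential-region ground truth.

    A ``promoter_fraction`` share of spikes is centred on TSSs of
    distinct genes; the rest land uniformly. All spike edges stay
    >= ``min_spike_gap`` apart (rejection sampling; raises with the
    required genome size when the packing is infeasible).
    """
    rng = rng or _rng(config, 0)
    if genes is None:
        genes = plan_genes(config, rng)
    need = config.n_spikes * (config.spike_width + config.min_spike_gap)
    total = sum(config.chrom_sizes.values())
    if need > total:
        raise ValueError(f"cannot pack {config.n_spikes} spikes: need a genome "
                         f"of at least {need} bp, have {total} bp")

    w = config.spike_width
    accepted: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chrom_sizes}

    def try_accept(chrom: str, start: int) -> bool:
        clen = config.chrom_sizes[chrom]
        if start < 0 or start + w > clen:
            return False
        for s, e in accepted[chrom]:
            if start < e + config.min_spike_gap and s < start + w + config.min_spike_gap:
                return False
        accepted[chrom].append((start, start + w))
        return True

    placed: list[tuple[str, int, int]] = []
    n_prom = round(config.promoter_fraction * config.n_spikes)
    from .annotation import tss_of
    order = rng.permutation(len(genes))
    for gidx in order:
        if len(placed) >= n_prom:
            break
        g = genes.iloc[gidx]
        tss = tss_of(g["strand"], g["start"], g["end"])
        start = tss - w // 2
        if try_accept(g["chrom"], start):
            placed.append((g["chrom"], start, start + w))
    chroms = list(config.chrom_sizes)
    weights = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    tries = 0
    while len(placed) < config.n_spikes:
        tries += 1
        if tries > 200 * config.n_spikes:
            raise ValueError("spike packing failed; increase the genome size "
                             f"(need roughly {2 * need} bp)")
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        start = int(rng.integers(0, config.chrom_sizes[chrom] - w))
        if try_accept(chrom, start):
            placed.append((chrom, start, start + w))

    placed.sort()
    n = len(placed)
    direction = np.where(rng.random(n) < config.gain_fraction, "gain", "loss")
    reversed_ = rng.random(n) < config.reversal_fraction
    truth = pd.DataFrame({
        "chrom": [p[0] for p in placed],
        "start": [p[1] for p in placed],
        "end": [p[2] for p in placed],
        "direction": direction,
        "fold": config.spike_fold,
        "reversed": reversed_,
    })
    return truth, genes


def _condition_multiplier(direction: str, reversed_: bool, fold: float,
                          condition: int) -> float:
    """Rate multiplier at a spike for one condition: gain spikes are
    elevated in condition 2, loss spikes in condition 1; condition 3
    copies condition 1 at reversed spikes, condition 2 otherwise."""
    mult_c1 = fold if direction == "loss" else 1.0
    mult_c2 = fold if direction == "gain" else 1.0
    if condition == 1:
        return mult_c1
    if condition == 2:
        return mult_c2
    if condition == 3:
        return mult_c1 if reversed_ else mult_c2
    raise ValueError(f"condition must be 1, 2 or 3, got {condition}")


def generate_condition_reads(config: SimConfig, truth: pd.DataFrame,
                             condition: int,
                             rng: np.random.Generator | None = None
                             ) -> list[AlignedRead]:
    """Draw aligned reads for one condition from the piecewise-constant
    Poisson read-start process, with PCR duplicates injected."""
    rng = rng or _rng(config, condition)
    reads: list[AlignedRead] = []
    for chrom, clen in config.chrom_sizes.items():
        spikes = truth[truth["chrom"] == chrom].sort_values("start")
        # piecewise segments: (start, end, multiplier)
        segments: list[tuple[int, int, float]] = []
        pos = 0
        for sp in spikes.itertuples(index=False):
            if sp.start > pos:
                segments.append((pos, sp.start, 1.0))
            segments.append((sp.start, sp.end, _condition_multiplier(
                sp.direction, bool(sp.reversed), sp.fold, condition)))
            pos = sp.end
        if pos < clen:
            segments.append((pos, clen, 1.0))
        max_start = max(1, clen - config.read_length)
        for s, e, mult in segments:
            rate = config.background_rate * mult
            if config.overdispersion > 0:
                shape = 1.0 / config.overdispersion
                rate *= rng.gamma(shape, 1.0 / shape)
            n = rng.poisson(rate * (e - s))
            if n == 0:
                continue
            starts = rng.integers(s, e, size=n)
            starts = np.minimum(starts, max_start)
            strands = rng.random(n) < 0.5
            reads.extend(AlignedRead(chrom, int(p), "+" if st else "-")
                         for p, st in zip(starts, strands))
    if config.duplicate_rate > 0 and reads:
        dup = rng.random(len(reads)) < config.duplicate_rate
        reads.extend(r for r, d in zip(list(reads), dup) if d)
    reads.sort(key=lambda r: (r.chrom, r.start, r.strand))
    return reads


def generate_experiment(config: SimConfig,
                        conditions: tuple[int, ...] = (1, 2, 3)) -> dict:
    """Plan truth + genes and draw reads for each condition."""
    truth, genes = plan_spikes(config)
    reads = {c: generate_condition_reads(config, truth, c) for c in conditions}
    return {"truth": truth, "genes": genes, "reads": reads, "config": config}


# ----------------------------------------------------------- presets/IO

PRESETS = {
    "default": SimConfig(),
    "smoke": SimConfig(chrom_sizes={"chrSim": 200_000}, n_genes=20,
                       n_spikes=10, spike_width=2000),
}


def write_fixture(outdir: str | Path, config: SimConfig,
                  marks: dict[str, str] | None = None) -> dict:
    """Write a complete fixture tree: per (mark x condition) reads BED,
    chrom.sizes, genes GTF, per-mark truth TSV and the config as YAML.
    Regeneration with the same config is byte-identical."""
    from . import io as dio

    marks = marks or {"H3K4me3": "punctate"}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dio.write_chrom_sizes(config.chrom_sizes, outdir / "chrom.sizes")
    genes = plan_genes(config)
    dio.write_genes_gtf(genes, outdir / "genes.gtf")
    manifest: dict = {"marks": {}, "chrom_sizes": str(outdir / "chrom.sizes"),
                      "genes": str(outdir / "genes.gtf")}
    for mi, (mark, mark_class) in enumerate(sorted(marks.items())):
        truth, _ = plan_spikes(config, genes=genes, rng=_rng(config, 100 + mi))
        truth.to_csv(outdir / f"truth_{mark}.tsv", sep="\t", index=False)
        entry = {"mark_class": mark_class,
                 "truth": str(outdir / f"truth_{mark}.tsv"), "reads": {}}
        for cond in (1, 2, 3):
            rng = _rng(config, 100 + mi, cond)
            reads = generate_condition_reads(config, truth, cond, rng)
            path = outdir / f"reads_{mark}_c{cond}.bed"
            dio.write_reads_bed(reads, path, config.read_length)
            entry["reads"][cond] = str(path)
        manifest["marks"][mark] = entry
    cfg = asdict(config)
    cfg["gene_length_range"] = list(cfg["gene_length_range"])
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    manifest["config"] = str(outdir / "config.yaml")
    return manifest


# ------------------------------------------------------------- scoring

def score_against_truth(dhmrs: pd.DataFrame, truth: pd.DataFrame,
                        min_cover: float = 0.5) -> dict:
    """Recall/precision of called DHMRs against the spike ground truth.

    A spike is recovered when some DHMR covers >= ``min_cover`` of it;
    a DHMR is a false positive when it overlaps no spike by >= 1 bp.
    """
    recovered = 0
    for sp in truth.itertuples(index=False):
        sub = dhmrs[dhmrs["chrom"] == sp.chrom]
        ov = np.minimum(sub["end"], sp.end) - np.maximum(sub["start"], sp.start)
        if len(sub) and (ov.max() >= min_cover * (sp.end - sp.start)):
            recovered += 1
    tp = 0
    for r in dhmrs.itertuples(index=False):
        sub = truth[truth["chrom"] == r.chrom]
        ov = np.minimum(sub["end"], r.end) - np.maximum(sub["start"], r.start)
        if len(sub) and (ov.max() >= 1):
            tp += 1
    recall = recovered / len(truth) if len(truth) else float("nan")
    precision = tp / len(dhmrs) if len(dhmrs) else float("nan")
    return {"recall": recall, "precision": precision,
            "n_truth": int(len(truth)), "n_called": int(len(dhmrs)),
            "n_recovered": recovered, "n_true_positive": tp}
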