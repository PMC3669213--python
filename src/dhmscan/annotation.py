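"""Promoter annotation of DHMRs and three-condition reversal analysis.

A gene whose promoter (TSS +/- 2 kb) overlaps at least one DHMR is a
differential histone modification gene (DHMG). Comparing the DHMG sets
from control-vs-treated and control-vs-treated+drug classifies each
treated-condition change as reversed by the drug (reciprocal direction,
or absent in the drug comparison) or retained. Metagene profiles and a
promoter-level z-test summarise global signal redistribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.special import ndtr

DEFAULT_PROMOTER_FLANK = 2000


def tss_of(strand: str, start: int, end: int) -> int:
    """Strand-aware TSS base index: span start for '+', last base for '-'."""
    return start if strand == "+" else end - 1


def promoter_of(strand: str, start: int, end: int, flank: int = DEFAULT_PROMOTER_FLANK,
                chrom_length: int | None = None) -> tuple[int, int]:
    """Promoter interval [TSS - flank, TSS + flank), clipped to the
    chromosome when its length is given."""
    tss = tss_of(strand, start, end)
    p0, p1 = tss - flank, tss + flank
    p0 = max(0, p0)
    if chrom_length is not None:
        p1 = min(chrom_length, p1)
    return p0, p1


def promoter_table(genes: pd.DataFrame, flank: int = DEFAULT_PROMOTER_FLANK,
                   chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """One promoter per distinct (gene_id, TSS) pair."""
    rows = []
    for g in genes.itertuples(index=False):
        clen = chrom_sizes.get(g.chrom) if chrom_sizes else None
        p0, p1 = promoter_of(g.strand, g.start, g.end, flank, clen)
        rows.append((g.gene_id, g.chrom, p0, p1))
    out = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    return out.drop_duplicates().reset_index(drop=True)


DHMG_COLUMNS = ["gene_id", "n_dhmrs", "direction", "best_overlap_bp"]


def map_dhmrs_to_genes(dhmrs: pd.DataFrame, genes: pd.DataFrame,
                       flank: int = DEFAULT_PROMOTER_FLANK,
                       chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """DHMGs: genes with >= 1 DHMR overlapping a promoter by >= 1 bp.

    A DHMR may annotate several genes. When a gene's promoters overlap
    DHMRs of mixed direction, the gene takes the direction of the DHMR
    with the largest promoter overlap, ties broken by larger
    |mean_b - mean_a|.
    """
    gene_chroms = set(genes["chrom"])
    dhmr_chroms = set(dhmrs["chrom"]) if len(dhmrs) else set()
    unmatched = dhmr_chroms - gene_chroms
    if unmatched:
        warnings.warn("DHMR chromosomes absent from gene models: "
                      + ", ".join(sorted(unmatched)))

    trees: dict[str, IntervalTree] = {}
    for idx, r in enumerate(dhmrs.itertuples(index=False)):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, idx)

    proms = promoter_table(genes, flank, chrom_sizes)
    per_gene: dict[str, list[tuple[int, float, str, int]]] = {}
    for p in proms.itertuples(index=False):
        tree = trees.get(p.chrom)
        if tree is None or p.end <= p.start:
            continue
        for iv in tree.overlap(p.start, p.end):
            r = dhmrs.iloc[iv.data]
            ov = min(p.end, r["end"]) - max(p.start, r["start"])
            per_gene.setdefault(p.gene_id, []).append(
                (ov, abs(r["mean_b"] - r["mean_a"]), r["direction"], iv.data))

    rows = []
    for gid, hits in per_gene.items():
        n = len({h[3] for h in hits})
        best = max(hits, key=lambda h: (h[0], h[1]))
        rows.append((gid, n, best[2], best[0]))
    out = pd.DataFrame(rows, columns=DHMG_COLUMNS)
    return out.sort_values("gene_id").reset_index(drop=True)


@dataclass
class ReversalReport:
    """Cross-match of DHMG sets from two comparisons sharing a control.

    ``reversed_genes`` = reciprocal (direction flips between the two
    comparisons) + specific to the first comparison; their fraction of
    the first comparison's DHMGs measures how far the drug restores the
    treated-condition changes.
    """

    common: set
    reciprocal: set
    tgf_specific: set
    drug_specific: set
    reversed_fraction: float | None
    reciprocal_fraction: float | None

    @property
    def reversed_genes(self) -> set:
        return self.reciprocal | self.tgf_specific

    def venn_counts(self) -> dict[str, int]:
        return {
            "common": len(self.common),
            "reciprocal": len(self.reciprocal),
            "tgf_specific": len(self.tgf_specific),
            "drug_specific": len(self.drug_specific),
            "reversed": len(self.reversed_genes),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, "reciprocal") for g in sorted(self.reciprocal)]
        rows += [(g, "tgf_specific") for g in sorted(self.tgf_specific)]
        rows += [(g, "common_same_direction")
                 for g in sorted(self.common - self.reciprocal)]
        rows += [(g, "drug_specific") for g in sorted(self.drug_specific)]
        return pd.DataFrame(rows, columns=["gene_id", "category"])


def classify_reversal(dhmgs_ct: pd.DataFrame, dhmgs_cts: pd.DataFrame) -> ReversalReport:
    """Classify control-vs-treated DHMGs by their fate in the
    control-vs-treated+drug comparison."""
    dir_ct = dict(zip(dhmgs_ct["gene_id"], dhmgs_ct["direction"]))
    dir_cts = dict(zip(dhmgs_cts["gene_id"], dhmgs_cts["direction"]))
    ct, cts = set(dir_ct), set(dir_cts)
    common = ct & cts
    reciprocal = {g for g in common if dir_ct[g] != dir_cts[g]}
    tgf_specific = ct - cts
    drug_specific = cts - ct
    if ct:
        rev_frac = (len(reciprocal) + len(tgf_specific)) / len(ct)
        rec_frac = len(reciprocal) / len(ct)
    else:
        warnings.warn("no DHMGs in the control-vs-treated comparison; "
                      "reversed fraction undefined")
        rev_frac = rec_frac = None
    return ReversalReport(common=common, reciprocal=reciprocal,
                          tgf_specific=tgf_specific, drug_specific=drug_specific,
                          reversed_fraction=rev_frac, reciprocal_fraction=rec_frac)


def dhmr_overlap_fraction(dhmrs_ct: pd.DataFrame, dhmrs_cts: pd.DataFrame) -> float | None:
    """Fraction of control-vs-treated DHMRs with no (>= 1 bp) overlap in
    the control-vs-treated+drug set — the 'disappeared' share."""
    if len(dhmrs_ct) == 0:
        warnings.warn("empty DHMR set; disappearance fraction undefined")
        return None
    trees: dict[str, IntervalTree] = {}
    for r in dhmrs_cts.itertuples(index=False):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    gone = 0
    for r in dhmrs_ct.itertuples(index=False):
        tree = trees.get(r.chrom)
        if tree is None or not tree.overlap(r.start, r.end):
            gone += 1
    return gone / len(dhmrs_ct)


# ----------------------------------------------------- signal profiles

def _portion_means(cs: np.ndarray, start: int, end: int, n_portions: int,
                   clen: int) -> np.ndarray:
    """Mean signal in n equal portions of [start, end); portions falling
    outside the chromosome give NaN, partial portions average their
    in-bounds part. cs is the per-base prefix sum."""
    edges = np.floor(np.linspace(start, end, n_portions + 1)).astype(np.int64)
    lo = np.clip(edges[:-1], 0, clen)
    hi = np.clip(edges[1:], 0, clen)
    width = (hi - lo).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = (cs[hi] - cs[lo]) / width
    means[width <= 0] = np.nan
    return means


def metagene_profile(track, genes: pd.DataFrame, body_portions: int = 100,
                     flank_portions: int = 25, flank_bp: int = 5000) -> pd.DataFrame:
    """Average gene-anchored signal profile.

    Each gene body (TSS to TTS) is divided into ``body_portions`` equal
    portions and each 5-kb flank into ``flank_portions`` portions;
    profiles are orientation-flipped for '-' genes and averaged over
    genes per position. Genes shorter than ``body_portions`` bp are
    skipped. Returns a 150-row table (position_class, position_index,
    mean_signal).
    """
    cs_cache: dict[str, np.ndarray] = {}
    profiles = []
    n_skipped = 0
    for g in genes.itertuples(index=False):
        if g.end - g.start < body_portions:
            n_skipped += 1
            continue
        if g.chrom not in track.chrom_sizes:
            continue
        if g.chrom not in cs_cache:
            cs_cache[g.chrom] = np.concatenate(
                ([0.0], np.cumsum(track.normalized(g.chrom))))
        cs = cs_cache[g.chrom]
        clen = track.chrom_sizes[g.chrom]
        up = _portion_means(cs, g.start - flank_bp, g.start, flank_portions, clen)
        body = _portion_means(cs, g.start, g.end, body_portions, clen)
        down = _portion_means(cs, g.end, g.end + flank_bp, flank_portions, clen)
        prof = np.concatenate([up, body, down])
        if g.strand == "-":
            prof = prof[::-1]
        profiles.append(prof)
    if n_skipped:
        warnings.warn(f"metagene_profile: skipped {n_skipped} genes shorter "
                      f"than {body_portions} bp")
    if not profiles:
        raise ValueError("no genes long enough to profile")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_prof = np.nanmean(np.vstack(profiles), axis=0)
    classes = (["upstream"] * flank_portions + ["body"] * body_portions
               + ["downstream"] * flank_portions)
    return pd.DataFrame({
        "position_class": classes,
        "position_index": np.arange(len(mean_prof)),
        "mean_signal": mean_prof,
    })


def promoter_mean_signal(track, genes: pd.DataFrame,
                         flank: int = DEFAULT_PROMOTER_FLANK) -> pd.DataFrame:
    """Mean normalized signal over each gene's promoter."""
    cs_cache: dict[str, np.ndarray] = {}
    rows = []
    for g in genes.itertuples(index=False):
        if g.chrom not in track.chrom_sizes:
            continue
        if g.chrom not in cs_cache:
            cs_cache[g.chrom] = np.concatenate(
                ([0.0], np.cumsum(track.normalized(g.chrom))))
        cs = cs_cache[g.chrom]
        p0, p1 = promoter_of(g.strand, g.start, g.end, flank,
                             track.chrom_sizes[g.chrom])
        if p1 > p0:
            rows.append((g.gene_id, (cs[p1] - cs[p0]) / (p1 - p0)))
    return pd.DataFrame(rows, columns=["gene_id", "mean_signal"])


def promoter_signal_ztest(track_x, track_y, genes: pd.DataFrame,
                          flank: int = DEFAULT_PROMOTER_FLANK,
                          alpha: float = 1e-5) -> dict:
    """Large-sample two-sample z-test comparing per-gene promoter means
    between two tracks: z = (mx - my) / sqrt(sx^2/nx + sy^2/ny),
    two-sided normal p, significant when p < 1e-5."""
    mx = promoter_mean_signal(track_x, genes, flank)["mean_signal"].to_numpy()
    my = promoter_mean_signal(track_y, genes, flank)["mean_signal"].to_numpy()
    if mx.size < 2 or my.size < 2:
        raise ValueError("promoter z-test needs at least two genes")
    vx, vy = mx.var(ddof=1), my.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("degenerate z-test: zero variance in both samples")
    z = (mx.mean() - my.mean()) / np.sqrt(vx / mx.size + vy / my.size)
    p = float(2.0 * ndtr(-abs(z)))
    return {"z": float(z), "p": p, "significant": p < alpha,
            "mean_x": float(mx.mean()), "mean_y": float(my.mean()),
            "n_x": int(mx.size), "n_y": int(my.size)}
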