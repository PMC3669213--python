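"""Readers and writers for the text formats the pipeline consumes and emits.

Internal coordinates are 0-based half-open. BED/bedGraph are already
0-based half-open on disk; GTF is 1-based closed and converted at this
boundary only.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import AlignedRead, SignalTrack

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- reads

def read_reads_bed(path: str | Path) -> list[AlignedRead]:
    """Read aligned reads from BED6 (columns chrom, start, strand used)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 5], names=["chrom", "start", "strand"],
                     dtype={0: str, 1: np.int64, 5: str})
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"{path}: malformed strand at line {bad.idxmax() + 1}")
    return [AlignedRead(c, int(s), st)
            for c, s, st in zip(df["chrom"], df["start"], df["strand"])]


def read_reads_sam(path: str | Path) -> list[AlignedRead]:
    """Read mapped reads from SAM via pysam (RNAME/POS/FLAG 0x10 used)."""
    import pysam

    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            strand = "-" if aln.is_reverse else "+"
            reads.append(AlignedRead(aln.reference_name, aln.reference_start, strand))
    return reads


def read_reads(path: str | Path) -> list[AlignedRead]:
    path = Path(path)
    if path.suffix.lower() == ".sam":
        return read_reads_sam(path)
    return read_reads_bed(path)


def write_reads_bed(reads, path: str | Path, read_length: int = 50) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.start + read_length}\t.\t0\t{r.strand}\n")


# ---------------------------------------------------------- chrom sizes

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


# ------------------------------------------------------------- bedGraph

def write_bedgraph(track: SignalTrack, path: str | Path, *,
                   view: str = "normalized") -> None:
    """Write a per-base track as run-length merged bedGraph.

    Adjacent equal-value runs are merged; zero runs are omitted (the
    reader restores them). Normalized values are written with full
    float64 precision so a round trip is exact per base.
    """
    with open(path, "w") as fh:
        for chrom in track.chroms:
            if view == "counts":
                vals = track.counts[chrom]
                fmt = "{}\t{}\t{}\t{:d}\n"
            elif view == "starts":
                vals = track.starts[chrom]
                fmt = "{}\t{}\t{}\t{:d}\n"
            else:
                vals = track.normalized(chrom)
                fmt = "{}\t{}\t{}\t{:.17g}\n"
            if len(vals) == 0:
                continue
            # run boundaries where the value changes
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vals)]))
            for s, e in zip(starts, ends):
                v = vals[s]
                if v != 0:
                    fh.write(fmt.format(chrom, s, e, v))


def read_bedgraph(path: str | Path, chrom_sizes: dict[str, int],
                  dtype=np.float64) -> dict[str, np.ndarray]:
    """Read a bedGraph into dense per-base arrays (absent bases = 0)."""
    arrays = {c: np.zeros(n, dtype=dtype) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in arrays:
                warnings.warn(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                continue
            arrays[chrom][s:e] = v
    return arrays


# ----------------------------------------------------------- gene models

GENE_COLUMNS = ["gene_id", "chrom", "strand", "start", "end"]


def read_genes_bed12(path: str | Path) -> pd.DataFrame:
    """Gene models from BED12 (or BED6): name, chrom, strand, span."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    genes = pd.DataFrame({
        "gene_id": df[3].astype(str),
        "chrom": df[0].astype(str),
        "strand": df[5].astype(str),
        "start": df[1].astype(np.int64),
        "end": df[2].astype(np.int64),
    })
    return genes[GENE_COLUMNS]


def read_genes_gtf(path: str | Path) -> pd.DataFrame:
    """Gene models from GTF: transcript spans with gene_id, converted
    from 1-based closed to 0-based half-open."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique",
                            disable_infer_genes=True,
                            disable_infer_transcripts=True)
    rows = []
    feat_types = set(db.featuretypes())
    use = [t for t in ("transcript", "mRNA", "gene") if t in feat_types]
    for ftype in use or feat_types:
        for f in db.features_of_type(ftype):
            gid = (f.attributes.get("gene_id") or [f.id])[0]
            rows.append((gid, f.seqid, f.strand, f.start - 1, f.end))
        if rows:
            break
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    return genes.drop_duplicates(subset=["gene_id", "chrom", "start", "end"])


def read_genes(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        return read_genes_gtf(path)
    return read_genes_bed12(path)


def write_genes_gtf(genes: pd.DataFrame, path: str | Path,
                    source: str = "dhmscan") -> None:
    """Write gene models as GTF transcript features (0-based half-open
    internal spans converted to 1-based closed)."""
    with open(path, "w") as fh:
        for g in genes.itertuples():
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.1";'
            fh.write(f"{g.chrom}\t{source}\ttranscript\t{g.start + 1}\t{g.end}"
                     f"\t.\t{g.strand}\t.\t{attrs}\n")


# ----------------------------------------------------------- DHMR tables

DHMR_COLUMNS = ["chrom", "start", "end", "mean_a", "mean_b", "fold_change",
                "scan_p", "enriched_a", "enriched_b", "direction"]


def write_dhmrs_bed(dhmrs: pd.DataFrame, path: str | Path,
                    mark: str = ".") -> None:
    """BED6+ DHMR output: name = mark, score = min(1000, -10*log10 p)."""
    with open(path, "w") as fh:
        for r in dhmrs.itertuples():
            p = max(r.scan_p, 1e-300)
            score = int(min(1000, round(-10.0 * np.log10(p))))
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{mark}\t{score}\t.\t"
                     f"{r.mean_a:.6g}\t{r.mean_b:.6g}\t{r.fold_change:.6g}\t"
                     f"{r.scan_p:.6g}\t{int(r.enriched_a)}\t{int(r.enriched_b)}\t"
                     f"{r.direction}\n")


def read_dhmrs_bed(path: str | Path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "mark", "score", "bed_strand",
             "mean_a", "mean_b", "fold_change", "scan_p",
             "enriched_a", "enriched_b", "direction"]
    df = pd.read_csv(path, sep="\t", header=None, names=names)
    df["enriched_a"] = df["enriched_a"].astype(bool)
    df["enriched_b"] = df["enriched_b"].astype(bool)
    return df
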