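"""Three-condition, multi-mark orchestration.

For each histone mark: build normalized tracks for control, treated and
treated+drug; call DHMRs for control-vs-treated and
control-vs-treated+drug; map both to promoters (DHMGs); classify
drug-mediated reversal; and emit metagene profiles and promoter
z-tests. All stages are deterministic given the inputs, so a re-run
with an identical config reproduces every artifact byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as dio
from .annotation import (classify_reversal, dhmr_overlap_fraction,
                         map_dhmrs_to_genes, metagene_profile,
                         promoter_signal_ztest)
from .coverage import SignalTrack, make_track
from .scan import DifferentialMarkModel, ScanParams

logger = logging.getLogger(__name__)

CONDITION_LABELS = {1: "control", 2: "treated", 3: "treated_drug"}


@dataclass
class MarkInput:
    mark_class: str
    reads: dict[int, str]   # condition (1..3) -> reads path


@dataclass
class RunConfig:
    chrom_sizes: str
    genes: str
    marks: dict[str, MarkInput]
    outdir: str = "dhmscan_out"
    ext_len: int = 150
    read_length: int = 50
    target_total: float = 1e9
    promoter_flank: int = 2000
    params: ScanParams = field(default_factory=ScanParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        marks = {m: MarkInput(mark_class=v["mark_class"],
                              reads={int(k): p for k, p in v["reads"].items()})
                 for m, v in raw.pop("marks").items()}
        params = ScanParams(**raw.pop("params", {}))
        return cls(marks=marks, params=params, **raw)


def analyze_mark(tracks: dict[int, SignalTrack], mark_class: str,
                 genes: pd.DataFrame, params: ScanParams = ScanParams(),
                 promoter_flank: int = 2000) -> dict:
    """In-memory three-condition analysis for one mark.

    ``tracks`` maps condition 1 (control), 2 (treated), 3 (treated+drug)
    to normalized tracks. Returns fitted results for both comparisons,
    DHMG tables, the reversal report and the DHMR disappearance
    fraction.
    """
    res_ct = DifferentialMarkModel(tracks[1], tracks[2], mark_class, params).fit()
    res_cts = DifferentialMarkModel(tracks[1], tracks[3], mark_class, params).fit()
    sizes = tracks[1].chrom_sizes
    dhmgs_ct = map_dhmrs_to_genes(res_ct.dhmrs, genes, promoter_flank, sizes)
    dhmgs_cts = map_dhmrs_to_genes(res_cts.dhmrs, genes, promoter_flank, sizes)
    report = classify_reversal(dhmgs_ct, dhmgs_cts)
    disappeared = dhmr_overlap_fraction(res_ct.dhmrs, res_cts.dhmrs)
    return {"ct": res_ct, "cts": res_cts, "dhmgs_ct": dhmgs_ct,
            "dhmgs_cts": dhmgs_cts, "reversal": report,
            "disappeared_fraction": disappeared}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full(config: RunConfig) -> dict:
    """File-to-file pipeline over every mark; writes tracks, DHMR BEDs,
    DHMG/reversal TSVs, metagene profiles, z-test results and a manifest
    with parameter values and input/output checksums."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sizes = dio.read_chrom_sizes(config.chrom_sizes)
    genes = dio.read_genes(config.genes)
    manifest: dict = {
        "parameters": {
            "ext_len": config.ext_len, "read_length": config.read_length,
            "target_total": config.target_total,
            "promoter_flank": config.promoter_flank,
            "scan": {k: v for k, v in vars(config.params).items()},
        },
        "inputs": {"chrom_sizes": _sha256(Path(config.chrom_sizes)),
                   "genes": _sha256(Path(config.genes))},
        "marks": {},
    }
    results: dict = {}
    for mark, mi in config.marks.items():
        stage = f"signal[{mark}]"
        try:
            tracks: dict[int, SignalTrack] = {}
            for cond, path in sorted(mi.reads.items()):
                manifest["inputs"][f"{mark}_c{cond}"] = _sha256(Path(path))
                reads = dio.read_reads(path)
                tracks[cond] = make_track(
                    reads, sizes, ext_len=config.ext_len,
                    read_length=config.read_length,
                    target_total=config.target_total)
                dio.write_bedgraph(tracks[cond],
                                   outdir / f"track_{mark}_c{cond}.bedgraph")
            stage = f"call/annotate/compare[{mark}]"
            res = analyze_mark(tracks, mi.mark_class, genes, config.params,
                               config.promoter_flank)
            res["ct"].to_bed(outdir / f"dhmrs_{mark}_ct.bed", mark=mark)
            res["cts"].to_bed(outdir / f"dhmrs_{mark}_cts.bed", mark=mark)
            res["dhmgs_ct"].to_csv(outdir / f"dhmgs_{mark}_ct.tsv", sep="\t",
                                   index=False)
            res["dhmgs_cts"].to_csv(outdir / f"dhmgs_{mark}_cts.tsv", sep="\t",
                                    index=False)
            rep = res["reversal"]
            rep.to_frame().to_csv(outdir / f"reversal_{mark}.tsv", sep="\t",
                                  index=False)
            stage = f"profiles[{mark}]"
            profiles = {c: metagene_profile(t, genes) for c, t in tracks.items()}
            for c, prof in profiles.items():
                prof.to_csv(outdir / f"metagene_{mark}_c{c}.tsv", sep="\t",
                            index=False)
            ztests = {f"c1_vs_c{c}": promoter_signal_ztest(
                tracks[1], tracks[c], genes, config.promoter_flank)
                for c in (2, 3) if c in tracks}
            res["ztests"] = ztests
            res["profiles"] = profiles
            results[mark] = res
            manifest["marks"][mark] = {
                "mark_class": mi.mark_class,
                "stage_counts_ct": res["ct"].stage_counts,
                "stage_counts_cts": res["cts"].stage_counts,
                "n_dhmrs_ct": res["ct"].n_dhmrs,
                "n_dhmrs_cts": res["cts"].n_dhmrs,
                "disappeared_fraction": res["disappeared_fraction"],
                "venn": rep.venn_counts(),
                "reversed_fraction": rep.reversed_fraction,
                "ztests": ztests,
            }
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage} failed: {exc}") from exc
    manifest["outputs"] = {p.name: _sha256(p) for p in sorted(outdir.iterdir())
                           if p.name != "manifest.json"}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    results["manifest"] = manifest
    return results
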