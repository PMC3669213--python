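"""Differential histone modification region (DHMR) calling.

Two normalized ChIP signal tracks for the same mark in two conditions
are compared with a three-criterion procedure:

1. **Seed-and-extend t-test scan.** The genome is partitioned into
   100-bp bins of mean normalized signal. Every 5-bin window whose
   paired two-sided t-test across the two conditions gives p < 0.01 is a
   seed; the window then slides downstream one bin per step, re-testing
   at each step, until a p > 0.01 is encountered or the accumulated
   region reaches 50 bins. The union of the accumulated stretches from
   all seeds forms the candidate regions. (An alternative extension
   rule that re-tests the whole growing window is available via
   ``ScanParams.extend_mode='grow'``; it drags region boundaries far
   past the differential stretch because a long window stays
   significant on the strength of its earliest bins, which dilutes the
   region means fed to the fold-change criterion.)
2. **Fold change and merging.** Candidates with less than a 2-fold
   change in mean normalized signal (pseudocount-stabilised ratio) are
   dropped; survivors separated by gaps under 1 kb are merged.
3. **Poisson local-background enrichment.** For each candidate, a
   per-sample background rate is estimated from read starts in a 10-kb
   window covering the region; 100-bp windows slide across the region
   in 1-bp steps and a window is enriched when its upper-tail Poisson
   p-value beats the mark-class threshold (1e-5 for punctate marks such
   as H3K4me3/H3K9ac, 1e-3 for broad marks such as H3K27me3/H3K9me3).
   Regions enriched in neither sample are discarded.

The Poisson test runs on raw read-start counts, not on extended-read
coverage: per-base extended coverage is serially correlated over the
fragment length and grossly violates the Poisson assumption, whereas
deduplicated read starts are approximately a Poisson process.

`DifferentialMarkModel` / `DHMRResults` wrap the procedure in a
model-fit interface; the stage functions below are the functional API.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import stdtr, stdtrit

from .coverage import BinnedTrack, SignalTrack, bin_track

logger = logging.getLogger(__name__)

MARK_ALPHA = {"punctate": 1e-5, "broad": 1e-3}

DHMR_COLUMNS = ["chrom", "start", "end", "mean_a", "mean_b", "fold_change",
                "scan_p", "enriched_a", "enriched_b", "direction"]


@dataclass(frozen=True)
class ScanParams:
    """Tunable constants of the three-criterion DHMR procedure.

    Defaults are the published operating point: 100-bp bins, 5-bin seed,
    50-bin cap, scan alpha 0.01, 2-fold minimum, <1 kb merging, 10-kb
    local background, 100-bp / 1-bp-step enrichment windows.
    """

    bin_size: int = 100
    seed_bins: int = 5
    max_bins: int = 50
    scan_alpha: float = 0.01
    min_fold: float = 2.0
    merge_gap: int = 1000
    background_extent: int = 10_000
    enrich_window: int = 100
    enrich_step: int = 1
    enrich_alpha: float | None = None   # None -> resolved from mark class
    pseudocount: float = 1.0            # normalized units, fold-change guard
    test: str = "paired"                # "paired" | "welch"
    extend_mode: str = "slide"          # "slide" | "grow" seed extension
    enrich_mode: str = "any"            # keep if enriched in >=1 ("any") or both

    def __post_init__(self):
        if self.seed_bins > self.max_bins:
            raise ValueError("seed_bins must be <= max_bins")
        if not (0 < self.scan_alpha < 1):
            raise ValueError("scan_alpha must lie in (0, 1)")
        for name in ("bin_size", "merge_gap", "background_extent",
                     "enrich_window", "enrich_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    def resolve_alpha(self, mark_class: str) -> float:
        if self.enrich_alpha is not None:
            return self.enrich_alpha
        if mark_class not in MARK_ALPHA:
            raise ValueError(
                f"mark_class must be one of {sorted(MARK_ALPHA)}, got {mark_class!r}")
        return MARK_ALPHA[mark_class]


# ------------------------------------------------------------- t testing

def paired_bin_test(vals_a: Sequence[float], vals_b: Sequence[float],
                    test: str = "paired") -> float:
    """Two-sided t-test p-value comparing positionally matched bin values.

    The default is the paired test on per-bin differences. Degenerate
    zero-variance inputs follow the limits of the t statistic: zero mean
    difference -> p = 1, nonzero constant difference -> p = 0.
    """
    a = np.asarray(vals_a, dtype=float)
    b = np.asarray(vals_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vals_a and vals_b must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two bins")
    if test == "welch":
        if np.var(a) == 0 and np.var(b) == 0:
            return 1.0 if a.mean() == b.mean() else 0.0
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    d = b - a
    mean = d.mean()
    var = d.var(ddof=1)
    if var <= 0:
        return 1.0 if mean == 0 else 0.0
    t = mean / math.sqrt(var / n)
    return float(2.0 * stdtr(n - 1, -abs(t)))


class _DiffStats:
    """O(1) paired-t statistics for bin windows via prefix sums."""

    def __init__(self, va: np.ndarray, vb: np.ndarray):
        d = vb.astype(float) - va.astype(float)
        self.n = d.size
        self.cs1 = np.concatenate(([0.0], np.cumsum(d)))
        self.cs2 = np.concatenate(([0.0], np.cumsum(d * d)))

    def window_stat(self, s: int, e: int) -> tuple[float, float]:
        """(|t|, df) for bins [s, e); |t| = inf encodes the degenerate
        nonzero-mean case, |t| = 0 with df<0 the all-equal case."""
        n = e - s
        s1 = self.cs1[e] - self.cs1[s]
        s2 = self.cs2[e] - self.cs2[s]
        mean = s1 / n
        var = (s2 - s1 * s1 / n) / (n - 1)
        if var <= 0:
            return (math.inf, n - 1) if mean != 0 else (0.0, -1.0)
        return abs(mean) / math.sqrt(var / n), n - 1

    def window_p(self, s: int, e: int) -> float:
        t_abs, df = self.window_stat(s, e)
        if df < 0:
            return 1.0
        if math.isinf(t_abs):
            return 0.0
        return float(2.0 * stdtr(df, -t_abs))

    def seed_tstats(self, k: int) -> np.ndarray:
        """|t| for every k-bin window start (vectorized); NaN encodes
        zero-variance windows, resolved by the caller via the mean."""
        s1 = self.cs1[k:] - self.cs1[:-k]
        s2 = self.cs2[k:] - self.cs2[:-k]
        mean = s1 / k
        var = (s2 - s1 * s1 / k) / (k - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(mean) / np.sqrt(var / k)
        t[var <= 0] = np.nan
        t[(var <= 0) & (mean != 0)] = np.inf
        return t


def seed_extend_scan(binned_a: BinnedTrack, binned_b: BinnedTrack,
                     params: ScanParams = ScanParams()) -> pd.DataFrame:
    """Criterion 1: the seed-and-extend t-test scan.

    Every significant seed window is extended downstream — by sliding
    the fixed-width window one bin per step (default) or by re-testing
    the whole growing window (``extend_mode='grow'``) — until the test
    fails or the accumulated stretch reaches ``max_bins``; stretches
    from all seeds are unioned wherever they overlap. Returns candidate
    regions in bp with the final significant window's p-value (minimum
    over contributing stretches).
    """
    if binned_a.bin_size != binned_b.bin_size:
        raise ValueError("binned tracks must share the bin grid")
    k = params.seed_bins
    # critical |t| per df so extension avoids per-step CDF calls
    t_crit = {df: float(stdtrit(df, 1.0 - params.scan_alpha / 2.0))
              for df in range(max(1, k - 1), params.max_bins)}
    out = []
    for chrom in binned_a.chrom_sizes:
        va, vb = binned_a.values[chrom], binned_b.values[chrom]
        st = _DiffStats(va, vb)
        n = st.n
        if n < k:
            continue
        tstats = st.seed_tstats(k)
        crit_k = t_crit[k - 1]
        with np.errstate(invalid="ignore"):
            strict = tstats > crit_k          # p < alpha: a valid seed
            loose = tstats >= crit_k          # p <= alpha: may continue
        strict[np.isnan(tstats)] = False
        loose[np.isnan(tstats)] = False
        seeds = np.flatnonzero(strict)
        windows: list[tuple[int, int, float]] = []
        if params.extend_mode == "slide":
            # next_fail[j] = first window start >= j whose test fails
            fail = np.flatnonzero(~loose)
            p5 = np.where(np.isinf(tstats), 0.0,
                          np.where(np.isnan(tstats), 1.0,
                                   2.0 * stdtr(k - 1, -tstats)))
            for s in seeds:
                limit = min(s + params.max_bins - k, n - k)
                i = np.searchsorted(fail, s + 1)
                m = int(min(fail[i] - 1 if i < fail.size else limit, limit))
                windows.append((int(s), m + k, float(p5[m])))
        elif params.extend_mode == "grow":
            for s in seeds:
                e = s + k
                while e < n and e - s < params.max_bins:
                    t_abs, df = st.window_stat(s, e + 1)
                    # continue while p <= alpha (first p > alpha stops)
                    if df < 0 or (not math.isinf(t_abs) and t_abs < t_crit[int(df)]):
                        break
                    e += 1
                windows.append((int(s), int(e), st.window_p(s, e)))
        else:
            raise ValueError(f"unknown extend_mode {params.extend_mode!r}")
        # union of overlapping/touching stretches
        for s, e, p in windows:
            if out and out[-1][0] == chrom and s <= out[-1][2]:
                prev = out[-1]
                out[-1] = (chrom, prev[1], max(prev[2], e), min(prev[3], p))
            else:
                out.append((chrom, s, e, p))
    bs = params.bin_size
    rows = [(c, s * bs, min(e * bs, binned_a.chrom_sizes[c]), p)
            for c, s, e, p in out]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "scan_p"])


# ------------------------------------------------- fold change & merging

class _TrackSums:
    """Cached per-chromosome prefix sums over a SignalTrack."""

    def __init__(self, track: SignalTrack):
        self.track = track
        self._counts: dict[str, np.ndarray] = {}
        self._starts: dict[str, np.ndarray] = {}

    def counts_cs(self, chrom: str) -> np.ndarray:
        if chrom not in self._counts:
            self._counts[chrom] = np.concatenate(
                ([0], np.cumsum(self.track.counts[chrom], dtype=np.int64)))
        return self._counts[chrom]

    def starts_cs(self, chrom: str) -> np.ndarray:
        if chrom not in self._starts:
            self._starts[chrom] = np.concatenate(
                ([0], np.cumsum(self.track.starts[chrom], dtype=np.int64)))
        return self._starts[chrom]

    def mean_normalized(self, chrom: str, s: int, e: int) -> float:
        cs = self.counts_cs(chrom)
        return float(cs[e] - cs[s]) / (e - s) * self.track.norm_factor

    def start_count(self, chrom: str, s: int, e: int) -> int:
        cs = self.starts_cs(chrom)
        return int(cs[e] - cs[s])


def region_fold_change(mean_a: float, mean_b: float, pseudocount: float) -> float:
    """Symmetric fold change max((b+psi)/(a+psi), (a+psi)/(b+psi))."""
    x, y = mean_a + pseudocount, mean_b + pseudocount
    return max(x / y, y / x)


def fold_change_filter(regions: pd.DataFrame, track_a: SignalTrack,
                       track_b: SignalTrack,
                       params: ScanParams = ScanParams()) -> pd.DataFrame:
    """Criterion 2a: keep regions with >= min_fold change in mean
    normalized signal; annotates mean_a/mean_b/fold_change."""
    sa, sb = _TrackSums(track_a), _TrackSums(track_b)
    return _annotate_and_filter_fold(regions, sa, sb, params)


def _annotate_and_filter_fold(regions, sa: _TrackSums, sb: _TrackSums,
                              params: ScanParams) -> pd.DataFrame:
    rows = []
    for r in regions.itertuples(index=False):
        ma = sa.mean_normalized(r.chrom, r.start, r.end)
        mb = sb.mean_normalized(r.chrom, r.start, r.end)
        fc = region_fold_change(ma, mb, params.pseudocount)
        if fc >= params.min_fold:
            rows.append((r.chrom, r.start, r.end, r.scan_p, ma, mb, fc))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "scan_p",
                                       "mean_a", "mean_b", "fold_change"])


def merge_candidates(regions: pd.DataFrame, merge_gap: int = 1000) -> pd.DataFrame:
    """Criterion 2b: transitively merge regions separated by gaps
    strictly under ``merge_gap`` bp; scan_p of a merged region is the
    minimum over its members. Direction is ignored during merging."""
    out_rows = []
    for chrom, grp in regions.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        cur = None
        for r in grp.itertuples(index=False):
            if cur is not None and r.start - cur[2] < merge_gap:
                cur = (chrom, cur[1], max(cur[2], r.end), min(cur[3], r.scan_p))
            else:
                if cur is not None:
                    out_rows.append(cur)
                cur = (chrom, r.start, r.end, r.scan_p)
        if cur is not None:
            out_rows.append(cur)
    return pd.DataFrame(out_rows, columns=["chrom", "start", "end", "scan_p"])


# ------------------------------------------------ Poisson enrichment

def poisson_pvalue(k: int, lam: float) -> float:
    """Upper-tail Poisson probability P(X >= k) under rate ``lam``.

    By convention k = 0 gives 1; lam = 0 gives 0 for any k > 0 (an
    observation under a zero-rate background is infinitely surprising).
    """
    if k <= 0:
        return 1.0
    if lam == 0:
        return 0.0
    return float(stats.poisson.sf(k - 1, lam))


def _min_enriched_count(lam: float, alpha: float) -> int:
    """Smallest k with P(X >= k | lam) < alpha."""
    if lam == 0:
        return 1
    k = int(stats.poisson.isf(alpha, lam)) + 2
    while k > 1 and poisson_pvalue(k - 1, lam) < alpha:
        k -= 1
    return k


def local_background(track: SignalTrack, chrom: str, start: int, end: int,
                     extent: int = 10_000) -> float:
    """Read-start rate (per bp) of the local background: a window of
    ``extent`` bp centred on the region (the region itself when it is
    wider than ``extent``), clipped at the chromosome ends."""
    clen = track.chrom_sizes[chrom]
    if end - start > extent:
        w0, w1 = start, end
    else:
        center = (start + end) // 2
        w0, w1 = center - extent // 2, center + extent // 2
    w0, w1 = max(0, w0), min(clen, w1)
    width = w1 - w0
    k = int(track.starts[chrom][w0:w1].sum())
    return k / width


def poisson_enrich_windows(track: SignalTrack, chrom: str, start: int, end: int,
                           lam_bp: float, window: int = 100, step: int = 1,
                           alpha: float = 1e-5,
                           _starts_cumsum: np.ndarray | None = None
                           ) -> tuple[bool, pd.DataFrame]:
    """Slide ``window``-bp windows across [start, end) in ``step``-bp
    steps and test each read-start count against Poisson(lam_bp*window).

    Returns (region contains >= 1 enriched window, table of enriched
    windows with counts and p-values).
    """
    clen = track.chrom_sizes[chrom]
    cs = _starts_cumsum if _starts_cumsum is not None else np.concatenate(
        ([0], np.cumsum(track.starts[chrom], dtype=np.int64)))
    if end - start <= window:
        w0 = np.array([start])
        w1 = np.array([min(start + window, clen)])
    else:
        w0 = np.arange(start, end - window + 1, step)
        w1 = w0 + window
    k = cs[w1] - cs[w0]
    lam = lam_bp * (w1 - w0)
    if lam_bp == 0:
        enriched = k > 0
    else:
        kmin = _min_enriched_count(lam_bp * window, alpha)
        enriched = k >= kmin
        short = w1 - w0 < window  # clipped terminal window: exact test
        if short.any():
            idx = np.flatnonzero(short)
            enriched[idx] = np.array(
                [poisson_pvalue(int(k[i]), lam[i]) < alpha for i in idx])
    hits = np.flatnonzero(enriched)
    table = pd.DataFrame({
        "start": w0[hits], "end": w1[hits], "count": k[hits],
        "p": [poisson_pvalue(int(k[i]), lam[i]) for i in hits],
    })
    return bool(hits.size), table


def enrichment_filter(regions: pd.DataFrame, track_a: SignalTrack,
                      track_b: SignalTrack, alpha: float,
                      params: ScanParams = ScanParams()) -> pd.DataFrame:
    """Criterion 3: drop regions that contain no enriched window in
    either sample (each sample tested against its own local background);
    the strict variant (``enrich_mode='both'``) requires enrichment in
    both samples."""
    keep = []
    ea_col, eb_col = [], []
    sums = {id(track_a): _TrackSums(track_a), id(track_b): _TrackSums(track_b)}
    for i, r in enumerate(regions.itertuples(index=False)):
        enr = []
        for track in (track_a, track_b):
            ts = sums[id(track)]
            cs = ts.starts_cs(r.chrom)
            clen = track.chrom_sizes[r.chrom]
            if r.end - r.start > params.background_extent:
                w0, w1 = r.start, r.end
            else:
                center = (r.start + r.end) // 2
                w0 = max(0, center - params.background_extent // 2)
                w1 = min(clen, center + params.background_extent // 2)
            lam = float(cs[w1] - cs[w0]) / (w1 - w0)
            ok, _ = poisson_enrich_windows(track, r.chrom, r.start, r.end, lam,
                                           params.enrich_window,
                                           params.enrich_step, alpha,
                                           _starts_cumsum=cs)
            enr.append(ok)
        kept = (enr[0] and enr[1]) if params.enrich_mode == "both" \
            else (enr[0] or enr[1])
        if kept:
            keep.append(i)
            ea_col.append(enr[0])
            eb_col.append(enr[1])
    out = regions.iloc[keep].copy().reset_index(drop=True)
    out["enriched_a"] = np.array(ea_col, dtype=bool)
    out["enriched_b"] = np.array(eb_col, dtype=bool)
    return out


# -------------------------------------------------------- orchestration

def call_dhmrs(track_a: SignalTrack, track_b: SignalTrack, mark_class: str,
               params: ScanParams = ScanParams(),
               _stage_counts: dict | None = None) -> pd.DataFrame:
    """Run the full three-criterion pipeline and return the DHMR table
    sorted by coordinate (columns: chrom, start, end, mean_a, mean_b,
    fold_change, scan_p, enriched_a, enriched_b, direction)."""
    alpha = params.resolve_alpha(mark_class)
    counts = _stage_counts if _stage_counts is not None else {}

    ba = bin_track(track_a, params.bin_size)
    bb = bin_track(track_b, params.bin_size)
    cand = seed_extend_scan(ba, bb, params)
    counts["candidates"] = len(cand)

    sa, sb = _TrackSums(track_a), _TrackSums(track_b)
    cand = _annotate_and_filter_fold(cand, sa, sb, params)
    counts["fold_pass"] = len(cand)

    merged = merge_candidates(cand, params.merge_gap)
    # recompute means over merged spans; enforce the emitted-record
    # fold-change contract, which merging across a gap could break
    merged = _annotate_and_filter_fold(merged, sa, sb, params)
    counts["merged"] = len(merged)

    final = enrichment_filter(merged, track_a, track_b, alpha, params)
    counts["enriched"] = len(final)
    logger.info("call_dhmrs stage survivors: %s", counts)

    final["direction"] = np.where(final["mean_b"] > final["mean_a"], "up", "down")
    final = final[DHMR_COLUMNS].sort_values(["chrom", "start"]).reset_index(drop=True)
    return final


@dataclass
class DifferentialMarkModel:
    """Differential-modification model for one histone mark in two
    conditions, built from normalized signal tracks.

    Parameters
    ----------
    track_a, track_b
        Normalized `SignalTrack`s on the same chromosome grid
        (condition A = reference, condition B = comparison).
    mark_class
        ``"punctate"`` (promoter-focused marks, enrichment alpha 1e-5)
        or ``"broad"`` (domain-scale marks, alpha 1e-3).
    params
        `ScanParams` overriding the published defaults.
    """

    track_a: SignalTrack
    track_b: SignalTrack
    mark_class: str = "punctate"
    params: ScanParams = field(default_factory=ScanParams)

    def __post_init__(self):
        if self.track_a.chrom_sizes != self.track_b.chrom_sizes:
            raise ValueError("tracks must share the chromosome grid")
        self.params.resolve_alpha(self.mark_class)  # validates mark_class

    def fit(self) -> "DHMRResults":
        """Run the three-criterion scan and return the results object."""
        stage_counts: dict[str, int] = {}
        dhmrs = call_dhmrs(self.track_a, self.track_b, self.mark_class,
                           self.params, _stage_counts=stage_counts)
        return DHMRResults(model=self, dhmrs=dhmrs, stage_counts=stage_counts)


@dataclass
class DHMRResults:
    """Fitted DHMR set with per-stage diagnostics."""

    model: DifferentialMarkModel
    dhmrs: pd.DataFrame
    stage_counts: dict[str, int]

    @property
    def n_dhmrs(self) -> int:
        return len(self.dhmrs)

    def summary(self) -> str:
        p = self.model.params
        lines = [
            "Differential Histone Modification Regions",
            "=" * 57,
            f"mark class:          {self.model.mark_class} "
            f"(enrichment alpha {p.resolve_alpha(self.model.mark_class):g})",
            f"scan:                {p.seed_bins}-bin seed, {p.max_bins}-bin cap, "
            f"p < {p.scan_alpha:g}",
            f"fold change:         >= {p.min_fold:g} (pseudocount {p.pseudocount:g})",
            f"merge gap:           < {p.merge_gap} bp",
            "-" * 57,
            "stage survivors:",
        ]
        for stage in ("candidates", "fold_pass", "merged", "enriched"):
            lines.append(f"  {stage:<18} {self.stage_counts.get(stage, 0):>8d}")
        lines.append("-" * 57)
        n_up = int((self.dhmrs["direction"] == "up").sum()) if self.n_dhmrs else 0
        lines.append(f"DHMRs:               {self.n_dhmrs} "
                     f"({n_up} up, {self.n_dhmrs - n_up} down)")
        if self.n_dhmrs:
            w = self.dhmrs["end"] - self.dhmrs["start"]
            lines.append(f"median width:        {int(w.median())} bp")
            lines.append(f"median fold change:  {self.dhmrs['fold_change'].median():.2f}")
        return "\n".join(lines)

    def to_bed(self, path, mark: str = ".") -> None:
        from .io import write_dhmrs_bed
        write_dhmrs_bed(self.dhmrs, path, mark=mark)
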