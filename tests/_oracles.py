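"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's prefix-sum/vectorised code paths:
coverage by per-base membership counting, window t-tests via
scipy.stats.ttest_rel on explicit slices, Poisson tails by direct series
summation, interval operations by quadratic scans.
"""

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats


def coverage_oracle(intervals, length):
    """counts[b] = #intervals containing base b, by per-base membership."""
    out = np.zeros(length, dtype=int)
    for b in range(length):
        out[b] = sum(1 for (_, s, e) in intervals if s <= b < e)
    return out


def window_pvalues(va, vb, k):
    """Paired two-sided t p-value for every k-bin window, via scipy on
    explicit sliding windows; degenerate zero-variance windows follow
    the t-statistic limits (p=1 at zero mean difference, else p=0)."""
    wa = sliding_window_view(np.asarray(va, float), k)
    wb = sliding_window_view(np.asarray(vb, float), k)
    d = wb - wa
    with np.errstate(all="ignore"):
        p = stats.ttest_rel(wb, wa, axis=1).pvalue
    degen = d.std(axis=1) == 0
    p[degen] = np.where(np.abs(d.mean(axis=1)[degen]) > 0, 0.0, 1.0)
    return p


def scan_oracle(va, vb, seed_bins=5, max_bins=50, alpha=0.01):
    """All-window seed-and-slide reference: for every start whose seed
    window has p < alpha, slide the window 1 bin at a time while each
    step's p <= alpha, capping the accumulated stretch at max_bins.
    Returns the per-seed stretches (bin coordinates)."""
    n = len(va)
    if n < seed_bins:
        return []
    p = window_pvalues(va, vb, seed_bins)
    stretches = []
    for s in range(n - seed_bins + 1):
        if p[s] < alpha:
            e = s + seed_bins
            j = s + 1
            while (j + seed_bins <= n and j + seed_bins - s <= max_bins
                   and p[j] <= alpha):
                e = j + seed_bins
                j += 1
            stretches.append((s, e, float(p[j - 1])))
    return stretches


def union_intervals(ivs):
    """Union of possibly overlapping [s, e) pairs (touching merges)."""
    out = []
    for s, e in sorted((s, e) for s, e, *_ in ivs):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def poisson_upper_tail_series(k, lam, tol=1e-25):
    """P(X >= k | Poisson(lam)) by direct term summation from i = k."""
    if k <= 0:
        return 1.0
    if lam == 0:
        return 0.0
    log_term = k * math.log(lam) - lam - math.lgamma(k + 1)
    term = math.exp(log_term)
    total = 0.0
    i = k
    while term > tol * max(total, 1e-300) or i < k + 10:
        total += term
        i += 1
        term *= lam / i
        if i > k + 10_000:
            break
    return min(total, 1.0)


def merge_oracle(intervals, gap):
    """Repeat-until-fixed-point merging of [s, e) pairs whose gap < gap."""
    ivs = [list(x) for x in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(ivs)):
            for j in range(i + 1, len(ivs)):
                a, b = ivs[i], ivs[j]
                if a and b and max(a[0], b[0]) - min(a[1], b[1]) < gap:
                    a[0], a[1] = min(a[0], b[0]), max(a[1], b[1])
                    ivs[j] = []
                    changed = True
        ivs = [x for x in ivs if x]
    return sorted(tuple(x) for x in ivs)


def overlap_pairs_oracle(set_a, set_b):
    """For each interval in set_a (chrom, s, e), whether any interval in
    set_b overlaps it by >= 1 bp; quadratic scan."""
    out = []
    for ca, sa, ea in set_a:
        hit = any(cb == ca and min(ea, eb) - max(sa, sb) >= 1
                  for cb, sb, eb in set_b)
        out.append(hit)
    return out
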