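"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plainly as possible (explicit loops, no shared
code with the package) so that agreement is evidence, not tautology.
"""

import math
from typing import Dict, List, Sequence, Tuple


def nearest_distance_bruteforce(queries, features) -> List[float]:
    """All-pairs minimum gap; NaN when a query's chromosome has no feature."""
    out = []
    for q in queries:
        best = None
        for f in features:
            if f.chrom != q.chrom:
                continue
            if f.start < q.end and q.start < f.end:
                d = 0
            elif f.start >= q.end:
                d = f.start - q.end
            else:
                d = q.start - f.end
            if best is None or d < best:
                best = d
        out.append(float("nan") if best is None else float(best))
    return out


def size_factors_bruteforce(counts_rows: Dict[str, List[float]],
                            ref_ids: Sequence[str]) -> List[float]:
    """Median-of-ratios with explicit geometric means; ref genes with any zero dropped."""
    usable = [g for g in ref_ids if all(v > 0 for v in counts_rows[g])]
    n_samples = len(next(iter(counts_rows.values())))
    geo = {}
    for g in usable:
        vals = counts_rows[g]
        geo[g] = math.exp(sum(math.log(v) for v in vals) / len(vals))
    factors = []
    for j in range(n_samples):
        ratios = sorted(counts_rows[g][j] / geo[g] for g in usable)
        m = len(ratios)
        if m % 2 == 1:
            factors.append(ratios[m // 2])
        else:
            factors.append((ratios[m // 2 - 1] + ratios[m // 2]) / 2.0)
    return factors


def weighted_counts_bruteforce(reads: Sequence[Tuple[str, List[Tuple[str, int, int]]]],
                               features) -> List[float]:
    """Accumulate 1/k per (location, feature) overlap, looping over everything."""
    totals = [0.0] * len(features)
    for _read_id, locations in reads:
        k = len(locations)
        for chrom, start, end in locations:
            for fi, f in enumerate(features):
                if f.chrom == chrom and f.start < end and start < f.end:
                    totals[fi] += 1.0 / k
    return totals


def scale_regions_bruteforce(coverage: Dict[str, List[float]], gene,
                             body_length=1000, flank=500, bin_size=10) -> List[float]:
    """Fractional-interval averaging done with explicit sub-bin integration."""
    cov = coverage.get(gene.chrom, [])

    def value_at(x: float) -> float:
        i = int(math.floor(x))
        if i < 0 or i >= len(cov):
            return 0.0
        return cov[i]

    def mean_over(lo: float, hi: float) -> float:
        # integrate the per-base step function over [lo, hi)
        total = 0.0
        x = lo
        while x < hi - 1e-12:
            nxt = min(math.floor(x) + 1.0, hi)
            total += value_at(x) * (nxt - x)
            x = nxt
        return total / (hi - lo)

    n_flank = flank // bin_size
    n_body = body_length // bin_size
    L = gene.end - gene.start
    bins = []
    if gene.strand == "+":
        for j in range(n_flank):
            lo = gene.start - flank + j * bin_size
            bins.append(mean_over(lo, lo + bin_size))
        for j in range(n_body):
            lo = gene.start + L * j / n_body
            hi = gene.start + L * (j + 1) / n_body
            bins.append(mean_over(lo, hi))
        for j in range(n_flank):
            lo = gene.end + j * bin_size
            bins.append(mean_over(lo, lo + bin_size))
    else:
        for j in range(n_flank):
            hi = gene.end + flank - j * bin_size
            bins.append(mean_over(hi - bin_size, hi))
        for j in range(n_body):
            hi = gene.end - L * j / n_body
            lo = gene.end - L * (j + 1) / n_body
            bins.append(mean_over(lo, hi))
        for j in range(n_flank):
            hi = gene.start - j * bin_size
            bins.append(mean_over(hi - bin_size, hi))
    return bins


def hypergeom_tail_bruteforce(n_a: int, n_b: int, k: int, universe: int) -> float:
    """P(X >= k) by direct enumeration of the hypergeometric pmf."""
    total = 0.0
    denom = math.comb(universe, n_b)
    for x in range(k, min(n_a, n_b) + 1):
        if n_b - x > universe - n_a:
            continue
        total += math.comb(n_a, x) * math.comb(universe - n_a, n_b - x) / denom
    return min(total, 1.0)


def bh_bruteforce(pvals: Sequence[float]) -> List[float]:
    """Step-up BH computed literally from the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = min(running, 1.0)
    return q
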