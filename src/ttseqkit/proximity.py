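"""Distance-to-nearest-feature association between DE genes and genomic sites.

For every gene the distance to its nearest feature (0 when they overlap) is
computed, the genes are bi-partitioned into significant and not-significant,
and the statistic is the ratio of the two partition medians.  A ratio below 1
means the significant genes sit closer to the feature set than the rest of
the genome.  When either median is zero (most genes overlap a feature) the
median is replaced by the fraction of zero-distance genes per partition and
the ratio becomes (null zero-fraction) / (significant zero-fraction), which
keeps the orientation: < 1 still reads "significant genes closer".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np

from .errors import DataError
from .formats import GeneRecord, GenomicInterval


@dataclass
class ProximityResult:
    feature_set_name: str
    median_sig: float
    median_null: float
    ratio: float
    fallback_used: bool
    n_sig: int
    n_null: int
    zero_tally_sig: int
    zero_tally_null: int
    n_excluded_sig: int = 0
    n_excluded_null: int = 0


def nearest_distance(
    queries: Sequence[GenomicInterval],
    features: Sequence[GenomicInterval],
) -> np.ndarray:
    """Per-query distance in bp to the nearest feature on the same chromosome.

    Overlapping intervals are at distance 0; otherwise the gap between the
    closest boundaries is returned.  Queries on chromosomes without any
    feature get NaN (callers exclude and report them).
    """
    if not features:
        raise DataError("feature set is empty")
    # per chromosome: starts sorted ascending, running max of ends
    index: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append(f)
    for chrom, fs in by_chrom.items():
        fs = sorted(fs, key=lambda f: f.start)
        starts = np.array([f.start for f in fs], dtype=np.int64)
        ends_cummax = np.maximum.accumulate(np.array([f.end for f in fs], dtype=np.int64))
        index[chrom] = (starts, ends_cummax)

    out = np.full(len(queries), np.nan)
    for qi, q in enumerate(queries):
        if q.chrom not in index:
            continue
        starts, ends_cummax = index[q.chrom]
        i = int(np.searchsorted(starts, q.end, side="left"))
        best = None
        if i > 0:
            left_end = int(ends_cummax[i - 1])
            if left_end > q.start:       # overlap
                out[qi] = 0.0
                continue
            best = q.start - left_end
        if i < len(starts):
            right = int(starts[i]) - q.end
            best = right if best is None else min(best, right)
        out[qi] = float(best)
    return out


def association_from_distances(
    sig_distances: Sequence[float],
    null_distances: Sequence[float],
    feature_set_name: str = "",
    n_excluded_sig: int = 0,
    n_excluded_null: int = 0,
) -> ProximityResult:
    """The median-ratio statistic from two pre-computed distance partitions."""
    sig = np.asarray(sig_distances, dtype=float)
    null = np.asarray(null_distances, dtype=float)
    if sig.size == 0 or null.size == 0:
        raise DataError("both distance partitions must be non-empty")
    if np.any(sig < 0) or np.any(null < 0):
        raise DataError("distances must be non-negative")
    median_sig = float(np.median(sig))
    median_null = float(np.median(null))
    zero_sig = int(np.sum(sig == 0))
    zero_null = int(np.sum(null == 0))
    fallback = median_sig == 0 or median_null == 0
    if not fallback:
        ratio = median_sig / median_null
    else:
        frac_sig = zero_sig / sig.size
        frac_null = zero_null / null.size
        ratio = frac_null / frac_sig if frac_sig > 0 else float("inf")
    return ProximityResult(
        feature_set_name=feature_set_name,
        median_sig=median_sig,
        median_null=median_null,
        ratio=ratio,
        fallback_used=fallback,
        n_sig=int(sig.size),
        n_null=int(null.size),
        zero_tally_sig=zero_sig,
        zero_tally_null=zero_null,
        n_excluded_sig=n_excluded_sig,
        n_excluded_null=n_excluded_null,
    )


def proximity_association(
    sig_genes: Iterable[str],
    all_genes: Sequence[GeneRecord],
    features: Sequence[GenomicInterval],
    feature_set_name: str = "",
) -> ProximityResult:
    """Median-distance ratio of significant vs. all other genes to a feature set.

    The null partition is every annotated gene not in ``sig_genes``.  Genes on
    chromosomes without any feature are excluded from both partitions
    symmetrically and reported in the result.
    """
    sig_set: Set[str] = set(sig_genes)
    unknown = sig_set - {g.gene_id for g in all_genes}
    if unknown:
        raise DataError(f"significant genes not in annotation: {sorted(unknown)[:5]}")
    distances = nearest_distance([g.interval for g in all_genes], features)
    sig_d, null_d = [], []
    excl_sig = excl_null = 0
    for gene, d in zip(all_genes, distances):
        if np.isnan(d):
            if gene.gene_id in sig_set:
                excl_sig += 1
            else:
                excl_null += 1
            continue
        (sig_d if gene.gene_id in sig_set else null_d).append(d)
    if not sig_d or not null_d:
        raise DataError("a distance partition is empty (no significant or no null genes)")
    return association_from_distances(
        sig_d, null_d, feature_set_name=feature_set_name,
        n_excluded_sig=excl_sig, n_excluded_null=excl_null,
    )
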