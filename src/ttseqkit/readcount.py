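"""Alignment filtering, stranded gene counting, and multi-mapping repeat counting.

The multi-mapping path mirrors the expanded-alignment approach used for yeast
Ty retrotransposons: every candidate location of a read becomes its own row,
weighted 1/k where k is the read's number of locations, so one read always
contributes exactly one unit of mass.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import DataError
from .formats import (
    AlignedLocation,
    AlignmentSet,
    GeneRecord,
    GenomicInterval,
    Read,
)

STRANDEDNESS = ("unstranded", "forward", "reverse")

EXPANDED_COLUMNS = ["read_id", "chrom", "start", "end", "strand",
                    "mismatches", "n_locations", "weight"]


def filter_alignments(
    alignments: AlignmentSet,
    max_mismatches: int = 2,
    require_unique: bool = True,
    require_primary: bool = True,
    keep_best: bool = False,
) -> AlignmentSet:
    """Apply the standard nascent-RNA alignment filters.

    Locations with more than ``max_mismatches`` mismatches are dropped (the
    default of 2 means "fewer than three mismatches").  With ``keep_best``,
    only locations tied at the read's minimum mismatch count survive.  With
    ``require_unique``, reads that retain more than one location are dropped
    entirely.  With ``require_primary``, only the primary location is kept.
    """
    if max_mismatches < 0:
        raise DataError("max_mismatches must be >= 0")
    out: List[Read] = []
    for read in alignments:
        locs = [l for l in read.locations if l.mismatches <= max_mismatches]
        if not locs:
            continue
        if keep_best:
            best = min(l.mismatches for l in locs)
            locs = [l for l in locs if l.mismatches == best]
        if require_unique and len(locs) > 1:
            continue
        if require_primary:
            locs = [l for l in locs if l.is_primary]
            if not locs:
                continue
        out.append(Read(read.read_id, tuple(locs)))
    return AlignmentSet(out)


def _gene_trees(annotation: Sequence[GeneRecord]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for idx, gene in enumerate(annotation):
        trees.setdefault(gene.chrom, IntervalTree()).addi(gene.start, gene.end, idx)
    return trees


def count_reads_per_gene(
    alignments: AlignmentSet,
    annotation: Sequence[GeneRecord],
    strandedness: str = "reverse",
    allow_multioverlap: bool = True,
) -> pd.Series:
    """Count uniquely mapped reads per gene with a >= 1 bp overlap rule.

    ``strandedness="reverse"`` counts a read only when its strand is opposite
    the gene's (the reverse-stranded single-end library convention, i.e.
    featureCounts ``-s 2``); with ``allow_multioverlap`` a read overlapping g
    genes increments each of them (featureCounts ``-O``), otherwise reads
    overlapping more than one eligible gene are discarded as ambiguous.
    """
    if strandedness not in STRANDEDNESS:
        raise DataError(f"strandedness must be one of {STRANDEDNESS}")
    trees = _gene_trees(annotation)
    counts = np.zeros(len(annotation), dtype=int)
    for read in alignments:
        if len(read.locations) != 1:
            raise DataError(
                f"read {read.read_id!r} has {len(read.locations)} locations; "
                "filter to uniquely mapped reads before gene counting"
            )
        loc = read.locations[0].interval
        tree = trees.get(loc.chrom)
        if tree is None:
            continue
        hits = []
        for hit in tree.overlap(loc.start, loc.end):
            gene = annotation[hit.data]
            if strandedness == "forward" and loc.strand != gene.strand:
                continue
            if strandedness == "reverse" and loc.strand == gene.strand:
                continue
            hits.append(hit.data)
        if allow_multioverlap:
            for idx in hits:
                counts[idx] += 1
        elif len(hits) == 1:
            counts[hits[0]] += 1
    return pd.Series(counts, index=[g.gene_id for g in annotation], name="count")


def expand_alignments(alignments: AlignmentSet) -> pd.DataFrame:
    """One row per (read, location), each weighted 1/k for a k-location read."""
    rows = []
    for read in alignments:
        k = len(read.locations)
        if k == 0:
            raise DataError(f"read {read.read_id!r} has no locations")
        w = 1.0 / k
        for loc in read.locations:
            iv = loc.interval
            rows.append((read.read_id, iv.chrom, iv.start, iv.end, iv.strand,
                         loc.mismatches, k, w))
    return pd.DataFrame(rows, columns=EXPANDED_COLUMNS)


def weighted_feature_counts(
    expanded: pd.DataFrame,
    features: Sequence[GenomicInterval],
    total_mapped_reads: Optional[int] = None,
) -> pd.DataFrame:
    """Sum expanded-alignment weights over features and normalize per million.

    A row contributes its full weight to every feature it overlaps by >= 1 bp,
    strand-agnostically.  ``total_mapped_reads`` defaults to the number of
    distinct reads in the table (each read counted once regardless of k).
    """
    n_reads = int(expanded["read_id"].nunique()) if len(expanded) else 0
    if total_mapped_reads is None:
        total_mapped_reads = n_reads
    if total_mapped_reads <= 0:
        raise DataError("total_mapped_reads must be positive")
    if total_mapped_reads < n_reads:
        raise DataError(
            f"total_mapped_reads ({total_mapped_reads}) is smaller than the "
            f"number of reads in the table ({n_reads})"
        )
    trees: Dict[str, IntervalTree] = {}
    for idx, f in enumerate(features):
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, idx)
    raw = np.zeros(len(features), dtype=float)
    if len(expanded):
        for row in expanded.itertuples(index=False):
            tree = trees.get(row.chrom)
            if tree is None:
                continue
            for hit in tree.overlap(row.start, row.end):
                raw[hit.data] += row.weight
    labels = [f.label for f in features]
    return pd.DataFrame(
        {
            "raw_weighted_count": raw,
            "per_million": raw * 1e6 / total_mapped_reads,
        },
        index=pd.Index(labels, name="feature"),
    )
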