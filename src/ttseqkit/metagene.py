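"""Coverage tracks from alignments and scale-regions metagene matrices.

Each gene row of the matrix has a fixed grid: 500 bp upstream flank, a gene
body rescaled onto 1,000 bp, and 500 bp downstream flank, all in 10 bp bins
(200 columns).  Gene bodies are rescaled by exact fractional-interval
averaging: a gene of length L contributes L/100 genomic bp to each body bin,
with partial bases weighted proportionally, so the operation is deterministic
and well defined for genes shorter or longer than the body grid.  Positions
beyond chromosome ends contribute zero coverage but full bin width
(missing-data-as-zero).  Minus-strand genes are traversed right-to-left so
columns always run upstream -> TSS -> body -> TES -> downstream.
"""

from __future__ import annotations

from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .errors import DataError
from .formats import AlignmentSet, CoverageTrack, GeneRecord


def coverage_from_alignments(
    alignments: AlignmentSet,
    chrom_sizes: Mapping[str, int],
    strand: str = "both",
) -> CoverageTrack:
    """Per-base read depth, optionally restricted to one read strand."""
    if strand not in ("+", "-", "both"):
        raise DataError("strand must be '+', '-' or 'both'")
    values = {c: np.zeros(int(n), dtype=float) for c, n in chrom_sizes.items()}
    for read in alignments:
        if len(read.locations) != 1:
            raise DataError(
                f"read {read.read_id!r} is multi-mapped; filter to unique reads first"
            )
        iv = read.locations[0].interval
        if strand != "both" and iv.strand != strand:
            continue
        if iv.chrom not in values:
            raise DataError(f"read on unknown chromosome {iv.chrom!r}")
        if iv.end > values[iv.chrom].size:
            raise DataError(
                f"read {read.read_id!r} extends past the end of {iv.chrom}"
            )
        values[iv.chrom][iv.start:iv.end] += 1.0
    return CoverageTrack(values=values, strand=strand)


def _coverage_integral(cov: np.ndarray):
    """Return F with F(x) = integral of the per-base step function over [0, x),
    evaluated at real-valued x, zero outside the chromosome."""
    length = cov.size
    cum = np.concatenate(([0.0], np.cumsum(cov)))

    def F(x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), 0.0, float(length))
        i = np.floor(x).astype(int)
        frac = x - i
        safe = np.minimum(i, max(length - 1, 0))
        add = np.where(i < length, frac * cov[safe], 0.0) if length else np.zeros_like(x)
        return cum[i] + add

    return F


def _gene_boundaries(gene: GeneRecord, body_length: int, flank: int, bin_size: int) -> np.ndarray:
    """Bin boundaries in genomic coordinates, ordered in transcript direction."""
    n_flank = flank // bin_size
    n_body = body_length // bin_size
    L = gene.end - gene.start
    if gene.strand == "+":
        up = gene.start - flank + bin_size * np.arange(n_flank + 1, dtype=float)
        body = gene.start + L * np.arange(n_body + 1, dtype=float) / n_body
        down = gene.end + bin_size * np.arange(n_flank + 1, dtype=float)
        return np.concatenate((up[:-1], body[:-1], down))
    up = gene.end + flank - bin_size * np.arange(n_flank + 1, dtype=float)
    body = gene.end - L * np.arange(n_body + 1, dtype=float) / n_body
    down = gene.start - bin_size * np.arange(n_flank + 1, dtype=float)
    return np.concatenate((up[:-1], body[:-1], down))


def scale_regions_matrix(
    track: CoverageTrack,
    annotation: Sequence[GeneRecord],
    body_length: int = 1000,
    flank: int = 500,
    bin_size: int = 10,
) -> pd.DataFrame:
    """Genes x bins matrix of mean coverage over the scaled gene grid."""
    if body_length % bin_size or flank % bin_size:
        raise DataError("bin_size must divide both flank and body_length")
    n_flank = flank // bin_size
    n_body = body_length // bin_size
    columns = (
        [f"up{j}" for j in range(n_flank)]
        + [f"body{j}" for j in range(n_body)]
        + [f"down{j}" for j in range(n_flank)]
    )
    integrals = {}
    rows = np.zeros((len(annotation), len(columns)))
    for gi, gene in enumerate(annotation):
        if gene.chrom not in integrals:
            cov = track.values.get(gene.chrom, np.zeros(0))
            integrals[gene.chrom] = _coverage_integral(cov)
        F = integrals[gene.chrom]
        b = _gene_boundaries(gene, body_length, flank, bin_size)
        if gene.strand == "+":
            lo, hi = b[:-1], b[1:]
        else:
            lo, hi = b[1:], b[:-1]
        rows[gi] = (F(hi) - F(lo)) / (hi - lo)
    return pd.DataFrame(rows, index=[g.gene_id for g in annotation], columns=columns)


def metagene_profile(
    matrices: Union[pd.DataFrame, Sequence[pd.DataFrame]],
) -> pd.DataFrame:
    """Column-wise mean and median over genes, optionally pooled over replicates.

    Replicate matrices are averaged elementwise first (they must share the
    same shape and bin labels), then summarised across genes.
    """
    if isinstance(matrices, pd.DataFrame):
        matrices = [matrices]
    matrices = list(matrices)
    if not matrices:
        raise DataError("need at least one coverage matrix")
    first = matrices[0]
    for m in matrices[1:]:
        if m.shape != first.shape or list(m.columns) != list(first.columns):
            raise DataError("replicate matrices differ in shape or bin labels")
    pooled = sum(m.to_numpy(float) for m in matrices) / len(matrices)
    return pd.DataFrame(
        {
            "mean": pooled.mean(axis=0) if pooled.size else np.zeros(first.shape[1]),
            "median": np.median(pooled, axis=0) if pooled.size else np.zeros(first.shape[1]),
        },
        index=pd.Index(first.columns, name="bin"),
    )
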