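"""Median-of-ratios size factors, count/coverage scaling, and global transcription ratios.

Two reference modes implement the central contrast of spike-in calibrated
nascent-RNA sequencing:

* ``internal`` - size factors computed from the target organism's genes.
  Any genome-wide shift in target transcription is absorbed into the factors,
  so normalized target values are blind to global changes.
* ``spikein`` - size factors computed only from the spike-in organism's
  genes, whose input mass is constant across samples.  Global shifts in
  target transcription survive normalization and become measurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import DataError
from .formats import CoverageTrack

MODES = ("internal", "spikein")
DEFAULT_EXCLUDE_SUFFIXES = ("rRNA", "RDN")


@dataclass
class SizeFactors:
    """Per-sample median-of-ratios scaling constants."""

    factors: pd.Series
    mode: str
    reference_gene_count: int

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise DataError(f"mode must be one of {MODES}")
        if self.reference_gene_count < 1:
            raise DataError("reference_gene_count must be >= 1")
        if (self.factors <= 0).any():
            raise DataError("size factors must be positive")


def size_factors(
    counts: pd.DataFrame,
    organism: Union[pd.Series, Mapping[str, str]],
    mode: str = "internal",
    exclude_suffixes: Sequence[str] = DEFAULT_EXCLUDE_SUFFIXES,
    exclude_ids: Iterable[str] = (),
) -> SizeFactors:
    """Median-of-ratios size factors over a reference gene subset.

    The reference is the target genes (``mode="internal"``) or the spike-in
    genes (``mode="spikein"``), minus genes whose names end in one of
    ``exclude_suffixes`` (ribosomal RNA conventions) or appear in
    ``exclude_ids``.  Genes with a zero count in any sample are dropped, a
    per-gene geometric mean across samples is the pseudo-reference, and each
    sample's factor is the median of its count-to-reference ratios.
    """
    if mode not in MODES:
        raise DataError(f"mode must be one of {MODES}")
    org = pd.Series(dict(organism)) if not isinstance(organism, pd.Series) else organism
    ref_org = "target" if mode == "internal" else "spikein"
    ref_ids = [g for g in counts.index if org.get(g) == ref_org]
    exclude_ids = set(exclude_ids)
    ref_ids = [
        g for g in ref_ids
        if g not in exclude_ids and not any(g.endswith(suf) for suf in exclude_suffixes)
    ]
    if not ref_ids:
        raise DataError(
            f"no eligible reference gene for mode={mode!r}: "
            "all reference genes were excluded by name filters or none exist"
        )
    sub = counts.loc[ref_ids].astype(float)
    positive = (sub > 0).all(axis=1)
    if not positive.any():
        raise DataError(
            f"no eligible reference gene for mode={mode!r}: "
            "all candidate reference genes contain a zero count"
        )
    ref = sub.loc[positive]
    geo_mean = np.exp(np.log(ref).mean(axis=1))
    # plain sample median of the ratios: an even reference count averages the
    # two central ratios arithmetically
    factors = ref.div(geo_mean, axis=0).median(axis=0)
    factors.name = "size_factor"
    return SizeFactors(factors=factors, mode=mode,
                       reference_gene_count=int(positive.sum()))


def normalize_counts(counts: pd.DataFrame, s: SizeFactors) -> pd.DataFrame:
    """Divide every sample column by its size factor (all genes, any organism)."""
    if list(counts.columns) != list(s.factors.index):
        raise DataError("size factor samples do not match count matrix columns")
    return counts.div(s.factors, axis=1)


def scale_coverage(track: CoverageTrack, s_j: float) -> CoverageTrack:
    """Divide every per-base value by the size factor ``s_j`` (recorded on the track)."""
    if s_j <= 0:
        raise DataError("size factor must be positive")
    values = {chrom: arr / s_j for chrom, arr in track.values.items()}
    return CoverageTrack(values=values, strand=track.strand, scale=track.scale * s_j)


def global_transcription_ratio(
    target_tally: pd.Series,
    spikein_tally: pd.Series,
) -> pd.Series:
    """Per-sample ratio of target-organism reads to spike-in reads.

    With constant spike-in mass per sample this ratio tracks absolute,
    genome-wide transcriptional output; internal normalization cannot see it.
    """
    if list(target_tally.index) != list(spikein_tally.index):
        raise DataError("target and spike-in tallies cover different samples")
    zero = spikein_tally[spikein_tally <= 0]
    if len(zero):
        raise DataError(
            f"global transcription ratio undefined: zero spike-in tally in "
            f"sample(s) {list(zero.index)}"
        )
    ratio = target_tally.astype(float) / spikein_tally.astype(float)
    ratio.name = "global_transcription_ratio"
    return ratio


def organism_tallies(
    counts: pd.DataFrame,
    organism: Union[pd.Series, Mapping[str, str]],
) -> Tuple[pd.Series, pd.Series]:
    """Total counts per sample for target and spike-in genes, respectively."""
    org = pd.Series(dict(organism)) if not isinstance(organism, pd.Series) else organism
    org = org.reindex(counts.index)
    target = counts.loc[org == "target"].sum(axis=0)
    spike = counts.loc[org == "spikein"].sum(axis=0)
    return target, spike


def condition_median_ratio(
    ratios: pd.Series,
    conditions: Mapping[str, str],
) -> pd.Series:
    """Median of the per-sample ratios within each condition (replicate summary)."""
    cond = pd.Series(dict(conditions)).reindex(ratios.index)
    if cond.isna().any():
        raise DataError("every sample needs a condition label")
    return ratios.groupby(cond).median()
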