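"""Base-composition bias around transcription end sites.

Nascent-RNA protocols that label uracil recover fragments preferentially
where the transcript is U-rich, i.e. where the template's sense strand is
A-rich.  This module measures the per-offset adenine (or any base) fraction
in a window around the TES of every gene, read on the sense strand, and
smooths it with a sliding window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .errors import DataError
from .formats import GeneRecord

BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class BaseFractionProfile:
    """Per-offset fraction of genes carrying a given sense-strand base near the TES."""

    offsets: np.ndarray          # -window .. window-1, TES at 0
    fraction: np.ndarray         # raw per-offset fraction (NaN if no gene valid)
    n_valid: np.ndarray          # genes contributing at each offset
    base: str
    window: int

    def smoothed(self, smooth_window: int = 16) -> np.ndarray:
        return sliding_smooth(self.fraction, smooth_window)

    def to_frame(self, smooth_window: int = 16) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "raw": self.fraction,
                "smoothed": self.smoothed(smooth_window),
                "n_genes": self.n_valid,
            }
        ).set_index("offset")


def _load_sequences(genome) -> Mapping[str, str]:
    if isinstance(genome, Mapping):
        return {c: str(s).upper() for c, s in genome.items()}
    from pyfaidx import Fasta

    fa = Fasta(str(Path(genome)))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def base_fraction_window(
    genome: Union[str, Path, Mapping[str, str]],
    annotation: Sequence[GeneRecord],
    base: str = "A",
    window: int = 100,
) -> BaseFractionProfile:
    """Fraction of genes whose sense-strand base at TES+offset equals ``base``.

    Offsets run from -window to window-1 with 0 being the first base past the
    gene end; minus-strand genes are read on the reverse complement with
    positive offsets pointing downstream.  Positions beyond a chromosome end
    are dropped from numerator and denominator at that offset.
    """
    if base not in BASES:
        raise DataError(f"base must be one of {BASES}")
    if window < 1:
        raise DataError("window must be >= 1")
    seqs = _load_sequences(genome)
    offsets = np.arange(-window, window)
    match = np.zeros(offsets.size, dtype=int)
    valid = np.zeros(offsets.size, dtype=int)
    want_minus = _COMPLEMENT[base]
    for gene in annotation:
        if gene.chrom not in seqs:
            raise DataError(f"chromosome {gene.chrom!r} missing from genome")
        seq = seqs[gene.chrom]
        length = len(seq)
        if gene.strand == "+":
            pos = gene.end + offsets
            want = base
        else:
            pos = gene.start - 1 - offsets
            want = want_minus
        ok = (pos >= 0) & (pos < length)
        valid += ok
        idx = np.flatnonzero(ok)
        for i in idx:
            if seq[pos[i]] == want:
                match[i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        fraction = np.where(valid > 0, match / np.maximum(valid, 1), np.nan)
    return BaseFractionProfile(offsets=offsets, fraction=fraction,
                               n_valid=valid, base=base, window=window)


def sliding_smooth(values: Sequence[float], window: int = 16) -> np.ndarray:
    """Centred moving average, truncated and renormalized at the edges.

    An even window has no centre; the fixed convention is offsets
    -window/2 .. window/2 - 1 around each position (e.g. -8..+7 for 16).
    NaN entries are ignored within each window.
    """
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if window < 1 or window > n:
        raise DataError("smoothing window must be in [1, len(values)]")
    half_lo = window // 2
    half_hi = window - half_lo
    out = np.empty(n)
    for i in range(n):
        chunk = arr[max(0, i - half_lo): min(n, i + half_hi)]
        finite = chunk[~np.isnan(chunk)]
        out[i] = finite.mean() if finite.size else np.nan
    return out
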