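"""Plain-text genomic formats and the domain types built from them.

Every coordinate held in memory is 0-based, half-open ([start, end)).
GTF-style gene tables, which are 1-based and inclusive, are converted at the
boundary on read and write.  BED intervals are already 0-based half-open and
pass through unchanged.

Supported exchange formats
--------------------------
* BED (3-6 columns) for feature-site interval sets.
* A tab-delimited gene table (header: gene_id, chrom, start, end, strand and
  optionally biotype, family) with GTF-style 1-based inclusive coordinates.
* Counts TSV: gene_id index column plus one column per sample.
* Alignment TSV: one row per candidate mapping location
  (read_id, chrom, start, end, strand, mismatches, is_primary).
* bedGraph (UCSC dialect) for coverage tracks.
* FASTA (written through Biopython, read through pyfaidx in `seqbias`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

STRANDS = ("+", "-", ".")
ORGANISMS = ("target", "spikein")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval. ``strand`` may be '.' for unstranded sets."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise DataError("interval chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise DataError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise DataError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share >= 1 bp (strand-agnostic)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def label(self) -> str:
        return self.name or f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its interval, organism tag and optional repeat family."""

    gene_id: str
    interval: GenomicInterval
    organism: str = "target"
    biotype: str = "protein_coding"
    family: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise DataError("gene_id must be non-empty")
        if self.organism not in ORGANISMS:
            raise DataError(f"organism must be one of {ORGANISMS}, got {self.organism!r}")
        if self.interval.strand not in ("+", "-"):
            raise DataError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand


GenomeAnnotation = List[GeneRecord]


def validate_annotation(genes: Sequence[GeneRecord]) -> None:
    seen = set()
    for g in genes:
        if g.gene_id in seen:
            raise DataError(f"duplicate gene_id {g.gene_id!r} in annotation")
        seen.add(g.gene_id)


def annotation_by_chrom(genes: Sequence[GeneRecord]) -> Dict[str, List[GeneRecord]]:
    out: Dict[str, List[GeneRecord]] = {}
    for g in genes:
        out.setdefault(g.chrom, []).append(g)
    return out


def chrom_sizes(genes: Sequence[GeneRecord], pad: int = 500) -> Dict[str, int]:
    """Chromosome sizes inferred from the right-most gene end plus a pad."""
    sizes: Dict[str, int] = {}
    for g in genes:
        sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.end + pad)
    return sizes


def organism_of_genes(genes: Sequence[GeneRecord]) -> pd.Series:
    """gene_id -> organism Series, in annotation order."""
    return pd.Series({g.gene_id: g.organism for g in genes})


@dataclass
class CoverageTrack:
    """Per-base coverage vectors, one per chromosome.

    ``scale`` records the size factor the track has been divided by
    (1.0 for an unscaled track); see ``normalization.scale_coverage``.
    """

    values: Dict[str, np.ndarray]
    strand: str = "."
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.strand not in STRANDS and self.strand != "both":
            raise DataError(f"invalid track strand {self.strand!r}")
        if self.scale <= 0:
            raise DataError("track scale factor must be positive")
        for chrom, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1:
                raise DataError(f"coverage for {chrom} must be a 1-D vector")
            if np.any(arr < 0):
                raise DataError(f"negative coverage value on {chrom}")
            self.values[chrom] = arr


@dataclass(frozen=True)
class AlignedLocation:
    interval: GenomicInterval
    mismatches: int = 0
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.mismatches < 0:
            raise DataError("mismatch count must be non-negative")


@dataclass(frozen=True)
class Read:
    """One sequenced read with >= 1 candidate mapping locations."""

    read_id: str
    locations: Tuple[AlignedLocation, ...]

    def __post_init__(self) -> None:
        if len(self.locations) == 0:
            raise DataError(f"read {self.read_id!r} has no mapping locations")
        if sum(loc.is_primary for loc in self.locations) > 1:
            raise DataError(f"read {self.read_id!r} has more than one primary location")


@dataclass
class AlignmentSet:
    reads: List[Read] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def __len__(self) -> int:
        return len(self.reads)


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_intervals(path) -> List[GenomicInterval]:
    """Read a BED file (>= 3 columns, 0-based half-open) in file order."""
    intervals: List[GenomicInterval] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = cols[3] if len(cols) >= 4 else ""
            strand = cols[5] if len(cols) >= 6 else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand, name))
            except DataError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_intervals(intervals: Sequence[GenomicInterval], path) -> None:
    """Write intervals as BED6 (name '.' when empty, score column 0)."""
    with Path(path).open("w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# gene table (GTF-like 1-based inclusive coordinates)
# ---------------------------------------------------------------------------

_ANNOT_REQUIRED = ("gene_id", "chrom", "start", "end", "strand")


def read_annotation(path, organism_of: Mapping[str, str]) -> GenomeAnnotation:
    """Read a tab-delimited gene table with 1-based inclusive coordinates.

    ``organism_of`` maps each chromosome name to ``"target"`` or
    ``"spikein"``; an unmapped chromosome is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _ANNOT_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    genes: GenomeAnnotation = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        gene_id = row.gene_id
        if gene_id in seen:
            raise FormatError(f"{path}:{i}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        chrom = row.chrom
        if chrom not in organism_of:
            raise FormatError(f"{path}:{i}: chromosome {chrom!r} not in organism mapping")
        try:
            start1, end1 = int(row.start), int(row.end)
        except ValueError as exc:
            raise FormatError(f"{path}:{i}: non-integer coordinates") from exc
        biotype = getattr(row, "biotype", None)
        if biotype is None or (isinstance(biotype, float) and np.isnan(biotype)) or pd.isna(biotype):
            biotype = "protein_coding"
        family = getattr(row, "family", None)
        if family is not None and pd.isna(family):
            family = None
        try:
            interval = GenomicInterval(chrom, start1 - 1, end1, row.strand)
            genes.append(
                GeneRecord(gene_id, interval, organism=organism_of[chrom],
                           biotype=str(biotype), family=family)
            )
        except DataError as exc:
            raise FormatError(f"{path}:{i}: {exc}") from exc
    return genes


def write_annotation(genes: Sequence[GeneRecord], path) -> None:
    """Write the gene table with 1-based inclusive coordinates."""
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "start": g.start + 1,
            "end": g.end,
            "strand": g.strand,
            "biotype": g.biotype,
            "family": g.family if g.family is not None else "",
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand",
                                "biotype", "family"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# counts TSV
# ---------------------------------------------------------------------------

def read_counts(path) -> pd.DataFrame:
    """Read a genes x samples counts TSV (gene_id index, one column per sample)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate gene ids")
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged rows or missing values")
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric count value") from exc
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative count value")
    df.index.name = "gene_id"
    return df


def write_counts(matrix: pd.DataFrame, path) -> None:
    if matrix.size and (matrix.to_numpy() < 0).any():
        raise DataError("count matrix contains negative values")
    matrix.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# alignment TSV
# ---------------------------------------------------------------------------

_ALN_COLUMNS = ("read_id", "chrom", "start", "end", "strand", "mismatches", "is_primary")
_TRUTHY = {"1", "true", "True", "TRUE"}
_FALSY = {"0", "false", "False", "FALSE"}


def read_alignments(path) -> AlignmentSet:
    """Read an alignment TSV; rows sharing a read_id become one multi-location read."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _ALN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    grouped: Dict[str, List[AlignedLocation]] = {}
    order: List[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            start, end = int(row.start), int(row.end)
            mismatches = int(row.mismatches)
        except ValueError as exc:
            raise FormatError(f"{path}:{i}: non-integer field") from exc
        flag = str(row.is_primary)
        if flag in _TRUTHY:
            is_primary = True
        elif flag in _FALSY:
            is_primary = False
        else:
            raise FormatError(f"{path}:{i}: invalid is_primary value {flag!r}")
        try:
            loc = AlignedLocation(
                GenomicInterval(row.chrom, start, end, row.strand),
                mismatches=mismatches,
                is_primary=is_primary,
            )
        except DataError as exc:
            raise FormatError(f"{path}:{i}: {exc}") from exc
        if row.read_id not in grouped:
            grouped[row.read_id] = []
            order.append(row.read_id)
        grouped[row.read_id].append(loc)
    reads = []
    for rid in order:
        try:
            reads.append(Read(rid, tuple(grouped[rid])))
        except DataError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return AlignmentSet(reads)


def write_alignments(alignments: AlignmentSet, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(_ALN_COLUMNS) + "\n")
        for read in alignments:
            for loc in read.locations:
                iv = loc.interval
                fh.write(
                    f"{read.read_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}"
                    f"\t{loc.mismatches}\t{int(loc.is_primary)}\n"
                )


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a coverage track as bedGraph.

    Adjacent equal values are merged into maximal runs, zero runs are omitted,
    and values use the shortest exact decimal representation (>= 6 significant
    digits), so re-expanding the file reproduces the track exactly.
    """
    with Path(path).open("w") as fh:
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            if np.any(arr < 0):
                raise DataError(f"negative coverage value on {chrom}")
            if arr.size == 0:
                continue
            boundaries = np.flatnonzero(np.diff(arr) != 0) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{_fmt_value(v)}\n")


def _fmt_value(v: float) -> str:
    v = float(v)
    if v == int(v):
        return str(int(v))
    return repr(v)


def read_bedgraph(path, chrom_sizes: Mapping[str, int],
                  strand: str = ".", scale: float = 1.0) -> CoverageTrack:
    """Expand a bedGraph file back into per-base vectors of the given sizes."""
    values = {c: np.zeros(int(n), dtype=float) for c, n in chrom_sizes.items()}
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            chrom = cols[0]
            if chrom not in values:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                s, e, v = int(cols[1]), int(cols[2]), float(cols[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed record") from exc
            if not (0 <= s < e <= values[chrom].size):
                raise FormatError(f"{path}:{lineno}: record outside chromosome bounds")
            values[chrom][s:e] = v
    return CoverageTrack(values, strand=strand, scale=scale)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
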