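"""Synthetic two-organism transcriptomes with known ground truth.

The generator emulates the statistical structure of a spike-in calibrated
nascent-RNA experiment in budding yeast:

* a target gene catalogue plus a spike-in catalogue on dedicated
  chromosomes, with the spike-in expected to carry ~10% of each library's
  mass (a 90:10 RNA mass mix);
* negative-binomial counts whose treated-condition means carry both
  per-gene differential effects and a genome-wide transcription scale
  (e.g. 1.0 vs 1/2.6 for a 2.6-fold global repression);
* truly differential genes preferentially placed within a configurable
  distance of feature sites, mimicking the spatial association between
  condensin-binding sites and condensin-responsive genes;
* multi-mapping reads drawn from repeat families with 1..k genomic copies;
* genome sequence with an optional adenine-rich window downstream of every
  transcription end site.

All generators are pure functions of (config, seed): each operation uses its
own child stream of the config seed, so adding draws to one generator never
perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .errors import DataError
from .formats import (
    AlignedLocation,
    AlignmentSet,
    GeneRecord,
    GenomeAnnotation,
    GenomicInterval,
    Read,
    chrom_sizes,
)

_STREAM_GENOME = 1
_STREAM_COUNTS = 2
_STREAM_GENE_READS = 3
_STREAM_SEQUENCES = 4
_STREAM_MULTIMAP = 5


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults encode a three-replicate, two-condition design with a 10%
    spike-in mass share, 10% truly differential genes at |log2FC| = 2, and
    80% of the differential genes placed within 2 kb of a feature site.
    The first key of ``global_scale`` is the control condition.
    """

    n_target_genes: int = 2000
    n_spikein_genes: int = 500
    n_feature_sites: int = 200
    n_samples_per_condition: int = 3
    global_scale: Mapping[str, float] = field(
        default_factory=lambda: {"control": 1.0, "treated": 1.0}
    )
    de_fraction: float = 0.1
    de_log2fc_location: float = 2.0
    de_log2fc_scale: float = 0.0
    nb_dispersion: float = 0.05
    proximity_enrichment: float = 0.8
    proximity_distance: int = 2000
    spike_mass_fraction: float = 0.10
    mean_count: float = 200.0
    depth_log_sd: float = 0.1
    gene_length_range: Tuple[int, int] = (500, 5000)
    intergenic_range: Tuple[int, int] = (200, 2000)
    n_target_chroms: int = 4
    n_spikein_chroms: int = 2
    chrom_length: int = 2_000_000
    site_length: int = 200
    read_length: int = 76
    a_rich_prob: float = 0.6
    a_rich_window: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_fraction", "proximity_enrichment", "spike_mass_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DataError(f"{name} must lie in [0, 1]")
        if any(v <= 0 for v in self.global_scale.values()):
            raise DataError("global_scale values must be positive")
        for name in ("n_target_genes", "n_spikein_genes", "n_samples_per_condition",
                     "chrom_length", "site_length", "read_length"):
            if getattr(self, name) < 1:
                raise DataError(f"{name} must be a positive integer")
        if self.nb_dispersion < 0:
            raise DataError("nb_dispersion must be >= 0")
        if not (0.0 < self.a_rich_prob <= 1.0):
            raise DataError("a_rich_prob must lie in (0, 1]")

    @property
    def conditions(self) -> List[str]:
        return list(self.global_scale)

    @property
    def control_condition(self) -> str:
        return self.conditions[0]

    def sample_names(self) -> List[str]:
        return [
            f"{cond}_{r + 1}"
            for cond in self.conditions
            for r in range(self.n_samples_per_condition)
        ]

    def sample_conditions(self) -> pd.Series:
        return pd.Series(
            {
                f"{cond}_{r + 1}": cond
                for cond in self.conditions
                for r in range(self.n_samples_per_condition)
            },
            name="condition",
        )


@dataclass
class SimulationTruth:
    """Ground truth for parameter-recovery tests."""

    true_de: Dict[str, float]            # gene_id -> signed true log2 fold change
    global_scale: Dict[str, float]
    site_linked: Set[str]
    family_abundances: Dict[str, float] = field(default_factory=dict)
    copy_numbers: Dict[str, int] = field(default_factory=dict)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([abs(int(config.seed)) % (2**31), stream])


def _place_genes(
    rng: np.random.Generator,
    config: SimulationConfig,
    n_genes: int,
    chrom_names: Sequence[str],
    prefix: str,
    organism: str,
) -> GenomeAnnotation:
    lo, hi = config.gene_length_range
    lengths = np.exp(rng.uniform(math.log(lo), math.log(hi), n_genes)).astype(int)
    strands = rng.choice(np.array(["+", "-"]), size=n_genes)
    per_chrom = np.array_split(np.arange(n_genes), len(chrom_names))
    genes: GenomeAnnotation = []
    g_lo, g_hi = config.intergenic_range
    for chrom, idx in zip(chrom_names, per_chrom):
        cursor = int(rng.integers(g_lo, g_hi + 1))
        for i in idx:
            glen = int(lengths[i])
            if cursor + glen > config.chrom_length:
                raise DataError(
                    f"requested genes exceed capacity of {chrom} "
                    f"(length {config.chrom_length})"
                )
            genes.append(
                GeneRecord(
                    gene_id=f"{prefix}{i:05d}",
                    interval=GenomicInterval(chrom, cursor, cursor + glen, strands[i]),
                    organism=organism,
                )
            )
            cursor += glen + int(rng.integers(g_lo, g_hi + 1))
    return genes


def simulate_genome(
    config: SimulationConfig,
) -> Tuple[GenomeAnnotation, List[GenomicInterval], SimulationTruth]:
    """Gene catalogue, feature sites, and ground truth, deterministic per seed."""
    rng = _rng(config, _STREAM_GENOME)
    target_chroms = [f"chrT{i + 1}" for i in range(config.n_target_chroms)]
    spike_chroms = [f"chrS{i + 1}" for i in range(config.n_spikein_chroms)]
    target = _place_genes(rng, config, config.n_target_genes, target_chroms, "TG", "target")
    spike = _place_genes(rng, config, config.n_spikein_genes, spike_chroms, "SG", "spikein")

    n_de = round(config.de_fraction * config.n_target_genes)
    de_idx = rng.choice(config.n_target_genes, size=n_de, replace=False)
    signs = rng.choice(np.array([-1.0, 1.0]), size=n_de)
    mags = np.abs(rng.normal(config.de_log2fc_location, config.de_log2fc_scale, n_de))
    true_de = {target[i].gene_id: float(s * m) for i, s, m in zip(de_idx, signs, mags)}

    n_linked = round(config.proximity_enrichment * n_de)
    if n_linked > config.n_feature_sites:
        raise DataError(
            f"cannot place {n_linked} site-linked DE genes with only "
            f"{config.n_feature_sites} feature sites"
        )
    linked_idx = rng.choice(de_idx, size=n_linked, replace=False) if n_linked else []
    sites: List[GenomicInterval] = []
    for k, gi in enumerate(linked_idx):
        gene = target[gi]
        gap = int(rng.integers(0, config.proximity_distance + 1))
        start = gene.end + gap
        if start + config.site_length > config.chrom_length:
            start = max(gene.start - gap - config.site_length, 0)
        sites.append(
            GenomicInterval(gene.chrom, start, start + config.site_length,
                            ".", f"site{k:04d}")
        )
    for k in range(len(sites), config.n_feature_sites):
        chrom = target_chroms[int(rng.integers(0, len(target_chroms)))]
        start = int(rng.integers(0, config.chrom_length - config.site_length))
        sites.append(
            GenomicInterval(chrom, start, start + config.site_length, ".", f"site{k:04d}")
        )

    truth = SimulationTruth(
        true_de=true_de,
        global_scale=dict(config.global_scale),
        site_linked={target[i].gene_id for i in linked_idx},
    )
    return target + spike, sites, truth


def simulate_counts(
    annotation: GenomeAnnotation,
    truth: SimulationTruth,
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial counts for all genes and samples, plus condition labels.

    Gene means are ``base * effect * scale * depth`` where the differential
    effect and the global transcription scale apply only to target genes in
    non-control conditions, and the per-sample depth applies to everything.
    """
    if not annotation:
        raise DataError("annotation is empty")
    organisms = {g.organism for g in annotation}
    if "spikein" not in organisms:
        raise DataError("annotation has no spike-in genes")
    rng = _rng(config, _STREAM_COUNTS)
    target_ids = [g.gene_id for g in annotation if g.organism == "target"]
    spike_ids = [g.gene_id for g in annotation if g.organism == "spikein"]

    sigma = 1.0
    base_target = rng.lognormal(math.log(config.mean_count), sigma, len(target_ids))
    base_spike = rng.lognormal(math.log(config.mean_count), sigma, len(spike_ids))
    if len(spike_ids):
        f = config.spike_mass_fraction
        if f > 0:
            base_spike *= (f / (1.0 - f)) * base_target.sum() / base_spike.sum()
        else:
            base_spike *= 0.0

    samples = config.sample_names()
    conditions = config.sample_conditions()
    depth = rng.lognormal(0.0, config.depth_log_sd, len(samples))
    control = config.control_condition

    effect = {gid: 2.0 ** lfc for gid, lfc in truth.true_de.items()}
    base = pd.Series(
        np.concatenate([base_target, base_spike]), index=target_ids + spike_ids
    ).reindex([g.gene_id for g in annotation])
    is_target = pd.Series(
        {g.gene_id: g.organism == "target" for g in annotation}
    ).reindex(base.index)

    mu = np.empty((len(base), len(samples)))
    for j, s in enumerate(samples):
        cond = conditions[s]
        col = base.to_numpy(float).copy()
        if cond != control:
            for gid, e in effect.items():
                col[base.index.get_loc(gid)] *= e
        scale = truth.global_scale.get(cond, 1.0)
        col = np.where(is_target.to_numpy(bool), col * scale, col)
        mu[:, j] = col * depth[j]

    if config.nb_dispersion > 0:
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    df = pd.DataFrame(counts, index=base.index, columns=samples)
    df.index.name = "gene_id"
    return df, conditions


def simulate_gene_reads(
    annotation: GenomeAnnotation,
    weights: pd.Series,
    n_reads: int,
    config: SimulationConfig,
) -> AlignmentSet:
    """Uniquely mapping reads sampled from genes proportionally to ``weights``.

    Read strand is opposite the gene strand (reverse-stranded library); a
    small fraction of reads carries 3 mismatches to exercise the filters.
    """
    w = weights.reindex([g.gene_id for g in annotation]).fillna(0.0).to_numpy(float)
    if w.sum() <= 0:
        raise DataError("gene weights sum to zero")
    rng = _rng(config, _STREAM_GENE_READS)
    p = w / w.sum()
    gene_idx = rng.choice(len(annotation), size=n_reads, p=p)
    mismatch_choices = np.array([0, 1, 2, 3])
    mismatch_p = np.array([0.65, 0.2, 0.1, 0.05])
    reads: List[Read] = []
    for i, gi in enumerate(gene_idx):
        gene = annotation[gi]
        glen = gene.end - gene.start
        rlen = min(config.read_length, glen)
        start = gene.start + int(rng.integers(0, glen - rlen + 1))
        strand = "-" if gene.strand == "+" else "+"
        mism = int(rng.choice(mismatch_choices, p=mismatch_p))
        reads.append(
            Read(
                f"r{i:07d}",
                (AlignedLocation(
                    GenomicInterval(gene.chrom, start, start + rlen, strand),
                    mismatches=mism, is_primary=True),),
            )
        )
    return AlignmentSet(reads)


def simulate_multimap_reads(
    families: Mapping[str, Sequence[GenomicInterval]],
    abundances: Mapping[str, float],
    n_reads: int,
    config: SimulationConfig,
) -> AlignmentSet:
    """Reads from repeat families, each mapping to all genomic copies of its family.

    A family with k copies yields k-location reads at the same offset in every
    copy; one location is flagged primary; mismatches are drawn from {0,1,2}.
    """
    fams = list(families)
    if not fams:
        raise DataError("no repeat families given")
    ab = np.array([float(abundances[f]) for f in fams])
    if ab.sum() <= 0:
        raise DataError("total family abundance must be positive")
    if np.any(ab < 0):
        raise DataError("family abundances must be non-negative")
    rng = _rng(config, _STREAM_MULTIMAP)
    p = ab / ab.sum()
    fam_idx = rng.choice(len(fams), size=n_reads, p=p)
    mismatch_choices = np.array([0, 1, 2])
    mismatch_p = np.array([0.7, 0.2, 0.1])
    reads: List[Read] = []
    for i, fi in enumerate(fam_idx):
        copies = list(families[fams[fi]])
        min_len = min(len(c) for c in copies)
        rlen = min(config.read_length, min_len)
        offset = int(rng.integers(0, min_len - rlen + 1))
        primary = int(rng.integers(0, len(copies)))
        locs = tuple(
            AlignedLocation(
                GenomicInterval(c.chrom, c.start + offset, c.start + offset + rlen,
                                c.strand if c.strand != "." else "+"),
                mismatches=int(rng.choice(mismatch_choices, p=mismatch_p)),
                is_primary=(k == primary),
            )
            for k, c in enumerate(copies)
        )
        reads.append(Read(f"m{i:07d}", locs))
    return AlignmentSet(reads)


def simulate_sequences(
    annotation: GenomeAnnotation,
    a_rich_downstream: bool,
    config: SimulationConfig,
) -> Dict[str, str]:
    """Genome sequence: uniform base composition, optionally A-rich after each TES.

    With ``a_rich_downstream`` the ``a_rich_window`` bases downstream of every
    TES carry adenine on the sense strand with probability ``a_rich_prob``
    (the remaining mass spread evenly over the other bases).
    """
    rng = _rng(config, _STREAM_SEQUENCES)
    sizes = chrom_sizes(annotation, pad=config.a_rich_window + 400)
    letters = np.frombuffer(b"ACGT", dtype="S1")
    out: Dict[str, np.ndarray] = {
        chrom: rng.choice(letters, size=size) for chrom, size in sizes.items()
    }
    if a_rich_downstream:
        p = config.a_rich_prob
        rest = (1.0 - p) / 3.0
        # sense-strand A downstream of the TES: genomic A after plus-strand
        # genes, genomic T before minus-strand genes
        probs_plus = np.array([p, rest, rest, rest])    # A C G T
        probs_minus = np.array([rest, rest, rest, p])
        for gene in annotation:
            arr = out[gene.chrom]
            if gene.strand == "+":
                lo, hi = gene.end, min(gene.end + config.a_rich_window, arr.size)
                probs = probs_plus
            else:
                lo, hi = max(gene.start - config.a_rich_window, 0), gene.start
                probs = probs_minus
            if hi > lo:
                arr[lo:hi] = rng.choice(letters, size=hi - lo, p=probs)
    return {chrom: arr.tobytes().decode("ascii") for chrom, arr in out.items()}
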