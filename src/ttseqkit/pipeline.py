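"""End-to-end orchestration: simulate -> filter/count -> normalize -> test ->
proximity / metagene / TES bias, with a manifest and a stage log.

Every run is a pure function of its configuration: re-running with the same
config reproduces byte-identical result tables (wall-clock timings live only
in the log, never in result files).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .differential import bh_adjust, call_de, nb_test, overlap_fisher
from .errors import DataError, PipelineError
from .formats import (
    chrom_sizes,
    organism_of_genes,
    read_annotation,
    read_counts,
    read_intervals,
    write_alignments,
    write_annotation,
    write_bedgraph,
    write_counts,
    write_fasta,
    write_intervals,
)
from .metagene import coverage_from_alignments, metagene_profile, scale_regions_matrix
from .normalization import (
    condition_median_ratio,
    global_transcription_ratio,
    normalize_counts,
    organism_tallies,
    scale_coverage,
    size_factors,
)
from .proximity import proximity_association
from .readcount import count_reads_per_gene, filter_alignments
from .seqbias import base_fraction_window
from .simulate import (
    SimulationConfig,
    simulate_counts,
    simulate_gene_reads,
    simulate_genome,
    simulate_sequences,
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: Path
    seed: int = 0
    mode: str = "spikein"                  # normalization mode for DE
    fdr_threshold: float = 0.05
    fc_threshold: float = 1.5
    universe_size: Optional[int] = None    # None -> number of target genes
    max_mismatches: int = 2
    n_coverage_reads: int = 100_000
    sim: Optional[SimulationConfig] = None
    # optional pre-existing inputs (all four or none); when given, the
    # simulation stage is skipped and truth-dependent outputs are omitted
    annotation_path: Optional[Path] = None
    counts_path: Optional[Path] = None
    conditions_path: Optional[Path] = None
    sites_path: Optional[Path] = None

    def __post_init__(self) -> None:
        if self.fdr_threshold <= 0 or self.fc_threshold < 1:
            raise DataError("thresholds must be positive (fold >= 1)")
        if self.sim is None:
            self.sim = SimulationConfig(seed=self.seed)

    def validate(self) -> None:
        external = [self.annotation_path, self.counts_path,
                    self.conditions_path, self.sites_path]
        given = [p for p in external if p is not None]
        if given and len(given) != 4:
            raise DataError(
                "external inputs require annotation, counts, conditions and sites together"
            )
        for p in given:
            if not Path(p).exists():
                raise DataError(f"input path does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Run every stage, writing result TSVs, a log, and a manifest.

    Returns a dict with the key in-memory results for programmatic use.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []
    results: Dict[str, object] = {}
    outputs: Dict[str, Path] = {}

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                dt = time.perf_counter() - self_inner.t0
                log_lines.append(f"{name}\t{dt:.3f}s")
                return False

        return _Stage()

    sim = config.sim
    external = config.annotation_path is not None

    with stage("simulate"):
        if external:
            truth = None
            counts = read_counts(config.counts_path)
            cond_df = pd.read_csv(config.conditions_path, sep="\t", index_col=0)
            conditions = cond_df.iloc[:, 0]
            annotation = read_annotation(
                config.annotation_path,
                organism_of=_organism_mapping_from_counts(config, counts),
            )
            sites = read_intervals(config.sites_path)
        else:
            annotation, sites, truth = simulate_genome(sim)
            counts, conditions = simulate_counts(annotation, truth, sim)
            write_annotation(annotation, out / "annotation.tsv")
            write_intervals(sites, out / "sites.bed")
            write_counts(counts, out / "counts.tsv")
            conditions.rename("condition").to_csv(out / "conditions.tsv", sep="\t",
                                                  index_label="sample")
            (out / "truth.json").write_text(json.dumps(
                {
                    "true_de": truth.true_de,
                    "global_scale": truth.global_scale,
                    "site_linked": sorted(truth.site_linked),
                }, indent=1, sort_keys=True))
            for name in ("annotation.tsv", "sites.bed", "counts.tsv",
                         "conditions.tsv", "truth.json"):
                outputs[name] = out / name
        organism = organism_of_genes(annotation)

    with stage("sequence"):
        genome = simulate_sequences(annotation, a_rich_downstream=True, config=sim)
        write_fasta(genome, out / "genome.fa")
        outputs["genome.fa"] = out / "genome.fa"

    with stage("reads"):
        first_sample = counts.columns[0]
        reads = simulate_gene_reads(annotation, counts[first_sample],
                                    config.n_coverage_reads, sim)
        write_alignments(reads, out / "reads.tsv")
        outputs["reads.tsv"] = out / "reads.tsv"

    with stage("filter_count"):
        filtered = filter_alignments(reads, max_mismatches=config.max_mismatches)
        gene_counts = count_reads_per_gene(filtered, annotation,
                                           strandedness="reverse",
                                           allow_multioverlap=True)
        gene_counts.rename(first_sample).to_csv(out / "gene_counts.tsv", sep="\t",
                                                index_label="gene_id")
        outputs["gene_counts.tsv"] = out / "gene_counts.tsv"
        results["gene_counts"] = gene_counts

    with stage("normalize"):
        sf = {mode: size_factors(counts, organism, mode=mode)
              for mode in ("internal", "spikein")}
        factors = pd.DataFrame({m: s.factors for m, s in sf.items()})
        factors.to_csv(out / "size_factors.tsv", sep="\t", index_label="sample")
        normalized = normalize_counts(counts, sf[config.mode])
        write_counts(normalized, out / "normalized.tsv")
        target_tally, spike_tally = organism_tallies(counts, organism)
        ratios = global_transcription_ratio(target_tally, spike_tally)
        summary = condition_median_ratio(ratios, conditions)
        pd.DataFrame({"ratio": ratios, "condition": conditions}).to_csv(
            out / "global_ratio.tsv", sep="\t", index_label="sample")
        summary.rename("median_ratio").to_csv(out / "global_ratio_by_condition.tsv",
                                              sep="\t", index_label="condition")
        for name in ("size_factors.tsv", "normalized.tsv", "global_ratio.tsv",
                     "global_ratio_by_condition.tsv"):
            outputs[name] = out / name
        results["size_factors"] = sf
        results["global_ratio"] = ratios
        results["global_ratio_by_condition"] = summary

    with stage("de"):
        conds = list(dict.fromkeys(conditions))
        if len(conds) < 2:
            raise DataError("differential testing needs two conditions")
        control, treated = conds[0], conds[1]
        de = nb_test(counts, sf[config.mode], conditions, treated=treated,
                     control=control)
        de["fdr"] = bh_adjust(de["p_value"])
        de["status"] = call_de(de["log2_fc"], de["fdr"],
                               fdr_threshold=config.fdr_threshold,
                               fc_threshold=config.fc_threshold)
        de_out = de[["base_mean", "log2_fc", "p_value", "fdr", "status"]]
        de_out.to_csv(out / "de_results.tsv", sep="\t", index_label="gene_id",
                      float_format="%.6g")
        outputs["de_results.tsv"] = out / "de_results.tsv"
        results["de"] = de

    sig_genes = set(de.index[de["status"] != "ns"])

    if truth is not None:
        with stage("overlap"):
            n_target = int((organism == "target").sum())
            universe = config.universe_size or n_target
            ot = overlap_fisher(sig_genes, set(truth.true_de),
                                universe_size=universe)
            pd.DataFrame([dataclasses.asdict(ot)]).to_csv(
                out / "overlap.tsv", sep="\t", index=False)
            outputs["overlap.tsv"] = out / "overlap.tsv"
            results["overlap"] = ot

    with stage("proximity"):
        target_genes = [g for g in annotation if g.organism == "target"]
        sig_target = sig_genes & {g.gene_id for g in target_genes}
        if sig_target and len(sig_target) < len(target_genes):
            prox = proximity_association(sig_target, target_genes, sites,
                                         feature_set_name="sites")
            pd.DataFrame([dataclasses.asdict(prox)]).to_csv(
                out / "proximity.tsv", sep="\t", index=False, float_format="%.6g")
            outputs["proximity.tsv"] = out / "proximity.tsv"
            results["proximity"] = prox
        else:
            log_lines.append("proximity\tskipped (degenerate partition)")

    with stage("metagene"):
        sizes = chrom_sizes(annotation, pad=600)
        track = coverage_from_alignments(filtered, sizes, strand="both")
        scaled = scale_coverage(track, float(sf["spikein"].factors[first_sample]))
        write_bedgraph(scaled, out / "coverage.bedgraph")
        matrix = scale_regions_matrix(scaled, target_genes)
        matrix.to_csv(out / "metagene_matrix.tsv", sep="\t", index_label="gene_id",
                      float_format="%.6g")
        profile = metagene_profile(matrix)
        profile.to_csv(out / "metagene_profile.tsv", sep="\t", float_format="%.6g")
        for name in ("coverage.bedgraph", "metagene_matrix.tsv", "metagene_profile.tsv"):
            outputs[name] = out / name
        results["metagene_profile"] = profile

    with stage("tes_bias"):
        profile = base_fraction_window(genome, target_genes, base="A", window=100)
        profile.to_frame().to_csv(out / "tes_bias.tsv", sep="\t", float_format="%.6g")
        outputs["tes_bias.tsv"] = out / "tes_bias.tsv"
        results["tes_bias"] = profile

    manifest = {
        "package": "ttseqkit",
        "version": __version__,
        "config": _config_dict(config),
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    results["manifest"] = manifest
    return results


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, Path):
            d[k] = str(v)
    d["out_dir"] = str(config.out_dir)
    if d.get("sim") and isinstance(d["sim"].get("global_scale"), dict):
        d["sim"]["global_scale"] = dict(d["sim"]["global_scale"])
    return d


def _organism_mapping_from_counts(config: RunConfig, counts: pd.DataFrame) -> dict:
    """Chromosome -> organism map for external annotations: spike-in chromosomes
    are expected to carry a 'chrS'/'spike' name prefix, all others are target."""
    mapping = {}
    with Path(config.annotation_path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            ci = header.index("chrom")
        except ValueError:
            raise DataError("annotation file lacks a 'chrom' column")
        for line in fh:
            chrom = line.rstrip("\n").split("\t")[ci]
            mapping[chrom] = (
                "spikein" if chrom.startswith(("chrS", "spike")) else "target"
            )
    return mapping
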