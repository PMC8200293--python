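import numpy as np
import pandas as pd
import pytest

from ttseqkit.errors import DataError
from ttseqkit.formats import GenomicInterval, organism_of_genes, validate_annotation
from ttseqkit.normalization import organism_tallies
from ttseqkit.proximity import nearest_distance
from ttseqkit.readcount import expand_alignments, weighted_feature_counts
from ttseqkit.simulate import (
    SimulationConfig,
    simulate_counts,
    simulate_genome,
    simulate_multimap_reads,
    simulate_sequences,
)


class TestGenome:
    def test_same_seed_reproduces_everything(self, small_sim_config):
        a1, s1, t1 = simulate_genome(small_sim_config)
        a2, s2, t2 = simulate_genome(small_sim_config)
        assert a1 == a2 and s1 == s2
        assert t1.true_de == t2.true_de and t1.site_linked == t2.site_linked

    def test_genes_valid_and_non_overlapping(self, small_sim_config):
        annotation, _, _ = simulate_genome(small_sim_config)
        validate_annotation(annotation)
        by_chrom = {}
        for g in annotation:
            by_chrom.setdefault(g.chrom, []).append(g)
        for genes in by_chrom.values():
            genes = sorted(genes, key=lambda g: g.start)
            for a, b in zip(genes, genes[1:]):
                assert a.end <= b.start

    def test_full_enrichment_places_every_de_gene_near_a_site(self):
        cfg = SimulationConfig(n_target_genes=200, n_spikein_genes=40,
                               n_feature_sites=30, proximity_enrichment=1.0,
                               de_fraction=0.1, seed=2)
        annotation, sites, truth = simulate_genome(cfg)
        lookup = {g.gene_id: g.interval for g in annotation}
        d = nearest_distance([lookup[g] for g in truth.true_de], sites)
        assert np.nanmax(d) <= cfg.proximity_distance

    def test_zero_enrichment_gives_null_like_ratios(self):
        """DE genes placed like any other gene: the median-distance ratio
        concentrates around 1 across seeds."""
        ratios = []
        for seed in range(20):
            cfg = SimulationConfig(n_target_genes=400, n_spikein_genes=40,
                                   n_feature_sites=50, proximity_enrichment=0.0,
                                   de_fraction=0.1, seed=seed)
            annotation, sites, truth = simulate_genome(cfg)
            target = [g for g in annotation if g.organism == "target"]
            d = nearest_distance([g.interval for g in target], sites)
            sig = np.array([g.gene_id in truth.true_de for g in target])
            ratios.append(np.median(d[sig]) / np.median(d[~sig]))
        assert 0.8 <= float(np.median(ratios)) <= 1.25

    def test_capacity_error(self):
        cfg = SimulationConfig(n_target_genes=500, n_spikein_genes=10,
                               chrom_length=10_000, n_target_chroms=1, seed=1)
        with pytest.raises(DataError, match="capacity"):
            simulate_genome(cfg)

    def test_more_linked_genes_than_sites_rejected(self):
        cfg = SimulationConfig(n_target_genes=500, n_spikein_genes=10,
                               n_feature_sites=5, de_fraction=0.5,
                               proximity_enrichment=1.0, seed=1)
        with pytest.raises(DataError, match="site"):
            simulate_genome(cfg)


class TestCounts:
    def test_deterministic_given_seed(self, small_sim_config):
        annotation, _, truth = simulate_genome(small_sim_config)
        c1, _ = simulate_counts(annotation, truth, small_sim_config)
        c2, _ = simulate_counts(annotation, truth, small_sim_config)
        assert c1.equals(c2)

    def test_null_configuration_has_no_expected_differences(self):
        cfg = SimulationConfig(n_target_genes=1000, n_spikein_genes=100,
                               de_fraction=0.0, depth_log_sd=0.0, seed=9)
        annotation, _, truth = simulate_genome(cfg)
        counts, cond = simulate_counts(annotation, truth, cfg)
        ctl = [s for s in counts if cond[s] == "control"]
        trt = [s for s in counts if cond[s] == "treated"]
        ratio = counts[trt].mean(axis=1).sum() / counts[ctl].mean(axis=1).sum()
        assert ratio == pytest.approx(1.0, abs=0.03)

    def test_spike_mass_fraction_near_ten_percent(self):
        cfg = SimulationConfig(seed=13)  # defaults: 10% spike mass
        annotation, _, truth = simulate_genome(cfg)
        counts, _ = simulate_counts(annotation, truth, cfg)
        target, spike = organism_tallies(counts, organism_of_genes(annotation))
        frac = spike / (spike + target)
        assert ((frac - 0.10).abs() < 0.02).all()

    def test_zero_dispersion_is_poisson_like(self):
        """With the NB dispersion at 0 the per-gene variance/mean ratio across
        replicates concentrates at 1."""
        cfg = SimulationConfig(n_target_genes=2000, n_spikein_genes=100,
                               n_samples_per_condition=8, nb_dispersion=0.0,
                               de_fraction=0.0, depth_log_sd=0.0,
                               global_scale={"control": 1.0}, seed=4)
        annotation, _, truth = simulate_genome(cfg)
        counts, _ = simulate_counts(annotation, truth, cfg)
        m = counts.mean(axis=1)
        v = counts.var(axis=1, ddof=1)
        keep = m > 10
        assert float((v[keep] / m[keep]).mean()) == pytest.approx(1.0, abs=0.1)

    def test_empty_or_spikeless_annotation_rejected(self, small_sim_config):
        annotation, _, truth = simulate_genome(small_sim_config)
        with pytest.raises(DataError):
            simulate_counts([], truth, small_sim_config)
        target_only = [g for g in annotation if g.organism == "target"]
        with pytest.raises(DataError, match="spike"):
            simulate_counts(target_only, truth, small_sim_config)


class TestMultimapReads:
    FAMILIES = {
        "Ty1": [GenomicInterval("chrI", 1000, 7000),
                GenomicInterval("chrII", 5000, 11_000),
                GenomicInterval("chrIII", 2000, 8000)],
        "Ty2": [GenomicInterval("chrI", 20_000, 26_000)],
    }

    def test_copy_number_sets_location_count(self, small_sim_config):
        reads = simulate_multimap_reads(self.FAMILIES, {"Ty1": 1.0, "Ty2": 1.0},
                                        200, small_sim_config)
        for read in reads:
            assert len(read.locations) in (1, 3)
            assert sum(l.is_primary for l in read.locations) == 1

    def test_single_copy_family_is_uniquely_mapped(self, small_sim_config):
        reads = simulate_multimap_reads({"Ty2": self.FAMILIES["Ty2"]}, {"Ty2": 2.0},
                                        100, small_sim_config)
        assert all(len(r.locations) == 1 for r in reads)

    def test_weighted_counts_recover_abundance_ratio(self, small_sim_config):
        reads = simulate_multimap_reads(self.FAMILIES, {"Ty1": 2.0, "Ty2": 1.0},
                                        10_000, small_sim_config)
        table = expand_alignments(reads)
        features = [
            GenomicInterval(c.chrom, c.start, c.end, ".", f"{fam}_{i}")
            for fam, copies in self.FAMILIES.items()
            for i, c in enumerate(copies)
        ]
        counts = weighted_feature_counts(table, features)
        ty1 = counts.loc[[f for f in counts.index if f.startswith("Ty1")],
                         "raw_weighted_count"].sum()
        ty2 = counts.loc[[f for f in counts.index if f.startswith("Ty2")],
                         "raw_weighted_count"].sum()
        assert ty1 / ty2 == pytest.approx(2.0, rel=0.05)

    def test_zero_abundance_rejected(self, small_sim_config):
        with pytest.raises(DataError):
            simulate_multimap_reads(self.FAMILIES, {"Ty1": 0.0, "Ty2": 0.0},
                                    10, small_sim_config)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"de_fraction": 1.5},
            {"spike_mass_fraction": -0.1},
            {"global_scale": {"control": 0.0}},
            {"nb_dispersion": -1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(DataError):
            SimulationConfig(**kwargs)
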