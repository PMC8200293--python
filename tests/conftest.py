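import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from ttseqkit.formats import GeneRecord, GenomicInterval
from ttseqkit.simulate import SimulationConfig


def make_gene(gene_id, chrom, start, end, strand="+", organism="target", **kw):
    return GeneRecord(gene_id, GenomicInterval(chrom, start, end, strand), organism, **kw)


@pytest.fixture
def toy_annotation():
    """Three target genes on two chromosomes plus one spike-in gene."""
    return [
        make_gene("g1", "chrI", 100, 600, "+"),
        make_gene("g2", "chrI", 1000, 2000, "-"),
        make_gene("g3", "chrII", 50, 950, "+"),
        make_gene("s1", "chrS1", 10, 510, "+", organism="spikein"),
    ]


@pytest.fixture
def small_sim_config():
    """A fast two-condition design with no global shift."""
    return SimulationConfig(
        n_target_genes=300,
        n_spikein_genes=80,
        n_feature_sites=40,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
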