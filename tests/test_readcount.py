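import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import weighted_counts_bruteforce
from ttseqkit.errors import DataError
from ttseqkit.formats import (
    AlignedLocation,
    AlignmentSet,
    GenomicInterval,
    Read,
)
from ttseqkit.readcount import (
    count_reads_per_gene,
    expand_alignments,
    filter_alignments,
    weighted_feature_counts,
)


def make_read(read_id, locs, primary_idx=0):
    return Read(
        read_id,
        tuple(
            AlignedLocation(
                GenomicInterval(chrom, start, end, strand),
                mismatches=mism,
                is_primary=(i == primary_idx),
            )
            for i, (chrom, start, end, strand, mism) in enumerate(locs)
        ),
    )


class TestFilter:
    def test_mismatch_filter_keeps_fewer_than_three(self):
        aset = AlignmentSet([
            make_read("r1", [("chrI", 10, 86, "+", 0), ("chrII", 10, 86, "+", 3)])
        ])
        out = filter_alignments(aset, max_mismatches=2, require_unique=False,
                                require_primary=False)
        assert len(out.reads[0].locations) == 1
        assert out.reads[0].locations[0].mismatches == 0

    def test_require_unique_drops_multimappers(self):
        aset = AlignmentSet([
            make_read("r1", [("chrI", 10, 86, "+", 0), ("chrII", 10, 86, "+", 1)]),
            make_read("r2", [("chrI", 200, 276, "-", 1)]),
        ])
        out = filter_alignments(aset, require_unique=True, require_primary=False)
        assert [r.read_id for r in out] == ["r2"]

    def test_keep_best_retains_minimum_mismatch_ties(self):
        aset = AlignmentSet([
            make_read("r1", [("chrI", 10, 86, "+", 1), ("chrII", 10, 86, "+", 1),
                             ("chrIII", 10, 86, "+", 2)])
        ])
        out = filter_alignments(aset, require_unique=False, require_primary=False,
                                keep_best=True)
        assert len(out.reads[0].locations) == 2
        assert all(l.mismatches == 1 for l in out.reads[0].locations)

    def test_empty_input_gives_empty_output(self):
        assert filter_alignments(AlignmentSet([])).n_reads == 0


class TestGeneCounting:
    def test_reverse_strandedness_rule(self, toy_annotation):
        # g1 is a plus-strand gene: reverse-stranded counting takes minus reads
        minus_read = AlignmentSet([make_read("r1", [("chrI", 150, 226, "-", 0)])])
        plus_read = AlignmentSet([make_read("r2", [("chrI", 150, 226, "+", 0)])])
        c_minus = count_reads_per_gene(minus_read, toy_annotation, "reverse")
        c_plus = count_reads_per_gene(plus_read, toy_annotation, "reverse")
        assert c_minus["g1"] == 1
        assert c_plus["g1"] == 0

    def test_multioverlap_increments_every_gene(self):
        genes = [
            GenomicInterval("chrI", 0, 100, "+"),
            GenomicInterval("chrI", 80, 200, "+"),
        ]
        from ttseqkit.formats import GeneRecord

        ann = [GeneRecord(f"g{i}", iv) for i, iv in enumerate(genes)]
        aset = AlignmentSet([make_read("r1", [("chrI", 70, 120, "-", 0)])])
        with_o = count_reads_per_gene(aset, ann, "reverse", allow_multioverlap=True)
        without = count_reads_per_gene(aset, ann, "reverse", allow_multioverlap=False)
        assert with_o.sum() == 2 and (with_o == 1).all()
        assert without.sum() == 0  # ambiguous, discarded

    def test_multilocation_read_is_an_error(self, toy_annotation):
        aset = AlignmentSet([
            make_read("r1", [("chrI", 10, 86, "+", 0), ("chrII", 10, 86, "+", 0)])
        ])
        with pytest.raises(DataError, match="filter"):
            count_reads_per_gene(aset, toy_annotation)

    def test_agrees_with_bruteforce_enumeration(self, toy_annotation, rng):
        reads = []
        for i in range(300):
            chrom = rng.choice(["chrI", "chrII"])
            start = int(rng.integers(0, 2500))
            strand = rng.choice(["+", "-"])
            reads.append(make_read(f"r{i}", [(chrom, start, start + 76, strand, 0)]))
        aset = AlignmentSet(reads)
        got = count_reads_per_gene(aset, toy_annotation, "reverse")
        expected = {g.gene_id: 0 for g in toy_annotation}
        for read in reads:
            iv = read.locations[0].interval
            for g in toy_annotation:
                if (g.chrom == iv.chrom and g.start < iv.end and iv.start < g.end
                        and g.strand != iv.strand):
                    expected[g.gene_id] += 1
        assert got.to_dict() == expected


class TestExpansion:
    def test_weights_are_one_over_k(self):
        aset = AlignmentSet([
            make_read("r1", [("chrI", 0, 76, "+", 0), ("chrI", 100, 176, "+", 0),
                             ("chrII", 0, 76, "+", 0)]),
            make_read("r2", [("chrI", 500, 576, "-", 1)]),
        ])
        table = expand_alignments(aset)
        assert len(table) == 4
        r1 = table[table.read_id == "r1"]
        assert np.allclose(r1.weight, 1 / 3)
        assert (r1.n_locations == 3).all()
        assert table[table.read_id == "r2"].weight.iloc[0] == 1.0

    @settings(derandomize=True, max_examples=50)
    @given(ks=st.lists(st.integers(min_value=1, max_value=10), min_size=1, max_size=30))
    def test_total_weight_equals_read_count(self, ks):
        reads = [
            make_read(
                f"r{i}",
                [("chrI", 100 * j, 100 * j + 50, "+", 0) for j in range(k)],
            )
            for i, k in enumerate(ks)
        ]
        table = expand_alignments(AlignmentSet(reads))
        assert table.weight.sum() == pytest.approx(len(ks), abs=1e-9)


class TestWeightedCounts:
    FEATURE = [GenomicInterval("chrI", 0, 1000, ".", "F")]

    def test_both_locations_inside_feature_sum_to_one(self):
        aset = AlignmentSet([
            make_read("r1", [("chrI", 10, 86, "+", 0), ("chrI", 500, 576, "+", 0)])
        ])
        out = weighted_feature_counts(expand_alignments(aset), self.FEATURE)
        assert out.loc["F", "raw_weighted_count"] == pytest.approx(1.0)

    def test_half_weight_when_one_location_outside(self):
        aset = AlignmentSet([
            make_read("r1", [("chrI", 10, 86, "+", 0), ("chrII", 500, 576, "+", 0)])
        ])
        out = weighted_feature_counts(expand_alignments(aset), self.FEATURE)
        assert out.loc["F", "raw_weighted_count"] == pytest.approx(0.5)

    def test_per_million_arithmetic(self):
        aset = AlignmentSet([
            make_read(f"r{i}", [("chrI", 10, 86, "+", 0)]) for i in range(3)
        ])
        out = weighted_feature_counts(expand_alignments(aset), self.FEATURE,
                                      total_mapped_reads=1_500_000)
        assert out.loc["F", "per_million"] == pytest.approx(2.0)

    def test_total_smaller_than_read_count_rejected(self):
        aset = AlignmentSet([
            make_read(f"r{i}", [("chrI", 10, 86, "+", 0)]) for i in range(5)
        ])
        with pytest.raises(DataError):
            weighted_feature_counts(expand_alignments(aset), self.FEATURE,
                                    total_mapped_reads=3)

    def test_agrees_with_bruteforce_oracle(self, rng):
        features = []
        for i in range(20):
            start = int(rng.integers(0, 5000))
            features.append(
                GenomicInterval(rng.choice(["chrI", "chrII"]), start,
                                start + int(rng.integers(50, 400)), ".", f"f{i}")
            )
        reads, plain = [], []
        for i in range(100):
            k = int(rng.integers(1, 5))
            locs = []
            for j in range(k):
                chrom = rng.choice(["chrI", "chrII"])
                start = int(rng.integers(0, 5200))
                locs.append((chrom, start, start + 76, "+", 0))
            reads.append(make_read(f"r{i}", locs))
            plain.append((f"r{i}", [(c, s, e) for c, s, e, _, _ in locs]))
        got = weighted_feature_counts(expand_alignments(AlignmentSet(reads)), features)
        expected = weighted_counts_bruteforce(plain, features)
        assert np.allclose(got["raw_weighted_count"].to_numpy(), expected, atol=1e-12)
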