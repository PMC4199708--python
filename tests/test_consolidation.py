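"""Repeat deflation: tandem classification, IR filtering, family clustering."""

import numpy as np
import pytest

import plastomics as pl
from plastomics._seqcodes import revcomp
from plastomics.consolidate import RepeatInstance, _merge_same_locus

from conftest import random_dna


def _pair(pos1, pos2, length=30, orientation="direct", mism=0, seq="A" * 30):
    return pl.RepeatPair(
        pos1=pos1, pos2=pos2, length=length, orientation=orientation,
        mismatches=mism, seq1=seq[:length], seq2=seq[:length],
    )


class TestClassifyTandem:
    def test_gap_just_under_threshold(self):
        assert pl.classify_tandem(_pair(0, 1029)) == "tandem"  # 999 bp gap

    def test_gap_just_over_threshold(self):
        assert pl.classify_tandem(_pair(0, 1031)) == "dispersed"  # 1001 bp gap

    def test_gap_exactly_threshold(self):
        assert pl.classify_tandem(_pair(0, 1030)) == "dispersed"  # 1000 bp gap

    def test_overlapping_copies_are_tandem(self):
        assert pl.classify_tandem(_pair(0, 10)) == "tandem"


class TestIRFilter:
    @pytest.fixture()
    def part(self):
        return pl.QuadripartitePartition(
            lsc=pl.Interval(0, 10000),
            ira=pl.Interval(10000, 13000),
            ssc=pl.Interval(13000, 15000),
            irb=pl.Interval(15000, 18000),
            seq_len=18000,
        )

    def test_both_copies_in_ir_removed(self, part):
        pairs = [_pair(10100, 17870, orientation="palindromic")]
        assert pl.filter_ir_duplicates(pairs, part) == []

    def test_copy_in_lsc_retained(self, part):
        pairs = [_pair(500, 10100)]
        assert pl.filter_ir_duplicates(pairs, part) == pairs

    def test_copy_straddling_ir_border_retained(self, part):
        pairs = [_pair(9990, 17000)]  # first copy spans LSC/IRa junction
        assert pl.filter_ir_duplicates(pairs, part) == pairs

    def test_synthetic_truth_expectation(self):
        cfg = pl.GeneratorConfig(
            lsc_len=12000, ssc_len=2500, ir_len=3000, seed=31,
            planted_repeats=(
                pl.PlantSpec("sc", repeat_len=35, n_copies=2, region="LSC"),
                pl.PlantSpec("ir", repeat_len=35, n_copies=2, region="IR"),
            ),
        )
        rec, _, truth = pl.generate_plastome(cfg)
        part = pl.true_partition(truth)
        pairs = pl.find_maximal_repeats(rec)
        dispersed = [p for p in pairs if pl.classify_tandem(p) == "dispersed"]
        kept = pl.filter_ir_duplicates(dispersed, part)
        # survivors: exactly the pairs touching the LSC family's two loci
        sc = [i for i in truth.instances if i.family_id == "sc"]
        assert len(kept) == 1
        assert kept[0].pos1 <= sc[0].start and kept[0].end1 >= sc[0].start
        # everything IR-only (planted ir family, its mirrors, the IR itself) is gone
        for p in kept:
            for iv in (pl.Interval(p.pos1, p.end1), pl.Interval(p.pos2, p.end2)):
                in_ir = iv.overlap_len(part.ira, 20500) + iv.overlap_len(part.irb, 20500)
                assert in_ir < len(iv)


class TestClusterFamilies:
    def test_eleven_dispersed_locations_one_family(self):
        cfg = pl.GeneratorConfig(
            lsc_len=20000, ssc_len=3000, ir_len=3000, seed=41,
            planted_repeats=(
                pl.PlantSpec("r1", repeat_len=37, n_copies=11, region="LSC"),
            ),
        )
        rec, _, truth = pl.generate_plastome(cfg)
        pairs = pl.find_maximal_repeats(rec)
        part = pl.true_partition(truth)
        fams, summary = pl.consolidate(pairs, part)
        assert len(fams) == 1
        assert fams[0].n_locations == 11
        assert summary.dispersed_unique_sequences == 1
        assert summary.dispersed_unique_locations == 11

    def test_same_locus_lengths_merge(self):
        a = RepeatInstance(100, 30, "ACGTACGTACGTACGTACGTACGTACGTAC")
        b = RepeatInstance(100, 36, "ACGTACGTACGTACGTACGTACGTACGTACGTACGT")
        merged = _merge_same_locus(sorted([a, b], key=lambda r: (r.position, r.length)))
        assert merged == [b]  # longest survives

    def test_dissimilar_families_stay_apart(self, rng):
        s1 = random_dna(rng, 35)
        s2 = random_dna(rng, 35)
        instances = [
            RepeatInstance(100, 35, s1), RepeatInstance(5000, 35, s1),
            RepeatInstance(10000, 35, s2), RepeatInstance(15000, 35, s2),
        ]
        fams = pl.cluster_families(instances)
        assert len(fams) == 2
        assert all(f.n_locations == 2 for f in fams)

    def test_revcomp_members_cluster_together(self, rng):
        s = random_dna(rng, 35)
        instances = [RepeatInstance(100, 35, s), RepeatInstance(5000, 35, revcomp(s))]
        fams = pl.cluster_families(instances)
        assert len(fams) == 1

    def test_idempotent(self, rng):
        s = random_dna(rng, 35)
        instances = [
            RepeatInstance(100, 35, s),
            RepeatInstance(5000, 35, s),
            RepeatInstance(9000, 35, s),
        ]
        once = pl.cluster_families(instances)
        again = pl.cluster_families(
            [m for f in once for m in f.members]
        )
        assert [(f.family_id, f.n_locations, f.representative, f.members) for f in once] == [
            (f.family_id, f.n_locations, f.representative, f.members) for f in again
        ]

    def test_order_invariance(self, rng):
        s1, s2 = random_dna(rng, 35), random_dna(rng, 40)
        instances = [
            RepeatInstance(100, 35, s1), RepeatInstance(3000, 35, s1),
            RepeatInstance(7000, 40, s2), RepeatInstance(12000, 40, s2),
        ]
        fwd = pl.cluster_families(instances)
        rev = pl.cluster_families(list(reversed(instances)))
        assert [(f.family_id, [m.position for m in f.members]) for f in fwd] == [
            (f.family_id, [m.position for m in f.members]) for f in rev
        ]

    def test_consensus_marks_ties_with_iupac(self):
        s1 = "AAAAAAAAAA"
        s2 = "AAAACAAAAA"
        fams = pl.cluster_families(
            [RepeatInstance(0, 10, s1), RepeatInstance(5000, 10, s2)],
            identity_threshold=0.9,
        )
        assert len(fams) == 1
        assert fams[0].representative[4] == "M"  # A/C tie


class TestAnnotateLocations:
    def _families(self, rng):
        s = random_dna(rng, 35)
        return pl.cluster_families(
            [RepeatInstance(100, 35, s), RepeatInstance(5000, 35, s)]
        )

    def test_coding_flags(self, rng):
        fams = self._families(rng)
        feats = pl.FeatureSet(
            [
                pl.Feature("geneA", pl.Interval(90, 200), type="CDS"),
                pl.Feature("geneB", pl.Interval(5034, 5200), type="gene"),
            ]
        )
        annotated = pl.annotate_locations(fams, feats)
        assert annotated[0].coding_flags == [True, True]  # 1 bp straddle counts

    def test_intergenic_member_false(self, rng):
        fams = self._families(rng)
        feats = pl.FeatureSet([pl.Feature("geneA", pl.Interval(600, 900), type="gene")])
        annotated = pl.annotate_locations(fams, feats)
        assert annotated[0].coding_flags == [False, False]


class TestSummarize:
    def test_four_location_family_combinatorics(self):
        cfg = pl.GeneratorConfig(
            lsc_len=10000, ssc_len=2000, ir_len=2500, seed=51,
            planted_repeats=(
                pl.PlantSpec("f", repeat_len=35, n_copies=4, region="LSC"),
            ),
        )
        rec, _, truth = pl.generate_plastome(cfg)
        pairs = pl.find_maximal_repeats(rec)
        part = pl.true_partition(truth)
        fams, summary = pl.consolidate(pairs, part)
        # C(4,2) pairs from the family + the IRa/IRb pair itself
        assert summary.raw_pair_count == 6 + 1
        assert summary.dispersed_unique_sequences == 1
        assert summary.dispersed_unique_locations == 4

    def test_empty_genome_zero_summary(self):
        cfg = pl.GeneratorConfig(lsc_len=8000, ssc_len=1500, ir_len=2000, seed=52)
        rec, _, truth = pl.generate_plastome(cfg)
        pairs = pl.find_maximal_repeats(rec)
        part = pl.true_partition(truth)
        fams, summary = pl.consolidate(pairs, part)
        assert fams == []
        # only the quadripartite IR pair itself is present, and it is filtered
        assert summary.raw_pair_count == 1
        assert summary.dispersed_unique_sequences == 0
        assert summary.dispersed_unique_locations == 0

    def test_mixed_scenario_matches_truth(self):
        cfg = pl.GeneratorConfig(
            lsc_len=14000, ssc_len=2500, ir_len=3000, seed=53,
            planted_repeats=(
                pl.PlantSpec("a", repeat_len=35, n_copies=3, region="LSC"),
                pl.PlantSpec("b", repeat_len=40, n_copies=2, region="SSC",
                             orientation="palindromic"),
                pl.PlantSpec("t", repeat_len=32, n_copies=3, placement="tandem",
                             region="LSC"),
                pl.PlantSpec("ir", repeat_len=35, n_copies=2, region="IR"),
            ),
        )
        rec, feats, truth = pl.generate_plastome(cfg)
        pairs = pl.find_maximal_repeats(rec)
        part = pl.true_partition(truth)
        fams, summary = pl.consolidate(pairs, part)
        # families: a (3 loci) and b (2 loci); tandem array classified out;
        # IR-region family and the IR pair filtered
        assert summary.dispersed_unique_sequences == 2
        assert summary.dispersed_unique_locations == 5
        assert summary.tandem_count == 3  # C(3,2) overlapping-extension pairs
        by_locs = sorted(f.n_locations for f in fams)
        assert by_locs == [2, 3]

    def test_pair_order_invariance(self):
        cfg = pl.GeneratorConfig(
            lsc_len=10000, ssc_len=2000, ir_len=2500, seed=54,
            planted_repeats=(
                pl.PlantSpec("f", repeat_len=35, n_copies=3, region="LSC"),
            ),
        )
        rec, _, truth = pl.generate_plastome(cfg)
        pairs = pl.find_maximal_repeats(rec)
        part = pl.true_partition(truth)
        r = np.random.default_rng(0)
        shuffled = list(pairs)
        r.shuffle(shuffled)
        assert pl.consolidate(pairs, part)[1] == pl.consolidate(shuffled, part)[1]
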