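"""IR detection, GC content, border-gene extents."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import plastomics as pl
from plastomics._seqcodes import revcomp
from plastomics.structure import rotate_features

from conftest import oracle_exact_palindromic_runs, random_dna


def _quadripartite(rng, lsc, ir, ssc) -> str:
    """Hand-built LSC+IRa+SSC+IRb string, independent of the generator.

    The four bases delimiting the IR junctions are pinned to A so a
    chance complement cannot extend the true maximal IR past ``ir``.
    """
    a = list(random_dna(rng, lsc))
    b = random_dna(rng, ir)
    c = list(random_dna(rng, ssc))
    a[0], a[-1] = "A", "A"
    c[0], c[-1] = "A", "A"
    return "".join(a) + b + "".join(c) + revcomp(b)


class TestDetection:
    def test_matches_generator_truth(self):
        cfg = pl.GeneratorConfig(lsc_len=10000, ssc_len=2000, ir_len=3000, seed=3)
        rec, _, truth = pl.generate_plastome(cfg)
        part = pl.detect_inverted_repeat(rec, min_ir_len=1000)
        assert part.ir_len == 3000
        assert (part.lsc_len, part.ssc_len) == (10000, 2000)
        tp = pl.true_partition(truth)
        assert (part.lsc, part.ira, part.ssc, part.irb) == (tp.lsc, tp.ira, tp.ssc, tp.irb)

    def test_no_ir_in_random_sequence(self, rng):
        rec = pl.PlastomeRecord("r", random_dna(rng, 30000), circular=False)
        with pytest.raises(pl.IRNotFoundError):
            pl.detect_inverted_repeat(rec, min_ir_len=1000)

    def test_sequence_too_short(self, rng):
        rec = pl.PlastomeRecord("r", random_dna(rng, 1000))
        with pytest.raises(ValueError):
            pl.detect_inverted_repeat(rec, min_ir_len=1000)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_rotation_invariance_of_lengths(self, seed):
        cfg = pl.GeneratorConfig(lsc_len=8000, ssc_len=1500, ir_len=2500, seed=seed)
        rec, _, _ = pl.generate_plastome(cfg)
        base = pl.detect_inverted_repeat(rec, min_ir_len=1000)
        r = np.random.default_rng(seed)
        for offset in r.integers(1, len(rec), size=4):
            rot = pl.detect_inverted_repeat(rec.rotated(int(offset)), min_ir_len=1000)
            assert (rot.ir_len, rot.lsc_len, rot.ssc_len) == (
                base.ir_len,
                base.lsc_len,
                base.ssc_len,
            )

    def test_origin_spanning_ir_found_on_circular_record(self, rng):
        seq = _quadripartite(rng, 3000, 800, 600)
        # rotate so IRb straddles the linearization origin
        rec = pl.PlastomeRecord("w", seq, circular=True).rotated(len(seq) - 400)
        part = pl.detect_inverted_repeat(rec, min_ir_len=500)
        assert part.ir_len == 800
        assert (part.lsc_len, part.ssc_len) == (3000, 600)

    @pytest.mark.parametrize("seed", [21, 22, 23, 24])
    def test_agrees_with_bruteforce_on_small_sequences(self, seed):
        r = np.random.default_rng(seed)
        lsc, ir, ssc = (
            int(r.integers(1500, 2500)),
            int(r.integers(200, 500)),
            int(r.integers(300, 800)),
        )
        seq = _quadripartite(r, lsc, ir, ssc)
        runs = oracle_exact_palindromic_runs(seq, 150)
        disjoint = [t for t in runs if t[0] + t[2] <= t[1]]
        exp_len = max(t[2] for t in disjoint)
        part = pl.detect_inverted_repeat(
            pl.PlastomeRecord("s", seq, circular=False), min_ir_len=150
        )
        # chance complements at the junctions can stretch the true
        # maximal run a base or two past the planted ir length
        assert part.ir_len == exp_len >= ir
        assert part.lsc_len + part.ssc_len + 2 * part.ir_len == len(seq)

    def test_partition_covers_sequence(self):
        cfg = pl.GeneratorConfig(lsc_len=6000, ssc_len=1200, ir_len=2000, seed=9)
        rec, _, _ = pl.generate_plastome(cfg)
        part = pl.detect_inverted_repeat(rec, min_ir_len=800)
        assert part.lsc_len + part.ssc_len + 2 * part.ir_len == len(rec)

    def test_irb_is_revcomp_of_ira(self):
        cfg = pl.GeneratorConfig(lsc_len=6000, ssc_len=1200, ir_len=2000, seed=10)
        rec, _, _ = pl.generate_plastome(cfg)
        part = pl.detect_inverted_repeat(rec, min_ir_len=800)
        ira = rec.sequence[part.ira.start : part.ira.end]
        irb = rec.sequence[part.irb.start : part.irb.end]
        assert irb == revcomp(ira)


class TestGCContent:
    def test_half_gc(self):
        assert pl.gc_content("ATGC") == 0.5

    def test_no_gc(self):
        assert pl.gc_content("AAAA") == 0.0

    def test_ambiguity_codes_excluded(self):
        assert pl.gc_content("GGNNRY") == 1.0  # only the two Gs count

    def test_all_ambiguous_is_error(self):
        with pytest.raises(ValueError):
            pl.gc_content("NNNN")

    def test_rounding_for_table_parity(self):
        assert pl.gc_content("G" * 353 + "A" * 647, digits=3) == 0.353

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 2**32 - 1), st.floats(0.1, 0.9))
    def test_gc_plus_at_is_one(self, seed, gc):
        r = np.random.default_rng(seed)
        seq = random_dna(r, 500, gc=gc)
        assert pl.gc_content(seq) + pl.at_content(seq) == pytest.approx(1.0)


class TestBorderGenes:
    def _parts(self):
        cfg = pl.GeneratorConfig(
            lsc_len=8000,
            ssc_len=1500,
            ir_len=2500,
            seed=14,
            border_genes=(
                pl.BorderGeneSpec("ycf1", duplicated_extent=463, total_len=2000),
                pl.BorderGeneSpec("rps19", duplicated_extent=61, total_len=280),
            ),
        )
        rec, feats, truth = pl.generate_plastome(cfg)
        part = pl.detect_inverted_repeat(rec, min_ir_len=1000)
        return rec, feats, part

    def test_gene_fully_inside_ir(self):
        _, _, part = self._parts()
        iv = pl.Interval(part.ira.start + 10, part.ira.start + 1510)
        assert pl.ir_overlap_extent(iv, part) == 1500

    def test_duplicated_extents_match_spec(self):
        rec, feats, part = self._parts()
        assert pl.ir_overlap_extent(feats.get("ycf1"), part) == 463
        assert pl.ir_overlap_extent(feats.get("rps19"), part) == 61

    def test_zero_overlap(self):
        _, _, part = self._parts()
        assert pl.ir_overlap_extent(pl.Interval(0, 100), part) == 0

    def test_origin_aware_overlap(self):
        _, _, part = self._parts()
        n = part.seq_len
        # wrapped interval reaching 50 bp into the start of the sequence
        iv = pl.Interval(n - 30, n + 50)
        # IRb ends at n, so the wrapped tail is outside the IRs
        assert pl.ir_overlap_extent(iv, part) == 30

    def test_structure_summary_row(self):
        rec, feats, part = self._parts()
        row = pl.structure_summary(rec, feats, ("ycf1", "rps19"), min_ir_len=1000)
        assert row["total"] == len(rec)
        assert row["lsc"] == 8000 and row["ssc"] == 1500 and row["ir"] == 2500
        assert row["ycf1_in_ir"] == 463
        assert row["rps19_in_ir"] == 61
        assert row["gc"] == round(pl.gc_content(rec), 3)


class TestRotationHelpers:
    def test_canonical_rotation_prefers_trnh(self):
        cfg = pl.GeneratorConfig(lsc_len=6000, ssc_len=1200, ir_len=2000, seed=15)
        rec, _, _ = pl.generate_plastome(cfg)
        rec = rec.rotated(1234)
        part = pl.detect_inverted_repeat(rec, min_ir_len=800)
        feats = pl.FeatureSet([pl.Feature("trnH", pl.Interval(500, 570))])
        rot, offset = pl.canonical_rotation(rec, part, feats)
        assert offset == 500
        assert rot.sequence == rec.sequence[500:] + rec.sequence[:500]
        # without trnH, the rotation starts at the detected LSC
        rot2, offset2 = pl.canonical_rotation(rec, part)
        assert offset2 == part.lsc.start % len(rec)
        shifted = rotate_features(feats, offset2, len(rec))
        assert len(shifted.get("trnH").interval) == 70

    def test_rotated_record_roundtrip(self, rng):
        rec = pl.PlastomeRecord("r", random_dna(rng, 100))
        assert rec.rotated(40).rotated(60).sequence == rec.sequence
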