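"""Quadripartite plastome structure: IR detection, GC content, border genes.

A typical angiosperm plastome is a circle of ~150 kb partitioned into a
large single-copy region (LSC), a small single-copy region (SSC), and
two inverted repeats (IRa/IRb) where IRb is the exact reverse
complement of IRa. This module detects that partition from sequence
alone, computes segment lengths and GC content, and measures how far a
border-straddling gene (ycf1, rps19) extends into the IR.

Detection is exact-match by default: the reported IR is the longest
pair of non-overlapping segments, each at least ``min_ir_len``, where
one equals the reverse complement of the other. A mismatch-tolerant
extension is available behind ``max_mismatch`` but stays off by
default, since plastome IRs are clean duplications and exactness gives
a crisp contract. The partition always interprets the sequence as a
circle when assigning segments (a linearized plastome usually splits
one single-copy region across the origin); the ``circular`` flag of the
record only controls whether an IR copy may itself span the origin.
"""

from __future__ import annotations

import numpy as np

from ._seqcodes import encode, revcomp_codes
from .records import Feature, FeatureSet, Interval, PlastomeRecord, QuadripartitePartition
from .repeats import (
    _collapse_seed_chains,
    _group_pairs_cross,
    _minimal_spans_at_seed,
    _mismatch_chunk_pal,
    _qmer_table,
)


class IRNotFoundError(ValueError):
    """No inverted repeat of the required length exists (the IR-loss case)."""


def _exact_pal_runs(codes: np.ndarray, min_len: int, max_mismatch: int) -> list[tuple[int, int, int]]:
    """Maximal palindromic self-matches >= min_len in a linear code array.

    Returns canonical (pos1, pos2, length) with pos1 <= pos2-as-mirrored.
    """
    m = codes.size
    q = max(1, min(31, min_len if max_mismatch == 0 else (min_len - max_mismatch) // (max_mismatch + 1)))
    pos, keys = _qmer_table(codes, q)
    rc = revcomp_codes(codes)
    pos_t, keys_t = _qmer_table(rc, q)
    sp, tp = _group_pairs_cross(pos, keys, pos_t, keys_t)
    if sp.size == 0:
        return []
    copy2 = m - tp - q
    anti = sp + copy2 + q - 1
    anti, u0 = _collapse_seed_chains(anti, sp, q)
    out = set()
    for c, u in zip(anti, u0):
        c, u = int(c), int(u)
        lo, hi = max(0, c - m + 1), min(m - 1, c)
        fn = lambda x, y: _mismatch_chunk_pal(codes, c, x, y)
        for a, b, mm in _minimal_spans_at_seed(fn, lo, hi, u, u + q - 1, max_mismatch, min_len):
            if a <= c - b:
                out.add((a, c - b, b - a + 1))
    return sorted(out)


def detect_inverted_repeat(
    rec: PlastomeRecord, min_ir_len: int = 10_000, max_mismatch: int = 0
) -> QuadripartitePartition:
    """Detect the LSC/IRa/SSC/IRb partition of a plastome.

    The longest pair of reverse-complementary, circularly disjoint
    segments of length >= ``min_ir_len`` is taken as the IR; the longer
    of the two remaining arcs is the LSC, the shorter the SSC. Ties on
    IR length break toward the smaller first-copy start coordinate.
    For circular records the search also considers IR copies that span
    the linearization origin.
    """
    n = len(rec)
    if n <= 2 * min_ir_len:
        raise ValueError("sequence length must exceed 2 x min_ir_len")
    codes = rec.codes
    work = np.concatenate([codes, codes]) if rec.circular else codes

    candidates = []
    for p1, p2, length in _exact_pal_runs(work, min_ir_len, max_mismatch):
        length = min(length, n)
        a1, a2 = p1 % n, p2 % n
        i1, i2 = Interval(a1, a1 + length), Interval(a2, a2 + length)
        if i1.overlap_len(i2, n) > 0:
            continue  # the two IR copies must be disjoint on the circle
        lo, hi = min(a1, a2), max(a1, a2)
        candidates.append((length, lo, hi))
    if not candidates:
        raise IRNotFoundError(f"no inverted repeat of length >= {min_ir_len} found in {rec.id}")

    candidates = sorted(set(candidates), key=lambda t: (-t[0], t[1], t[2]))
    length, s1, s2 = candidates[0]
    gap_after_1 = (s2 - (s1 + length)) % n  # arc from end of copy1 to start of copy2
    gap_after_2 = (s1 - (s2 + length)) % n
    assert gap_after_1 + gap_after_2 + 2 * length == n

    # IRa is the copy followed (clockwise) by the SSC
    if gap_after_1 <= gap_after_2:
        ssc_start, ssc_len = (s1 + length) % n, gap_after_1
        lsc_start, lsc_len = (s2 + length) % n, gap_after_2
        ira_start, irb_start = s1, s2
    else:
        ssc_start, ssc_len = (s2 + length) % n, gap_after_2
        lsc_start, lsc_len = (s1 + length) % n, gap_after_1
        ira_start, irb_start = s2, s1

    return QuadripartitePartition(
        lsc=Interval(lsc_start, lsc_start + lsc_len),
        ira=Interval(ira_start, ira_start + length),
        ssc=Interval(ssc_start, ssc_start + ssc_len),
        irb=Interval(irb_start, irb_start + length),
        seq_len=n,
    )


def gc_content(rec: PlastomeRecord | str, digits: int | None = None) -> float:
    """(G + C) / (A + C + G + T); ambiguity codes and N are excluded
    from both numerator and denominator. ``digits`` optionally rounds,
    e.g. 3 for summary-table parity."""
    seq = rec.sequence if isinstance(rec, PlastomeRecord) else rec.upper()
    codes = encode(seq)
    plain = codes < 4
    total = int(plain.sum())
    if total == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    gc = int(((codes == 1) | (codes == 2)).sum())
    frac = gc / total
    return round(frac, digits) if digits is not None else frac


def at_content(rec: PlastomeRecord | str) -> float:
    """Complement of gc_content over unambiguous bases."""
    seq = rec.sequence if isinstance(rec, PlastomeRecord) else rec.upper()
    codes = encode(seq)
    plain = codes < 4
    total = int(plain.sum())
    if total == 0:
        raise ValueError("AT content undefined: no unambiguous bases")
    at = int(((codes == 0) | (codes == 3)).sum())
    return at / total


def ir_overlap_extent(feature: Interval | Feature, part: QuadripartitePartition) -> int:
    """Bases of a feature lying inside IRa or IRb (origin-aware).

    For a border gene this is the duplicated extent: the stretch of the
    gene carried twice in the genome because it reaches into the IR.
    """
    iv = feature.interval if isinstance(feature, Feature) else feature
    n = part.seq_len
    return iv.overlap_len(part.ira, n) + iv.overlap_len(part.irb, n)


def canonical_rotation(
    rec: PlastomeRecord, part: QuadripartitePartition, features: FeatureSet | None = None
) -> tuple[PlastomeRecord, int]:
    """Rotate so the record starts at trnH when such a feature exists,
    else at the detected LSC start. Returns (rotated record, offset)."""
    offset = part.lsc.start % part.seq_len
    if features is not None:
        try:
            offset = features.get("trnH").interval.start % part.seq_len
        except KeyError:
            pass
    return rec.rotated(offset), offset


def rotate_features(features: FeatureSet, offset: int, n: int) -> FeatureSet:
    """Shift feature coordinates after a sequence rotation by ``offset``."""
    out = []
    for f in features:
        s = (f.interval.start - offset) % n
        out.append(Feature(f.name, Interval(s, s + len(f.interval)), f.strand, f.type))
    return FeatureSet(out)


def structure_summary(
    rec: PlastomeRecord,
    features: FeatureSet | None = None,
    border_genes: tuple[str, ...] = (),
    min_ir_len: int = 10_000,
) -> dict:
    """One summary-table row: total/LSC/SSC/IR lengths, duplicated
    extents of requested border genes, and GC content (3 dp)."""
    part = detect_inverted_repeat(rec, min_ir_len=min_ir_len)
    row = {
        "id": rec.id,
        "total": len(rec),
        "lsc": part.lsc_len,
        "ssc": part.ssc_len,
        "ir": part.ir_len,
    }
    for name in border_genes:
        if features is None:
            raise ValueError("border gene extents require a FeatureSet")
        row[f"{name}_in_ir"] = ir_overlap_extent(features.get(name), part)
    row["gc"] = gc_content(rec, digits=3)
    return row
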