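"""Shared fixtures and independent brute-force oracles.

The oracles re-derive expected outputs by exhaustive scans over every
diagonal/antidiagonal, with no seeding, no locality and no prefilter,
so they share no failure modes with the production search path.
"""

from __future__ import annotations

import numpy as np
import pytest

from plastomics._seqcodes import encode

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(BASES[i] for i in rng.choice(4, size=n, p=p))


def _minimal_spans(P: np.ndarray, axis_len: int, k: int, min_len: int):
    """Minimal mismatch-flanked spans on one axis.

    P: sorted real mismatch positions. A span runs between two flanking
    mismatches (or the axis ends), holds <= k internal mismatches, is
    >= min_len long, and contains no sub-span with the same properties.
    For each left bound the tightest right bound is found; keeping the
    largest left bound per right bound leaves exactly the minimal set.
    """
    Pf = np.concatenate(([-1], P, [axis_len])).astype(np.int64)
    targets = Pf[:-1] + min_len + 1
    js = np.searchsorted(Pf, targets, side="left")
    best: dict[int, int] = {}
    for i in range(len(Pf) - 1):
        j = int(js[i])
        if j >= len(Pf) or j - i - 1 > k:
            continue
        best[j] = max(best.get(j, -1), i)
    return [(int(Pf[i]) + 1, int(Pf[j]) - 1, j - i - 1) for j, i in best.items()]


def oracle_repeat_pairs(seq: str, min_len: int, k: int, kinds=("direct", "palindromic")):
    """Exhaustive enumeration of all reportable repeat pairs.

    Returns a set of (orientation, pos1, pos2, length, mismatches).
    """
    codes = encode(seq)
    n = codes.size
    out = set()
    if "direct" in kinds:
        for d in range(1, n - min_len + 1):
            a, b = codes[:-d], codes[d:]
            mism = ~((a < 4) & (b < 4) & (a == b))
            for s, e, mm in _minimal_spans(np.flatnonzero(mism), n - d, k, min_len):
                out.add(("direct", s, s + d, e - s + 1, mm))
    if "palindromic" in kinds:
        for c in range(2 * n - 1):
            lo, hi = max(0, c - n + 1), min(n - 1, c)
            a = codes[lo : hi + 1]
            b = codes[c - hi : c - lo + 1][::-1]
            mism = ~((a < 4) & (b < 4) & (a == 3 - b))
            for s, e, mm in _minimal_spans(np.flatnonzero(mism), hi - lo + 1, k, min_len):
                s, e = s + lo, e + lo
                if s <= c - e:  # canonical copy ordering
                    out.add(("palindromic", s, c - e, e - s + 1, mm))
    return out


def pairs_as_tuples(pairs):
    return {(p.orientation, p.pos1, p.pos2, p.length, p.mismatches) for p in pairs}


def oracle_exact_palindromic_runs(seq: str, min_len: int):
    """All maximal exact reverse-complement self-matches >= min_len,
    as canonical (pos1, pos2, length) with the copies linearly ordered."""
    codes = encode(seq)
    n = codes.size
    out = set()
    for c in range(2 * n - 1):
        lo, hi = max(0, c - n + 1), min(n - 1, c)
        a = codes[lo : hi + 1]
        b = codes[c - hi : c - lo + 1][::-1]
        match = (a < 4) & (b < 4) & (a == 3 - b)
        padded = np.concatenate(([False], match, [False]))
        starts = np.flatnonzero(padded[1:].astype(int) - padded[:-1].astype(int) == 1)
        ends = np.flatnonzero(padded[1:].astype(int) - padded[:-1].astype(int) == -1)
        for s, e in zip(starts, ends):
            length = e - s
            if length < min_len:
                continue
            u0, u1 = s + lo, e - 1 + lo  # inclusive axis window
            p1, p2 = u0, c - u1
            if p1 <= p2:
                out.add((int(p1), int(p2), int(length)))
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    # function-scoped so each test sees the same stream regardless of
    # which other tests ran first
    return np.random.default_rng(20240901)
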