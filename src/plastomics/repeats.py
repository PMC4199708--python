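"""Maximal approximate repeat detection under a Hamming-distance model.

Finds every *maximal* pair of equal-length substrings (direct, or
palindromic = reverse-complement) whose Hamming distance is at most
``max_mismatch`` and whose length is at least ``min_len``.

The reported canonical form is the *mismatch-flanked minimal span*: a
pair is reported iff (i) it is bounded on both ends by a mismatch or
the sequence end — extending it in either direction would immediately
add a mismatch or run off — (ii) it carries at most ``max_mismatch``
internal mismatches, (iii) it is at least ``min_len`` long, and (iv) no
proper sub-span also satisfies (i)–(iii). An isolated repeat locus is
thus reported exactly once, trimmed to its mismatch boundaries with its
true internal mismatch count, rather than once per way of padding it
with absorbed flank mismatches; distinct nearby cores can still yield
overlapping listings. Tandem (overlapping) copies are permitted and a
self-overlapping perfect palindrome is reported once.

The default criterion — length >= 30 bp at >= 90% identity, i.e. at most
3 mismatches — is the classic organellar-genome repeat screen.

Search strategy
---------------
Pigeonhole seed-and-extend. A window of length ``m`` containing at most
``k`` mismatches is split by those mismatches into at most ``k+1`` exact
runs covering ``m-k`` bases, so it must contain an exact run of length
``q = ceil((m-k)/(k+1))``. Every exact shared q-mer between the sequence
and itself (direct) or its reverse complement (palindromic) is a seed;
seeds on the same (anti)diagonal whose runs abut are collapsed; each
surviving seed is extended by enumerating the maximal mismatch windows
around it. A vectorized prefilter discards the overwhelming majority of
spurious seeds before any per-seed work.

Direct matches live on diagonals (positions pair as ``u, u+d``);
palindromic matches live on antidiagonals (positions pair as
``u, c-u``), where extension on one copy's left is the other copy's
right. Only the output contract above is normative; the seeding detail
is an implementation choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seqcodes import encode, revcomp, revcomp_codes
from .records import PlastomeRecord

_CHUNK = 50_000  # seed rows per vectorized prefilter block


@dataclass(frozen=True)
class SearchParams:
    """Parameters of the repeat screen."""

    min_len: int = 30
    max_mismatch: int = 3
    kinds: frozenset[str] = field(default_factory=lambda: frozenset({"direct", "palindromic"}))
    exclude_trivial_self: bool = True

    def __post_init__(self) -> None:
        if self.min_len < 8:
            raise ValueError("min_len must be >= 8")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        bad = set(self.kinds) - {"direct", "palindromic"}
        if bad:
            raise ValueError(f"unknown repeat kinds: {sorted(bad)}")
        object.__setattr__(self, "kinds", frozenset(self.kinds))


@dataclass(frozen=True)
class RepeatPair:
    """One maximal repeat hit; pos1 < pos2 except for a self-mirrored
    perfect palindrome where the two copies coincide mirror-wise."""

    pos1: int
    pos2: int
    length: int
    orientation: str  # "direct" | "palindromic"
    mismatches: int
    seq1: str
    seq2: str

    @property
    def end1(self) -> int:
        return self.pos1 + self.length

    @property
    def end2(self) -> int:
        return self.pos2 + self.length

    @property
    def identity(self) -> float:
        return 1.0 - self.mismatches / self.length


def pair_identity(a: str, b: str) -> float:
    """Fraction of positions at which two equal-length strings agree.

    The 30 bp / Hamming-distance-3 search criterion corresponds to an
    identity of exactly 0.90 under this definition.
    """
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("empty strings")
    mism = sum(x != y for x, y in zip(a.upper(), b.upper()))
    return 1.0 - mism / len(a)


def _seed_length(min_len: int, k: int) -> int:
    q = -(-(min_len - k) // (k + 1)) if min_len > k else 1
    return max(1, min(q, 31))


def _qmer_table(codes: np.ndarray, q: int) -> tuple[np.ndarray, np.ndarray]:
    """(positions, packed q-mer keys) for every all-unambiguous window."""
    n = codes.size
    if n < q:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    valid = codes < 4
    x = np.where(valid, codes, 0).astype(np.int64)
    m = n - q + 1
    key = np.zeros(m, dtype=np.int64)
    for t in range(q):
        key = key * 4 + x[t : t + m]
    bad = np.cumsum(~valid)
    ok = (bad[q - 1 :] - np.concatenate(([0], bad[:-q]))) == 0
    pos = np.flatnonzero(ok)
    return pos, key[pos]


def _group_pairs_self(pos: np.ndarray, keys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All ordered position pairs (p1 < p2) sharing a q-mer key."""
    order = np.argsort(keys, kind="stable")
    sk, sp = keys[order], pos[order]
    cut = np.flatnonzero(np.concatenate(([True], sk[1:] != sk[:-1])))
    ends = np.append(cut[1:], sk.size)
    p1_all, p2_all = [], []
    for s, e in zip(cut, ends):
        m = e - s
        if m < 2:
            continue
        g = np.sort(sp[s:e])
        ii, jj = np.triu_indices(m, 1)
        p1_all.append(g[ii])
        p2_all.append(g[jj])
    if not p1_all:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    return np.concatenate(p1_all), np.concatenate(p2_all)


def _group_pairs_cross(
    pos_a: np.ndarray, keys_a: np.ndarray, pos_b: np.ndarray, keys_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """All cross pairs (a-position, b-position) sharing a q-mer key."""
    if pos_a.size == 0 or pos_b.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    oa, ob = np.argsort(keys_a, kind="stable"), np.argsort(keys_b, kind="stable")
    ka, pa = keys_a[oa], pos_a[oa]
    kb, pb = keys_b[ob], pos_b[ob]
    common, ia, ib = np.intersect1d(ka, kb, return_indices=True)
    a_out, b_out = [], []
    # run-lengths of each common key in the two sorted arrays
    for key in common:
        a0, a1 = np.searchsorted(ka, key), np.searchsorted(ka, key, side="right")
        b0, b1 = np.searchsorted(kb, key), np.searchsorted(kb, key, side="right")
        ga, gb = pa[a0:a1], pb[b0:b1]
        a_out.append(np.repeat(ga, gb.size))
        b_out.append(np.tile(gb, ga.size))
    if not a_out:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    return np.concatenate(a_out), np.concatenate(b_out)


def _collapse_seed_chains(axis: np.ndarray, u0: np.ndarray, q: int) -> tuple[np.ndarray, np.ndarray]:
    """Keep one seed per chain of abutting exact runs on each (anti)diagonal.

    Two seeds on the same axis with starts within q of each other belong
    to one contiguous exact run; any maximal window covering the later
    run also covers the earlier one, so only the chain head is needed.
    """
    if axis.size == 0:
        return axis, u0
    order = np.lexsort((u0, axis))
    ax, uu = axis[order], u0[order]
    keep = np.concatenate(([True], (ax[1:] != ax[:-1]) | (uu[1:] - uu[:-1] > q)))
    return ax[keep], uu[keep]


def _mismatch_chunk_direct(codes: np.ndarray, d: int, lo: int, hi: int) -> np.ndarray:
    a = codes[lo : hi + 1]
    b = codes[lo + d : hi + 1 + d]
    return ~((a < 4) & (b < 4) & (a == b))


def _mismatch_chunk_pal(codes: np.ndarray, c: int, lo: int, hi: int) -> np.ndarray:
    a = codes[lo : hi + 1]
    b = codes[c - hi : c - lo + 1][::-1]
    return ~((a < 4) & (b < 4) & (a == 3 - b))


def _walk(mism_fn, start: int, stop: int, step: int, need: int) -> list[int]:
    """Collect up to ``need`` mismatch positions walking from start
    toward stop (inclusive bounds), in 256-base chunks."""
    out: list[int] = []
    u = start
    while (u >= stop if step < 0 else u <= stop) and len(out) < need:
        if step < 0:
            lo = max(stop, u - 255)
            block = mism_fn(lo, u)
            hits = np.flatnonzero(block)[::-1]
            for h in hits:
                out.append(lo + int(h))
                if len(out) == need:
                    break
            u = lo - 1
        else:
            hi = min(stop, u + 255)
            block = mism_fn(u, hi)
            for h in np.flatnonzero(block):
                out.append(u + int(h))
                if len(out) == need:
                    break
            u = hi + 1
    return out


def _span_mismatches(P: list[int], i: int, j: int) -> int:
    return sum(1 for x in P[i + 1 : j] if P[i] < x < P[j])


def _minimal_spans_at_seed(
    mism_fn, lo: int, hi: int, seed_lo: int, seed_hi: int, k: int, min_len: int
) -> list[tuple[int, int, int]]:
    """Minimal mismatch-flanked spans containing the seed's exact core.

    ``P`` holds the k+1 nearest mismatch positions on each side of the
    seed run (sequence ends act as virtual mismatches, encoded as
    duplicate pad values). Any reportable span whose core contains the
    seed is bounded by two entries of P; minimality is checked against
    every sub-span, including ones that do not touch the seed core.
    Returns (a, b, n_mismatches) with a, b inclusive axis positions.
    """
    lefts = _walk(mism_fn, seed_lo - 1, lo, -1, k + 1)
    rights = _walk(mism_fn, seed_hi + 1, hi, +1, k + 1)
    lpad, rpad = lo - 1, hi + 1
    lefts += [lpad] * (k + 1 - len(lefts))
    rights += [rpad] * (k + 1 - len(rights))
    P = lefts[::-1] + rights  # ascending; core sits between P[k] and P[k+1]
    m = len(P)

    def valid(i: int, j: int) -> tuple[int, int, int] | None:
        a, b = P[i] + 1, P[j] - 1
        if b - a + 1 < min_len:
            return None
        mm = _span_mismatches(P, i, j)
        if mm > k:
            return None
        return (a, b, mm)

    out = set()
    for i in range(k + 1):
        for j in range(k + 1, m):
            cand = valid(i, j)
            if cand is None:
                continue
            a, b, _ = cand
            has_sub = False
            for i2 in range(i, j):
                for j2 in range(i2 + 1, j + 1):
                    sub = valid(i2, j2)
                    if sub is not None and (sub[0], sub[1]) != (a, b):
                        has_sub = True
                        break
                if has_sub:
                    break
            if not has_sub:
                out.add(cand)
    return sorted(out)


def _prefilter(
    codes: np.ndarray, axis: np.ndarray, u0: np.ndarray, q: int, k: int, min_len: int, pal: bool
) -> np.ndarray:
    """Boolean mask: seed could sit inside a reportable window.

    Exact in the no-miss direction: any qualifying maximal window of
    length >= min_len contains a length-min_len subwindow covering the
    seed with <= k mismatches, and that subwindow lies inside the patch.
    """
    n = codes.size
    R = min_len + k + 1
    offs = np.arange(-R, R + q, dtype=np.int64)
    keep = np.zeros(axis.size, dtype=bool)
    for s0 in range(0, axis.size, _CHUNK):
        s1 = min(s0 + _CHUNK, axis.size)
        U = u0[s0:s1, None] + offs[None, :]
        if pal:
            V = axis[s0:s1, None] - U
            inb = (U >= 0) & (U < n) & (V >= 0) & (V < n)
        else:
            V = U + axis[s0:s1, None]
            inb = (U >= 0) & (V < n)
        a = codes[np.clip(U, 0, n - 1)]
        b = codes[np.clip(V, 0, n - 1)]
        if pal:
            match = (a < 4) & (b < 4) & (a == 3 - b)
        else:
            match = (a < 4) & (b < 4) & (a == b)
        cost = np.where(inb & match, 0, np.where(inb, 1, k + 1)).astype(np.int32)
        cs = np.concatenate(
            [np.zeros((cost.shape[0], 1), np.int32), np.cumsum(cost, axis=1)], axis=1
        )
        w = min_len
        lo_s, hi_s = R - (w - q), R
        wsum = cs[:, lo_s + w : hi_s + w + 1] - cs[:, lo_s : hi_s + 1]
        keep[s0:s1] = (wsum <= k).any(axis=1)
    return keep


def find_maximal_repeats(rec: PlastomeRecord, params: SearchParams | None = None) -> list[RepeatPair]:
    """All maximal direct/palindromic repeat pairs of ``rec`` meeting
    the length and mismatch criteria. Output is sorted by
    (pos1, pos2, length, orientation) and deterministic.

    The genome is searched as a linear string, matching the reporting
    conventions of the classic repeat-screening tools.
    """
    params = params or SearchParams()
    seq = rec.sequence
    n = len(seq)
    if n < params.min_len:
        raise ValueError("sequence shorter than min_len")
    codes = encode(seq)
    k = params.max_mismatch
    q = _seed_length(params.min_len, k)
    pos, keys = _qmer_table(codes, q)

    found: set[tuple[str, int, int, int, int]] = set()

    if "direct" in params.kinds:
        p1, p2 = _group_pairs_self(pos, keys)
        diag = p2 - p1
        diag, u0 = _collapse_seed_chains(diag, p1, q)
        good = _prefilter(codes, diag, u0, q, k, params.min_len, pal=False)
        for d, u in zip(diag[good], u0[good]):
            d, u = int(d), int(u)
            fn = lambda x, y: _mismatch_chunk_direct(codes, d, x, y)
            for a, b, m in _minimal_spans_at_seed(
                fn, 0, n - 1 - d, u, u + q - 1, k, params.min_len
            ):
                found.add(("direct", a, a + d, b - a + 1, m))

    if "palindromic" in params.kinds:
        rc = revcomp_codes(codes)
        pos_t, keys_t = _qmer_table(rc, q)
        sp, tp = _group_pairs_cross(pos, keys, pos_t, keys_t)
        if sp.size:
            copy2 = n - tp - q
            anti = sp + copy2 + q - 1
            anti, u0 = _collapse_seed_chains(anti, sp, q)
            good = _prefilter(codes, anti, u0, q, k, params.min_len, pal=True)
            for c, u in zip(anti[good], u0[good]):
                c, u = int(c), int(u)
                lo, hi = max(0, c - n + 1), min(n - 1, c)
                fn = lambda x, y: _mismatch_chunk_pal(codes, c, x, y)
                for a, b, m in _minimal_spans_at_seed(
                    fn, lo, hi, u, u + q - 1, k, params.min_len
                ):
                    if a <= c - b:  # canonical copy; mirror is the same pair
                        found.add(("palindromic", a, c - b, b - a + 1, m))

    pairs = []
    for orient, pos1, pos2, length, mism in sorted(found, key=lambda t: (t[1], t[2], t[3], t[0])):
        pairs.append(
            RepeatPair(
                pos1=pos1,
                pos2=pos2,
                length=length,
                orientation=orient,
                mismatches=mism,
                seq1=seq[pos1 : pos1 + length],
                seq2=seq[pos2 : pos2 + length],
            )
        )
    return pairs


def oriented_second(pair: RepeatPair) -> str:
    """seq2 in the frame that aligns position-by-position with seq1."""
    return revcomp(pair.seq2) if pair.orientation == "palindromic" else pair.seq2
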