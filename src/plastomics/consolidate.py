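"""Consolidation of raw repeat pairs into families and summary counts.

A raw maximal-pair listing inflates the apparent number of repeats: a
repeat present at k locations is reported as all C(k,2) pairs, and
near-identical sequences at the same locus can be listed repeatedly at
different lengths. This module deflates that listing the way a careful
curator would:

1. classify each pair as tandem (copies within 1000 bp of each other,
   nearest edges) or dispersed;
2. discard dispersed pairs whose copies both lie wholly inside the
   inverted repeats — those are trivial consequences of the IR
   duplication, not independent repeats;
3. merge instances that occupy the same locus (containment, or >= 80%
   overlap of the shorter);
4. single-linkage cluster the merged loci into families at >= 90%
   ungapped identity over the shorter member, reverse-complement
   matches included;
5. report unique sequences (families), unique locations, and tandem
   counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from ._seqcodes import revcomp
from .records import FeatureSet, Interval, QuadripartitePartition
from .repeats import RepeatPair

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H", frozenset("AGT"): "D",
    frozenset("CGT"): "B", frozenset("ACGT"): "N",
}


@dataclass(frozen=True)
class RepeatInstance:
    position: int
    length: int
    sequence: str
    orientation: str = "direct"

    @property
    def interval(self) -> Interval:
        return Interval(self.position, self.position + self.length)

    @property
    def end(self) -> int:
        return self.position + self.length


@dataclass
class RepeatFamily:
    family_id: str
    representative: str
    members: list[RepeatInstance]
    n_locations: int
    classification: str  # "tandem" | "dispersed"
    ir_status: str | None = None  # "ir_only" | "spans_ir_and_sc" | "single_copy_regions"
    coding_flags: list[bool] = field(default_factory=list)


@dataclass(frozen=True)
class RepeatSummary:
    raw_pair_count: int
    tandem_count: int
    dispersed_unique_locations: int
    dispersed_unique_sequences: int

    def __post_init__(self) -> None:
        if not (
            self.dispersed_unique_sequences
            <= self.dispersed_unique_locations
            <= 2 * self.raw_pair_count
        ):
            raise ValueError("inconsistent summary counts")


def classify_tandem(pair: RepeatPair, threshold: int = 1000) -> str:
    """Tandem iff the gap from the end of the first copy to the start
    of the second is below the threshold; overlapping copies (gap <= 0)
    are always tandem."""
    gap = pair.pos2 - pair.end1
    return "tandem" if gap < threshold else "dispersed"


def _wholly_in_ir(iv: Interval, part: QuadripartitePartition) -> bool:
    n = part.seq_len
    inside = iv.overlap_len(part.ira, n) + iv.overlap_len(part.irb, n)
    return inside == len(iv)


def filter_ir_duplicates(
    pairs: list[RepeatPair], part: QuadripartitePartition
) -> list[RepeatPair]:
    """Drop pairs whose two copies both lie entirely within IRa u IRb;
    keep any pair with at least one copy touching a single-copy region."""
    out = []
    for p in pairs:
        c1 = Interval(p.pos1, p.end1)
        c2 = Interval(p.pos2, p.end2)
        if _wholly_in_ir(c1, part) and _wholly_in_ir(c2, part):
            continue
        out.append(p)
    return out


def instances_from_pairs(pairs: list[RepeatPair]) -> list[RepeatInstance]:
    """Both copies of every pair, as location-bearing instances."""
    inst = []
    for p in pairs:
        inst.append(RepeatInstance(p.pos1, p.length, p.seq1, "direct"))
        inst.append(
            RepeatInstance(
                p.pos2, p.length, p.seq2,
                "palindromic" if p.orientation == "palindromic" else "direct",
            )
        )
    return sorted(set(inst), key=lambda r: (r.position, r.length, r.orientation))


def _same_locus(a: RepeatInstance, b: RepeatInstance) -> bool:
    ov = a.interval.overlap_len(b.interval)
    shorter = min(a.length, b.length)
    if ov == shorter:  # containment
        return True
    return ov >= 0.8 * shorter


def _slide(a: str, b: str):
    """Ungapped offsets of ``a`` against ``b``, overhangs allowed.

    Yields (offset, matches, overlap); identity over the shorter is
    matches/len(a), so overhanging bases count against it.
    """
    la, lb = len(a), len(b)
    for off in range(-(la - 1), lb):
        lo, hi = max(0, off), min(lb, off + la)
        overlap = hi - lo
        if overlap <= 0:
            continue
        matches = sum(
            1 for t in range(lo, hi) if a[t - off] == b[t]
        )
        yield off, matches, overlap


def _best_identity(a: str, b: str) -> float:
    """Best ungapped identity over the shorter sequence's length, any
    offset (overhang allowed), either orientation."""
    if len(a) > len(b):
        a, b = b, a
    best = 0.0
    for probe in (a, revcomp(a)):
        for _, matches, _ in _slide(probe, b):
            best = max(best, matches / len(a))
            if best == 1.0:
                return best
    return best


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _merge_same_locus(instances: list[RepeatInstance]) -> list[RepeatInstance]:
    """Collapse instances occupying one locus to the longest of them."""
    if not instances:
        return []
    uf = _UnionFind(len(instances))
    for i in range(len(instances)):
        for j in range(i + 1, len(instances)):
            if instances[j].position >= instances[i].end:
                break  # sorted by position: no further overlap possible
            if _same_locus(instances[i], instances[j]):
                uf.union(i, j)
    groups: dict[int, list[RepeatInstance]] = {}
    for i, inst in enumerate(instances):
        groups.setdefault(uf.find(i), []).append(inst)
    merged = [
        max(g, key=lambda r: (r.length, -r.position)) for g in groups.values()
    ]
    return sorted(merged, key=lambda r: (r.position, r.length))


def _consensus(members: list[RepeatInstance]) -> str:
    """Majority consensus over members aligned (ungapped, best offset
    and orientation) to the longest member; ties become IUPAC codes."""
    ref = max(members, key=lambda r: (r.length, -r.position))
    votes: list[dict[str, int]] = [dict() for _ in range(ref.length)]
    for m in members:
        best, best_seq, best_off = -1, m.sequence, 0
        for probe in (m.sequence, revcomp(m.sequence)):
            for off, matches, _ in _slide(probe, ref.sequence):
                if matches > best:
                    best, best_seq, best_off = matches, probe, off
        for t, base in enumerate(best_seq):
            col = best_off + t
            if 0 <= col < ref.length:
                votes[col][base] = votes[col].get(base, 0) + 1
    out = []
    for col in votes:
        if not col:
            out.append("N")
            continue
        top = max(col.values())
        tied = frozenset(b for b, v in col.items() if v == top if b in "ACGT")
        out.append(_IUPAC.get(tied, "N"))
    return "".join(out)


def _classify_family(members: list[RepeatInstance], threshold: int) -> str:
    if len(members) < 2:
        return "tandem"
    starts = sorted((m.position, m.end) for m in members)
    gaps = [starts[i + 1][0] - starts[i][1] for i in range(len(starts) - 1)]
    return "tandem" if all(g < threshold for g in gaps) else "dispersed"


def _ir_status(members: list[RepeatInstance], part: QuadripartitePartition) -> str:
    inside = [_wholly_in_ir(m.interval, part) for m in members]
    touches = [
        m.interval.overlap_len(part.ira, part.seq_len)
        + m.interval.overlap_len(part.irb, part.seq_len)
        > 0
        for m in members
    ]
    if all(inside):
        return "ir_only"
    if any(touches):
        return "spans_ir_and_sc"
    return "single_copy_regions"


def cluster_families(
    instances: list[RepeatInstance],
    identity_threshold: float = 0.90,
    tandem_threshold: int = 1000,
    part: QuadripartitePartition | None = None,
) -> list[RepeatFamily]:
    """Merge same-locus instances, then single-linkage cluster the loci
    into families at >= identity_threshold (reverse-complement aware).

    Families are labelled R1, R2, ... ordered by descending location
    count then leftmost position, which makes the output independent of
    input order.
    """
    instances = sorted(set(instances), key=lambda r: (r.position, r.length, r.orientation))
    merged = _merge_same_locus(instances)
    if not merged:
        return []
    uf = _UnionFind(len(merged))
    for i in range(len(merged)):
        for j in range(i + 1, len(merged)):
            if _best_identity(merged[i].sequence, merged[j].sequence) >= identity_threshold:
                uf.union(i, j)
    groups: dict[int, list[RepeatInstance]] = {}
    for i, inst in enumerate(merged):
        groups.setdefault(uf.find(i), []).append(inst)
    raw = sorted(
        groups.values(), key=lambda g: (-len(g), min(m.position for m in g))
    )
    families = []
    for idx, members in enumerate(raw, start=1):
        members = sorted(members, key=lambda r: r.position)
        families.append(
            RepeatFamily(
                family_id=f"R{idx}",
                representative=_consensus(members),
                members=members,
                n_locations=len(members),
                classification=_classify_family(members, tandem_threshold),
                ir_status=_ir_status(members, part) if part is not None else None,
            )
        )
    return families


def annotate_locations(
    families: list[RepeatFamily], features: FeatureSet
) -> list[RepeatFamily]:
    """Set per-member coding flags: true iff the member interval
    intersects any gene/CDS feature."""
    coding = features.of_type("gene", "CDS")
    out = []
    for fam in families:
        flags = [
            any(m.interval.overlap_len(f.interval) > 0 for f in coding)
            for m in fam.members
        ]
        out.append(replace_coding(fam, flags))
    return out


def replace_coding(fam: RepeatFamily, flags: list[bool]) -> RepeatFamily:
    return RepeatFamily(
        family_id=fam.family_id,
        representative=fam.representative,
        members=list(fam.members),
        n_locations=fam.n_locations,
        classification=fam.classification,
        ir_status=fam.ir_status,
        coding_flags=flags,
    )


def summarize(
    pairs: list[RepeatPair],
    families: list[RepeatFamily],
    part: QuadripartitePartition | None = None,
    tandem_threshold: int = 1000,
) -> RepeatSummary:
    """Summary-table row: raw pair count, tandem pair count, and the
    deflated dispersed unique-location / unique-sequence counts."""
    tandem = sum(1 for p in pairs if classify_tandem(p, tandem_threshold) == "tandem")
    return RepeatSummary(
        raw_pair_count=len(pairs),
        tandem_count=tandem,
        dispersed_unique_locations=sum(f.n_locations for f in families),
        dispersed_unique_sequences=len(families),
    )


def consolidate(
    pairs: list[RepeatPair],
    part: QuadripartitePartition | None = None,
    features: FeatureSet | None = None,
    identity_threshold: float = 0.90,
    tandem_threshold: int = 1000,
) -> tuple[list[RepeatFamily], RepeatSummary]:
    """The full deflation pipeline over one genome's raw pairs."""
    dispersed = [p for p in pairs if classify_tandem(p, tandem_threshold) == "dispersed"]
    if part is not None:
        dispersed = filter_ir_duplicates(dispersed, part)
    families = cluster_families(
        instances_from_pairs(dispersed),
        identity_threshold=identity_threshold,
        tandem_threshold=tandem_threshold,
        part=part,
    )
    if features is not None:
        families = annotate_locations(families, features)
    summary = summarize(pairs, families, part, tandem_threshold)
    return families, summary
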