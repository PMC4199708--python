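"""Core domain records: genomes, intervals, features, partitions.

Coordinates are 0-based half-open throughout the library; file formats
that use 1-based inclusive coordinates (GFF3) are converted at the I/O
boundary. Intervals on circular sequences may wrap: an interval with
``end > n`` denotes positions taken modulo the sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from ._seqcodes import encode, is_valid_dna


@dataclass(frozen=True)
class Interval:
    """Half-open interval [start, end); end may exceed the sequence
    length on circular sequences, meaning the interval wraps the origin."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"interval end {self.end} < start {self.start}")

    def __len__(self) -> int:
        return self.end - self.start

    def pieces(self, n: int) -> list[tuple[int, int]]:
        """Unwrapped [start, end) pieces on a sequence of length n."""
        if self.end <= n:
            return [(self.start, self.end)]
        return [(self.start, n), (0, self.end - n)]

    def overlap_len(self, other: "Interval", n: int | None = None) -> int:
        """Number of shared positions; origin-aware when n is given."""
        mine = self.pieces(n) if n else [(self.start, self.end)]
        theirs = other.pieces(n) if n else [(other.start, other.end)]
        total = 0
        for a0, a1 in mine:
            for b0, b1 in theirs:
                total += max(0, min(a1, b1) - max(a0, b0))
        return total


@dataclass
class PlastomeRecord:
    """A single plastome: identifier, DNA sequence, circularity flag."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        self.sequence = self.sequence.upper()
        if not is_valid_dna(self.sequence):
            raise ValueError(f"record {self.id}: non-IUPAC characters in sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        return encode(self.sequence)

    def rotated(self, offset: int) -> "PlastomeRecord":
        """Rotate the linearization so old position ``offset`` becomes 0."""
        n = len(self.sequence)
        offset %= n
        return PlastomeRecord(
            id=self.id,
            sequence=self.sequence[offset:] + self.sequence[:offset],
            circular=self.circular,
        )


@dataclass(frozen=True)
class Feature:
    name: str
    interval: Interval
    strand: str = "+"
    type: str = "gene"


@dataclass
class FeatureSet:
    """Gene features on one plastome; a thin list wrapper with lookup."""

    features: list[Feature] = field(default_factory=list)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def get(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"no feature named {name!r}")

    def of_type(self, *types: str) -> list[Feature]:
        return [f for f in self.features if f.type in types]


@dataclass
class QuadripartitePartition:
    """LSC / IRa / SSC / IRb intervals on the linearized sequence.

    Canonical reading order around the circle is LSC → IRa → SSC → IRb;
    IRa is the inverted-repeat copy immediately preceding the SSC.
    """

    lsc: Interval
    ira: Interval
    ssc: Interval
    irb: Interval
    seq_len: int

    @property
    def ir_len(self) -> int:
        return len(self.ira)

    @property
    def lsc_len(self) -> int:
        return len(self.lsc)

    @property
    def ssc_len(self) -> int:
        return len(self.ssc)

    def __post_init__(self) -> None:
        if len(self.ira) != len(self.irb):
            raise ValueError("IRa and IRb lengths differ")
        total = len(self.lsc) + len(self.ssc) + 2 * len(self.ira)
        if total != self.seq_len:
            raise ValueError(
                f"partition does not cover sequence: {total} != {self.seq_len}"
            )

    def ir_intervals(self) -> tuple[Interval, Interval]:
        return self.ira, self.irb


def alignment_from_strings(ids: Sequence[str], rows: Sequence[str]) -> "AlignmentMatrix":
    from .diversity import AlignmentMatrix

    return AlignmentMatrix(ids=list(ids), rows=[r.upper() for r in rows])
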