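"""Alignment-based diversity and substitution-rate estimation.

Works on a fixed multiple sequence alignment (no alignment is computed
here). Gap and ambiguity handling is pairwise deletion: a column counts
for a pair only when both rows carry an unambiguous A/C/G/T, which
matches the convention of recording pairwise single-nucleotide
differences while excluding indel polymorphisms. For two sequences,
nucleotide diversity is then exactly pi = S / L with S the segregating
sites and L the compared sites; for more sequences pi is the average of
the per-pair values.

Substitution rates are calibrated molecular-clock style:
r = S / (L x T) with T the divergence time in years. Dividing by T
(not 2T) is the table convention reproduced here; the per-lineage 2T
convention is available behind a flag. No multiple-hit correction is
applied — at the plastome divergences this package targets (pi on the
order of 1e-3 to 1e-2) the correction is far below sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._seqcodes import encode


@dataclass
class AlignmentMatrix:
    """Equal-length aligned sequences over {A,C,G,T,-,N,IUPAC}."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows of unequal length: {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]
        self._codes = np.vstack([encode(r) for r in self.rows])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def codes(self) -> np.ndarray:
        return self._codes

    def index_of(self, taxon: str) -> int:
        return self.ids.index(taxon)

    def subset_columns(self, keep: np.ndarray) -> "AlignmentMatrix":
        sub = self._codes[:, keep]
        from ._seqcodes import decode

        return AlignmentMatrix(ids=list(self.ids), rows=[decode(r) for r in sub])


@dataclass(frozen=True)
class PairwiseStats:
    snps: int
    compared_sites: int
    pi: float


@dataclass(frozen=True)
class RateEstimate:
    rate: float
    snps: int
    aligned_sites: int
    divergence_time: float


class CalibrationTable:
    """Divergence times in years, keyed by unordered taxon pair."""

    def __init__(self, times: Mapping[tuple[str, str], float]) -> None:
        self._times: dict[frozenset[str], float] = {}
        for (a, b), t in times.items():
            if t <= 0:
                raise ValueError(f"divergence time for ({a}, {b}) must be > 0")
            self._times[frozenset((a, b))] = float(t)

    def get(self, a: str, b: str) -> float:
        key = frozenset((a, b))
        if key not in self._times:
            raise KeyError(f"no calibration for taxon pair ({a}, {b})")
        return self._times[key]

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return frozenset(pair) in self._times


def count_pairwise_snps(aln: AlignmentMatrix, i: int, j: int) -> PairwiseStats:
    """Segregating sites and compared sites for one row pair.

    A column is compared iff both rows carry an unambiguous base; a SNP
    is a compared column where the bases differ.
    """
    if i == j:
        raise ValueError("row indices must differ")
    a, b = aln.codes()[i], aln.codes()[j]
    both = (a < 4) & (b < 4)
    compared = int(both.sum())
    snps = int(((a != b) & both).sum())
    pi = snps / compared if compared else 0.0
    return PairwiseStats(snps=snps, compared_sites=compared, pi=pi)


def nucleotide_diversity(aln: AlignmentMatrix) -> float:
    """Average over all unordered row pairs of per-pair pi (pairwise
    deletion of gapped/ambiguous columns)."""
    n = aln.n_rows
    vals = [
        count_pairwise_snps(aln, i, j).pi for i in range(n) for j in range(i + 1, n)
    ]
    return float(np.mean(vals))


def substitution_rate(
    snps: int, aligned_sites: int, divergence_time: float, per_lineage: bool = False
) -> RateEstimate:
    """r = snps / (aligned_sites x T); with ``per_lineage`` the
    denominator uses 2T (substitutions accumulate on both lineages)."""
    if aligned_sites <= 0:
        raise ValueError("aligned_sites must be > 0")
    if divergence_time <= 0:
        raise ValueError("divergence_time must be > 0")
    if snps < 0:
        raise ValueError("snps must be >= 0")
    denom_t = 2 * divergence_time if per_lineage else divergence_time
    return RateEstimate(
        rate=snps / (aligned_sites * denom_t),
        snps=snps,
        aligned_sites=aligned_sites,
        divergence_time=divergence_time,
    )


@dataclass
class RateMatrixResult:
    """SNPs above the diagonal, rates below, plus capture flags.

    ``flagged`` lists unordered taxon pairs whose rate is anomalously
    low relative to the rates of the other pairs sharing a taxon — the
    signature of chloroplast capture, where a calibration date taken
    from the nuclear genome overstates the true plastome divergence.
    """

    taxa: list[str]
    snps: pd.DataFrame
    rates: pd.DataFrame
    flagged: list[tuple[str, str]]

    def combined(self) -> pd.DataFrame:
        """One square table, SNPs upper triangle / rates lower."""
        out = pd.DataFrame("", index=self.taxa, columns=self.taxa, dtype=object)
        for i, a in enumerate(self.taxa):
            for j, b in enumerate(self.taxa):
                if i < j:
                    out.loc[a, b] = int(self.snps.loc[a, b])
                elif i > j:
                    mark = "*" if tuple(sorted((a, b))) in self.flagged else ""
                    out.loc[a, b] = f"{self.rates.loc[a, b]:.2E}{mark}"
        return out


def rate_matrix(
    aln: AlignmentMatrix,
    calib: CalibrationTable,
    per_lineage: bool = False,
    flag_factor: float = 0.5,
) -> RateMatrixResult:
    """Pairwise SNP / substitution-rate matrix with low-rate flagging.

    Taxa are sorted into canonical (input) order; a pair is flagged
    when its rate falls below ``flag_factor`` times the median rate of
    all other pairs involving either taxon.
    """
    taxa = list(aln.ids)
    n = len(taxa)
    snps = pd.DataFrame(np.zeros((n, n)), index=taxa, columns=taxa)
    rates = pd.DataFrame(np.zeros((n, n)), index=taxa, columns=taxa)
    pair_rate: dict[tuple[str, str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = taxa[i], taxa[j]
            stats = count_pairwise_snps(aln, i, j)
            est = substitution_rate(
                stats.snps, stats.compared_sites, calib.get(a, b), per_lineage
            )
            snps.iloc[i, j] = snps.iloc[j, i] = stats.snps
            rates.iloc[i, j] = rates.iloc[j, i] = est.rate
            pair_rate[tuple(sorted((a, b)))] = est.rate

    flagged = []
    for pair, r in sorted(pair_rate.items()):
        others = [
            v
            for p, v in pair_rate.items()
            if p != pair and (set(p) & set(pair))
        ]
        if others and r < flag_factor * float(np.median(others)):
            flagged.append(pair)
    return RateMatrixResult(taxa=taxa, snps=snps, rates=rates, flagged=flagged)


def windowed_identity(
    aln: AlignmentMatrix, ref_row: int | str = 0, window: int = 100, step: int = 25
) -> pd.DataFrame:
    """Sliding-window percent identity of every row against a reference.

    Identity per window is matches / columns where both rows are
    unambiguous; windows with no comparable column give NaN. A window
    longer than the alignment collapses to a single full-length window.
    Returns a DataFrame with ``start``/``end`` columns (0-based,
    half-open) and one identity column per non-reference row.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    ref = aln.index_of(ref_row) if isinstance(ref_row, str) else ref_row
    L = aln.n_cols
    if window > L:
        window = L
    starts = list(range(0, L - window + 1, step))
    codes = aln.codes()
    a = codes[ref]
    data: dict[str, list[float]] = {"start": [], "end": []}
    for s in starts:
        data["start"].append(s)
        data["end"].append(s + window)
    for i, name in enumerate(aln.ids):
        if i == ref:
            continue
        b = codes[i]
        both = (a < 4) & (b < 4)
        match = both & (a == b)
        cb = np.concatenate(([0], np.cumsum(both)))
        cm = np.concatenate(([0], np.cumsum(match)))
        vals = []
        for s in starts:
            comp = cb[s + window] - cb[s]
            vals.append((cm[s + window] - cm[s]) / comp if comp else np.nan)
        data[name] = vals
    return pd.DataFrame(data)
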