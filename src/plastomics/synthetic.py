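"""Synthetic plastomes with known ground truth.

Two generators live here. ``generate_plastome`` emits a quadripartite
LSC–IRa–SSC–IRb genome (default dimensions follow a typical perennial
Glycine plastome: LSC 83,844 / SSC 17,840 / IR 25,555 bp, GC 0.353)
with planted repeat families, border genes straddling the LSC/IRa
junction, and a machine-readable truth record. ``evolve_sequences``
evolves an ancestor along a dated tree at a fixed per-site per-year
substitution rate under an equal-rates (Jukes–Cantor-style) model with
no indels, so the tips stay aligned by construction.

Background sequence is i.i.d. with per-base probabilities tuned to the
GC target. At plastome scale the probability that such background
contains an accidental >= 30 bp repeat at <= 3 mismatches is of order
1e-3; a post-generation self-scan nevertheless rejects and regenerates
any draw where one appears, so planted truth is exhaustive.

Everything is driven by a single integer seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import dendropy
import numpy as np
import yaml

from ._seqcodes import decode, revcomp_codes
from .records import Feature, FeatureSet, Interval, PlastomeRecord, QuadripartitePartition
from .repeats import SearchParams, find_maximal_repeats

_PAD = 50  # clearance kept between planted elements, bp


class PlacementError(ValueError):
    """A planted repeat family could not be placed without overlap."""


@dataclass(frozen=True)
class PlantSpec:
    """One repeat family to plant.

    ``mismatches_per_copy`` Hamming edits are applied to every copy
    after the first; copies of a palindromic family alternate strand.
    Tandem placement keeps nearest-end gaps under 1000 bp, dispersed
    placement keeps them at or above 1000 bp.
    """

    family_id: str
    repeat_len: int = 35
    n_copies: int = 2
    orientation: str = "direct"  # "direct" | "palindromic"
    mismatches_per_copy: int = 0
    placement: str = "dispersed"  # "tandem" | "dispersed"
    region: str = "LSC"  # "LSC" | "SSC" | "IR" | "any"

    def __post_init__(self) -> None:
        if self.repeat_len < 1 or self.n_copies < 2:
            raise ValueError(f"{self.family_id}: need repeat_len >= 1 and n_copies >= 2")
        if self.orientation not in ("direct", "palindromic"):
            raise ValueError(f"{self.family_id}: bad orientation {self.orientation}")
        if self.placement not in ("tandem", "dispersed"):
            raise ValueError(f"{self.family_id}: bad placement {self.placement}")
        if self.region not in ("LSC", "SSC", "IR", "any"):
            raise ValueError(f"{self.family_id}: bad region {self.region}")
        if not 0 <= self.mismatches_per_copy < self.repeat_len:
            raise ValueError(f"{self.family_id}: bad mismatches_per_copy")


@dataclass(frozen=True)
class BorderGeneSpec:
    """A gene straddling the LSC/IRa junction, partially duplicated."""

    name: str
    duplicated_extent: int
    total_len: int

    def __post_init__(self) -> None:
        if not 0 < self.duplicated_extent < self.total_len:
            raise ValueError(f"{self.name}: need 0 < duplicated_extent < total_len")


@dataclass(frozen=True)
class GeneratorConfig:
    lsc_len: int = 83_844
    ssc_len: int = 17_840
    ir_len: int = 25_555
    gc_target: float = 0.353
    planted_repeats: tuple[PlantSpec, ...] = ()
    border_genes: tuple[BorderGeneSpec, ...] = ()
    seed: int = 0
    self_scan: bool = True

    def __post_init__(self) -> None:
        if min(self.lsc_len, self.ssc_len, self.ir_len) <= 0:
            raise ValueError("all segment lengths must be > 0")
        if not 0.0 <= self.gc_target <= 1.0:
            raise ValueError("gc_target must lie in [0, 1]")
        object.__setattr__(self, "planted_repeats", tuple(self.planted_repeats))
        object.__setattr__(self, "border_genes", tuple(self.border_genes))
        longest = max((p.repeat_len for p in self.planted_repeats), default=0)
        if self.ir_len < 2 * longest:
            raise ValueError("ir_len must be at least twice the longest planted repeat")

    @property
    def total_len(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len


@dataclass(frozen=True)
class PlantedInstance:
    family_id: str
    copy_index: int
    start: int  # genome coordinate, 0-based
    length: int
    strand: str  # "forward" | "revcomp" relative to the family motif
    mismatches: int


@dataclass
class SyntheticTruth:
    """Ground truth emitted beside every synthetic artifact.

    For genomes: the partition, the planted instances (plus the IRb
    mirror images of anything planted in IRa). For evolved sequence
    sets: realized substitution events per branch and per tip pair.
    """

    config: dict
    partition: dict | None = None
    instances: list[PlantedInstance] = field(default_factory=list)
    ir_mirrors: list[PlantedInstance] = field(default_factory=list)
    branch_events: dict[str, int] = field(default_factory=dict)
    pair_events: dict[str, int] = field(default_factory=dict)
    pair_hamming: dict[str, int] = field(default_factory=dict)

    def to_yaml(self) -> str:
        payload = {
            "config": self.config,
            "partition": self.partition,
            "instances": [asdict(i) for i in self.instances],
            "ir_mirrors": [asdict(i) for i in self.ir_mirrors],
            "branch_events": self.branch_events,
            "pair_events": self.pair_events,
            "pair_hamming": self.pair_hamming,
        }
        return yaml.safe_dump(payload, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticTruth":
        d = yaml.safe_load(text)
        return cls(
            config=d["config"],
            partition=d.get("partition"),
            instances=[PlantedInstance(**i) for i in d.get("instances", [])],
            ir_mirrors=[PlantedInstance(**i) for i in d.get("ir_mirrors", [])],
            branch_events=d.get("branch_events", {}),
            pair_events=d.get("pair_events", {}),
            pair_hamming=d.get("pair_hamming", {}),
        )


@dataclass(frozen=True)
class DatedTree:
    """A newick tree whose branch lengths are in years."""

    newick: str

    def tree(self) -> dendropy.Tree:
        t = dendropy.Tree.get(data=self.newick, schema="newick")
        for edge in t.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("branch lengths must be >= 0")
        return t


def _config_dict(config: GeneratorConfig) -> dict:
    d = asdict(config)
    d["planted_repeats"] = [asdict(p) for p in config.planted_repeats]
    d["border_genes"] = [asdict(b) for b in config.border_genes]
    return d


def _region_bounds(config: GeneratorConfig, region: str) -> tuple[int, int]:
    lsc, ir, ssc = config.lsc_len, config.ir_len, config.ssc_len
    return {
        "LSC": (0, lsc),
        "IR": (lsc, lsc + ir),
        "SSC": (lsc + ir, lsc + ir + ssc),
        "any": (0, lsc + ir + ssc),
    }[region]


def _overlaps(start: int, end: int, occupied: list[tuple[int, int]]) -> bool:
    return any(start < e + _PAD and end > s - _PAD for s, e in occupied)


def _place_family(
    rng: np.random.Generator,
    spec: PlantSpec,
    bounds: tuple[int, int],
    occupied: list[tuple[int, int]],
) -> list[int]:
    lo, hi = bounds
    L = spec.repeat_len
    if spec.placement == "tandem":
        # keep the whole array compact enough that EVERY copy pair has an
        # end-to-start distance under 1000 bp, not just adjacent copies
        max_gap = (999 - (spec.n_copies - 2) * L) // max(1, spec.n_copies - 1)
        if max_gap < 1:
            raise PlacementError(
                f"tandem family {spec.family_id}: copies too long/numerous for "
                "all pairs to stay within the tandem threshold"
            )
        for _ in range(300):
            gaps = rng.integers(1, max_gap + 1, size=spec.n_copies - 1)
            span = spec.n_copies * L + int(gaps.sum())
            if hi - lo < span:
                continue
            s0 = int(rng.integers(lo, hi - span + 1))
            if _overlaps(s0, s0 + span, occupied):
                continue
            starts = [s0]
            for g in gaps:
                starts.append(starts[-1] + L + int(g))
            occupied.append((s0, s0 + span))
            return starts
        raise PlacementError(f"cannot place tandem family {spec.family_id}")
    starts: list[int] = []
    for _ in range(2000):
        if len(starts) == spec.n_copies:
            break
        s = int(rng.integers(lo, hi - L + 1))
        e = s + L
        if _overlaps(s, e, occupied):
            continue
        # dispersed: nearest-end distance >= 1000 bp from same-family copies
        if any(s < t + L + 1000 and e > t - 1000 for t in starts):
            continue
        starts.append(s)
        occupied.append((s, e))
    if len(starts) != spec.n_copies:
        raise PlacementError(f"cannot place dispersed family {spec.family_id}")
    return sorted(starts)


def _scan_clean(core: np.ndarray) -> bool:
    rec = PlastomeRecord(id="scan", sequence=decode(core), circular=False)
    return not find_maximal_repeats(rec, SearchParams())


def generate_plastome(
    config: GeneratorConfig,
) -> tuple[PlastomeRecord, FeatureSet, SyntheticTruth]:
    """Generate one quadripartite genome plus features and truth.

    The emitted sequence is LSC + IRa + SSC + IRb with IRb the exact
    reverse complement of IRa; identical configs (including seed) give
    byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    gc = config.gc_target
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    core_len = config.lsc_len + config.ir_len + config.ssc_len

    core = None
    for _ in range(25):
        draw = rng.choice(4, size=core_len, p=probs).astype(np.uint8)
        if not config.self_scan or _scan_clean(draw):
            core = draw
            break
    if core is None:
        raise PlacementError(
            "background keeps producing accidental repeats; gc_target too extreme?"
        )

    # reserve the bases that delimit the IR so no plant sits on them and
    # they can be resampled to stop the IR extending by chance
    lsc, ir, ssc = config.lsc_len, config.ir_len, config.ssc_len
    boundary = [0, lsc - 1, lsc + ir, core_len - 1]
    occupied: list[tuple[int, int]] = [(b, b + 1) for b in boundary]
    instances: list[PlantedInstance] = []
    for spec in config.planted_repeats:
        bounds = _region_bounds(config, spec.region)
        starts = _place_family(rng, spec, bounds, occupied)
        motif = rng.choice(4, size=spec.repeat_len, p=probs).astype(np.uint8)
        for idx, s in enumerate(starts):
            copy = motif.copy()
            strand = "forward"
            if spec.orientation == "palindromic" and idx % 2 == 1:
                copy = revcomp_codes(copy)
                strand = "revcomp"
            n_mut = spec.mismatches_per_copy if idx > 0 else 0
            if n_mut:
                sites = rng.choice(spec.repeat_len, size=n_mut, replace=False)
                for site in sites:
                    copy[site] = (copy[site] + rng.integers(1, 4)) % 4
            core[s : s + spec.repeat_len] = copy
            instances.append(
                PlantedInstance(
                    family_id=spec.family_id,
                    copy_index=idx,
                    start=int(s),
                    length=spec.repeat_len,
                    strand=strand,
                    mismatches=int(n_mut),
                )
            )

    # ensure the planted IR is exactly maximal: the bases flanking each
    # IR junction must not complement their mirror images
    for left, right in ((lsc - 1, 0), (lsc + ir, core_len - 1)):
        while core[left] == 3 - core[right]:
            core[left] = rng.integers(0, 4)

    n = config.total_len
    ira_codes = core[lsc : lsc + ir]
    genome = np.concatenate([core, revcomp_codes(ira_codes)])
    rec = PlastomeRecord(id=f"synthetic_seed{config.seed}", sequence=decode(genome))

    # planted copies inside IRa exist a second time, mirrored, in IRb
    mirrors = []
    irb_start = lsc + ir + ssc
    for inst in instances:
        if lsc <= inst.start and inst.start + inst.length <= lsc + ir:
            off = inst.start - lsc
            mstart = irb_start + (ir - off - inst.length)
            mirrors.append(
                PlantedInstance(
                    family_id=inst.family_id,
                    copy_index=inst.copy_index,
                    start=int(mstart),
                    length=inst.length,
                    strand="revcomp" if inst.strand == "forward" else "forward",
                    mismatches=inst.mismatches,
                )
            )

    for b in config.border_genes:
        if b.duplicated_extent > ir or b.total_len - b.duplicated_extent > lsc:
            raise ValueError(f"border gene {b.name} does not fit the genome")
    features = [
        Feature(
            name=b.name,
            interval=Interval(lsc - (b.total_len - b.duplicated_extent), lsc + b.duplicated_extent),
            strand="+",
            type="gene",
        )
        for b in config.border_genes
    ]

    truth = SyntheticTruth(
        config=_config_dict(config),
        partition={
            "lsc": [0, lsc],
            "ira": [lsc, lsc + ir],
            "ssc": [lsc + ir, lsc + ir + ssc],
            "irb": [irb_start, n],
        },
        instances=instances,
        ir_mirrors=mirrors,
    )
    return rec, FeatureSet(features), truth


def true_partition(truth: SyntheticTruth) -> QuadripartitePartition:
    """The generator's partition as a QuadripartitePartition object."""
    p = truth.partition
    n = p["irb"][1]
    return QuadripartitePartition(
        lsc=Interval(*p["lsc"]),
        ira=Interval(*p["ira"]),
        ssc=Interval(*p["ssc"]),
        irb=Interval(*p["irb"]),
        seq_len=n,
    )


def evolve_sequences(
    ancestor: PlastomeRecord | str,
    tree: DatedTree | str,
    rate: float,
    seed: int = 0,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Evolve an ancestor along a dated tree at ``rate`` subs/site/yr.

    Per branch, each site independently substitutes with probability
    rate x branch_years (at most once per branch), the new base drawn
    uniformly from the other three — an equal-rates Jukes–Cantor-style
    model linearized for the small per-branch divergences this package
    targets; realized pairwise differences between two tips separated
    by a total path of P years are Binomial(L, ~rate x P) up to the
    (tiny) chance of multiple hits on different branches. No indels, so
    tips remain aligned to the ancestor. Returns
    ({tip label: sequence}, truth) where truth holds realized
    substitution counts per branch and per tip pair plus the realized
    pairwise Hamming distances.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    seq = ancestor.sequence if isinstance(ancestor, PlastomeRecord) else ancestor
    if not seq:
        raise ValueError("empty ancestor sequence")
    dtree = tree if isinstance(tree, DatedTree) else DatedTree(tree)
    t = dtree.tree()
    rng = np.random.default_rng(seed)

    from ._seqcodes import encode

    root_codes = encode(seq)
    L = root_codes.size
    node_seq: dict[int, np.ndarray] = {id(t.seed_node): root_codes}
    branch_events: dict[str, int] = {}
    node_path: dict[int, dict[str, int]] = {id(t.seed_node): {}}

    counter = 0
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        parent_codes = node_seq[id(node.parent_node)]
        years = node.edge.length or 0.0
        p = rate * years
        if p > 1.0:
            raise ValueError(
                f"rate x branch length = {p:.3g} exceeds 1; "
                "split long branches or lower the rate"
            )
        child = parent_codes.copy()
        hit = (rng.random(L) < p) & (child < 4)
        sites = np.flatnonzero(hit)
        total = int(sites.size)
        if total:
            child[sites] = (child[sites] + rng.integers(1, 4, size=total).astype(np.uint8)) % 4
        label = node.taxon.label if node.taxon else f"node{counter}"
        counter += 1
        branch_events[label] = total
        node_seq[id(node)] = child
        path = dict(node_path[id(node.parent_node)])
        path[label] = total
        node_path[id(node)] = path

    tips = {}
    tip_paths = {}
    for leaf in t.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else "tip"
        tips[label] = decode(node_seq[id(leaf)])
        tip_paths[label] = node_path[id(leaf)]

    pair_events: dict[str, int] = {}
    pair_hamming: dict[str, int] = {}
    labels = sorted(tips)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            pa, pb = tip_paths[a], tip_paths[b]
            shared = set(pa) & set(pb)
            ev = sum(v for k, v in pa.items() if k not in shared) + sum(
                v for k, v in pb.items() if k not in shared
            )
            key = f"{a}|{b}"
            pair_events[key] = ev
            ca, cb = encode(tips[a]), encode(tips[b])
            pair_hamming[key] = int((ca != cb).sum())

    truth = SyntheticTruth(
        config={"rate": rate, "seed": seed, "newick": dtree.newick, "length": int(L)},
        branch_events=branch_events,
        pair_events=pair_events,
        pair_hamming=pair_hamming,
    )
    return tips, truth
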