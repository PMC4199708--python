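# Methods

This note records the models, definitions and numerical choices behind
`plastomics`, including the places where the design was genuinely open
and what the synthetic-data tests do and do not demonstrate.

## Quadripartite structure detection

The partition is defined operationally: the IR is the longest pair of
reverse-complementary, circularly disjoint segments of the genome, each
at least `min_ir_len` (default 10 kb, safely below real plastome IRs of
~25 kb yet far above any chance match); the longer remaining arc is the
LSC and the shorter the SSC, read in the canonical order
LSC → IRa → SSC → IRb (IRa is the copy followed by the SSC).

Detection is exact-match by default. Plastome IRs are essentially
perfect duplications, and exactness yields a crisp, brute-force
checkable contract; a mismatch-tolerant extension exists behind
`max_mismatch` for divergent IRs but is off by default. Matching uses
31-mer anchors between the sequence and its reverse complement
(packed 2-bit codes in an int64), extended to maximal runs; for
circular records the search runs on the doubled sequence so an IR copy
may span the linearization origin, with candidates deduplicated modulo
the genome length. Ties on IR length break toward the smaller start
coordinate of the first copy, making the output deterministic.

Segment assignment always treats the sequence as a circle — a
linearized plastome usually splits one single-copy region across the
origin — while the record's `circular` flag only governs whether an IR
copy itself may wrap. If no qualifying IR exists (the situation in
lineages that lost one IR copy), detection raises a dedicated error
rather than inventing a partition. Records can be normalized to start
at a trnH feature when one is annotated, else at the detected LSC
start.

GC content is (G+C)/(A+C+G+T) with ambiguity codes excluded from both
numerator and denominator, reported optionally at 3 decimals for
summary-table parity. Border-gene extents are the bases of the feature
interval inside IRa ∪ IRb, origin-aware.

## Maximal approximate repeats

The screen looks for direct and palindromic (reverse-complement)
repeat pairs under a Hamming model: length ≥ 30 bp at ≥ 90% identity,
i.e. at most 3 mismatches — the two formulations coincide exactly at
30 bp. Indels are out of scope by design; the downstream statistics
operate on fixed alignments and treat indels separately.

**Canonical output.** Classic screening tools emit heavily redundant
listings (nested lengths at one position, every pairwise combination of
a multi-copy family). To give downstream consolidation a deterministic,
testable input, the finder reports each locus pair once, in a canonical
trimmed form: a reported pair is a *mismatch-flanked minimal span* —
bounded on both ends by a mismatch or the sequence end, carrying at
most `max_mismatch` internal mismatches, at least `min_len` long, and
containing no proper sub-span with the same properties. An isolated
planted copy pair is thus reported exactly once with its true internal
mismatch count; distinct nearby repeat cores can still produce
overlapping listings, which consolidation then merges. Tandem copies
may overlap, and a perfect palindrome that mirrors onto itself is
reported once. Ambiguity codes never match anything, themselves
included, so N-runs cannot seed spurious hits.

**Search.** Pigeonhole seed-and-extend: a window of length m with at
most k mismatches is cut by them into at most k+1 exact runs covering
m−k bases, so it must contain an exact run of length
q = ⌈(m−k)/(k+1)⌉ (7 for the 30/3 default — note the bound uses m−k,
not m, in the numerator). All shared q-mers between the sequence and
itself (direct; diagonals) or its reverse complement (palindromic;
antidiagonals) are seeds; abutting seeds on one (anti)diagonal collapse
to a chain head; a vectorized prefilter (sliding mismatch counts over a
local patch, sequence ends costed as k+1) discards spurious seeds
exactly — it can produce false positives but never false negatives —
and only surviving candidates pay for full span enumeration. The test
suite checks the whole path against an exhaustive per-diagonal
enumeration that shares none of the seeding machinery.

A caveat recorded deliberately: "raising `min_len` or lowering
`max_mismatch` never increases the number of reported pairs" holds on
realistic inputs (isolated repeats in non-repetitive background) and is
tested there, but adversarial arrangements of closely spaced repeat
cores can violate it under any single-listing output convention,
because loosening one knob can fuse two listings into one.

## Repeat consolidation ("deflation")

Raw pairs are post-processed in a fixed order:

1. **Tandem vs dispersed.** A pair is tandem when the gap from the end
   of its first copy to the start of its second is < 1000 bp
   (overlapping copies ⇒ tandem). Nearest-edge distance is the
   strictest reading of "within 1000 bp" and handles overlaps
   naturally.
2. **IR filtering** (pair level, before clustering). Dispersed pairs
   whose copies both lie entirely inside IRa ∪ IRb are discarded — they
   restate the IR duplication; pairs with at least one copy touching a
   single-copy region are kept.
3. **Same-locus merging.** Instances merge when one interval contains
   the other or they overlap by ≥ 80% of the shorter — this absorbs the
   nested-length listings and 1–2 bp end jitter; the longest instance
   represents the locus.
4. **Family clustering.** Single-linkage at ≥ 90% ungapped identity
   over the shorter member (best offset, overhangs allowed,
   reverse-complement aware). The 0.90 threshold mirrors the search
   identity and is an exposed parameter; the original interactive
   assembly-based grouping it replaces did not state one. Families are
   labelled R1, R2, … by descending location count then leftmost
   position, making output independent of input order.
5. **Summary.** Raw pair count, tandem pair count, and the deflated
   dispersed unique-location and unique-sequence counts.

Family representatives are majority consensus over members aligned
ungapped to the longest member, with IUPAC codes on ties (so an A/C tie
prints M). This consensus-calling is a pragmatic choice, adequate for
labelling families, not a profile alignment.

## Synthetic plastomes and ground truth

The generator emits LSC + IRa + SSC + IRb with IRb the exact reverse
complement of IRa. Default dimensions are a typical perennial wild-soy
plastome — LSC 83,844, SSC 17,840, IR 25,555 bp at GC 0.353; the tests
and acceptance script run the architecture scaled down (e.g. LSC 20 kb
/ SSC 4 kb / IR 6 kb) to keep dozens of replicates cheap, which leaves
every ratio and algorithmic code path intact.

Background sequence is i.i.d. with per-base probabilities set by the GC
target. The chance of an accidental ≥ 30 bp, ≤ 3-mismatch repeat in
such background is of order 10⁻³ at plastome scale; a post-generation
self-scan (the repeat finder itself, run on the single-copy core before
the IR is appended) rejects and regenerates any unlucky draw, so the
truth record is exhaustive. The four bases delimiting the IR junctions
are reserved and resampled so chance complements cannot extend the IR
past its configured boundary — without this, roughly half of generated
genomes have a true maximal IR one or two bases longer than configured,
which is correct behavior of the detector but noise for truth
comparison.

Planted families place non-overlapping copies (50 bp clearance from
other elements) with dispersed copies ≥ 1000 bp apart edge-to-edge and
tandem arrays compact enough that *every* copy pair, not only adjacent
ones, stays under the tandem threshold. Palindromic families alternate
strand between copies; each copy after the first receives exactly
`mismatches_per_copy` substitutions (so two mutated copies can be up to
twice that apart — keep 2 × `mismatches_per_copy` ≤ `max_mismatch` when
the pair itself must stay detectable). Copies planted in IRa are
mirrored into IRb by construction; the truth file records these mirror
instances explicitly. Border genes straddle the LSC/IRa junction with a
configured duplicated extent. Truth serializes to YAML and round-trips
losslessly.

**Evolution.** `evolve_sequences` walks a dated newick tree (branch
lengths in years, parsed by dendropy). Per branch, each site
independently substitutes with probability rate × years, at most once,
the new base uniform over the other three — an equal-rates
Jukes–Cantor-style model linearized for small per-branch divergences
(it refuses rate × years > 1). No indels, so tips stay aligned by
construction. Realized pairwise differences between tips whose paths
total P years are Binomial(L, ≈ rate × P), with only the tiny
cross-branch collision term (≈ λ²) separating them from the nominal
expectation; the rate-recovery experiments use an ancestor–descendant
pair (one zero-length branch), for which the S/(L·T) estimator is
exactly unbiased under the model. Truth records realized substitution
counts per branch and per tip pair plus realized Hamming distances.

What the generator does **not** emulate: real gene content and intron
structure, rate heterogeneity among sites or lineages, indels,
base-compositional heterogeneity along the genome, and the
low-complexity/SSR repeat classes of real plastomes. Passing tests
therefore demonstrate correctness of the measurement machinery on
clean, fully specified inputs — not robustness to annotation errors or
alignment artifacts in real data.

## Diversity and substitution rates

Columns count toward a pair only when both rows carry an unambiguous
A/C/G/T (pairwise deletion); a SNP is a compared column whose bases
differ. For two sequences π = S/L exactly; for more, π is the plain
mean of per-pair values, without finite-sample corrections (the
convention is recorded here rather than in output metadata). No
multiple-hit correction is applied anywhere: at the divergences this
package targets (π ~ 10⁻³–10⁻²) the JC correction is an order of
magnitude below sampling error.

Rates divide by T, the divergence time in years: r = S / (L × T).
Back-calculation from published whole-plastome comparisons (e.g.
~2,000 SNPs at 5.25 Myr giving ~2.5 × 10⁻⁹ with L ≈ the ~158 kb
alignment) shows the T convention, not 2T, is what such tables use;
the per-lineage 2T convention is available via `per_lineage=True`.
Calibration times are explicit caller input (a `CalibrationTable`
keyed by unordered taxon pair), since which node date belongs to which
pair is a scientific decision, not something the package should guess.

The rate matrix prints SNPs above the diagonal and rates below. A pair
is flagged as a chloroplast-capture candidate when its rate falls below
0.5 × the median rate of all other pairs involving either of its taxa.
The reference set is the matrix row *and* column of the cell rather
than the printed row alone, because with small taxon sets a literal
row can contain a single cell — its own median — and could never flag;
the row+column reading is equivalent in spirit and remains well-defined
from three taxa upward. The 0.5 factor is exposed as `flag_factor`.

Windowed identity against a chosen reference row (default window
100 columns, step 25) is matches / comparable columns per window, NaN
when a window has no comparable column; a window longer than the
alignment collapses to one full-length window. This reproduces the
logic of sequence-similarity plots without any plotting dependency.

## Numerical and interface conventions

- Coordinates are 0-based half-open internally; GFF3 I/O converts to
  1-based inclusive, BED output stays 0-based half-open, and TSV repeat
  tables print 1-based positions.
- All randomness flows from integer seeds through
  `numpy.random.default_rng`; identical config + seed reproduces
  byte-identical artifacts, and the CLI stamps every table with the
  package version and a SHA-256 parameter digest.
- Intervals on circular sequences may wrap (end > sequence length,
  positions mod n); overlap arithmetic is origin-aware throughout.
- The genome is treated as linear during repeat search (matching the
  conventions of the classic tools); IR detection is the only stage
  that searches across the origin.

## Known limitations

- The repeat search is Hamming-only; diverged repeats containing indels
  are found, if at all, as separate shorter loci.
- Family consensus calling is heuristic (ungapped, longest-member
  frame) and is validated only for the clustering decisions it
  supports, not as a motif model.
- Real-data structure values (segment lengths, border-gene extents, GC)
  depend on the assembly and annotation conventions of the input
  records; digit-exact agreement with published tables additionally
  requires the same alignment and gap treatment those tables used,
  which published methods do not always specify.
- The evolver's linearized substitution model is intentionally invalid
  for rate × branch length approaching 1; it targets the ≪ 0.05
  per-site divergences of congeneric plastomes.
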