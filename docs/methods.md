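# Methods

## Detection model

`l1pd` treats a full-length L1 as a *spatial constellation* of conserved
k-mers rather than as an alignable sequence. A probe set is an ordered
list of non-overlapping k-mers, each with an offset from the first base
of ORF1; the probes act as a template that a surviving full-length copy
must reproduce up to point mutations (bounded by the edit distance e) and
indel drift (bounded by the distance threshold t). The assumptions are:

- the target elements retain most of both ORFs (5'-truncated copies,
  the majority of genomic L1s, are deliberately *not* targets);
- divergence since the family consensus is small enough that at least m
  probes still match within e edits;
- indels between consecutive matched probes displace spacings by at
  most t.

### Mapping

The built-in mapper computes, for every genomic end position, the best
semi-global edit distance of the probe against any window ending there
(Sellers dynamic programming, one numpy row per probe base; the
within-row "gap in the probe" dependency is resolved with a prefix-minimum
scan, so the whole row costs a constant number of array passes).
Minus-strand hits are found by mapping the reverse complement of the
probe and reported in forward coordinates. `N` never matches a probe base:
assembly gaps cannot seed hits.

A single diverged locus yields a run of qualifying end positions, one per
co-optimal alignment. These are collapsed to one hit per locus: ends
within e of each other (transitively) form one locus, represented by the
minimal edit distance and, among tied ends, the leftmost achievable
window start (recovered with a reversed prefix-anchored edlib alignment).
Without this collapse a diverged locus would contribute a smear of
near-duplicate hits and inflate pattern counts.

The mapper's correctness bar is equivalence with a brute-force
window-sweep oracle (tests), not any particular algorithm. Mapping cost
is O(k·n) per probe and strand, so a probe panel costs roughly
(total probe bases) × genome length; panels are mapped in batches to
amortize array overhead.

### Chaining

Hits are chained per (chromosome, strand). On the minus strand each hit
is keyed by −(pos + matched_len): ordering and pairwise gaps then behave
exactly as on the plus strand of the reverse complement, without needing
the chromosome length. A chain is valid when probe indices strictly
increase, keys strictly increase, and every *consecutive* pair satisfies
the distance predicate. The consecutive-pair form (default) tolerates
cumulative indel drift along a 6 kb element; an anchor-relative variant
(every member constrained against the chain's first hit) is available as
`DetectionParams(gap_mode="anchor")` for users who want a rigid template.

Among valid chains the implementation returns the optimum under the
priority (maximum probe count, minimum summed gap deviation, leftmost,
then lexicographically smallest hit sequence), found by longest-path
dynamic programming over the hit DAG — a single state per hit suffices
because chain extensibility depends only on the last hit, so a longer
chain ending at the same hit dominates. Accepted chains consume their
hits and extraction repeats until no chain reaches m. An exhaustive
enumeration oracle asserts equivalence on small instances; greedy
nearest-expected extension was rejected because it cannot guarantee the
maximum-cardinality optimum this priority requires.

Patterns whose projected element intervals overlap a better pattern's
interval by more than 50% of the shorter are suppressed (priority: more
probes, smaller gap error, leftmost). Deduplication is strand-blind, so a
shadow pattern of the same locus on the other strand cannot double-call
an element.

### Boundary extrapolation

Component lengths vary between species, so the detector derives them from
the metadata CSV as per-component **modes** (most common value; ties
resolved to the smallest tied value for determinism across platforms).
The mode of the *total* length is computed independently rather than as
the sum of component modes — the sum of modes is not the mode of sums.
With anchor probe offset o and hit position h (0-based), plus-strand
calls span `[h − o − mode(5'UTR), … + mode(total) − 1]`, mirrored on the
minus strand from the hit's right edge; coordinates are clamped to the
chromosome and emitted 1-based inclusive in GFF3. The GFF3 attribute is
written `Name=LINE1` without padding, as tag=value syntax requires.

## Probe generation

Per-ORF alignments are reduced to a per-column majority consensus; a
column qualifies when the majority base's frequency over all rows (gaps
count in the denominator, never as consensus) reaches the identity
threshold (default 0.95). Candidates are all k-windows of consecutive
qualifying positions (stride 1 — the final non-overlap step handles
packing, and stride 1 keeps the hit-count ordering meaningful).
Refinement maps every candidate genome-wide at a small edit distance
(`e_map`, default 2 — universality should be a strict test) and keeps
candidates with a hit inside the annotated genomic interval of their
source ORF in at least one element, then only those with a hit inside
the corresponding ORF interval of *every* element. Interval membership is
positional containment with `e_map` bp of slack per edge (a boundary
indel must not disqualify an interior hit) and ignores hit strand.
Survivors are ordered by ascending genome-wide hit count (fewer hits,
fewer false positives; ties to the smaller offset) and accepted greedily
subject to non-overlap. Greedy selection is deterministic but not
guaranteed maximal — the tests assert validity and reproducibility, not
optimality. An empty survivor set raises an explicit "no universal
probes" error suggesting a lower identity or k, rather than silently
emitting a weak panel. ORF2 offsets are shifted into the ORF1-anchored
frame by the modal ORF1-start→ORF2-start distance; how to merge the two
per-ORF coordinate systems was an open design point and this modal shift
is this package's own definition.

Inputs must be pre-aligned (any MSA program's FASTA output); the package
does not invoke aligners.

## Evaluation

A call is a true positive when it can be matched one-to-one to a truth
element of the same strand that it overlaps by ≥ 50% of the truth
element's length (both the fraction and strand enforcement are flags;
the 50% one-to-one rule is this package's definition — reasonable
alternatives exist and results should cite the criterion used). With zero
denominators, precision, recall and F1 are defined as 0 so parameter
sweeps stay total at extreme settings. The sweep recomputes the hit table
once per distinct e and selects the argmax-F1 row (ties: higher
precision, then lower e).

## The simulator

`synthdata` generates the complete study fixture: one ancestral element
with the human-like architecture 5'UTR 909, ORF1 1017, spacer 63,
ORF2 3828, 3'UTR 205 bp (6022 bp total); 30 intact descendant copies
(default) at 1% substitutions and 0.1% indels (geometric lengths,
mean 2), five 5'-truncated copies (uniform 50–90% of the element removed
from the 5' end — always the whole 5'UTR and at least part of ORF1);
all planted on random strands in 250 kb of i.i.d. background at GC 0.42.
Because the full mutation history is recorded, the truth is exact: the
per-ORF MSA is *reconstructed* from the history (each insertion gets its
own columns), the metadata CSV coordinates bound each planted copy
exactly, and `mutation_audit` recounts events independently of the log.

What the simulator does **not** emulate: target-site duplications, poly-A
tails, subfamily phylogenies (all copies descend from one ancestor at one
divergence), nested insertions, GC isochores or repeat-rich background.
Passing the planted-recovery tests therefore demonstrates the machinery
is correct under the stated divergence model, not that field performance
on real genomes will match; real assemblies contain old, fragmented L1
relics and segmental duplications that only the full probe-refinement
step (small hit counts, universality) defends against.

Fixture-scale detection parameters are derived from the planted
divergence rather than the shipped per-species defaults: at 1%
substitutions a 50-mer expects 0.5 edits (e = 5 gives generous margin),
per-gap indel drift is a few bases (t = 100), and m = 70% of the panel is
comfortably below intact copies' support but above what a ≥ 50%-truncated
copy can retain. The replicate sizes used by the test-suite and
acceptance script (10 seeds × 30 copies, 250 kb genomes) were chosen to
give stable rate estimates at desk scale.

## Numerical and degenerate-input choices

- Internal coordinates are 0-based half-open everywhere; conversion to
  1-based inclusive happens only at the GFF3/CSV boundary.
- All mode computations break ties toward the smallest value.
- Hit-collapse ties break toward the leftmost start, then leftmost end.
- Chain ties break leftmost, then by lexicographic hit sequence.
- Metadata rows with any empty required field are skipped and counted,
  never guessed; a file with zero complete rows is an error.
- SAM records lacking NM are imported at edit distance 0 with a warning
  (tolerating minimal emitters); unmapped records are dropped; *no*
  secondary-alignment suppression is applied.
- Boundary extrapolation clamps to the chromosome rather than erroring
  near contig edges.
- The L1Base2-style CSV schema (chrom, l1_start, l1_end, strand, and
  element-relative 1-based component intervals) is this package's own
  documented emulation; the native export layout is not reproduced.

## Known limitations

- Truncated and heavily rearranged elements are out of scope by design;
  recall is defined over full-length intact elements only.
- The chaining optimum is per-(chromosome, strand) and hit-consuming;
  overlapping *nested* full-length elements would compete for hits.
- Probe generation at high k and high identity can legitimately fail on
  small or diverged families (the explicit no-universal-probes error);
  automatic search for a feasible k is not implemented.
- The mapper is exact but O(k·n) per probe; for chromosome-scale genomes
  with large panels, importing mappings from a dedicated read mapper via
  SAM may be preferable.
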