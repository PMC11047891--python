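"""The detection core: chain probe hits that occur in probe order at the
expected spacings into L1 calls.

A full-length element leaves a constellation of probe hits whose order and
pairwise gaps mirror the probe offsets. Chaining finds, per chromosome and
strand, the best constellations under three knobs: the mapping edit
distance e, the distance threshold t (allowed deviation between an
observed inter-hit gap and the gap the probe offsets predict), and the
minimum number m of matched probes per pattern.

Chains are scored by maximum probe count, then minimum summed gap
deviation, then leftmost position; accepted chains consume their hits and
chaining repeats until no chain of >= m probes remains. Minus-strand hits
are chained in the reverse-complement frame via the coordinate key
-(pos + matched_len), which preserves probe order and gaps without
needing the chromosome length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .mapper import HitTable, ProbeHit, map_probeset
from .seqio import ComponentLengthModel, L1AnnotationRecord, ProbeRecord, length_modes

#: Default (edit distance, distance threshold, min probes) per (species, k).
DEFAULT_PARAMS: dict[tuple[str, int], tuple[int, int, int]] = {
    ("human", 50): (15, 625, 18),
    ("human", 75): (30, 625, 17),
    ("human", 100): (30, 600, 9),
}


@dataclass(frozen=True)
class DetectionParams:
    """User-tunable detection knobs.

    ``gap_mode`` selects whether the distance predicate constrains each
    consecutive pair of matched probes (default; tolerates cumulative
    indel drift along the element) or every member against the pattern
    anchor.
    """

    e: int
    t: int
    m: int
    gap_mode: str = "consecutive"

    def __post_init__(self) -> None:
        if self.e < 0 or self.t < 0:
            raise ValueError("e and t must be >= 0")
        if self.m < 2:
            raise ValueError("min probes m must be >= 2")
        if self.gap_mode not in ("consecutive", "anchor"):
            raise ValueError(f"unknown gap_mode {self.gap_mode!r}")

    @classmethod
    def for_species(cls, species: str, k: int) -> "DetectionParams":
        try:
            e, t, m = DEFAULT_PARAMS[(species.lower(), k)]
        except KeyError:
            raise KeyError(
                f"no default parameters for species={species!r}, k={k}; "
                "pass e/t/m explicitly"
            ) from None
        return cls(e=e, t=t, m=m)


@dataclass
class Pattern:
    """An accepted chain of probe hits on one chromosome and strand."""

    chrom: str
    strand: str
    members: list[tuple[int, ProbeHit]]  # (probe index, hit), probe index ascending
    gap_error_sum: int
    projected_interval: Optional[tuple[int, int]] = field(default=None, compare=False)

    @property
    def n_probes(self) -> int:
        return len(self.members)

    @property
    def anchor_pos(self) -> int:
        """0-based genomic position of the leftmost hit (forward coords)."""
        return min(h.pos for _, h in self.members)

    def hit_span(self) -> tuple[int, int]:
        """0-based half-open interval covered by the member hits."""
        return (
            min(h.pos for _, h in self.members),
            max(h.end for _, h in self.members),
        )


@dataclass(frozen=True)
class L1Call:
    """A detected element, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    n_probes: int
    gap_error_sum: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid call bounds {self.start}..{self.end}")


def distance_ok(
    hit_i: ProbeHit,
    hit_j: ProbeHit,
    probe_i: ProbeRecord,
    probe_j: ProbeRecord,
    t: int,
) -> bool:
    """Is the observed gap between two hits within t of the expected gap?

    Expected gap = difference of probe offsets; observed = difference of
    hit positions (forward-strand orientation assumed: probe_i before
    probe_j and hit_i left of hit_j).
    """
    observed = hit_j.pos - hit_i.pos
    expected = probe_j.offset - probe_i.offset
    return abs(observed - expected) <= t


def _strand_key(hit: ProbeHit, strand: str) -> int:
    """Position key under which probe order is ascending on either strand."""
    return hit.pos if strand == "+" else -(hit.pos + hit.matched_len)


class _Node:
    __slots__ = ("key", "probe_idx", "hit", "consumed")

    def __init__(self, key: int, probe_idx: int, hit: ProbeHit):
        self.key = key
        self.probe_idx = probe_idx
        self.hit = hit
        self.consumed = False


def _best_chain_consecutive(
    nodes: list[_Node], edges: list[list[tuple[int, int]]]
) -> Optional[tuple[int, int, tuple[int, ...]]]:
    """Best chain under (max length, min gap error, leftmost) among live nodes.

    ``edges[i]`` lists (pred_index, gap_err). Nodes are index-sorted by
    (key, probe_idx), so lexicographic comparison of node-index tuples is
    the leftmost tie-break. Returns (length, gap, chain) or None.
    """
    best_at: list[Optional[tuple[int, int, tuple[int, ...]]]] = [None] * len(nodes)
    overall: Optional[tuple[int, int, tuple[int, ...]]] = None
    for i, node in enumerate(nodes):
        if node.consumed:
            continue
        cand = (1, 0, (i,))
        for j, err in edges[i]:
            prev = best_at[j]
            if prev is None:
                continue
            ext = (prev[0] + 1, prev[1] + err, prev[2] + (i,))
            if _chain_key(ext) < _chain_key(cand):
                cand = ext
        best_at[i] = cand
        if overall is None or _chain_key(cand) < _chain_key(overall):
            overall = cand
    return overall


def _chain_key(chain: tuple[int, int, tuple[int, ...]]):
    length, gap, seq = chain
    return (-length, gap, seq)


def _best_chain_anchor(
    nodes: list[_Node], probes: Sequence[ProbeRecord], t: int
) -> Optional[tuple[int, int, tuple[int, ...]]]:
    """Best chain when every member is constrained against the anchor.

    Quadratic per anchor; intended for modest hit counts.
    """
    overall = None
    live = [i for i, n in enumerate(nodes) if not n.consumed]
    for a_pos, a in enumerate(live):
        na = nodes[a]
        elig = [
            i
            for i in live[a_pos + 1 :]
            if nodes[i].probe_idx > na.probe_idx
            and nodes[i].key > na.key
            and abs(
                (nodes[i].key - na.key)
                - (probes[nodes[i].probe_idx].offset - probes[na.probe_idx].offset)
            )
            <= t
        ]
        order = [a] + elig
        best_at: list[Optional[tuple[int, int, tuple[int, ...]]]] = [None] * len(order)
        best_at[0] = (1, 0, (a,))
        for pi in range(1, len(order)):
            i = order[pi]
            ni = nodes[i]
            cand = None
            for pj in range(pi):
                j = order[pj]
                prev = best_at[pj]
                if prev is None or nodes[j].probe_idx >= ni.probe_idx:
                    continue
                if nodes[j].key >= ni.key:
                    continue
                err = abs(
                    (ni.key - nodes[j].key)
                    - (probes[ni.probe_idx].offset - probes[nodes[j].probe_idx].offset)
                )
                ext = (prev[0] + 1, prev[1] + err, prev[2] + (i,))
                if cand is None or _chain_key(ext) < _chain_key(cand):
                    cand = ext
            best_at[pi] = cand
            if cand is not None and (
                overall is None or _chain_key(cand) < _chain_key(overall)
            ):
                overall = cand
        if overall is None or _chain_key(best_at[0]) < _chain_key(overall):
            overall = best_at[0]
    return overall


def chain_hits(
    table: HitTable, probes: Sequence[ProbeRecord], params: DetectionParams
) -> list[Pattern]:
    """Chain probe hits into patterns of >= m probes, per (chrom, strand).

    Repeatedly extracts the best remaining chain (max probe count, then
    min gap_error_sum, then leftmost), consuming its hits, until no chain
    reaches m members.
    """
    probe_order = {p.probe_id: i for i, p in enumerate(probes)}
    max_exp = probes[-1].offset - probes[0].offset if probes else 0
    patterns: list[Pattern] = []
    for (chrom, strand), hits in table.groups.items():
        nodes = [
            _Node(_strand_key(h, strand), probe_order[h.probe_id], h)
            for h in hits
            if h.probe_id in probe_order
        ]
        nodes.sort(key=lambda n: (n.key, n.probe_idx))
        if params.gap_mode == "consecutive":
            edges: list[list[tuple[int, int]]] = [[] for _ in nodes]
            for i, ni in enumerate(nodes):
                j = i - 1
                while j >= 0 and ni.key - nodes[j].key <= max_exp + params.t:
                    nj = nodes[j]
                    if nj.probe_idx < ni.probe_idx and nj.key < ni.key:
                        err = abs(
                            (ni.key - nj.key)
                            - (
                                probes[ni.probe_idx].offset
                                - probes[nj.probe_idx].offset
                            )
                        )
                        if err <= params.t:
                            edges[i].append((j, err))
                    j -= 1
        while True:
            if params.gap_mode == "consecutive":
                # drop edges into consumed nodes lazily inside the DP
                live_edges = [
                    [(j, err) for j, err in edges[i] if not nodes[j].consumed]
                    for i in range(len(nodes))
                ]
                best = _best_chain_consecutive(nodes, live_edges)
            else:
                best = _best_chain_anchor(nodes, probes, params.t)
            if best is None or best[0] < params.m:
                break
            length, gap, seq = best
            members = [(nodes[i].probe_idx, nodes[i].hit) for i in seq]
            patterns.append(
                Pattern(chrom=chrom, strand=strand, members=members, gap_error_sum=gap)
            )
            for i in seq:
                nodes[i].consumed = True
    return patterns


def dedupe_patterns(patterns: list[Pattern]) -> list[Pattern]:
    """Suppress patterns matched to an already-retained element.

    A pattern is suppressed when its projected call interval overlaps a
    retained pattern's interval by more than 50% of the shorter interval.
    Retention priority: more probes, then smaller gap_error_sum, then
    leftmost. Uses the raw hit span when no projected interval is attached.
    """

    def interval(p: Pattern) -> tuple[int, int]:
        return p.projected_interval if p.projected_interval else p.hit_span()

    ranked = sorted(
        patterns,
        key=lambda p: (-p.n_probes, p.gap_error_sum, interval(p)[0], p.strand),
    )
    kept: list[Pattern] = []
    for p in ranked:
        s, e = interval(p)
        duplicate = False
        for q in kept:
            if q.chrom != p.chrom:
                continue
            qs, qe = interval(q)
            overlap = min(e, qe) - max(s, qs)
            shorter = min(e - s, qe - qs)
            if shorter > 0 and overlap > 0.5 * shorter:
                duplicate = True
                break
        if not duplicate:
            kept.append(p)
    kept.sort(key=lambda p: (p.chrom, interval(p)[0], p.strand))
    return kept


def call_from_pattern(
    p: Pattern,
    probes: Sequence[ProbeRecord],
    model: ComponentLengthModel,
    chrom_len: int,
) -> L1Call:
    """Extrapolate element boundaries from the pattern's anchor probe.

    The anchor (lowest-index matched probe) sits mode_5utr + offset bases
    into the element; the element spans mode_total bases. Coordinates are
    clamped to the chromosome and reported 1-based inclusive.
    """
    probe_idx, hit = min(p.members, key=lambda m: m[0])
    offset = probes[probe_idx].offset
    if p.strand == "+":
        start0 = hit.pos - offset - model.mode_5utr
        end0 = start0 + model.mode_total - 1
    else:
        end0 = (hit.pos + hit.matched_len - 1) + offset + model.mode_5utr
        start0 = end0 - model.mode_total + 1
    start0 = max(0, min(start0, chrom_len - 1))
    end0 = max(0, min(end0, chrom_len - 1))
    return L1Call(
        chrom=p.chrom,
        start=start0 + 1,
        end=end0 + 1,
        strand=p.strand,
        n_probes=p.n_probes,
        gap_error_sum=p.gap_error_sum,
    )


def detect(
    genome: dict[str, str],
    probes: Sequence[ProbeRecord],
    meta: Sequence[L1AnnotationRecord],
    params: DetectionParams,
    hit_table: Optional[HitTable] = None,
) -> list[L1Call]:
    """End-to-end detection: map (or import) -> chain -> dedupe -> call."""
    model = length_modes(meta)
    if hit_table is None:
        hit_table = map_probeset(genome, probes, params.e)
    patterns = chain_hits(hit_table, probes, params)
    for p in patterns:
        call = call_from_pattern(p, probes, model, len(genome[p.chrom]))
        p.projected_interval = (call.start - 1, call.end)
    retained = dedupe_patterns(patterns)
    calls = [
        call_from_pattern(p, probes, model, len(genome[p.chrom])) for p in retained
    ]
    calls.sort(key=lambda c: (c.chrom, c.start, c.end))
    return calls
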