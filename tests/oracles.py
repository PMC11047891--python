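"""Independent reference implementations used to verify the package.

These deliberately avoid the package's own algorithms: the mapping oracle
sweeps every window with edlib global alignments; the chaining oracle
enumerates every valid chain; ORF-interval membership is tested directly
with edlib on the annotated segment.
"""

from __future__ import annotations

import edlib

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_hits(text: str, probe: str, e_max: int) -> list[tuple[int, int, int]]:
    """All collapsed probe occurrences by exhaustive window sweep.

    For each end position, the best global edit distance over all window
    lengths within e_max of k; qualifying ends within e_max of each other
    form one locus reported as (leftmost-start alignment of the minimal
    distance). Mirrors the mapping contract, computed independently.
    """
    k = len(probe)
    n = len(text)
    end_dist: dict[int, int] = {}
    for end in range(1, n + 1):
        best = None
        for ln in range(max(0, k - e_max), min(end, k + e_max) + 1):
            d = edlib.align(probe, text[end - ln : end], mode="NW")["editDistance"]
            if best is None or d < best:
                best = d
        if best is not None and best <= e_max:
            end_dist[end] = best

    ends = sorted(end_dist)
    hits = []
    cluster: list[int] = []
    for end in ends:
        if cluster and end - cluster[-1] > max(e_max, 0):
            hits.append(_locus_hit(text, probe, cluster, end_dist))
            cluster = []
        cluster.append(end)
    if cluster:
        hits.append(_locus_hit(text, probe, cluster, end_dist))
    hits.sort()
    return hits


def _locus_hit(text, probe, cluster, end_dist):
    dmin = min(end_dist[e] for e in cluster)
    k = len(probe)
    best = None
    for end in cluster:
        if end_dist[end] != dmin:
            continue
        for s in range(max(0, end - k - dmin), end - (k - dmin) + 1):
            if edlib.align(probe, text[s:end], mode="NW")["editDistance"] == dmin:
                cand = (s, end)
                if best is None or cand < best:
                    best = cand
                break  # leftmost start for this end found
    s, end = best
    return (s, dmin, end - s)


def _strand_key(hit, strand: str) -> int:
    return hit.pos if strand == "+" else -(hit.pos + hit.matched_len)


def enumerate_patterns(table, probes, t: int, m: int):
    """Exhaustive chaining oracle (consecutive-gap mode).

    Enumerates every chain (increasing key and probe index, each
    consecutive pair's gap deviation <= t), repeatedly accepts the best by
    (max cardinality, min gap error, leftmost) and consumes its hits.
    Returns patterns as (chrom, strand, ((probe_id, pos), ...), gap) tuples.
    """
    probe_order = {p.probe_id: i for i, p in enumerate(probes)}
    out = []
    for (chrom, strand), hits in table.groups.items():
        nodes = sorted(
            ((_strand_key(h, strand), probe_order[h.probe_id], h) for h in hits),
            key=lambda n: (n[0], n[1]),
        )
        alive = set(range(len(nodes)))
        while True:
            best = None

            def extend(chain, gap):
                nonlocal best
                cand = (-len(chain), gap, tuple(chain))
                if best is None or cand < best:
                    best = cand
                last = chain[-1]
                for j in sorted(alive):
                    if j <= last:
                        continue
                    kj, pj, hj = nodes[j]
                    ki, pi, hi = nodes[last]
                    if pj <= pi or kj <= ki:
                        continue
                    err = abs((kj - ki) - (probes[pj].offset - probes[pi].offset))
                    if err <= t:
                        extend(chain + [j], gap + err)

            for i in sorted(alive):
                extend([i], 0)
            if best is None or -best[0] < m:
                break
            seq = best[2]
            out.append(
                (
                    chrom,
                    strand,
                    tuple((nodes[i][2].probe_id, nodes[i][2].pos) for i in seq),
                    best[1],
                )
            )
            alive -= set(seq)
    return out


def pattern_tuples(patterns):
    """Convert package Patterns to the oracle's comparable form."""
    return [
        (p.chrom, p.strand, tuple((h.probe_id, h.pos) for _, h in p.members), p.gap_error_sum)
        for p in patterns
    ]


def orf_interval_contains(genome, record, orf: int, probe_seq: str, e_max: int) -> bool:
    """Does the probe occur (either strand, distance <= e_max) inside the
    element's annotated ORF interval (with e_max bp of edge slack)?"""
    g0, g1 = record.orf_genomic_interval(orf)
    seg = genome[record.chrom][max(0, g0 - e_max) : g1 + e_max]
    for q in (probe_seq, rc(probe_seq)):
        if edlib.align(q, seg, mode="HW", k=e_max)["editDistance"] >= 0:
            return True
    return False
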