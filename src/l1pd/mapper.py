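"""Approximate probe mapping: every occurrence of each probe within a
maximum edit distance, on both strands.

The engine is a vectorized Sellers semi-global dynamic program: one numpy
row per probe base, with the horizontal (text-gap) term resolved by a
prefix-minimum scan, giving the best edit distance of the probe against a
window ending at every genomic position in O(k) array passes. Nearby
co-optimal alignments of one locus are collapsed to a single hit
(minimal distance, then leftmost start); 'N' in the genome matches no
probe base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np

from .seqio import ProbeRecord

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
# everything else (N and any stray byte) stays 4: never equal to a probe base

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ProbeHit:
    """One approximate occurrence of a probe in the genome.

    ``pos`` is the 0-based start of the matched window in forward-strand
    coordinates regardless of hit strand.
    """

    probe_id: str
    chrom: str
    pos: int
    strand: str
    edit_distance: int
    matched_len: int

    @property
    def end(self) -> int:
        """0-based exclusive end of the matched window."""
        return self.pos + self.matched_len


class HitTable:
    """Probe hits grouped by (chrom, strand), each group sorted by position."""

    def __init__(self, groups: dict[tuple[str, str], list[ProbeHit]]):
        self.groups = groups

    @classmethod
    def from_hits(cls, hits: Iterable[ProbeHit]) -> "HitTable":
        groups: dict[tuple[str, str], dict] = {}
        for h in hits:
            key = (h.chrom, h.strand)
            # dict keyed by identity tuple deduplicates exact repeats
            groups.setdefault(key, {})[(h.probe_id, h.pos, h.strand)] = h
        return cls(
            {
                key: sorted(d.values(), key=lambda h: (h.pos, h.probe_id))
                for key, d in sorted(groups.items())
            }
        )

    def all_hits(self) -> list[ProbeHit]:
        return [h for g in self.groups.values() for h in g]

    def __len__(self) -> int:
        return sum(len(g) for g in self.groups.values())


def end_distances(text_codes: np.ndarray, probe_codes: np.ndarray) -> np.ndarray:
    """Best semi-global edit distance for windows ending at each position.

    Returns D of length n+1 where D[j] = min over starts s ≤ j of the
    edit distance between the probe and text[s:j].
    """
    return end_distances_batch(text_codes, probe_codes[None, :])[0]


def end_distances_batch(text_codes: np.ndarray, probes: np.ndarray) -> np.ndarray:
    """Vectorized end-distance rows for several equal-length probes.

    ``probes`` is (C, k); returns (C, n+1) int32.
    """
    n = text_codes.shape[0]
    c, k = probes.shape
    idx = np.arange(n + 1, dtype=np.int32)
    dp = np.zeros((c, n + 1), dtype=np.int32)
    row = np.empty_like(dp)
    text = text_codes[None, :]
    for i in range(1, k + 1):
        mismatch = (probes[:, i - 1 : i] != text).astype(np.int32)
        row[:, 0] = i
        # min(diagonal substitution/match, probe-gap step)
        np.minimum(dp[:, :-1] + mismatch, dp[:, 1:] + 1, out=row[:, 1:])
        # text-gap steps: dp[j] = min_{l<=j} row[l] + (j-l), via prefix min
        row -= idx
        np.minimum.accumulate(row, axis=1, out=row)
        row += idx
        dp, row = row, dp
    return dp


def _leftmost_start(text: str, probe: str, end: int, dist: int) -> int:
    """Leftmost window start achieving edit distance ``dist`` ending at ``end``.

    Recovered with a reversed prefix-anchored (SHW) alignment: among optimal
    end positions in the reversed frame, the largest corresponds to the
    leftmost start in the forward frame.
    """
    k = len(probe)
    lo = max(0, end - k - dist)
    seg = text[lo:end][::-1]
    res = edlib.align(probe[::-1], seg, mode="SHW", task="locations", k=dist)
    if res["editDistance"] < 0 or res["editDistance"] > dist:  # pragma: no cover
        raise AssertionError("start recovery disagrees with DP distance")
    longest = max(loc[1] for loc in res["locations"])
    return end - (longest + 1)


def cluster_end_candidates(
    ends: Sequence[int], dists: Sequence[int], e_max: int
) -> list[tuple[list[int], int]]:
    """Group qualifying end positions into loci.

    Ends within ``e_max`` of each other (transitively chained) form one
    locus. Returns, per locus, the ends achieving the locus-minimal edit
    distance together with that distance; the caller picks the alignment
    with the leftmost start among them.
    """
    out: list[tuple[list[int], int]] = []
    cluster: list[tuple[int, int]] = []

    def flush() -> None:
        dmin = min(d for _, d in cluster)
        out.append(([end for end, d in cluster if d == dmin], dmin))

    prev = None
    for end, d in zip(ends, dists):
        if prev is not None and end - prev > max(e_max, 0):
            flush()
            cluster = []
        cluster.append((end, d))
        prev = end
    if cluster:
        flush()
    return out


def find_matches(
    genome_seq: str, probe_seq: str, e_max: int
) -> list[tuple[int, int, int]]:
    """All collapsed occurrences of a probe within edit distance ``e_max``.

    Returns (pos, edit_distance, matched_len) triples sorted by position.
    """
    k = len(probe_seq)
    if e_max < 0:
        raise ValueError("e_max must be >= 0")
    if k <= e_max:
        raise ValueError(f"probe length {k} must exceed e_max={e_max}")
    dp = end_distances(encode(genome_seq), encode(probe_seq))
    return _hits_from_end_row(genome_seq, probe_seq, dp, e_max)


def _hits_from_end_row(
    genome_seq: str, probe_seq: str, dp: np.ndarray, e_max: int
) -> list[tuple[int, int, int]]:
    ends = np.nonzero(dp[1:] <= e_max)[0] + 1
    if ends.size == 0:
        return []
    loci = cluster_end_candidates(ends.tolist(), dp[ends].tolist(), e_max)
    hits = []
    for tied_ends, d in loci:
        start, end = min(
            (
                (_leftmost_start(genome_seq, probe_seq, int(end), int(d)), int(end))
                for end in tied_ends
            ),
        )
        hits.append((start, int(d), end - start))
    hits.sort()
    return hits


def map_probeset(
    genome: dict[str, str],
    probes: Sequence[ProbeRecord],
    e_max: int,
    chunk: int = 32,
) -> HitTable:
    """Map every probe against every sequence, both strands.

    Minus-strand hits are found by searching the reverse complement of the
    probe and are reported in forward coordinates with strand "-".
    """
    if not probes:
        return HitTable({})
    k = probes[0].k
    if k <= e_max:
        raise ValueError(f"k={k} must exceed e_max={e_max}")
    hits: list[ProbeHit] = []
    for chrom, seq in genome.items():
        text_codes = encode(seq)
        for strand in "+-":
            queries = [
                (p.probe_id, p.sequence if strand == "+" else revcomp(p.sequence))
                for p in probes
            ]
            for lo in range(0, len(queries), chunk):
                batch = queries[lo : lo + chunk]
                mat = np.stack([encode(q) for _, q in batch])
                dps = end_distances_batch(text_codes, mat)
                for (probe_id, qseq), dp in zip(batch, dps):
                    for pos, d, mlen in _hits_from_end_row(seq, qseq, dp, e_max):
                        hits.append(
                            ProbeHit(probe_id, chrom, pos, strand, d, mlen)
                        )
    return HitTable.from_hits(hits)
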