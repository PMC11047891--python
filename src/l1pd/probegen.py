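"""Probe generation from aligned full-length intact L1 ORF sequences.

Probes are k-mers drawn from highly conserved columns of a per-ORF
multiple sequence alignment, then refined against a reference genome and
its element annotations in four steps: (1) keep k-mers that map back into
their source ORF, (2) keep k-mers that map into the corresponding ORF of
every annotated element ("universal" probes), (3) order by genome-wide
hit count (fewer hits, fewer false positives), (4) greedily keep a
non-overlapping subset in that order. ORF2 probes are then shifted into
the ORF1-anchored offset frame using the modal ORF1-start-to-ORF2-start
distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import mapper
from .seqio import (
    ComponentLengthModel,
    FormatError,
    L1AnnotationRecord,
    ProbeRecord,
    number_probes,
    validate_probeset,
)


class NoUniversalProbesError(RuntimeError):
    """No candidate k-mer mapped into the target ORF of every element."""

    def __init__(self, orf: int, k: int, identity: float):
        super().__init__(
            f"no universal probes for ORF{orf} at k={k}, identity={identity}: "
            "no conserved k-mer maps into that ORF of every annotated element; "
            "try a lower identity threshold or a smaller k"
        )


@dataclass
class MsaBlock:
    """Equal-length aligned rows over A/C/G/T/- for one ORF."""

    rows: list[str]
    row_ids: list[str]
    orf_source: int

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise FormatError("MSA needs at least 2 rows")
        if len(set(len(r) for r in self.rows)) != 1:
            raise FormatError("MSA rows differ in length")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise FormatError("duplicate MSA row ids")


@dataclass
class ConsensusResult:
    """Ungapped consensus with a per-position conservation mask."""

    consensus: str
    qualifying: np.ndarray  # bool per consensus position
    column_map: list[int]  # alignment column -> consensus position (monotone)


@dataclass
class ProbeCandidate:
    sequence: str
    orf_offset: int  # 0-based within the ungapped ORF consensus
    orf_source: int
    genome_hit_count: int = 0
    per_l1_hit: dict = field(default_factory=dict)


def read_msa(path, orf_source: int) -> MsaBlock:
    """Read a pre-aligned FASTA (rows may contain '-')."""
    from Bio import SeqIO

    rows, ids = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        rows.append(str(rec.seq).upper())
        ids.append(rec.id)
    return MsaBlock(rows=rows, row_ids=ids, orf_source=orf_source)


def column_consensus(msa: MsaBlock, identity: float) -> ConsensusResult:
    """Per-column majority consensus with a conservation threshold.

    A column's consensus base is its most frequent non-gap base (ties to
    the alphabetically smallest); the column qualifies when that base's
    frequency over *all* rows (gaps count in the denominator) is at least
    ``identity``. All-gap columns are dropped from the consensus frame.
    """
    if not 0 < identity <= 1:
        raise ValueError("identity must be in (0, 1]")
    n_rows = len(msa.rows)
    length = len(msa.rows[0])
    consensus = []
    qualifying = []
    column_map = []
    for col in range(length):
        counts: dict[str, int] = {}
        for row in msa.rows:
            base = row[col]
            if base != "-":
                counts[base] = counts.get(base, 0) + 1
        if not counts:
            column_map.append(-1)
            continue
        base = max(sorted(counts), key=lambda b: counts[b])
        column_map.append(len(consensus))
        consensus.append(base)
        qualifying.append(counts[base] / n_rows >= identity)
    return ConsensusResult(
        consensus="".join(consensus),
        qualifying=np.asarray(qualifying, dtype=bool),
        column_map=column_map,
    )


def candidate_kmers(cons: ConsensusResult, k: int, orf_source: int = 1) -> list[ProbeCandidate]:
    """Every k-window of consecutive qualifying consensus positions (stride 1)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    out = []
    mask = cons.qualifying
    n = len(cons.consensus)
    run = 0
    for j in range(n):
        run = run + 1 if mask[j] else 0
        if run >= k:
            start = j - k + 1
            out.append(
                ProbeCandidate(
                    sequence=cons.consensus[start : start + k],
                    orf_offset=start,
                    orf_source=orf_source,
                )
            )
    return out


def _hit_in_interval(pos: int, end: int, iv: tuple[int, int], slack: int) -> bool:
    return pos >= iv[0] - slack and end <= iv[1] + slack


def refine_candidates(
    cands: Sequence[ProbeCandidate],
    genome: dict[str, str],
    meta: Sequence[L1AnnotationRecord],
    e_map: int,
    orf_source: int,
    chunk: int = 64,
) -> list[ProbeCandidate]:
    """Apply the four-step refinement; returns surviving candidates sorted
    by ORF offset (offsets stay ORF-local).

    Interval membership is positional (strand-ignored) containment in the
    annotated ORF's genomic interval, with ``e_map`` bp of slack per edge
    so boundary indels do not disqualify internal hits.
    """
    if not meta:
        raise ValueError("refinement requires at least one annotated element")
    if not cands:
        return []
    k = len(cands[0].sequence)
    intervals = {
        (r.chrom, i): r.orf_genomic_interval(orf_source)
        for i, r in enumerate(meta)
    }

    # map all candidates genome-wide, both strands, in batches
    hit_lists: list[list[tuple[str, int, int]]] = [[] for _ in cands]
    for chrom, seq in genome.items():
        text_codes = mapper.encode(seq)
        for strand in "+-":
            seqs = [
                c.sequence if strand == "+" else mapper.revcomp(c.sequence)
                for c in cands
            ]
            for lo in range(0, len(seqs), chunk):
                mat = np.stack([mapper.encode(s) for s in seqs[lo : lo + chunk]])
                dps = mapper.end_distances_batch(text_codes, mat)
                for off, dp in enumerate(dps):
                    ci = lo + off
                    for pos, _d, mlen in mapper._hits_from_end_row(
                        seq, seqs[ci], dp, e_map
                    ):
                        hit_lists[ci].append((chrom, pos, pos + mlen))

    survivors = []
    for cand, hits in zip(cands, hit_lists):
        cand.genome_hit_count = len(hits)
        cand.per_l1_hit = {
            li: any(
                chrom == r.chrom and _hit_in_interval(pos, end, intervals[(r.chrom, li)], e_map)
                for chrom, pos, end in hits
            )
            for li, r in enumerate(meta)
        }
        # step 1: mapped into the source ORF of at least one element
        if not any(cand.per_l1_hit.values()):
            continue
        # step 2: mapped into the corresponding ORF of every element
        if not all(cand.per_l1_hit.values()):
            continue
        survivors.append(cand)
    if not survivors:
        raise NoUniversalProbesError(orf_source, k, identity=float("nan"))
    return select_nonoverlapping(survivors)


def select_nonoverlapping(cands: Sequence[ProbeCandidate]) -> list[ProbeCandidate]:
    """Steps 3-4 of refinement: order by ascending genome-wide hit count
    (ties toward smaller offset), then greedily accept candidates whose
    offset interval overlaps no already-accepted one. Result sorted by
    offset."""
    ordered = sorted(cands, key=lambda c: (c.genome_hit_count, c.orf_offset))
    accepted: list[ProbeCandidate] = []
    for cand in ordered:
        s, e = cand.orf_offset, cand.orf_offset + len(cand.sequence)
        if all(
            e <= a.orf_offset or s >= a.orf_offset + len(a.sequence) for a in accepted
        ):
            accepted.append(cand)
    accepted.sort(key=lambda c: c.orf_offset)
    return accepted


def assemble_probeset(
    orf1: Sequence[ProbeCandidate],
    orf2: Sequence[ProbeCandidate],
    model: ComponentLengthModel,
) -> list[ProbeRecord]:
    """Merge per-ORF candidates into one ORF1-anchored probe set.

    ORF1 offsets pass through; ORF2 offsets are shifted by the modal
    ORF1-start-to-ORF2-start distance. The merged set is renumbered,
    re-sorted and re-validated (cross-ORF overlap is an error).
    """
    if not orf1 and not orf2:
        raise ValueError("no probes to assemble")
    recs = []
    for c in orf1:
        recs.append(
            ProbeRecord(
                probe_id=f"tmp_orf1_{c.orf_offset}",
                orf_source=1,
                k=len(c.sequence),
                offset=c.orf_offset,
                sequence=c.sequence,
            )
        )
    shift = model.mode_orf1start_to_orf2start
    for c in orf2:
        recs.append(
            ProbeRecord(
                probe_id=f"tmp_orf2_{c.orf_offset}",
                orf_source=2,
                k=len(c.sequence),
                offset=c.orf_offset + shift,
                sequence=c.sequence,
            )
        )
    return validate_probeset(number_probes(recs))


def generate_probes(
    orf1_msa: MsaBlock,
    orf2_msa: MsaBlock,
    genome: dict[str, str],
    meta: Sequence[L1AnnotationRecord],
    k: int,
    identity: float = 0.95,
    e_map: int = 2,
) -> list[ProbeRecord]:
    """Full probe-generation pipeline for both ORFs."""
    from .seqio import length_modes

    sets = []
    for msa, orf in ((orf1_msa, 1), (orf2_msa, 2)):
        cons = column_consensus(msa, identity)
        cands = candidate_kmers(cons, k, orf_source=orf)
        if not cands:
            raise NoUniversalProbesError(orf, k, identity)
        try:
            sets.append(refine_candidates(cands, genome, meta, e_map, orf))
        except NoUniversalProbesError:
            raise NoUniversalProbesError(orf, k, identity) from None
    model = length_modes(meta)
    return assemble_probeset(sets[0], sets[1], model)
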