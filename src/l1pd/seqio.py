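"""Readers and writers for the formats the tool touches.

FASTA genomes and probe sets (Biopython), SAM probe-hit import (pysam),
GFF3 call output, and the L1Base2-style CSV metadata schema together with
the component-length mode computation used to extrapolate element
boundaries.

Internal coordinates are 0-based half-open everywhere; conversion to the
1-based inclusive convention of GFF3/CSV happens only in this module.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger("l1pd")

GENOME_ALPHABET = set("ACGTN")
PROBE_ALPHABET = set("ACGT")

#: Required columns of the L1 metadata CSV. ``l1_*`` coordinates are genomic,
#: component columns are element-relative; all 1-based inclusive.
METADATA_COLUMNS = [
    "chrom",
    "l1_start",
    "l1_end",
    "strand",
    "utr5_start",
    "utr5_end",
    "orf1_start",
    "orf1_end",
    "orf2_start",
    "orf2_end",
    "utr3_start",
    "utr3_end",
]


class FormatError(ValueError):
    """Malformed input file (bad FASTA/SAM/CSV record, broken invariant)."""


class EmptyMetadataError(FormatError):
    """CSV metadata contained no complete rows."""


@dataclass(frozen=True)
class ProbeRecord:
    """One probe: a conserved k-mer with its offset from the ORF1 start."""

    probe_id: str
    orf_source: int  # 1 or 2
    k: int
    offset: int  # 0-based distance from the first base of ORF1
    sequence: str

    def __post_init__(self) -> None:
        if self.orf_source not in (1, 2):
            raise FormatError(f"{self.probe_id}: orf_source must be 1 or 2")
        if self.offset < 0:
            raise FormatError(f"{self.probe_id}: negative offset")
        if len(self.sequence) != self.k:
            raise FormatError(
                f"{self.probe_id}: sequence length {len(self.sequence)} != k={self.k}"
            )
        if not set(self.sequence) <= PROBE_ALPHABET:
            raise FormatError(f"{self.probe_id}: non-ACGT character in probe")


def validate_probeset(probes: Sequence[ProbeRecord]) -> list[ProbeRecord]:
    """Check ProbeSet invariants: sorted, non-overlapping, uniform k, unique ids.

    Returns the probes as a list (unchanged) so callers can chain the call.
    """
    probes = list(probes)
    if not probes:
        raise FormatError("empty probe set")
    ks = {p.k for p in probes}
    if len(ks) > 1:
        raise FormatError(f"mixed k-mer sizes in probe set: {sorted(ks)}")
    ids = [p.probe_id for p in probes]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate probe ids")
    for a, b in zip(probes, probes[1:]):
        if b.offset <= a.offset:
            raise FormatError(
                f"probes not sorted by strictly ascending offset: "
                f"{a.probe_id}@{a.offset} then {b.probe_id}@{b.offset}"
            )
        if b.offset < a.offset + a.k:
            raise FormatError(
                f"overlapping probes {a.probe_id} [{a.offset},{a.offset + a.k}) "
                f"and {b.probe_id} [{b.offset},{b.offset + b.k})"
            )
    return probes


@dataclass(frozen=True)
class L1AnnotationRecord:
    """Truth metadata for one full-length intact L1.

    ``l1_start``/``l1_end`` are 1-based inclusive genomic coordinates;
    the component coordinates are 1-based inclusive *within the element*
    (position 1 = first base of the element on its own strand).
    """

    chrom: str
    l1_start: int
    l1_end: int
    strand: str
    utr5_start: int
    utr5_end: int
    orf1_start: int
    orf1_end: int
    orf2_start: int
    orf2_end: int
    utr3_start: int
    utr3_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"bad strand {self.strand!r}")
        if not 1 <= self.l1_start <= self.l1_end:
            raise FormatError(f"bad element bounds {self.l1_start}..{self.l1_end}")
        comps = [
            (self.utr5_start, self.utr5_end),
            (self.orf1_start, self.orf1_end),
            (self.orf2_start, self.orf2_end),
            (self.utr3_start, self.utr3_end),
        ]
        prev_end = 0
        for s, e in comps:
            if not 1 <= s <= e:
                raise FormatError(f"bad component interval {s}..{e}")
            if s <= prev_end:
                raise FormatError("component intervals out of order or overlapping")
            prev_end = e

    @property
    def length(self) -> int:
        return self.l1_end - self.l1_start + 1

    def component_lengths(self) -> dict[str, int]:
        """Lengths of the five canonical components, in bp."""
        return {
            "utr5": self.utr5_end - self.utr5_start + 1,
            "orf1": self.orf1_end - self.orf1_start + 1,
            "spacer": self.orf2_start - self.orf1_end - 1,
            "orf2": self.orf2_end - self.orf2_start + 1,
            "utr3": self.utr3_end - self.utr3_start + 1,
        }

    def orf_genomic_interval(self, orf: int) -> tuple[int, int]:
        """0-based half-open genomic interval of ORF1 or ORF2, strand-aware."""
        s, e = (self.orf1_start, self.orf1_end) if orf == 1 else (self.orf2_start, self.orf2_end)
        if self.strand == "+":
            g0 = self.l1_start - 1 + (s - 1)
            g1 = self.l1_start - 1 + e
        else:
            g0 = self.l1_end - e
            g1 = self.l1_end - (s - 1)
        return g0, g1


@dataclass(frozen=True)
class ComponentLengthModel:
    """Modes (most common values) of the L1 component lengths.

    ``mode_total`` is the mode of full element lengths, computed
    independently rather than as the sum of component modes.
    ``mode_orf1start_to_orf2start`` shifts ORF2-local probe offsets into
    the ORF1-anchored coordinate system.
    """

    mode_5utr: int
    mode_orf1: int
    mode_spacer: int
    mode_orf2: int
    mode_3utr: int
    mode_total: int
    mode_orf1start_to_orf2start: int


def _mode(values: Iterable[int]) -> int:
    """Most common value; ties broken by the smallest tied value."""
    counts = Counter(values)
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]


def length_modes(records: Sequence[L1AnnotationRecord]) -> ComponentLengthModel:
    """Compute the component-length modes over annotated elements."""
    if not records:
        raise ValueError("length_modes requires at least one complete record")
    comp = [r.component_lengths() for r in records]
    return ComponentLengthModel(
        mode_5utr=_mode(c["utr5"] for c in comp),
        mode_orf1=_mode(c["orf1"] for c in comp),
        mode_spacer=_mode(c["spacer"] for c in comp),
        mode_orf2=_mode(c["orf2"] for c in comp),
        mode_3utr=_mode(c["utr3"] for c in comp),
        mode_total=_mode(r.length for r in records),
        mode_orf1start_to_orf2start=_mode(
            r.orf2_start - r.orf1_start for r in records
        ),
    )


# ---------------------------------------------------------------------------
# FASTA

def read_genome(path) -> dict[str, str]:
    """Read an assembled genome FASTA into an ordered id → sequence map.

    Sequence ids are the first whitespace-delimited header token. Sequences
    are uppercased; characters outside {A,C,G,T,N} are rejected.
    """
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in genome:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        if not seq:
            raise FormatError(f"empty sequence for {rec.id!r}")
        bad = set(seq) - GENOME_ALPHABET
        if bad:
            raise FormatError(
                f"record {rec.id!r}: characters outside A/C/G/T/N: {sorted(bad)}"
            )
        genome[rec.id] = seq
    if not genome:
        raise FormatError(f"no FASTA records in {path}")
    return genome


def _parse_probe_header(header: str) -> tuple[str, dict[str, int]]:
    fields = header.split("|")
    probe_id = fields[0].strip()
    kv: dict[str, int] = {}
    for f in fields[1:]:
        if "=" not in f:
            raise FormatError(f"bad probe header field {f!r} in {header!r}")
        key, val = f.split("=", 1)
        try:
            kv[key.strip()] = int(val)
        except ValueError as exc:
            raise FormatError(f"non-integer {key}={val!r} in {header!r}") from exc
    for key in ("orf", "k", "offset"):
        if key not in kv:
            raise FormatError(f"probe header missing key {key!r}: {header!r}")
    return probe_id, kv


def read_probes(path) -> list[ProbeRecord]:
    """Read a probe FASTA with the ``|orf=|k=|offset=`` header dialect."""
    probes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        probe_id, kv = _parse_probe_header(rec.description)
        probes.append(
            ProbeRecord(
                probe_id=probe_id,
                orf_source=kv["orf"],
                k=kv["k"],
                offset=kv["offset"],
                sequence=str(rec.seq).upper(),
            )
        )
    return validate_probeset(probes)


def write_probes(probes: Sequence[ProbeRecord], path) -> None:
    """Write a probe set in the bit-exact header dialect read_probes expects."""
    validate_probeset(probes)
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f">{p.probe_id}|orf={p.orf_source}|k={p.k}|offset={p.offset}\n")
            fh.write(p.sequence + "\n")


def number_probes(probes: Sequence[ProbeRecord]) -> list[ProbeRecord]:
    """Re-id probes as L1PD_probe_<n>, n = 1-based rank by offset."""
    out = []
    for n, p in enumerate(sorted(probes, key=lambda p: p.offset), start=1):
        out.append(
            ProbeRecord(
                probe_id=f"L1PD_probe_{n}",
                orf_source=p.orf_source,
                k=p.k,
                offset=p.offset,
                sequence=p.sequence,
            )
        )
    return out


# ---------------------------------------------------------------------------
# CSV metadata

def read_metadata(path) -> tuple[list[L1AnnotationRecord], int]:
    """Read L1 metadata CSV; returns (complete records, skipped-row count).

    Rows with any required field empty are skipped and counted (annotation
    databases ship a few incomplete entries; they must not abort a run).
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata CSV missing required columns: {missing}")
    records: list[L1AnnotationRecord] = []
    skipped = 0
    for _, row in df.iterrows():
        vals = {c: row[c] for c in METADATA_COLUMNS}
        if any(pd.isna(v) or str(v).strip() == "" for v in vals.values()):
            skipped += 1
            continue
        records.append(
            L1AnnotationRecord(
                chrom=str(vals["chrom"]).strip(),
                strand=str(vals["strand"]).strip(),
                **{
                    c: int(vals[c])
                    for c in METADATA_COLUMNS
                    if c not in ("chrom", "strand")
                },
            )
        )
    if skipped:
        logger.info("read_metadata: skipped %d incomplete row(s)", skipped)
    if not records:
        raise EmptyMetadataError(f"no complete metadata rows in {path}")
    return records, skipped


def write_metadata(records: Sequence[L1AnnotationRecord], path) -> None:
    rows = [
        {c: getattr(r, c) for c in METADATA_COLUMNS} for r in records
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GFF3

def write_gff3(calls, path, extra_header: Sequence[str] = ()) -> None:
    """Write L1 calls as GFF3.

    Seven of the nine columns are filled: seqid, source "L1PD", type
    "mobile_genetic_element", start, end, strand and the attribute
    Name=LINE1; score and phase stay ".". Records are sorted by
    (seqid, start). ``extra_header`` lines are emitted as "#!" comments
    after the version directive.
    """
    calls = sorted(calls, key=lambda c: (c.chrom, c.start, c.end))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in extra_header:
            fh.write(f"#!{line}\n")
        for c in calls:
            if not 1 <= c.start <= c.end:
                raise ValueError(f"invalid call interval {c.start}..{c.end}")
            fh.write(
                f"{c.chrom}\tL1PD\tmobile_genetic_element\t{c.start}\t{c.end}"
                f"\t.\t{c.strand}\t.\tName=LINE1\n"
            )


# ---------------------------------------------------------------------------
# SAM import

def read_sam_hits(path, probes: Sequence[ProbeRecord]):
    """Import probe alignments from a SAM file as a HitTable.

    Uses QNAME/FLAG/RNAME/POS and the NM tag (missing NM → edit distance 0
    with a warning). Unmapped records are dropped; every other reported
    alignment becomes a hit — no secondary suppression. Query names not in
    the probe set are skipped with a warning.
    """
    from .mapper import HitTable, ProbeHit  # local import avoids a cycle

    known = {p.probe_id: p for p in probes}
    hits = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            if rec.query_name not in known:
                warnings.warn(
                    f"SAM record for unknown probe {rec.query_name!r} skipped"
                )
                continue
            probe = known[rec.query_name]
            if rec.has_tag("NM"):
                nm = int(rec.get_tag("NM"))
            else:
                warnings.warn(
                    f"SAM record for {rec.query_name!r} lacks NM tag; "
                    "edit distance set to 0"
                )
                nm = 0
            mlen = rec.reference_length or probe.k
            hits.append(
                ProbeHit(
                    probe_id=rec.query_name,
                    chrom=rec.reference_name,
                    pos=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    edit_distance=nm,
                    matched_len=mlen,
                )
            )
    return HitTable.from_hits(hits)
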