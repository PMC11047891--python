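"""Seeded generator of L1Base2-like fixtures.

Simulates one ancestral full-length element (5'UTR, ORF1, inter-ORF
spacer, ORF2, 3'UTR), a family of diverged intact copies plus 5'-truncated
copies, and a host genome with every copy planted on a random strand.
Because the whole mutation history is recorded, the generator also emits
the exact truth: per-copy metadata CSV, truth GFF3, per-ORF intact-copy
FASTA, and the true per-ORF multiple sequence alignment reconstructed from
the indel history (no aligner involved).

Mutation model: per-base substitutions (Binomial count, positions without
replacement, new base differs), then indels (Binomial count, insertion or
deletion 50/50, geometric lengths); an indel whose span collides with a
previously applied indel is skipped so the history stays unambiguous.
Substitutions erased by a later deletion are dropped from the log.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .mapper import revcomp
from .seqio import (
    L1AnnotationRecord,
    ProbeRecord,
    length_modes,
    number_probes,
    write_metadata,
)

COMPONENTS = ("utr5", "orf1", "spacer", "orf2", "utr3")


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic fixture.

    Component lengths default to the human full-length L1 architecture
    (~6 kb total); divergence defaults emulate a young, mostly intact
    family: 1% substitutions, 0.1% indels of geometric mean length 2.
    """

    seed: int = 0
    genome_length: int = 250_000
    n_intact: int = 30
    n_truncated: int = 5
    len_utr5: int = 909
    len_orf1: int = 1017
    len_spacer: int = 63
    len_orf2: int = 3828
    len_utr3: int = 205
    sub_rate: float = 0.01
    indel_rate: float = 0.001
    mean_indel_len: float = 2.0
    truncation_range: tuple[float, float] = (0.5, 0.9)
    gc_content: float = 0.42
    min_spacing: int = 100
    chrom_name: str = "chr1"

    @property
    def element_length(self) -> int:
        return (
            self.len_utr5 + self.len_orf1 + self.len_spacer + self.len_orf2 + self.len_utr3
        )

    def component_bounds(self) -> dict[str, tuple[int, int]]:
        """Ancestral element-relative 1-based inclusive component intervals."""
        bounds = {}
        start = 1
        for name, ln in zip(
            COMPONENTS,
            (self.len_utr5, self.len_orf1, self.len_spacer, self.len_orf2, self.len_utr3),
        ):
            bounds[name] = (start, start + ln - 1)
            start += ln
        return bounds

    def validate(self) -> None:
        for r in (self.sub_rate, self.indel_rate):
            if not 0 <= r < 1:
                raise SimulationError("mutation rates must be in [0, 1)")
        if min(
            self.len_utr5, self.len_orf1, self.len_spacer, self.len_orf2, self.len_utr3
        ) <= 0:
            raise SimulationError("all component lengths must be > 0")
        if not 0 < self.gc_content < 1:
            raise SimulationError("gc_content must be in (0, 1)")
        lo, hi = self.truncation_range
        min_cut = (self.len_utr5 + 1) / self.element_length
        if not min_cut <= lo <= hi < 1:
            raise SimulationError(
                "truncation_range must remove at least the 5'UTR and part of ORF1"
            )
        total = (self.n_intact + self.n_truncated) * self.element_length
        if self.genome_length <= total + (self.n_intact + self.n_truncated + 1) * self.min_spacing:
            raise SimulationError(
                f"genome_length {self.genome_length} too small for "
                f"{self.n_intact}+{self.n_truncated} copies of {self.element_length} bp"
            )


@dataclass
class CopyHistory:
    """Recorded mutation log for one simulated copy."""

    copy_id: str
    substitutions: list[tuple[int, str, str]]  # (ancestral pos 1-based, old, new)
    insertions: list[tuple[int, str]]  # (anchored before ancestral pos, bases)
    deletions: list[tuple[int, int]]  # (first deleted ancestral pos, length)


@dataclass
class SimTruth:
    """Everything the simulator knows about its fixture."""

    config: SimConfig
    genome: dict[str, str]
    records: list[L1AnnotationRecord]  # intact copies only (detection truth)
    truncated: list[tuple[str, int, int, str]]  # (chrom, start, end, strand) 1-based
    ancestor: str
    ancestor_bounds: dict[str, tuple[int, int]]
    copy_ids: list[str]
    copy_seqs: dict[str, str]
    histories: dict[str, CopyHistory]
    msa: dict[str, list[str]] = field(default_factory=dict)  # orf name -> rows
    copy_components: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)

    def orf_sequences(self, orf: str) -> dict[str, str]:
        """De-gapped per-copy ORF sequences from the true MSA."""
        return {
            cid: row.replace("-", "")
            for cid, row in zip(self.copy_ids, self.msa[orf])
        }


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def _mutate(
    rng: np.random.Generator, ancestor: str, cfg: SimConfig, copy_id: str
) -> CopyHistory:
    length = len(ancestor)
    bases = "ACGT"
    n_sub = rng.binomial(length, cfg.sub_rate)
    sub_pos = sorted(rng.choice(length, size=n_sub, replace=False).tolist())
    subs = []
    for p in sub_pos:
        old = ancestor[p]
        new = bases[(bases.index(old) + rng.integers(1, 4)) % 4]
        subs.append((p + 1, old, new))

    n_indel = rng.binomial(length, cfg.indel_rate)
    indel_pos = sorted(rng.choice(length, size=n_indel, replace=False).tolist())
    insertions: list[tuple[int, str]] = []
    deletions: list[tuple[int, int]] = []
    occupied: list[tuple[int, int]] = []  # half-open ancestral spans of deletions
    for p in indel_pos:
        ln = int(rng.geometric(1.0 / cfg.mean_indel_len))
        if rng.random() < 0.5:
            ins = "".join(bases[i] for i in rng.integers(0, 4, size=ln))
            if any(s <= p < e for s, e in occupied):
                continue
            insertions.append((p + 1, ins))
        else:
            span = (p, min(p + ln, length))
            if any(s < span[1] and span[0] < e for s, e in occupied):
                continue
            occupied.append(span)
            deletions.append((p + 1, span[1] - span[0]))
    deleted = set()
    for start1, ln in deletions:
        deleted.update(range(start1, start1 + ln))
    subs = [s for s in subs if s[0] not in deleted]
    return CopyHistory(copy_id, subs, insertions, deletions)


def _build_rows(
    ancestor: str,
    histories: Sequence[CopyHistory],
    comp_of: list[str],
) -> tuple[list[str], list[str], list[dict[str, tuple[int, int]]]]:
    """Build full-element alignment rows from recorded histories.

    Returns (rows, column component labels, per-copy component intervals in
    copy coordinates). Insertion columns are attributed to the component of
    the preceding ancestral base.
    """
    length = len(ancestor)
    per_copy = []
    for h in histories:
        per_copy.append(
            {
                "sub": {p: new for p, _old, new in h.substitutions},
                "ins": {p: s for p, s in h.insertions},
                "del": {
                    q for start1, ln in h.deletions for q in range(start1, start1 + ln)
                },
            }
        )
    rows = [[] for _ in histories]
    col_comp: list[str] = []
    coords = [0] * len(histories)  # running copy coordinate (bases emitted)
    comp_intervals: list[dict[str, list[int]]] = [dict() for _ in histories]

    def emit(ci: int, chars: str, comp: str) -> None:
        rows[ci].append(chars)
        n = sum(1 for ch in chars if ch != "-")
        if n:
            iv = comp_intervals[ci].setdefault(comp, [coords[ci] + 1, 0])
            coords[ci] += n
            iv[1] = coords[ci]

    for p in range(1, length + 1):
        comp_prev = comp_of[p - 2] if p > 1 else comp_of[0]
        for ci, pc in enumerate(per_copy):
            if p in pc["ins"]:
                ins = pc["ins"][p]
                for cj in range(len(histories)):
                    emit(cj, ins if cj == ci else "-" * len(ins), comp_prev)
                col_comp.extend([comp_prev] * len(ins))
        comp = comp_of[p - 1]
        for ci, pc in enumerate(per_copy):
            if p in pc["del"]:
                emit(ci, "-", comp)
            else:
                emit(ci, pc["sub"].get(p, ancestor[p - 1]), comp)
        col_comp.append(comp)

    out_intervals = []
    for iv in comp_intervals:
        missing = [c for c in COMPONENTS if c not in iv]
        if missing:
            raise SimulationError(f"component(s) fully deleted: {missing}")
        out_intervals.append({c: (iv[c][0], iv[c][1]) for c in COMPONENTS})
    return ["".join(r) for r in rows], col_comp, out_intervals


def simulate(config: SimConfig) -> SimTruth:
    """Generate a fixture; deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    bounds = config.component_bounds()
    ancestor = _random_seq(rng, config.element_length, config.gc_content)
    comp_of = []
    for name in COMPONENTS:
        s, e = bounds[name]
        comp_of.extend([name] * (e - s + 1))

    copy_ids = [f"L1_intact_{i + 1}" for i in range(config.n_intact)]
    histories = {cid: _mutate(rng, ancestor, config, cid) for cid in copy_ids}
    rows, col_comp, comp_intervals = _build_rows(
        ancestor, [histories[c] for c in copy_ids], comp_of
    )
    copy_seqs = {cid: row.replace("-", "") for cid, row in zip(copy_ids, rows)}
    copy_components = dict(zip(copy_ids, comp_intervals))

    # truncated copies: fresh mutants with the 5' prefix removed
    trunc_seqs = []
    for i in range(config.n_truncated):
        h = _mutate(rng, ancestor, config, f"L1_trunc_{i + 1}")
        trows, _, _ = _build_rows(ancestor, [h], comp_of)
        seq = trows[0].replace("-", "")
        frac = rng.uniform(*config.truncation_range)
        cut = int(round(frac * len(seq)))
        trunc_seqs.append(seq[cut:])

    # placement: shuffle all copies, distribute free space as random gaps
    order = [("intact", cid) for cid in copy_ids] + [
        ("trunc", i) for i in range(config.n_truncated)
    ]
    perm = rng.permutation(len(order))
    order = [order[i] for i in perm]
    lens = [
        len(copy_seqs[key]) if kind == "intact" else len(trunc_seqs[key])
        for kind, key in order
    ]
    free = config.genome_length - sum(lens) - (len(order) + 1) * config.min_spacing
    if free < 0:
        raise SimulationError("copies do not fit in the genome")
    gaps = rng.multinomial(free, [1.0 / (len(order) + 1)] * (len(order) + 1))
    strands = ["+" if rng.random() < 0.5 else "-" for _ in order]

    pieces = []
    pos = 0
    records: list[L1AnnotationRecord] = []
    truncated: list[tuple[str, int, int, str]] = []
    chrom = config.chrom_name
    for idx, ((kind, key), strand) in enumerate(zip(order, strands)):
        gap_len = int(gaps[idx]) + config.min_spacing
        pieces.append(_random_seq(rng, gap_len, config.gc_content))
        pos += gap_len
        seq = copy_seqs[key] if kind == "intact" else trunc_seqs[key]
        planted = seq if strand == "+" else revcomp(seq)
        pieces.append(planted)
        start1, end1 = pos + 1, pos + len(seq)
        if kind == "intact":
            comp = copy_components[key]
            records.append(
                L1AnnotationRecord(
                    chrom=chrom,
                    l1_start=start1,
                    l1_end=end1,
                    strand=strand,
                    utr5_start=comp["utr5"][0],
                    utr5_end=comp["utr5"][1],
                    orf1_start=comp["orf1"][0],
                    orf1_end=comp["orf1"][1],
                    orf2_start=comp["orf2"][0],
                    orf2_end=comp["orf2"][1],
                    utr3_start=comp["utr3"][0],
                    utr3_end=comp["utr3"][1],
                )
            )
        else:
            truncated.append((chrom, start1, end1, strand))
        pos += len(seq)
    tail = config.genome_length - pos
    pieces.append(_random_seq(rng, tail, config.gc_content))
    genome = {chrom: "".join(pieces)}

    orf_cols = {
        orf: [i for i, c in enumerate(col_comp) if c == orf] for orf in ("orf1", "orf2")
    }
    msa = {
        orf: ["".join(row[i] for i in cols) for row in rows]
        for orf, cols in orf_cols.items()
    }
    return SimTruth(
        config=config,
        genome=genome,
        records=sorted(records, key=lambda r: r.l1_start),
        truncated=sorted(truncated, key=lambda t: t[1]),
        ancestor=ancestor,
        ancestor_bounds=bounds,
        copy_ids=copy_ids,
        copy_seqs=copy_seqs,
        histories=histories,
        msa=msa,
        copy_components=copy_components,
    )


def mutation_audit(truth: SimTruth) -> dict[str, dict[str, int]]:
    """Recount mutations per copy by replaying coordinates against the
    ancestor (independent of the logs' own lengths).

    For each copy: substitutions = surviving ancestral positions whose base
    differs from the ancestor; insertion/deletion events and bases from the
    recorded anchors. Tests compare these counts with the raw logs.
    """
    out = {}
    for cid in truth.copy_ids:
        h = truth.histories[cid]
        deleted = {
            q for start1, ln in h.deletions for q in range(start1, start1 + ln)
        }
        inserted = {p: s for p, s in h.insertions}
        seq = truth.copy_seqs[cid]
        i = 0
        n_sub = 0
        for p in range(1, len(truth.ancestor) + 1):
            if p in inserted:
                i += len(inserted[p])
            if p in deleted:
                continue
            if seq[i] != truth.ancestor[p - 1]:
                n_sub += 1
            i += 1
        out[cid] = {
            "substitutions": n_sub,
            "insertions": len(h.insertions),
            "deletions": len(h.deletions),
            "inserted_bases": sum(len(s) for _, s in h.insertions),
            "deleted_bases": sum(ln for _, ln in h.deletions),
        }
    return out


def ancestral_probes(truth: SimTruth, k: int) -> list[ProbeRecord]:
    """Tile the ancestral ORFs with non-overlapping k-mers.

    Offsets are measured from the ORF1 start through the ancestral
    architecture, giving a probe template of the kind probe generation
    would produce on an undiverged family.
    """
    recs = []
    orf1_start = truth.ancestor_bounds["orf1"][0]
    for orf, src in (("orf1", 1), ("orf2", 2)):
        s, e = truth.ancestor_bounds[orf]
        seg = truth.ancestor[s - 1 : e]
        base_offset = s - orf1_start
        for j in range(0, len(seg) - k + 1, k):
            recs.append(
                ProbeRecord(
                    probe_id=f"tmp_{orf}_{j}",
                    orf_source=src,
                    k=k,
                    offset=base_offset + j,
                    sequence=seg[j : j + k],
                )
            )
    return number_probes(recs)


def write_outputs(truth: SimTruth, outdir, extra_header: Sequence[str] = ()) -> dict[str, Path]:
    """Write the fixture to disk in the formats the detector consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def fasta(path: Path, entries: dict[str, str]) -> None:
        with open(path, "w") as fh:
            for name, seq in entries.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    paths["genome"] = outdir / "genome.fa"
    fasta(paths["genome"], truth.genome)
    paths["truth_csv"] = outdir / "truth.csv"
    write_metadata(truth.records, paths["truth_csv"])
    paths["truth_gff3"] = outdir / "truth.gff3"
    with open(paths["truth_gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for line in extra_header:
            fh.write(f"#!{line}\n")
        feats = [
            (r.chrom, r.l1_start, r.l1_end, r.strand, "Name=LINE1")
            for r in truth.records
        ] + [
            (c, s, e, st, "Name=LINE1;Note=truncated") for c, s, e, st in truth.truncated
        ]
        for chrom, s, e, st, attr in sorted(feats, key=lambda f: (f[0], f[1])):
            fh.write(
                f"{chrom}\tl1pd-sim\tmobile_genetic_element\t{s}\t{e}\t.\t{st}\t.\t{attr}\n"
            )
    for orf in ("orf1", "orf2"):
        paths[f"{orf}_msa"] = outdir / f"{orf}_msa.fa"
        fasta(paths[f"{orf}_msa"], dict(zip(truth.copy_ids, truth.msa[orf])))
        paths[orf] = outdir / f"{orf}.fa"
        fasta(paths[orf], truth.orf_sequences(orf))
    paths["config"] = outdir / "config.json"
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(truth.config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
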