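"""Precision/recall/F1 against truth annotations and the parameter sweep.

A call is a true positive when it can be matched one-to-one to a truth
element it overlaps by at least ``min_overlap`` of the truth element's
length (strand-aware unless disabled). Zero denominators yield 0 so the
sweep stays total at extreme parameter settings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .mapper import map_probeset
from .patternmatch import DetectionParams, L1Call, detect
from .seqio import L1AnnotationRecord, ProbeRecord


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class SweepRow:
    k: int
    e: int
    t: int
    m: int
    result: EvalResult


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must be in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def match_calls(
    calls: Sequence[L1Call],
    truth: Sequence[L1AnnotationRecord],
    min_overlap: float = 0.5,
    ignore_strand: bool = False,
) -> tuple[int, int, int]:
    """Greedy one-to-one call/truth matching; returns (tp, fp, fn).

    Calls are visited in ascending start order; each matches the unmatched
    truth element with the largest qualifying overlap (>= min_overlap of
    the truth length, ties toward the smaller truth start).
    """
    unmatched = list(range(len(truth)))
    tp = 0
    for call in sorted(calls, key=lambda c: (c.chrom, c.start, c.end)):
        best: Optional[tuple[int, int, int]] = None  # (-overlap, start, idx)
        for idx in unmatched:
            rec = truth[idx]
            if rec.chrom != call.chrom:
                continue
            if not ignore_strand and rec.strand != call.strand:
                continue
            overlap = min(call.end, rec.l1_end) - max(call.start, rec.l1_start) + 1
            if overlap >= min_overlap * rec.length:
                cand = (-overlap, rec.l1_start, idx)
                if best is None or cand < best:
                    best = cand
        if best is not None:
            tp += 1
            unmatched.remove(best[2])
    return tp, len(calls) - tp, len(truth) - tp


def evaluate(
    calls: Sequence[L1Call],
    truth: Sequence[L1AnnotationRecord],
    min_overlap: float = 0.5,
    ignore_strand: bool = False,
) -> EvalResult:
    tp, fp, fn = match_calls(calls, truth, min_overlap, ignore_strand)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return EvalResult(tp, fp, fn, precision, recall, f1_score(precision, recall))


def sweep(
    genome: dict[str, str],
    probes: Sequence[ProbeRecord],
    meta: Sequence[L1AnnotationRecord],
    truth: Sequence[L1AnnotationRecord],
    grid: Sequence[tuple[int, int, int]],
    min_overlap: float = 0.5,
    ignore_strand: bool = False,
) -> tuple[list[SweepRow], SweepRow]:
    """Run detection + evaluation per (e, t, m) combination.

    The hit table is recomputed once per distinct e and shared across the
    (t, m) combinations that use it. Returns all rows plus the argmax row
    (best f1; ties toward higher precision, then lower e).
    """
    if not grid:
        raise ValueError("empty parameter grid")
    k = probes[0].k
    rows: list[SweepRow] = []
    by_e: dict[int, object] = {}
    for e, t, m in grid:
        if e not in by_e:
            by_e[e] = map_probeset(genome, probes, e)
        params = DetectionParams(e=e, t=t, m=m)
        calls = detect(genome, probes, meta, params, hit_table=by_e[e])
        res = evaluate(calls, truth, min_overlap, ignore_strand)
        rows.append(SweepRow(k=k, e=e, t=t, m=m, result=res))
    return rows, select_best(rows)


def select_best(rows: Sequence[SweepRow]) -> SweepRow:
    """Argmax by f1; ties broken by higher precision, then lower e."""
    return max(rows, key=lambda r: (r.result.f1, r.result.precision, -r.e))


def write_sweep_tsv(rows: Sequence[SweepRow], path, extra_header=()) -> None:
    """Write the sweep table (5-decimal fixed point metrics)."""
    with open(path, "w") as fh:
        for line in extra_header:
            fh.write(f"#{line}\n")
        fh.write("k\te\tt\tm\ttp\tfp\tfn\tprecision\trecall\tf1\n")
        for r in rows:
            s = r.result
            fh.write(
                f"{r.k}\t{r.e}\t{r.t}\t{r.m}\t{s.tp}\t{s.fp}\t{s.fn}"
                f"\t{s.precision:.5f}\t{s.recall:.5f}\t{s.f1:.5f}\n"
            )
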