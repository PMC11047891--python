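import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from l1pd.mapper import HitTable, ProbeHit, revcomp
from l1pd.patternmatch import (
    DetectionParams,
    Pattern,
    call_from_pattern,
    chain_hits,
    dedupe_patterns,
    detect,
    distance_ok,
)
from l1pd.seqio import ComponentLengthModel, ProbeRecord

import oracles
from conftest import make_record


def probes_at(offsets, k=20):
    return [
        ProbeRecord(f"L1PD_probe_{i+1}", 1, k, off, "A" * k)
        for i, off in enumerate(offsets)
    ]


def hit(pid, pos, strand="+", k=20, d=0):
    return ProbeHit(pid, "chr1", pos, strand, d, k)


MODEL = ComponentLengthModel(
    mode_5utr=900,
    mode_orf1=1000,
    mode_spacer=60,
    mode_orf2=3800,
    mode_3utr=240,
    mode_total=6000,
    mode_orf1start_to_orf2start=1060,
)


class TestDistanceOk:
    P = probes_at([0, 500])

    def test_zero_deviation(self):
        assert distance_ok(hit("a", 10_000), hit("b", 10_500), *self.P, t=0)

    def test_deviation_beyond_threshold(self):
        assert not distance_ok(hit("a", 10_000), hit("b", 10_560), *self.P, t=50)

    def test_default_human_threshold_absorbs_deviation(self):
        assert distance_ok(hit("a", 10_000), hit("b", 10_560), *self.P, t=625)


class TestChainHits:
    def test_all_probes_at_exact_spacing(self):
        probes = probes_at([0, 500, 1100, 1800, 2600])
        hits = [hit(p.probe_id, 10_000 + p.offset) for p in probes]
        patterns = chain_hits(
            HitTable.from_hits(hits), probes, DetectionParams(e=0, t=0, m=2)
        )
        assert len(patterns) == 1
        assert patterns[0].n_probes == 5
        assert patterns[0].gap_error_sum == 0

    def test_below_min_probes_yields_nothing(self):
        probes = probes_at([0, 500, 1100])
        hits = [hit(probes[0].probe_id, 10_000), hit(probes[1].probe_id, 10_500)]
        assert (
            chain_hits(HitTable.from_hits(hits), probes, DetectionParams(e=0, t=0, m=3))
            == []
        )

    def test_skipped_probe_and_insertion_drift_matches_oracle(self):
        """Probe 2 absent, +40 insertion upstream of probes 4-5; t=50, m=3."""
        probes = probes_at([0, 500, 1100, 1800, 2600])
        positions = {1: 10_000, 3: 11_100, 4: 11_840, 5: 12_640}  # probe rank -> pos
        hits = [hit(probes[r - 1].probe_id, pos) for r, pos in positions.items()]
        table = HitTable.from_hits(hits)
        params = DetectionParams(e=0, t=50, m=3)
        patterns = chain_hits(table, probes, params)
        assert len(patterns) == 1
        assert [pr for pr, _ in patterns[0].members] == [0, 2, 3, 4]
        assert oracles.pattern_tuples(patterns) == oracles.enumerate_patterns(
            table, probes, t=50, m=3
        )

    def test_oracle_equivalence_random_instances(self):
        probes = probes_at([0, 60, 130, 210, 300])
        rng = np.random.default_rng(2024)
        for case in range(40):
            n = int(rng.integers(2, 11))
            hits = []
            for _ in range(n):
                p = probes[int(rng.integers(0, len(probes)))]
                base = int(rng.integers(0, 3)) * 1000
                jitter = int(rng.integers(-30, 31))
                strand = "+" if rng.random() < 0.8 else "-"
                hits.append(hit(p.probe_id, base + p.offset + jitter, strand))
            table = HitTable.from_hits(hits)
            t = int(rng.integers(0, 60))
            m = int(rng.integers(2, 4))
            got = oracles.pattern_tuples(
                chain_hits(table, probes, DetectionParams(e=0, t=t, m=m))
            )
            assert got == oracles.enumerate_patterns(table, probes, t=t, m=m), case

    def test_hit_order_invariance(self):
        probes = probes_at([0, 60, 130])
        hits = [
            hit(probes[0].probe_id, 100),
            hit(probes[1].probe_id, 160),
            hit(probes[2].probe_id, 160),  # equal position, different probe
            hit(probes[2].probe_id, 230),
        ]
        params = DetectionParams(e=0, t=10, m=2)
        base = oracles.pattern_tuples(
            chain_hits(HitTable.from_hits(hits), probes, params)
        )
        for perm in ([3, 2, 1, 0], [1, 3, 0, 2], [2, 0, 3, 1]):
            shuffled = HitTable.from_hits([hits[i] for i in perm])
            assert oracles.pattern_tuples(chain_hits(shuffled, probes, params)) == base

    @given(st.integers(0, 200), st.integers(0, 300), st.integers(2, 5))
    def test_validity_monotonicity(self, t, extra_t, m):
        """A pattern valid at (t, m) stays valid at t' >= t and m' <= m."""
        probes = probes_at([0, 60, 130, 210, 300])
        rng = np.random.default_rng(t * 7 + m)
        hits = [
            hit(p.probe_id, 5_000 + p.offset + int(rng.integers(-40, 41)))
            for p in probes
        ]
        patterns = chain_hits(
            HitTable.from_hits(hits), probes, DetectionParams(e=0, t=t, m=m)
        )
        for p in patterns:
            assert p.n_probes >= m  # m' <= m trivially satisfied
            ranks = [r for r, _ in p.members]
            assert ranks == sorted(ranks) and len(set(ranks)) == len(ranks)
            for (ri, hi), (rj, hj) in zip(p.members, p.members[1:]):
                err = abs(
                    (hj.pos - hi.pos) - (probes[rj].offset - probes[ri].offset)
                )
                assert err <= t <= t + extra_t

    def test_anchor_mode_single_element(self):
        probes = probes_at([0, 500, 1100])
        hits = [hit(p.probe_id, 10_000 + p.offset) for p in probes]
        patterns = chain_hits(
            HitTable.from_hits(hits),
            probes,
            DetectionParams(e=0, t=5, m=3, gap_mode="anchor"),
        )
        assert len(patterns) == 1 and patterns[0].n_probes == 3


class TestDedupe:
    def pattern(self, interval, n, gap=0, strand="+"):
        members = [
            (i, hit(f"L1PD_probe_{i+1}", interval[0] + i, strand)) for i in range(n)
        ]
        return Pattern("chr1", strand, members, gap, projected_interval=interval)

    def test_more_probes_wins(self):
        a, b = self.pattern((100, 6100), 9), self.pattern((100, 6100), 7)
        assert dedupe_patterns([b, a]) == [a]

    def test_disjoint_both_kept(self):
        a, b = self.pattern((100, 6100), 9), self.pattern((20_000, 26_000), 9)
        assert len(dedupe_patterns([a, b])) == 2

    def test_equal_priority_leftmost_kept(self):
        a, b = self.pattern((100, 6100), 9), self.pattern((103, 6103), 9)
        kept = dedupe_patterns([b, a])
        assert kept == [a]


class TestCallFromPattern:
    def test_plus_strand_extrapolation(self):
        probes = probes_at([120], k=50)
        p = Pattern("chr1", "+", [(0, hit("L1PD_probe_1", 10_000, k=50))], 0)
        call = call_from_pattern(p, probes, MODEL, chrom_len=50_000)
        assert (call.start, call.end) == (8_981, 14_980)

    def test_start_clamped_to_chromosome(self):
        probes = probes_at([120], k=50)
        p = Pattern("chr1", "+", [(0, hit("L1PD_probe_1", 50, k=50))], 0)
        call = call_from_pattern(p, probes, MODEL, chrom_len=50_000)
        assert call.start == 1

    def test_minus_strand_mirrors_plus(self):
        probes = probes_at([120], k=50)
        L = 50_000
        plus = call_from_pattern(
            Pattern("chr1", "+", [(0, hit("a", 10_000, k=50))], 0), probes, MODEL, L
        )
        # the same locus seen on the reverse-complemented genome
        rc_pos = L - (10_000 + 50)
        minus = call_from_pattern(
            Pattern("chr1", "-", [(0, hit("a", rc_pos, "-", k=50))], 0),
            probes,
            MODEL,
            L,
        )
        assert (minus.start, minus.end) == (L - plus.end + 1, L - plus.start + 1)


class TestDetect:
    def test_strand_symmetry_on_synthetic_genome(self, small_truth, small_probes, small_params):
        calls = detect(small_truth.genome, small_probes, small_truth.records, small_params)
        chrom = small_truth.config.chrom_name
        L = len(small_truth.genome[chrom])
        rc_genome = {chrom: revcomp(small_truth.genome[chrom])}
        rc_calls = detect(rc_genome, small_probes, small_truth.records, small_params)
        mirrored = sorted(
            (c.chrom, L - c.end + 1, L - c.start + 1, "+" if c.strand == "-" else "-")
            for c in rc_calls
        )
        assert mirrored == sorted((c.chrom, c.start, c.end, c.strand) for c in calls)

    def test_truncated_copy_yields_no_call(self, small_truth, small_probes, small_params):
        calls = detect(small_truth.genome, small_probes, small_truth.records, small_params)
        for _, s, e, _ in small_truth.truncated:
            for c in calls:
                overlap = min(c.end, e) - max(c.start, s) + 1
                assert overlap < 0.5 * (e - s + 1)

    def test_no_calls_on_element_free_sequence(self, small_probes, small_params):
        rng = np.random.default_rng(99)
        genome = {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, size=30_000))}
        calls = detect(genome, small_probes, [make_record()], small_params)
        assert calls == []
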