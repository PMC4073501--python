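"""CNVR aggregation: overlap-closure oracle, merging, summary arithmetic."""

import itertools

import numpy as np
import pytest

from cnvherd import Cnvr, CnvCall, cnvr, default_genome
from cnvherd.core import BOTH, GAIN, LOSS, overlap_bp


def brute_force_components(intervals):
    """Transitive closure of pairwise interval overlap, by explicit graph walk."""
    n = len(intervals)
    adj = {i: set() for i in range(n)}
    for i, j in itertools.combinations(range(n), 2):
        ci, cj = intervals[i], intervals[j]
        if ci[0] == cj[0] and overlap_bp(ci[1], ci[2], cj[1], cj[2]) > 0:
            adj[i].add(j)
            adj[j].add(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        comps.append(comp)
    return {
        (
            intervals[min(c)][0],
            min(intervals[k][1] for k in c),
            max(intervals[k][2] for k in c),
            frozenset(c),
        )
        for c in comps
    }


def call(sample, chrom, start, end, state=LOSS):
    return CnvCall(sample, chrom, start, end, state, -0.8 if state == LOSS else 0.8, 6)


class TestBuildCnvrs:
    def test_single_call_single_cnvr(self):
        (r,) = cnvr.build_cnvrs([call("A", "1", 100, 200)], ["A", "B", "C"])
        assert (r.chrom, r.start, r.end) == ("1", 100, 200)
        assert r.carriers == ("A",)
        assert r.frequency == pytest.approx(1 / 3)

    def test_gain_plus_loss_makes_both(self):
        (r,) = cnvr.build_cnvrs(
            [call("A", "1", 100, 200, GAIN), call("B", "1", 150, 250, LOSS)], ["A", "B"]
        )
        assert (r.start, r.end, r.state) == (100, 250, BOTH)
        assert r.carriers == ("A", "B")

    def test_disjoint_calls_stay_separate(self):
        rs = cnvr.build_cnvrs([call("A", "1", 0, 100), call("A", "1", 200, 300)], ["A"])
        assert len(rs) == 2

    def test_bookended_calls_do_not_merge(self):
        rs = cnvr.build_cnvrs([call("A", "1", 0, 100), call("B", "1", 100, 200)], ["A", "B"])
        assert len(rs) == 2

    def test_components_match_brute_force_closure(self, rng):
        """Random call sets: regions equal the pairwise-overlap transitive closure."""
        for trial in range(200):
            n = int(rng.integers(1, 31))
            calls = []
            for k in range(n):
                chrom = str(rng.integers(1, 4))
                start = int(rng.integers(0, 5000))
                length = int(rng.integers(1, 800))
                calls.append(call(f"s{k % 7}", chrom, start, start + length))
            regions = cnvr.build_cnvrs(calls, [f"s{i}" for i in range(7)])
            got = {(r.chrom, r.start, r.end) for r in regions}
            want = {(c, s, e) for c, s, e, _ in brute_force_components(
                [(c.chrom, c.start, c.end) for c in calls]
            )}
            assert got == want

    def test_idempotent_when_cnvrs_fed_back_as_calls(self, rng):
        calls = [
            call(f"s{k}", "1", int(rng.integers(0, 3000)), int(rng.integers(3000, 6000)))
            for k in range(12)
        ]
        regions = cnvr.build_cnvrs(calls, [f"s{k}" for k in range(12)])
        again = cnvr.build_cnvrs(
            [call(r.carriers[0], r.chrom, r.start, r.end) for r in regions],
            [f"s{k}" for k in range(12)],
        )
        assert [(r.chrom, r.start, r.end) for r in again] == [
            (r.chrom, r.start, r.end) for r in regions
        ]

    def test_input_order_invariance(self, rng):
        calls = [
            call(f"s{k % 3}", str(rng.integers(1, 3)), int(s := rng.integers(0, 2000)), int(s) + 500)
            for k in range(15)
        ]
        a = cnvr.build_cnvrs(calls, ["s0", "s1", "s2"])
        b = cnvr.build_cnvrs(list(reversed(calls)), ["s0", "s1", "s2"])
        assert [(r.chrom, r.start, r.end, r.state, r.carriers) for r in a] == [
            (r.chrom, r.start, r.end, r.state, r.carriers) for r in b
        ]

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValueError, match="not in the group"):
            cnvr.build_cnvrs([call("X", "1", 0, 10)], ["A"])

    def test_every_call_contained_in_exactly_one_cnvr(self, rng):
        calls = [
            call("A", "1", int(s := rng.integers(0, 4000)), int(s) + int(rng.integers(50, 500)))
            for _ in range(25)
        ]
        regions = cnvr.build_cnvrs(calls, ["A"])
        for c in calls:
            containing = [
                r for r in regions if r.chrom == c.chrom and r.start <= c.start and c.end <= r.end
            ]
            assert len(containing) == 1
        # regions pairwise disjoint
        for r1, r2 in itertools.combinations(regions, 2):
            if r1.chrom == r2.chrom:
                assert overlap_bp(r1.start, r1.end, r2.start, r2.end) == 0


class TestMergeGroups:
    def cnvr_of(self, gid, chrom, start, end, carriers=("x",), state=LOSS):
        return Cnvr(gid, chrom, start, end, state, tuple(carriers), 0.5)

    def test_identical_regions_merge_with_both_provenances(self):
        merged, venn = cnvr.merge_groups(
            {
                "taurine": [self.cnvr_of("t1", "1", 100, 200, ("a",))],
                "yak": [self.cnvr_of("y1", "1", 100, 200, ("b",))],
            },
            total_samples=2,
        )
        (m,) = merged
        assert m.groups == ("taurine", "yak")
        assert venn == {("taurine", "yak"): 1}

    def test_disjoint_group_exclusive_regions(self):
        merged, venn = cnvr.merge_groups(
            {
                "t": [self.cnvr_of("t1", "1", 0, 100)],
                "y": [self.cnvr_of("y1", "1", 200, 300)],
                "b": [self.cnvr_of("b1", "2", 0, 100)],
            },
            total_samples=3,
        )
        assert len(merged) == 3
        assert venn == {("t",): 1, ("y",): 1, ("b",): 1}

    def test_nested_overlap_provenance_matches_brute_force(self, rng):
        for _ in range(50):
            sets = {}
            flat = []
            for g in ("t", "y", "b"):
                rs = []
                for k in range(int(rng.integers(1, 8))):
                    s = int(rng.integers(0, 3000))
                    e = s + int(rng.integers(100, 900))
                    rs.append(self.cnvr_of(f"{g}{k}", "1", s, e, carriers=(f"{g}{k}",)))
                    flat.append((g, s, e))
                sets[g] = rs
            merged, _ = cnvr.merge_groups(sets)
            comps = brute_force_components([("1", s, e) for _, s, e in flat])
            want = {
                (s, e, frozenset(flat[k][0] for k in members))
                for _, s, e, members in comps
            }
            got = {(m.start, m.end, frozenset(m.groups)) for m in merged}
            assert got == want


class TestSummarize:
    def test_accounting_reproduces_published_style_arithmetic(self):
        """329 loss + 113 gain + 44 both over 24 samples, 71.5 of 2918.1 Mb -> 2.45%."""
        states = [LOSS] * 329 + [GAIN] * 113 + [BOTH] * 44
        total_len = 71_500_000
        per = total_len // 486
        cnvrs = [
            Cnvr(f"r{i}", "1", i * 200_000, i * 200_000 + per + (1 if i < total_len % 486 else 0),
                 st, ("s1",) if i < 96 else ("s1", "s2"), 1 / 24)
            for i, st in enumerate(states)
        ]
        s = cnvr.summarize(cnvrs, genome_length=2_918_100_000, n_samples=24)
        assert s.n_cnvrs == 486
        assert (s.n_gain, s.n_loss, s.n_both) == (113, 329, 44)
        assert s.n_unique == 96
        assert s.cnvrs_per_sample == pytest.approx(20.25, abs=0.01)
        assert s.percent_genome == pytest.approx(2.45, abs=0.01)

    def test_empty_set_all_zero(self):
        s = cnvr.summarize([], genome_length=1000, n_samples=2)
        assert s.n_cnvrs == 0 and s.total_length_bp == 0 and s.percent_genome == 0.0

    def test_rejects_zero_genome(self):
        with pytest.raises(ValueError):
            cnvr.summarize([], genome_length=0, n_samples=1)


class TestChromCoverage:
    def test_single_chromosome_coverage(self):
        g = default_genome()  # 5 x 10 Mb + M
        rs = [Cnvr("r1", "1", 0, 1_000_000, LOSS, ("a",), 0.5)]
        cov = dict(cnvr.chrom_coverage(rs, g))
        assert cov["1"] == pytest.approx(10.0)
        assert cov["2"] == 0.0

    def test_full_chromosome_is_100_percent(self):
        g = default_genome()
        rs = [Cnvr("r1", "M", 0, 16_338, GAIN, ("a",), 1.0)]
        assert dict(cnvr.chrom_coverage(rs, g))["M"] == pytest.approx(100.0)

    def test_coverage_conserves_total_length(self, rng):
        g = default_genome()
        rs = []
        pos = 0
        for i in range(10):
            start = pos + int(rng.integers(1000, 5000))
            end = start + int(rng.integers(1000, 30_000))
            rs.append(Cnvr(f"r{i}", str((i % 5) + 1), start, end, LOSS, ("a",), 1.0))
            pos = 0  # chromosomes differ, overlap impossible across them
        total_from_cov = sum(
            pct / 100.0 * g.length_of(c) for c, pct in cnvr.chrom_coverage(rs, g)
        )
        assert total_from_cov == pytest.approx(sum(r.length for r in rs))
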