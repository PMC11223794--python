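"""Detection grammar, loop localization, strand handling."""

import numpy as np
import pytest

from imseeker.detect import (DetectionConfigError, DetectionParams,
                             assign_loops, enumerate_candidates, find_c_runs,
                             reverse_complement, scan)
from oracles import char_scan_c_runs, oracle_candidates


def random_seq(rng, n, p_c=0.3):
    """C-enriched random sequence so candidates actually occur."""
    rest = (1 - p_c) / 3
    return "".join(rng.choice(list("ACGT"), size=n,
                              p=[rest, p_c, rest, rest]))


class TestFindCRuns:
    @pytest.mark.parametrize("seq,expected", [
        ("CCCACCC", [(0, 3), (4, 7)]),
        ("AGTG", []),
        ("", []),
        ("CCCC", [(0, 4)]),
        ("ACCNCC", [(1, 3), (4, 6)]),
    ])
    def test_examples(self, seq, expected):
        assert find_c_runs(seq) == expected

    def test_matches_character_scan(self, rng):
        for _ in range(30):
            seq = random_seq(rng, 200)
            assert find_c_runs(seq) == char_scan_c_runs(seq)


class TestEnumerate:
    def test_canonical_telomeric_motif(self):
        cands = enumerate_candidates("CCCTAACCCTAACCCTAACCC")
        assert len(cands) == 1
        c = cands[0]
        assert (c.start, c.end) == (0, 21)
        assert [t.length for t in c.tracts] == [3, 3, 3, 3]
        assert c.loop_lengths() == (3, 3, 3)
        assert [lp.role for lp in c.loops] == ["side", "middle", "side"]

    def test_pure_poly_c_yields_nothing(self):
        assert enumerate_candidates("C" * 10) == []
        assert enumerate_candidates("C" * 60) == []

    def test_invalid_params_name_offending_field(self):
        with pytest.raises(DetectionConfigError, match="tract_len_max"):
            enumerate_candidates("CCC", DetectionParams(tract_len_min=5,
                                                        tract_len_max=3))
        with pytest.raises(DetectionConfigError, match="side_loop_max"):
            DetectionParams(side_loop_max=99).validate()

    def test_tiling_invariant(self, rng):
        """Tracts and loops alternate and tile the motif exactly."""
        for _ in range(20):
            seq = random_seq(rng, 300)
            for c in enumerate_candidates(seq, DetectionParams(
                    allow_overlap=True)):
                total = sum(t.length for t in c.tracts) + \
                    sum(lp.length for lp in c.loops)
                assert total == c.length
                assert c.sequence[0] == "C" and c.sequence[-1] == "C"
                pieces = []
                for t, lp in zip(c.tracts, list(c.loops) + [None]):
                    pieces.append((t.start, t.end))
                    if lp is not None:
                        pieces.append((lp.start, lp.end))
                flat = [x for p in pieces for x in p]
                assert flat[0] == 0 and flat[-1] == c.length
                assert all(a == b for a, b in zip(flat[1:-1:2], flat[2::2]))

    def test_monotone_in_loop_and_tract_relaxation(self, rng):
        base = DetectionParams(allow_overlap=True)
        wider = DetectionParams(allow_overlap=True, loop_max=20,
                                tract_len_max=7)
        for _ in range(15):
            seq = random_seq(rng, 300)
            assert len(enumerate_candidates(seq, wider)) >= \
                len(enumerate_candidates(seq, base))

    def test_overlap_filter_keeps_leftmost(self):
        seq = "CCCACCCACCCACCCACCCACCC"  # 6 runs: anchors 1..3 feasible
        allo = enumerate_candidates(seq, DetectionParams(allow_overlap=True))
        dis = enumerate_candidates(seq, DetectionParams(allow_overlap=False))
        assert len(allo) == 3
        assert len(dis) == 1
        assert dis[0].start == min(c.start for c in allo)

    def test_greedy_extends_nongreedy(self):
        seq = "CCCCCTAACCCCTAACCCTAACCCCC"
        ng = enumerate_candidates(seq, DetectionParams(greedy=False))[0]
        g = enumerate_candidates(seq, DetectionParams(greedy=True))[0]
        assert g.length > ng.length
        assert g.start <= ng.start and g.end >= ng.end


class TestAssignLoops:
    def test_equal_vs_short_side_modes(self):
        region = "CCCCACCCTTTTCCCACCCC"
        t, loops = assign_loops(region, DetectionParams(
            loop_mode="equal_loops"), tract_len=3)
        assert tuple(lp.length for lp in loops) == (2, 4, 2)
        t, loops = assign_loops(region, DetectionParams(
            loop_mode="short_side_loops"), tract_len=3)
        assert tuple(lp.length for lp in loops) == (1, 4, 1)

    def test_unique_placement_modes_agree(self):
        region = "CCCTAACCCTTACCCGTACCC"  # every run exactly 3 C
        a = assign_loops(region, DetectionParams(loop_mode="equal_loops"))
        b = assign_loops(region, DetectionParams(loop_mode="short_side_loops"))
        assert a == b

    def test_optimum_matches_exhaustive_search(self, rng):
        """Chosen placement attains the brute-force optimum objective."""
        from oracles import _loop_objective, _roles_ok, all_parses
        for _ in range(20):
            # region with exactly four C-runs so every parse uses all of them
            parts = []
            for i in range(4):
                parts.append("C" * int(rng.integers(3, 7)))
                if i < 3:
                    n = int(rng.integers(1, 9))
                    parts.append("".join(rng.choice(list("AGT"), size=n)))
            region = "".join(parts)
            for mode in ("equal_loops", "short_side_loops"):
                params = DetectionParams(loop_mode=mode)
                res = assign_loops(region, params)
                parses = [p for p in all_parses(region, params)
                          if _roles_ok(p, params) and len(p) == 4]
                if not parses:
                    assert res is None
                    continue
                tracts, _ = res
                got = _loop_objective(
                    tuple((t.start, t.end) for t in tracts), mode)
                best = min(_loop_objective(p, mode) for p in parses)
                assert got == best

    def test_infeasible_region_rejected(self):
        assert assign_loops("CCCACCC", DetectionParams()) is None


class TestScan:
    def test_reverse_complement_symmetry(self, rng):
        both = DetectionParams(scan_reverse_complement=True)
        fwd = DetectionParams(scan_reverse_complement=False)
        for _ in range(10):
            seq = random_seq(rng, 400)
            n_both = len(list(scan([("s", seq)], both)))
            n_f = len(list(scan([("s", seq)], fwd)))
            n_r = len(list(scan([("s", reverse_complement(seq))], fwd)))
            assert n_both == n_f + n_r

    def test_mirrored_records_give_mirrored_strands(self):
        seq = "TTTT" + "CCCTAACCCTAACCCTAACCC" + "TTTT"
        recs = [("a", seq), ("b", reverse_complement(seq))]
        hits = list(scan(recs, DetectionParams(scan_reverse_complement=True)))
        by_rec = {h.seq_id: h for h in hits}
        assert len(hits) == 2
        assert by_rec["a"].strand == "+" and by_rec["b"].strand == "-"
        assert by_rec["a"].sequence == by_rec["b"].sequence
        assert (by_rec["a"].start, by_rec["a"].end) == \
            (by_rec["b"].start, by_rec["b"].end)

    def test_all_n_record_is_empty(self):
        assert list(scan([("n", "N" * 500)])) == []


class TestOracleEquivalence:
    @pytest.mark.parametrize("greedy", [False, True])
    @pytest.mark.parametrize("mode", ["equal_loops", "short_side_loops"])
    def test_random_sequences_match_grammar_oracle(self, rng, greedy, mode):
        params = DetectionParams(greedy=greedy, loop_mode=mode)
        for _ in range(25):
            seq = random_seq(rng, 150, p_c=0.35)
            got = [(c.start, c.end) for c in enumerate_candidates(seq, params)]
            want = [(s, e) for s, e, _ in oracle_candidates(seq, params)]
            assert got == want, seq

    def test_parses_match_not_just_extents(self, rng):
        params = DetectionParams(allow_overlap=True)
        for _ in range(10):
            seq = random_seq(rng, 150, p_c=0.35)
            got = {(c.start, c.end):
                   tuple((t.start + c.start, t.end + c.start)
                         for t in c.tracts)
                   for c in enumerate_candidates(seq, params)}
            want = {(s, e): p for s, e, p in oracle_candidates(seq, params)}
            assert got == want
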