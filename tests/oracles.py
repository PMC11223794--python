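"""Independent brute-force oracles used to cross-check the implementation.

The detection oracle walks the constraint grammar character by character
from every possible start position, enumerating *all* valid parses of every
substring, then applies the published selection rules (per-anchor extent
preference, loop-localization objective, left-to-right overlap resolution).
It shares no code with the run-based scanner in the package.
"""

from __future__ import annotations

from typing import Iterator, List, Optional, Sequence, Tuple

from imseeker.detect import DetectionParams

Parse = Tuple[Tuple[int, int], ...]  # absolute (tract_start, tract_end) pairs


def char_scan_c_runs(seq: str) -> List[Tuple[int, int]]:
    """Maximal C-runs by a plain character scan."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "C":
            j = i
            while j < n and seq[j] == "C":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _loop_ok(seq: str, lo: int, hi: int, params: DetectionParams) -> bool:
    loop = seq[lo:hi]
    if all(c == "C" for c in loop):
        return False  # a loop must contain at least one non-C base
    if not params.allow_n_in_loops and any(c not in "ACGT" for c in loop):
        return False
    return True


def _role(i: int, k: int) -> str:
    return "side" if i == 0 or i == k - 2 else "middle"


def all_parses(seq: str, params: DetectionParams) -> Iterator[Parse]:
    """Every valid parse (tract placement) anywhere in the sequence."""
    n = len(seq)
    runs = char_scan_c_runs(seq)
    eligible = [(s, e) for s, e in runs if e - s >= params.tract_len_min]

    def buried_run(lo: int, hi: int) -> bool:
        return any(lo <= s and e <= hi for s, e in eligible)

    def rec(tracts: List[Tuple[int, int]]) -> Iterator[Parse]:
        k_now = len(tracts)
        if k_now >= params.n_tracts_min:
            yield tuple(tracts)
        if k_now == params.n_tracts_max:
            return
        prev_end = tracts[-1][1]
        # role of the next loop depends on the final tract count; try every
        # compatible bound and validate roles on the complete parse instead
        max_hi = max(params.loop_bounds("side")[1],
                     params.loop_bounds("middle")[1])
        for l in range(1, max_hi + 1):
            ts = prev_end + l
            if ts >= n or seq[ts] != "C":
                continue
            if not _loop_ok(seq, prev_end, ts, params):
                continue
            if buried_run(prev_end, ts):
                continue
            for t in range(params.tract_len_min, params.tract_len_max + 1):
                if ts + t > n or any(seq[ts + i] != "C" for i in range(t)):
                    break
                yield from rec(tracts + [(ts, ts + t)])

    for start in range(n):
        for t in range(params.tract_len_min, params.tract_len_max + 1):
            if start + t > n or any(seq[start + i] != "C" for i in range(t)):
                break
            yield from rec([(start, start + t)])


def _roles_ok(parse: Parse, params: DetectionParams) -> bool:
    k = len(parse)
    for i in range(k - 1):
        lo, hi = params.loop_bounds(_role(i, k))
        ll = parse[i + 1][0] - parse[i][1]
        if not (lo <= ll <= hi):
            return False
    return True


def _loop_objective(parse: Parse, mode: str) -> Tuple:
    lens = [parse[i + 1][0] - parse[i][1] for i in range(len(parse) - 1)]
    if not lens:
        return ()
    m = sum(lens) / len(lens)
    var = sum((x - m) ** 2 for x in lens) / len(lens)
    if mode == "short_side_loops":
        return (lens[0] + lens[-1], var)
    return (var,)


def oracle_candidates(seq: str, params: DetectionParams
                      ) -> List[Tuple[int, int, Parse]]:
    """The candidate set the grammar implies, as (start, end, parse) tuples."""
    seq = seq.upper()
    runs = char_scan_c_runs(seq)

    def anchor_of(pos: int) -> int:
        for i, (s, e) in enumerate(runs):
            if s <= pos < e:
                return i
        raise AssertionError("parse start not in a C-run")

    per_anchor = {}
    for parse in all_parses(seq, params):
        if not _roles_ok(parse, params):
            continue
        extent = parse[-1][1] - parse[0][0]
        k = len(parse)
        if params.greedy:
            key = (-extent, -k, _loop_objective(parse, params.loop_mode), parse)
        else:
            key = (extent, k, _loop_objective(parse, params.loop_mode), parse)
        a = anchor_of(parse[0][0])
        if a not in per_anchor or key < per_anchor[a][0]:
            per_anchor[a] = (key, parse)
    cands = sorted(((p[0][0], p[-1][1], p) for _, p in per_anchor.values()),
                   key=lambda c: (c[0], c[1]))
    if not params.allow_overlap:
        kept = []
        max_end = -1
        for c in cands:
            if c[0] >= max_end:
                kept.append(c)
                max_end = c[1]
        cands = kept
    return cands


def brute_force_r2_best(objective, values) -> Tuple:
    """Exhaustive argmax over a finite 1-D domain."""
    best_v, best_y = None, float("-inf")
    for v in values:
        y = objective(v)
        if y > best_y:
            best_v, best_y = v, y
    return best_v, best_y
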