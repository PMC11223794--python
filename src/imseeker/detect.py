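"""Detection of putative i-motif forming sequences.

An i-motif forming sequence is modelled as ``k`` cytosine tracts (runs of
consecutive C) separated by ``k - 1`` loops.  The first and last loops are
*side* loops, interior ones *middle* loops, and each role carries its own
length bounds.  Detection enumerates candidates under a canonical grammar:

* tracts are sub-intervals of maximal C-runs, and each maximal run hosts at
  most one tract (equivalently, every loop contains at least one non-C base);
* a candidate uses *consecutive* eligible runs: no run long enough to serve
  as a tract may lie wholly inside a loop;
* each eligible run is an *anchor* and yields at most one candidate — the
  minimal-extent valid motif starting there (non-greedy, the default) or the
  maximal-extent one (greedy).

When a run is longer than the tract length placed in it, the tract's offset
within the run is chosen by the loop-localization objective: ``equal_loops``
minimizes the variance of loop lengths, ``short_side_loops`` minimizes the
summed side-loop length first.  Leftover cytosines of the run spill into the
adjacent loops.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple

__all__ = [
    "CTract",
    "Loop",
    "DetectionParams",
    "IMotifCandidate",
    "DetectionConfigError",
    "FastaFormatError",
    "find_c_runs",
    "assign_loops",
    "enumerate_candidates",
    "scan",
    "reverse_complement",
]

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_C_RUN = re.compile(r"C+")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC beyond ACGTN maps to itself)."""
    return seq.translate(_RC)[::-1]


class DetectionConfigError(ValueError):
    """Raised when a DetectionParams field is out of its sanity range."""


class FastaFormatError(ValueError):
    """Raised when an input FASTA stream cannot be parsed."""


@dataclass(frozen=True)
class CTract:
    """One cytosine tract, 0-based half-open, relative to the motif start."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Loop:
    """One loop between consecutive tracts; role is 'side' or 'middle'."""

    start: int
    end: int
    role: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DetectionParams:
    """All knobs of the i-motif prediction function.

    Defaults follow the common configuration: exactly four C-tracts of
    3-5 cytosines each, loops of 1-12 nucleotides, non-greedy extension,
    no overlapping calls, both strands scanned at genome scale.
    """

    n_tracts_min: int = 4
    n_tracts_max: int = 4
    tract_len_min: int = 3
    tract_len_max: int = 5
    loop_min: int = 1
    loop_max: int = 12
    side_loop_min: Optional[int] = None
    side_loop_max: Optional[int] = None
    middle_loop_min: Optional[int] = None
    middle_loop_max: Optional[int] = None
    greedy: bool = False
    allow_overlap: bool = False
    loop_mode: str = "equal_loops"
    scan_reverse_complement: bool = True
    allow_n_in_loops: bool = False

    def validate(self) -> None:
        for name in ("n_tracts_min", "tract_len_min", "loop_min"):
            if getattr(self, name) < 1:
                raise DetectionConfigError(f"{name} must be >= 1")
        if self.n_tracts_max < self.n_tracts_min:
            raise DetectionConfigError("n_tracts_max < n_tracts_min")
        if self.tract_len_max < self.tract_len_min:
            raise DetectionConfigError("tract_len_max < tract_len_min")
        if self.loop_max < self.loop_min:
            raise DetectionConfigError("loop_max < loop_min")
        for name in ("side_loop_min", "side_loop_max", "middle_loop_min",
                     "middle_loop_max"):
            v = getattr(self, name)
            if v is not None and not (1 <= v <= 50):
                raise DetectionConfigError(f"{name} must lie in [1, 50]")
        for role in ("side", "middle"):
            lo, hi = self.loop_bounds(role)
            if hi < lo:
                raise DetectionConfigError(f"{role}_loop_max < {role}_loop_min")
        if self.loop_mode not in ("equal_loops", "short_side_loops"):
            raise DetectionConfigError(
                f"loop_mode must be 'equal_loops' or 'short_side_loops', "
                f"got {self.loop_mode!r}")

    def loop_bounds(self, role: str) -> Tuple[int, int]:
        """Effective (min, max) length for a loop of the given role."""
        if role == "side":
            lo = self.side_loop_min if self.side_loop_min is not None else self.loop_min
            hi = self.side_loop_max if self.side_loop_max is not None else self.loop_max
        else:
            lo = self.middle_loop_min if self.middle_loop_min is not None else self.loop_min
            hi = self.middle_loop_max if self.middle_loop_max is not None else self.loop_max
        return lo, hi


@dataclass(frozen=True)
class IMotifCandidate:
    """One detected putative i-motif.

    ``start``/``end`` are 0-based half-open forward-strand coordinates on the
    source record; ``sequence`` is the motif read in its C-rich orientation,
    and tract/loop offsets are relative to the motif start in that
    orientation.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    sequence: str
    tracts: Tuple[CTract, ...]
    loops: Tuple[Loop, ...]

    @property
    def length(self) -> int:
        return self.end - self.start

    def tract_string(self) -> str:
        return ";".join(f"{t.start}-{t.end}" for t in self.tracts)

    def loop_lengths(self) -> Tuple[int, ...]:
        return tuple(lp.length for lp in self.loops)


def find_c_runs(sequence: str) -> List[Tuple[int, int]]:
    """Maximal runs of 'C' as 0-based half-open intervals, sorted by start."""
    return [(m.start(), m.end()) for m in _C_RUN.finditer(sequence)]


def _loop_role(i: int, k: int) -> str:
    return "side" if i == 0 or i == k - 2 else "middle"


def _loop_objective(loop_lens: Sequence[int], mode: str) -> Tuple[float, ...]:
    n = len(loop_lens)
    mean = sum(loop_lens) / n
    var = sum((x - mean) ** 2 for x in loop_lens) / n
    if mode == "short_side_loops":
        return (loop_lens[0] + loop_lens[-1], var)
    return (var,)


def _placements(seq: str, runs: Sequence[Tuple[int, int]], params: DetectionParams
                ) -> Iterator[Tuple[Tuple[int, int], ...]]:
    """Enumerate all valid tract placements over the given consecutive runs.

    Yields tuples of absolute (tract_start, tract_end) pairs, one per run.
    Loops between consecutive tracts are validated against their role bounds
    and, unless ``allow_n_in_loops``, against an ACGT-only alphabet.
    """
    k = len(runs)
    out: List[Tuple[int, int]] = []

    def rec(i: int, prev_end: int) -> Iterator[Tuple[Tuple[int, int], ...]]:
        s, e = runs[i]
        run_len = e - s
        for t in range(params.tract_len_min,
                       min(params.tract_len_max, run_len) + 1):
            for o in range(run_len - t + 1):
                ts, te = s + o, s + o + t
                if i > 0:
                    lo, hi = params.loop_bounds(_loop_role(i - 1, k))
                    loop_len = ts - prev_end
                    if not (lo <= loop_len <= hi):
                        continue
                    if not params.allow_n_in_loops:
                        loop = seq[prev_end:ts]
                        if any(c not in "ACGT" for c in loop):
                            continue
                out.append((ts, te))
                if i == k - 1:
                    yield tuple(out)
                else:
                    yield from rec(i + 1, te)
                out.pop()

    yield from rec(0, -1)


def _placement_key(placement: Sequence[Tuple[int, int]], params: DetectionParams,
                   ) -> Tuple:
    """Secondary ordering: loop objective for the configured mode, then leftmost."""
    loop_lens = [placement[i + 1][0] - placement[i][1]
                 for i in range(len(placement) - 1)]
    if not loop_lens:
        return ((), placement)
    return (_loop_objective(loop_lens, params.loop_mode), placement)


def _best_at_anchor(seq: str, eligible: Sequence[Tuple[int, int]], j: int,
                    params: DetectionParams
                    ) -> Optional[Tuple[Tuple[int, int], ...]]:
    """Best placement anchored at eligible run ``j``, or None.

    Extent (motif length) is the primary objective: minimal for non-greedy,
    maximal for greedy; among equal extents the tract count follows the same
    preference, then the loop-localization objective, then leftmost.
    """
    best = None
    best_key = None
    for k in range(params.n_tracts_min, params.n_tracts_max + 1):
        if j + k > len(eligible):
            break
        runs = eligible[j:j + k]
        # cheap feasibility: the inter-run gap is a lower bound on each loop
        feasible = True
        for i in range(k - 1):
            gap = runs[i + 1][0] - runs[i][1]
            _, hi = params.loop_bounds(_loop_role(i, k))
            if gap > hi:
                feasible = False
                break
        if not feasible:
            continue
        for placement in _placements(seq, runs, params):
            extent = placement[-1][1] - placement[0][0]
            if params.greedy:
                key = (-extent, -k, _placement_key(placement, params))
            else:
                key = (extent, k, _placement_key(placement, params))
            if best_key is None or key < best_key:
                best_key = key
                best = placement
    return best


def _make_candidate(seq_id: str, seq: str, placement: Sequence[Tuple[int, int]],
                    strand: str = "+", offset: int = 0) -> IMotifCandidate:
    start = placement[0][0]
    end = placement[-1][1]
    k = len(placement)
    tracts = tuple(CTract(ts - start, te - start) for ts, te in placement)
    loops = tuple(
        Loop(placement[i][1] - start, placement[i + 1][0] - start,
             _loop_role(i, k))
        for i in range(k - 1))
    return IMotifCandidate(seq_id=seq_id, start=start + offset, end=end + offset,
                           strand=strand, sequence=seq[start:end],
                           tracts=tracts, loops=loops)


def assign_loops(region: str, params: DetectionParams,
                 tract_len: Optional[int] = None
                 ) -> Optional[Tuple[Tuple[CTract, ...], Tuple[Loop, ...]]]:
    """Locate tracts and loops within a candidate region.

    The region's eligible C-runs each host one tract; tract offsets within
    longer runs are chosen purely by the loop-localization objective
    (``equal_loops``: minimal loop-length variance; ``short_side_loops``:
    minimal side-loop sum, then variance), ties broken by leftmost placement.
    ``tract_len`` pins every tract to a fixed length; by default lengths vary
    freely within the configured range.  Returns None when no placement
    satisfies the loop bounds.
    """
    params.validate()
    if tract_len is not None:
        params = replace(params, tract_len_min=tract_len, tract_len_max=tract_len)
    region = region.upper()
    eligible = [r for r in find_c_runs(region)
                if r[1] - r[0] >= params.tract_len_min]
    k = len(eligible)
    if not (params.n_tracts_min <= k <= params.n_tracts_max):
        return None
    best = None
    best_key = None
    for placement in _placements(region, eligible, params):
        key = _placement_key(placement, params)
        if best_key is None or key < best_key:
            best_key = key
            best = placement
    if best is None:
        return None
    start = 0  # offsets reported relative to the region itself
    tracts = tuple(CTract(ts - start, te - start) for ts, te in best)
    loops = tuple(Loop(best[i][1], best[i + 1][0], _loop_role(i, k))
                  for i in range(k - 1))
    return tracts, loops


def enumerate_candidates(sequence: str, params: Optional[DetectionParams] = None,
                         seq_id: str = "seq", offset: int = 0
                         ) -> List[IMotifCandidate]:
    """All i-motif candidates on the forward strand of ``sequence``.

    One candidate per anchor (eligible C-run); with ``allow_overlap=False``
    candidates are selected left-to-right, skipping any that intersect an
    accepted one.  Results are sorted by (start, end).
    """
    if params is None:
        params = DetectionParams()
    params.validate()
    seq = sequence.upper()
    eligible = [r for r in find_c_runs(seq)
                if r[1] - r[0] >= params.tract_len_min]
    found: List[IMotifCandidate] = []
    for j in range(len(eligible)):
        placement = _best_at_anchor(seq, eligible, j, params)
        if placement is not None:
            found.append(_make_candidate(seq_id, seq, placement, offset=offset))
    found.sort(key=lambda c: (c.start, c.end))
    if not params.allow_overlap:
        found = _select_non_overlapping(found)
    return found


def _select_non_overlapping(cands: List[IMotifCandidate]) -> List[IMotifCandidate]:
    kept: List[IMotifCandidate] = []
    max_end = -1
    for c in cands:  # sorted by start
        if c.start >= max_end:
            kept.append(c)
            max_end = c.end
    return kept


def _map_to_forward(cand: IMotifCandidate, seq_len: int) -> IMotifCandidate:
    """Map a candidate found on the reverse complement back to forward coords."""
    return replace(cand, start=seq_len - cand.end, end=seq_len - cand.start,
                   strand="-")


def scan(records: Iterable[Tuple[str, str]],
         params: Optional[DetectionParams] = None
         ) -> Iterator[IMotifCandidate]:
    """Scan (seq_id, sequence) records, optionally on both strands.

    Reverse-strand motifs are reported in C-rich orientation with forward
    half-open coordinates and strand '-'.  Overlap resolution is per strand,
    so the both-strand count is the sum of the two single-strand counts.
    Motifs never span records.
    """
    if params is None:
        params = DetectionParams()
    params.validate()
    for seq_id, sequence in records:
        seq = str(sequence).upper()
        fwd = enumerate_candidates(seq, params, seq_id=seq_id)
        if params.scan_reverse_complement:
            rc = reverse_complement(seq)
            rev = [_map_to_forward(c, len(seq))
                   for c in enumerate_candidates(rc, params, seq_id=seq_id)]
            merged = sorted(fwd + rev, key=lambda c: (c.start, c.end, c.strand))
        else:
            merged = fwd
        yield from merged
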