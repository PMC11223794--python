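"""Detect i-motif candidates in a DNA fragment.

The human telomeric C-rich repeat (CCCTAA)n is the textbook i-motif former:
four cytosine tracts separated by TAA loops. Detection reports each
candidate's coordinates, tract layout and loop lengths.
"""

from imseeker import DetectionParams, enumerate_candidates

fragment = "TTAGGG" + "CCCTAACCCTAACCCTAACCC" + "ATATAT" + \
    "CCCCTTCCCCTTCCCCTTCCCC"

for params in (DetectionParams(),
               DetectionParams(greedy=True, loop_mode="short_side_loops")):
    mode = "greedy" if params.greedy else "non-greedy"
    print(f"\n--- {mode}, {params.loop_mode} ---")
    for c in enumerate_candidates(fragment, params):
        tracts = "/".join(str(t.length) for t in c.tracts)
        loops = "/".join(str(lp.length) for lp in c.loops)
        print(f"[{c.start:3d},{c.end:3d}) {c.strand}  tracts {tracts}  "
              f"loops {loops}  {c.sequence}")

# Each line is one putative i-motif: half-open coordinates on the fragment,
# the per-tract cytosine counts (3-5 allowed by default) and the loop
# lengths between them (1-12 allowed). Greedy mode prefers the longest
# valid motif at each anchor, non-greedy the shortest.
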