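"""Synthetic genomes and labelled training sets with known ground truth.

Two generators back all desk-scale testing of the package:

* genomes — an i.i.d. background at a chosen GC content, certified free of
  i-motif candidates on both strands, with a requested number of motifs drawn
  from the constraint grammar spiked in at recorded coordinates and strands;
* labelled datasets — random valid i-motif sequences whose label (e.g. a
  transition pH) is a known linear function of the canonical features plus
  Gaussian noise, so model-recovery can be measured against the truth.

Spiked motifs are built so that detection recovers them exactly: every
C-run has exactly the sampled tract length (the parse is unique), loops
contain no cytosine and no G-run long enough to seed a reverse-strand tract,
and each motif is padded with A/T-only flanks wider than the maximal loop
so it cannot recombine with background C-runs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .detect import (DetectionParams, IMotifCandidate, enumerate_candidates,
                     reverse_complement, scan)
from .features import FEATURE_NAMES, extract_features

__all__ = [
    "LabelModel",
    "SyntheticSpec",
    "TruthMotif",
    "random_background",
    "random_imotif",
    "spike_motifs",
    "synthetic_genome",
    "labelled_dataset",
]

PH_WINDOW = (5.5, 7.5)


@dataclass(frozen=True)
class LabelModel:
    """Linear feature->label ground truth: label = intercept + coef.x + noise."""

    coefficients: Dict[str, float]
    intercept: float
    noise_sd: float = 0.0

    def __post_init__(self):
        unknown = set(self.coefficients) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature names: {sorted(unknown)}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def signal(self, features: Dict[str, float]) -> float:
        return self.intercept + sum(c * features[n]
                                    for n, c in self.coefficients.items())


#: Default ground truth used by the desk-scale studies: transition-pH-like
#: labels driven by tract length, total loop length and A content.
DEFAULT_LABEL_MODEL = LabelModel(
    coefficients={"tract_len_mean": 0.25, "loop_len_total": -0.02,
                  "frac_A": 0.8},
    intercept=6.0,
    noise_sd=0.0,
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic genome; seed is mandatory."""

    genome_length: int
    seed: int
    gc_content: float = 0.42
    n_motifs: int = 0
    motif_params: DetectionParams = field(default_factory=DetectionParams)
    label_model: LabelModel = DEFAULT_LABEL_MODEL

    def __post_init__(self):
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must lie in (0, 1)")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")


@dataclass(frozen=True)
class TruthMotif:
    """Ground-truth placement of one spiked motif (forward half-open coords)."""

    start: int
    end: int
    strand: str
    sequence: str  # C-rich orientation


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def random_background(length: int, gc: float = 0.42, seed: int = 0,
                      params: Optional[DetectionParams] = None) -> str:
    """An i.i.d. background sequence certified motif-free on both strands.

    Accidental valid i-motifs (either strand) are destroyed by substituting
    one tract cytosine (C->T forward, G->A for reverse-strand tracts) and the
    sequence is re-scanned until clean.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if params is None:
        params = DetectionParams()
    params = _both_strand(params)
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=length, p=p))
    for _ in range(100):
        hits = list(scan([("bg", "".join(seq))], params))
        if not hits:
            return "".join(seq)
        for c in hits:
            # first base of the second tract, mapped to forward coordinates
            t = c.tracts[1]
            if c.strand == "+":
                seq[c.start + t.start] = "T"
            else:
                seq[c.end - 1 - t.start] = "A"
    raise RuntimeError("failed to produce a motif-free background")


def _both_strand(params: DetectionParams) -> DetectionParams:
    from dataclasses import replace
    return replace(params, scan_reverse_complement=True, allow_overlap=True)


def random_imotif(rng: np.random.Generator,
                  params: Optional[DetectionParams] = None) -> str:
    """One random valid i-motif sequence drawn from the constraint grammar.

    Every C-run equals its sampled tract length and loops contain no C and
    no G-run of tract length, so the sequence parses uniquely and spikes
    cleanly into a genome.
    """
    if params is None:
        params = DetectionParams()
    k = int(rng.integers(params.n_tracts_min, params.n_tracts_max + 1))
    tract_lens = rng.integers(params.tract_len_min, params.tract_len_max + 1,
                              size=k)
    bad_g = re.compile("G{%d,}" % params.tract_len_min)
    parts: List[str] = []
    for i in range(k):
        parts.append("C" * int(tract_lens[i]))
        if i < k - 1:
            role = "side" if i == 0 or i == k - 2 else "middle"
            lo, hi = params.loop_bounds(role)
            n = int(rng.integers(lo, hi + 1))
            while True:
                loop = "".join(rng.choice(list("ATG"), size=n,
                                          p=[0.4, 0.4, 0.2]))
                if not bad_g.search(loop):
                    break
            parts.append(loop)
    return "".join(parts)


def spike_motifs(background: str, n: int,
                 motif_params: Optional[DetectionParams] = None,
                 seed: int = 0, min_separation: int = 50
                 ) -> Tuple[str, List[TruthMotif]]:
    """Overwrite ``n`` motifs into a motif-free background, keeping length.

    Motifs are placed on random strands at random non-overlapping positions
    separated by at least ``min_separation`` nt, each padded by A/T-only
    flanks wider than the maximal loop bound.  The result is verified by a
    full both-strand scan against the returned truth table.
    """
    if motif_params is None:
        motif_params = DetectionParams()
    rng = np.random.default_rng(seed)
    flank = max(motif_params.loop_bounds("side")[1],
                motif_params.loop_bounds("middle")[1]) + \
        motif_params.tract_len_max + 3
    genome = list(background)
    L = len(genome)
    placed: List[Tuple[int, int]] = []
    truth: List[TruthMotif] = []
    attempts = 0
    while len(truth) < n:
        attempts += 1
        if attempts > 200 * max(n, 1):
            raise ValueError("insufficient room to place all motifs")
        motif = random_imotif(rng, motif_params)
        m = len(motif)
        pos = int(rng.integers(flank, L - m - flank + 1)) if L - m - 2 * flank >= 0 else None
        if pos is None:
            raise ValueError("background too short for a motif with flanks")
        lo, hi = pos - flank, pos + m + flank
        if any(not (hi + min_separation <= s or e + min_separation <= lo)
               for s, e in placed):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        insert = motif if strand == "+" else reverse_complement(motif)
        genome[lo:pos] = rng.choice(list("AT"), size=pos - lo).tolist()
        genome[pos:pos + m] = list(insert)
        genome[pos + m:hi] = rng.choice(list("AT"), size=hi - pos - m).tolist()
        placed.append((lo, hi))
        # the canonical detected extent of the motif itself is the truth:
        # non-greedy detection flushes over-long side tracts inward
        c0 = enumerate_candidates(motif, _strict(motif_params))[0]
        if strand == "+":
            t_start, t_end = pos + c0.start, pos + c0.end
        else:
            t_start, t_end = pos + m - c0.end, pos + m - c0.start
        truth.append(TruthMotif(start=t_start, end=t_end, strand=strand,
                                sequence=c0.sequence))
    out = "".join(genome)
    truth.sort(key=lambda t: t.start)
    found = list(scan([("genome", out)], _strict(motif_params)))
    got = [(c.start, c.end, c.strand) for c in found]
    want = [(t.start, t.end, t.strand) for t in truth]
    if got != want:
        raise RuntimeError("spiked genome failed truth verification")
    return out, truth


def _strict(params: DetectionParams) -> DetectionParams:
    from dataclasses import replace
    return replace(params, scan_reverse_complement=True, allow_overlap=False)


def synthetic_genome(spec: SyntheticSpec) -> Tuple[str, List[TruthMotif]]:
    """Generate (genome, truth table) for a SyntheticSpec, reproducibly."""
    rng = np.random.default_rng(spec.seed)
    bg_seed, spike_seed = _child_seed(rng), _child_seed(rng)
    bg = random_background(spec.genome_length, spec.gc_content, bg_seed,
                           spec.motif_params)
    if spec.n_motifs == 0:
        return bg, []
    return spike_motifs(bg, spec.n_motifs, spec.motif_params, spike_seed)


def labelled_dataset(n: int, label_model: Optional[LabelModel] = None,
                     seed: int = 0, target_r2: Optional[float] = None,
                     params: Optional[DetectionParams] = None,
                     ph_window: bool = False
                     ) -> Tuple[pd.DataFrame, LabelModel]:
    """``n`` (sequence, label) rows with a known linear feature->label truth.

    With ``target_r2`` set, the noise standard deviation is chosen so the
    noise-free signal explains that fraction of the label variance on this
    sample; the resolved :class:`LabelModel` (with its effective noise_sd)
    is returned alongside the data.  With neither ``label_model.noise_sd``
    nor ``target_r2`` given, the default study condition of signal R^2 = 0.9
    is used.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if label_model is None:
        label_model = DEFAULT_LABEL_MODEL
        if target_r2 is None:
            target_r2 = 0.9
    if params is None:
        params = DetectionParams()
    rng = np.random.default_rng(seed)
    seqs, signals = [], []
    for _ in range(n):
        s = random_imotif(rng, params)
        cand = enumerate_candidates(s, params)[0]
        feats = extract_features(cand).as_dict()
        seqs.append(s)
        signals.append(label_model.signal(feats))
    signals = np.asarray(signals)
    if target_r2 is not None:
        sd_sig = float(signals.std())
        noise_sd = sd_sig * np.sqrt((1 - target_r2) / target_r2)
        label_model = LabelModel(label_model.coefficients,
                                 label_model.intercept, float(noise_sd))
    labels = signals + rng.normal(0.0, label_model.noise_sd, size=n)
    if ph_window:
        labels = np.clip(labels, *PH_WINDOW)
    df = pd.DataFrame({"sequence": seqs, "label": labels})
    return df, label_model
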