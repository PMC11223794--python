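"""Genome-scale i-motif density statistics.

Per assembly: cytosine density (fraction of unambiguous bases that are C),
the i-motif count from a both-strand non-overlapping scan, iPM (i-motifs per
million nucleotides of single-strand assembly length, N's included in the
length), and — when a scoring bundle is supplied — the mean stability score.
Across a set of assemblies the mean scores are min-max normalized to a 0-1
relative score for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bundle import ModelBundle, score_candidates
from .detect import DetectionParams, scan

__all__ = ["GenomeSummary", "c_density", "ipm", "summarize_set"]


@dataclass
class GenomeSummary:
    label: str
    genome_length: int
    c_density: float
    n_motifs: int
    ipm: float
    mean_score: Optional[float] = None
    relative_score: Optional[float] = None
    motifs: Optional[list] = None  # candidates/ScoredMotifs when requested


def _as_records(source) -> Iterable[Tuple[str, str]]:
    if isinstance(source, str):
        from .io import read_fasta
        return read_fasta(source)
    return ((sid, str(seq).upper()) for sid, seq in source)


def c_density(source) -> Tuple[int, float]:
    """(total bases, fraction of A/C/G/T bases that are C), case-insensitive.

    ``source`` is a FASTA path or an iterable of (id, sequence).  N and other
    ambiguity codes count toward the genome length but are excluded from
    both the numerator and denominator of the density.
    """
    total = 0
    acgt = 0
    cs = 0
    for _, seq in _as_records(source):
        total += len(seq)
        for b in "ACGT":
            n = seq.count(b)
            acgt += n
            if b == "C":
                cs += n
    if acgt == 0:
        raise ValueError("no unambiguous (ACGT) bases in input")
    return total, cs / acgt


def ipm(source, params: Optional[DetectionParams] = None,
        bundle: Optional[ModelBundle] = None,
        label: str = "genome", return_motifs: bool = False) -> GenomeSummary:
    """Genome summary: both-strand non-overlapping motif density.

    iPM = n_motifs / genome_length * 1e6, where genome_length is the
    single-strand assembly length (all bases, N included).
    """
    if params is None:
        params = DetectionParams()
    params = replace(params, scan_reverse_complement=True,
                     allow_overlap=False)
    records = list(_as_records(source))
    genome_length, density = c_density(records)
    motifs = list(scan(records, params))
    mean_score = None
    kept = motifs
    if bundle is not None and motifs:
        kept = score_candidates(bundle, motifs)
        mean_score = float(np.mean([s.stability_score for s in kept]))
    n = len(motifs)
    return GenomeSummary(label=label, genome_length=genome_length,
                         c_density=density, n_motifs=n,
                         ipm=n / genome_length * 1e6, mean_score=mean_score,
                         motifs=kept if return_motifs else None)


def summarize_set(summaries: Sequence[GenomeSummary]) -> pd.DataFrame:
    """Cross-species table with 0-1 relative stability scores.

    relative_score = (mean_score - min) / (max - min) over the set; when all
    means coincide every relative score is 0.5 (with a warning).
    """
    with_scores = [s for s in summaries if s.mean_score is not None]
    if len(with_scores) >= 2:
        vals = [s.mean_score for s in with_scores]
        lo, hi = min(vals), max(vals)
        for s in with_scores:
            if hi == lo:
                s.relative_score = 0.5
            else:
                s.relative_score = (s.mean_score - lo) / (hi - lo)
        if hi == lo:
            warnings.warn("all mean scores equal; relative scores set to 0.5")
    return pd.DataFrame([{
        "label": s.label,
        "genome_length": s.genome_length,
        "c_density": s.c_density,
        "n_motifs": s.n_motifs,
        "ipm": s.ipm,
        "mean_score": s.mean_score,
        "relative_score": s.relative_score,
    } for s in summaries])
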