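"""FASTA input (plain or gzipped) and BED/TSV report output."""

from __future__ import annotations

import gzip
from typing import IO, Iterable, Iterator, List, Optional, Sequence, Tuple

from Bio import SeqIO

from .bundle import ScoredMotif
from .detect import FastaFormatError, IMotifCandidate

__all__ = ["read_fasta", "write_bed", "write_tsv"]


def _open_text(path: str) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str) -> Iterator[Tuple[str, str]]:
    """Yield (record_id, uppercased sequence) from a FASTA file.

    Raises :class:`FastaFormatError` naming the last good record when the
    stream cannot be parsed.
    """
    n = 0
    last = "<start of file>"
    try:
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                n += 1
                last = rec.id
                yield rec.id, str(rec.seq).upper()
    except (ValueError, OSError, UnicodeDecodeError) as exc:
        raise FastaFormatError(
            f"unreadable FASTA {path!r} after record {n} ({last}): {exc}"
        ) from exc
    if n == 0:
        raise FastaFormatError(f"no FASTA records found in {path!r}")


def write_bed(motifs: Sequence, path: str) -> None:
    """BED6: chrom, start, end, iM_<n>, score 0-1000, strand.

    Accepts IMotifCandidate or ScoredMotif items; without a stability score
    the BED score column is 0.
    """
    with open(path, "w") as fh:
        for i, m in enumerate(motifs, start=1):
            if isinstance(m, ScoredMotif):
                cand, score = m.candidate, int(round(m.stability_score * 1000))
            else:
                cand, score = m, 0
            fh.write(f"{cand.seq_id}\t{cand.start}\t{cand.end}\tiM_{i}\t"
                     f"{score}\t{cand.strand}\n")


def write_tsv(motifs: Sequence, path: str) -> None:
    """Human-readable report; coordinates are 1-based inclusive here."""
    header = ["seq_id", "start_1based", "end_1based", "length", "strand",
              "sequence", "tracts", "loop_lengths", "predicted_label",
              "stability_score"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for m in motifs:
            if isinstance(m, ScoredMotif):
                cand = m.candidate
                label = f"{m.predicted_label:.4f}"
                score = f"{m.stability_score:.4f}"
            else:
                cand, label, score = m, "", ""
            fh.write("\t".join([
                cand.seq_id, str(cand.start + 1), str(cand.end),
                str(cand.length), cand.strand, cand.sequence,
                cand.tract_string(),
                ",".join(str(x) for x in cand.loop_lengths()),
                label, score,
            ]) + "\n")
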