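"""Genome scanning: score every candidate ATG with a trained model and
write predictions as GFF3, BED or TSV.

Coordinates in all output formats refer to the forward strand.  GFF3
records are 1-based inclusive spanning the 3-nt codon with the probability
in the score column; BED records are the 0-based half-open equivalent.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ConfigurationError
from .model import TrainedModel
from .sequence_io import GenomeSequence, extract_window, find_atg_candidates

logger = logging.getLogger(__name__)

FORMATS = ("gff3", "bed", "tsv")


@dataclass(frozen=True)
class Prediction:
    seq_id: str
    pos: int  # 1-based forward-strand coordinate of the A
    strand: str
    score: float
    label: int  # 1 above threshold


def _codon_span(p: Prediction) -> tuple[int, int]:
    """1-based inclusive forward-strand span of the codon."""
    return (p.pos, p.pos + 2) if p.strand == "+" else (p.pos - 2, p.pos)


def scan(
    genomes: Sequence[GenomeSequence],
    model: TrainedModel,
    strands: Sequence[str] = ("+", "-"),
    threshold: float | None = None,
) -> list[Prediction]:
    """Score every ATG candidate with full flanks on the requested strands.

    Every candidate is reported independently (overlapping ATGs included);
    output is ordered by (sequence id, coordinate, '+' before '-').
    """
    thr = model.threshold if threshold is None else threshold
    out: list[Prediction] = []
    for genome in genomes:
        candidates = find_atg_candidates(genome, model.window, strands)
        logger.info("%s: %d candidate ATGs", genome.id, len(candidates))
        if not candidates:
            continue
        windows = [extract_window(genome, pos, strand, model.window)
                   for pos, strand in candidates]
        scores = model.score_windows(windows)
        out.extend(
            Prediction(genome.id, pos, strand, float(s), int(s >= thr))
            for (pos, strand), s in zip(candidates, scores)
        )
    out.sort(key=lambda p: (p.seq_id, p.pos, 0 if p.strand == "+" else 1))
    return out


def write_predictions(predictions: Iterable[Prediction], path: str | Path, format: str = "gff3") -> None:
    if format not in FORMATS:
        raise ConfigurationError(f"unknown format {format!r}; expected one of {FORMATS}")
    with open(path, "w", newline="") as fh:
        if format == "gff3":
            fh.write("##gff-version 3\n")
            for p in predictions:
                start, end = _codon_span(p)
                fh.write(
                    f"{p.seq_id}\ttispred\tTIS\t{start}\t{end}\t{p.score:.6g}\t"
                    f"{p.strand}\t.\tlabel={p.label}\n"
                )
        elif format == "bed":
            fh.write('track name="TIS" useScore=0\n')
            for p in predictions:
                start, end = _codon_span(p)
                fh.write(
                    f"{p.seq_id}\t{start - 1}\t{end}\tTIS\t{p.score:.6g}\t{p.strand}\n"
                )
        else:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["seq_id", "pos", "strand", "score", "label"])
            for p in predictions:
                w.writerow([p.seq_id, p.pos, p.strand, repr(p.score), p.label])


def read_predictions(path: str | Path, format: str = "gff3", threshold: float = 0.5) -> list[Prediction]:
    if format not in FORMATS:
        raise ConfigurationError(f"unknown format {format!r}; expected one of {FORMATS}")
    out = []
    with open(path) as fh:
        if format == "tsv":
            for row in csv.DictReader(fh, delimiter="\t"):
                out.append(Prediction(row["seq_id"], int(row["pos"]), row["strand"],
                                      float(row["score"]), int(row["label"])))
            return out
        for line in fh:
            if line.startswith(("#", "track")) or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if format == "gff3":
                seq_id, start, end, score, strand = f[0], int(f[3]), int(f[4]), float(f[5]), f[6]
                label = 1 if "label=1" in f[8] else 0 if "label=0" in f[8] else int(score >= threshold)
            else:  # bed: 0-based half-open
                seq_id, start, end = f[0], int(f[1]) + 1, int(f[2])
                score, strand = float(f[4]), f[5]
                label = int(score >= threshold)
            pos = start if strand == "+" else end
            out.append(Prediction(seq_id, pos, strand, score, label))
    return out
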