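"""Genome I/O and strand-aware candidate-window extraction.

Candidate windows are fixed-length stretches of genomic DNA read 5'->3' on
the strand of the candidate start codon, with the A of the ATG at a fixed
1-based offset inside the window (default geometry: 300 nt, ATG at
positions 150-152).  All external coordinates are 1-based inclusive and
refer to the forward strand of the source sequence, following GFF3
convention; for a minus-strand candidate the reported coordinate is the
forward-strand position of the base that pairs with the A.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import ConfigurationError, InvalidAlphabetError, WindowOutOfBoundsError

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

POSITIVE = "positive"
NEGATIVE = "negative"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class GenomeSequence:
    """One uppercase-normalized nucleotide sequence over {A,C,G,T,N}."""

    id: str
    residues: str

    def __post_init__(self):
        normalized = self.residues.upper()
        bad = set(normalized) - VALID_BASES
        if bad:
            raise InvalidAlphabetError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}"
            )
        object.__setattr__(self, "residues", normalized)

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class WindowConfig:
    """Geometry of a candidate window.

    ``tis_offset`` is the 1-based position of the A of the candidate ATG
    within the window.
    """

    window_length: int = 300
    tis_offset: int = 150

    def __post_init__(self):
        if not (1 <= self.tis_offset and self.tis_offset + 2 <= self.window_length):
            raise ConfigurationError(
                f"tis_offset={self.tis_offset} with window_length="
                f"{self.window_length} cannot hold a codon"
            )

    @property
    def upstream_length(self) -> int:
        """Number of bases strictly 5' of the A."""
        return self.tis_offset - 1

    @property
    def downstream_length(self) -> int:
        """Number of bases strictly 3' of the G."""
        return self.window_length - self.tis_offset - 2


@dataclass(frozen=True)
class TISWindow:
    """A strand-resolved candidate window.

    ``origin`` is (sequence id, 1-based forward-strand coordinate of the A
    of the candidate codon, strand).
    """

    sequence: str
    label: str = UNKNOWN
    origin: tuple[str, int, str] = ("", 0, "+")

    def codon(self, cfg: WindowConfig) -> str:
        i = cfg.tis_offset - 1
        return self.sequence[i : i + 3]


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    bad = set(seq.upper()) - VALID_BASES
    if bad:
        raise InvalidAlphabetError(f"invalid characters {sorted(bad)}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (multi-record, wrapped) FASTA file.

    The record id is the header token before the first whitespace.
    """
    return [
        GenomeSequence(id=rec.id, residues=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(genomes: Iterable[GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, g.length, width):
                fh.write(g.residues[i : i + width] + "\n")


def _forward_span(pos: int, strand: str, cfg: WindowConfig) -> tuple[int, int]:
    """1-based inclusive forward-strand span covered by the window."""
    if strand == "+":
        return pos - cfg.tis_offset + 1, pos + cfg.window_length - cfg.tis_offset
    if strand == "-":
        return pos - (cfg.window_length - cfg.tis_offset), pos + cfg.tis_offset - 1
    raise ConfigurationError(f"strand must be '+' or '-', got {strand!r}")


def extract_window(
    genome: GenomeSequence,
    pos: int,
    strand: str,
    cfg: WindowConfig = WindowConfig(),
    label: str = UNKNOWN,
    pad: bool = False,
) -> TISWindow:
    """Extract the window anchored on the candidate codon at ``pos``/``strand``.

    ``pos`` is the 1-based forward-strand coordinate of the A of the
    candidate.  Windows that would run off either end raise
    :class:`WindowOutOfBoundsError` unless ``pad`` is set, in which case the
    missing flank is N-filled (intended for scanning short contigs).
    """
    start, end = _forward_span(pos, strand, cfg)
    if (start < 1 or end > genome.length) and not pad:
        raise WindowOutOfBoundsError(
            f"window [{start},{end}] for pos={pos}{strand} exceeds "
            f"{genome.id!r} of length {genome.length}"
        )
    left_pad = max(0, 1 - start)
    right_pad = max(0, end - genome.length)
    core = genome.residues[max(start, 1) - 1 : min(end, genome.length)]
    forward = "N" * left_pad + core + "N" * right_pad
    seq = forward if strand == "+" else reverse_complement(forward)
    return TISWindow(sequence=seq, label=label, origin=(genome.id, pos, strand))


def find_atg_candidates(
    genome: GenomeSequence,
    cfg: WindowConfig = WindowConfig(),
    strands: Sequence[str] = ("+", "-"),
) -> list[tuple[int, str]]:
    """Every (pos, strand) whose strand-local triplet is ATG and whose full
    window fits inside the sequence, sorted by (pos, '+' before '-')."""
    hits: list[tuple[int, str]] = []
    s = genome.residues
    if "+" in strands:
        i = s.find("ATG")
        while i != -1:
            pos = i + 1
            start, end = _forward_span(pos, "+", cfg)
            if start >= 1 and end <= genome.length:
                hits.append((pos, "+"))
            i = s.find("ATG", i + 1)
    if "-" in strands:
        # a minus-strand ATG reads CAT on the forward strand; the A pairs
        # with the forward T at the 3' end of the CAT
        i = s.find("CAT")
        while i != -1:
            pos = i + 3
            start, end = _forward_span(pos, "-", cfg)
            if start >= 1 and end <= genome.length:
                hits.append((pos, "-"))
            i = s.find("CAT", i + 1)
    hits.sort(key=lambda h: (h[0], 0 if h[1] == "+" else 1))
    return hits
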