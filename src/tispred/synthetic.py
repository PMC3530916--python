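"""Synthetic genomes with a planted start-codon context signal.

The generator emulates the statistical structure a TIS classifier exploits:
genuine starts carry a Kozak-like consensus in a short window around the
ATG (e.g. purine at -3, G at +4) and a downstream in-frame stretch biased
toward non-stop, coding-like codons, while decoy ATGs arise from the
background composition alone and carry neither signal.

The signal model is deliberately simple -- independent per-position
consensus emission plus an independent per-codon bias -- so that ground
truth is exactly known for recovery tests.  With both
``consensus_strength`` and ``codon_bias_strength`` at 0, planted starts are
drawn entirely from the background and are indistinguishable from decoys
in expectation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .sequence_io import GenomeSequence, WindowConfig

BASES = "ACGT"

#: Kozak-like consensus around the start codon; keys are signed positions
#: relative to the A of the ATG (A = +1, so -3 is three bases 5' of the A
#: and +4 is the first base after the G).
DEFAULT_CONSENSUS: dict[int, str] = {
    -10: "A", -9: "A", -8: "C", -7: "A", -6: "A", -5: "C",
    -4: "A", -3: "A", -2: "A", -1: "A", 4: "G", 5: "C",
}

#: Stop-free, compositionally biased codon pool used for the downstream
#: coding-frame signal.
PREFERRED_CODONS = (
    "GCT", "GCC", "GAA", "GAG", "GAT", "GGA", "GGT", "AAG",
    "CTT", "CTC", "TCT", "TCC", "ACT", "ACC", "GTT", "GTC",
)

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class SyntheticConfig:
    n_sequences: int = 3
    sequence_length: int = 20_000
    n_genes: int = 30
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    consensus_strength: float = 0.9
    codon_bias_strength: float = 0.9
    decoy_atg_per_kb: float = 0.5
    gene_strands: tuple[str, ...] = ("+",)
    seed: int = 0
    window: WindowConfig = field(default_factory=WindowConfig)

    def __post_init__(self):
        if not 0.0 <= self.consensus_strength <= 1.0:
            raise ConfigurationError("consensus_strength must be in [0,1]")
        if not 0.0 <= self.codon_bias_strength <= 1.0:
            raise ConfigurationError("codon_bias_strength must be in [0,1]")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ConfigurationError("background composition must sum to 1")
        if self.sequence_length < self.window.window_length:
            raise ConfigurationError("sequences shorter than one window")


def _rel_to_index0(r: int, pos0: int) -> int:
    """0-based sequence index of signed position r relative to an A at pos0."""
    return pos0 + r if r < 0 else pos0 + r - 1


def _plant_gene(seq: list[str], pos0: int, cfg: SyntheticConfig, rng: np.random.Generator) -> None:
    p = np.asarray(cfg.background)
    seq[pos0 : pos0 + 3] = list("ATG")
    for r, base in DEFAULT_CONSENSUS.items():
        i = _rel_to_index0(r, pos0)
        if rng.random() < cfg.consensus_strength:
            seq[i] = base
        else:
            seq[i] = BASES[rng.choice(4, p=p)]
    # downstream in-frame codons after the ATG, as many as fit in the window
    n_codons = cfg.window.downstream_length // 3
    for c in range(n_codons):
        i = pos0 + 3 + 3 * c
        if rng.random() < cfg.codon_bias_strength:
            codon = PREFERRED_CODONS[rng.integers(len(PREFERRED_CODONS))]
        else:
            codon = "".join(BASES[b] for b in rng.choice(4, size=3, p=p))
        seq[i : i + 3] = list(codon)


def generate(cfg: SyntheticConfig) -> tuple[list[GenomeSequence], str, pd.DataFrame]:
    """Generate (genomes, GFF3 annotation text, ground-truth table).

    Fully reproducible from ``cfg.seed``.  The annotation marks each
    planted gene as a protein-coding ``gene`` with one ``CDS`` child.  The
    truth table has columns seq_id, pos (1-based forward coordinate of the
    A), strand.
    """
    rng = np.random.default_rng(cfg.seed)
    p = np.asarray(cfg.background)
    w = cfg.window

    seqs = [
        list("".join(BASES[b] for b in rng.choice(4, size=cfg.sequence_length, p=p)))
        for _ in range(cfg.n_sequences)
    ]
    ids = [f"synth{i + 1}" for i in range(cfg.n_sequences)]

    # spread genes across sequences round-robin; sites must keep a full
    # window inside the sequence and not overlap another gene's window
    per_seq: list[list[tuple[int, str]]] = [[] for _ in range(cfg.n_sequences)]
    for g in range(cfg.n_genes):
        si = g % cfg.n_sequences
        # 1-based A coordinate bounds safe for either strand
        lo = w.window_length - w.tis_offset + 1
        hi = cfg.sequence_length - w.window_length + w.tis_offset
        lo, hi = max(lo, w.tis_offset + 1), min(hi, cfg.sequence_length - w.tis_offset)
        placed = False
        for _ in range(2000):
            pos = int(rng.integers(lo, hi + 1))
            if all(abs(pos - q) >= w.window_length for q, _ in per_seq[si]):
                strand = cfg.gene_strands[int(rng.integers(len(cfg.gene_strands)))]
                per_seq[si].append((pos, strand))
                placed = True
                break
        if not placed:
            raise ConfigurationError(
                f"could not place gene {g} on {ids[si]}: sequence too crowded"
            )

    gff = io.StringIO()
    gff.write("##gff-version 3\n")
    truth_rows = []
    gene_no = 0
    for si, sites in enumerate(per_seq):
        for pos, strand in sorted(sites):
            gene_no += 1
            pos0 = pos - 1
            if strand == "+":
                _plant_gene(seqs[si], pos0, cfg, rng)
                cds_start, cds_end = pos, pos + 3 * (w.downstream_length // 3) + 2
            else:
                # plant on the reverse complement coordinate frame: write the
                # gene into a scratch revcomp view, then mirror back
                rc_pos0 = cfg.sequence_length - pos
                rc = [_complement(b) for b in reversed(seqs[si])]
                _plant_gene(rc, rc_pos0, cfg, rng)
                seqs[si] = [_complement(b) for b in reversed(rc)]
                cds_end = pos
                cds_start = pos - 3 * (w.downstream_length // 3) - 2
            gid = f"gene{gene_no}"
            gff.write(
                f"{ids[si]}\ttispred_synth\tgene\t{cds_start}\t{cds_end}\t.\t{strand}\t.\t"
                f"ID={gid};biotype=protein_coding\n"
            )
            gff.write(
                f"{ids[si]}\ttispred_synth\tCDS\t{cds_start}\t{cds_end}\t.\t{strand}\t0\t"
                f"ID={gid}.cds;Parent={gid}\n"
            )
            truth_rows.append({"seq_id": ids[si], "pos": pos, "strand": strand})

    # optional extra decoy ATG triplets, written outside planted windows
    n_decoys = int(round(cfg.decoy_atg_per_kb * cfg.sequence_length / 1000))
    for si in range(cfg.n_sequences):
        planted = per_seq[si]
        for _ in range(n_decoys):
            for _ in range(200):
                pos = int(rng.integers(w.tis_offset, cfg.sequence_length - w.window_length + w.tis_offset + 1))
                if all(abs(pos - q) >= w.window_length for q, _ in planted):
                    seqs[si][pos - 1 : pos + 2] = list("ATG")
                    break

    genomes = [GenomeSequence(id=ids[i], residues="".join(seqs[i])) for i in range(cfg.n_sequences)]
    truth = pd.DataFrame(truth_rows, columns=["seq_id", "pos", "strand"])
    return genomes, gff.getvalue(), truth


def _complement(b: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}[b]
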