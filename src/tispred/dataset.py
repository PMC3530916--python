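"""Labeled window sets from genome + annotation, and reproducible splits.

Positives are one window per annotated protein-coding translation start
(strand-aware).  Negatives are ATG-centered windows sampled uniformly
without replacement, with per-sequence quotas proportional to sequence
length (largest-remainder apportionment), excluding annotated start
coordinates and any window whose 300-nt sequence occurs in the positive
set.  Splitting is a seeded uniform shuffle into test / feature-estimation
/ validation / network-training partitions, each class-balanced.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np

from .errors import ConfigurationError, ShortfallError
from .sequence_io import (
    NEGATIVE,
    POSITIVE,
    GenomeSequence,
    TISWindow,
    WindowConfig,
    extract_window,
    find_atg_candidates,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitConfig:
    train_fraction: float = 0.65
    feature_estimation_per_class: int = 5000
    validation_per_class: int = 2920
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must be in (0,1)")


@dataclass(frozen=True)
class DatasetSplit:
    """Four disjoint class-balanced partitions of labeled windows."""

    feature_estimation: list[TISWindow]
    ann_training: list[TISWindow]
    validation: list[TISWindow]
    test: list[TISWindow]

    def partitions(self) -> dict[str, list[TISWindow]]:
        return {
            "feature_estimation": self.feature_estimation,
            "ann_training": self.ann_training,
            "validation": self.validation,
            "test": self.test,
        }


def _load_gff_db(annotation: str | Path) -> gffutils.FeatureDB:
    text: str | None = None
    if isinstance(annotation, Path):
        annotation = str(annotation)
    if "\n" in annotation or annotation.lstrip().startswith("##gff"):
        text = annotation
    elif os.path.exists(annotation):
        text = Path(annotation).read_text()
    else:
        raise ConfigurationError(f"annotation file not found: {annotation!r}")
    try:
        return gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return None


def _is_protein_coding(feature: gffutils.Feature) -> bool:
    for key in ("biotype", "gene_biotype", "locus_type"):
        if key in feature.attributes:
            return feature.attributes[key][0] == "protein_coding"
    return True  # plain 'gene' records without a biotype attribute


def annotated_starts(annotation: str | Path) -> list[tuple[str, int, str]]:
    """(seq_id, 1-based coordinate of the A, strand) for every annotated
    protein-coding gene's translation start.

    The start is taken from CDS children when present (first CDS base on the
    + strand, last on the -), otherwise from the gene record's own bounds.
    Records of non-coding types (pseudogene etc.) contribute nothing.
    """
    db = _load_gff_db(annotation)
    if db is None:  # annotation with zero records
        return []
    starts = []
    for gene in db.features_of_type("gene"):
        if not _is_protein_coding(gene):
            continue
        cds = list(db.children(gene, featuretype="CDS"))
        if cds:
            start = min(c.start for c in cds)
            end = max(c.end for c in cds)
        else:
            start, end = gene.start, gene.end
        pos = start if gene.strand == "+" else end
        starts.append((gene.seqid, pos, gene.strand))
    return starts


def build_positive_set(
    genomes: Sequence[GenomeSequence],
    annotation: str | Path,
    cfg: WindowConfig = WindowConfig(),
) -> list[TISWindow]:
    """One positive window per annotated protein-coding translation start.

    Starts whose extracted triplet is not ATG are dropped with a warning
    (non-canonical starts are out of scope), as are starts too close to a
    sequence end for a full window.  Exact duplicate window sequences are
    collapsed to one.
    """
    by_id = {g.id: g for g in genomes}
    windows: list[TISWindow] = []
    seen: set[str] = set()
    for seq_id, pos, strand in annotated_starts(annotation):
        genome = by_id.get(seq_id)
        if genome is None:
            logger.warning("annotation references unknown sequence %r; skipped", seq_id)
            continue
        try:
            w = extract_window(genome, pos, strand, cfg, label=POSITIVE)
        except Exception as exc:  # out-of-bounds near contig edge
            logger.warning("start %s:%d%s skipped: %s", seq_id, pos, strand, exc)
            continue
        if w.codon(cfg) != "ATG":
            logger.warning(
                "start %s:%d%s has non-ATG codon %r; skipped (non-canonical "
                "starts out of scope)", seq_id, pos, strand, w.codon(cfg),
            )
            continue
        if w.sequence in seen:
            continue
        seen.add(w.sequence)
        windows.append(w)
    return windows


def proportional_quotas(lengths: Sequence[int], n: int) -> list[int]:
    """Apportion ``n`` among sequences proportionally to length by the
    largest-remainder method."""
    total = sum(lengths)
    if total <= 0:
        raise ConfigurationError("total sequence length must be positive")
    exact = [n * L / total for L in lengths]
    quotas = [math.floor(e) for e in exact]
    short = n - sum(quotas)
    order = sorted(range(len(lengths)), key=lambda i: (exact[i] - quotas[i], -i), reverse=True)
    for i in order[:short]:
        quotas[i] += 1
    return quotas


def sample_negatives(
    genomes: Sequence[GenomeSequence],
    positives: Sequence[TISWindow],
    n: int,
    seed: int,
    cfg: WindowConfig = WindowConfig(),
    strands: Sequence[str] = ("+",),
    exclude_positions: Iterable[tuple[str, int, str]] = (),
) -> list[TISWindow]:
    """Sample ``n`` negative ATG-centered windows.

    Eligible candidates are ATGs that are not at an annotated/positive start
    coordinate and whose full window sequence does not occur among the
    positives.  Quotas per sequence are proportional to sequence length;
    sampling is uniform without replacement within each sequence and
    reproducible from ``seed``.
    """
    if n == 0:
        return []
    positive_seqs = {w.sequence for w in positives}
    excluded = {(w.origin[0], w.origin[1], w.origin[2]) for w in positives}
    excluded |= set(exclude_positions)
    quotas = proportional_quotas([g.length for g in genomes], n)
    rng = np.random.default_rng(seed)
    out: list[TISWindow] = []
    for genome, quota in zip(genomes, quotas):
        if quota == 0:
            continue
        eligible = []
        for pos, strand in find_atg_candidates(genome, cfg, strands):
            if (genome.id, pos, strand) in excluded:
                continue
            w = extract_window(genome, pos, strand, cfg, label=NEGATIVE)
            if w.sequence in positive_seqs:
                continue
            eligible.append(w)
        if len(eligible) < quota:
            raise ShortfallError(
                f"sequence {genome.id!r} has {len(eligible)} eligible negative "
                f"candidates but quota is {quota}"
            )
        idx = rng.choice(len(eligible), size=quota, replace=False)
        out.extend(eligible[i] for i in sorted(idx))
    return out


def partition_sizes(n_per_class: int, cfg: SplitConfig) -> dict[str, int]:
    """Per-class partition sizes implied by the split rule.

    train = floor(train_fraction * N); test = remainder; train is then
    subdivided into feature-estimation, validation, and network-training
    remainders.
    """
    n_train = math.floor(cfg.train_fraction * n_per_class)
    n_test = n_per_class - n_train
    n_ann = n_train - cfg.feature_estimation_per_class - cfg.validation_per_class
    if n_ann <= 0:
        raise ConfigurationError(
            f"feature_estimation ({cfg.feature_estimation_per_class}) + validation "
            f"({cfg.validation_per_class}) leave no network-training samples out of "
            f"{n_train} per-class training windows"
        )
    return {
        "feature_estimation": cfg.feature_estimation_per_class,
        "ann_training": n_ann,
        "validation": cfg.validation_per_class,
        "test": n_test,
    }


def split_dataset(
    positives: Sequence[TISWindow],
    negatives: Sequence[TISWindow],
    cfg: SplitConfig,
) -> DatasetSplit:
    """Seeded, class-balanced split into the four working partitions."""
    if len(positives) != len(negatives):
        raise ConfigurationError(
            f"classes must be equal-sized; got {len(positives)} positives, "
            f"{len(negatives)} negatives"
        )
    n = len(positives)
    sizes = partition_sizes(n, cfg)
    rng = np.random.default_rng(cfg.seed)
    pos = [positives[i] for i in rng.permutation(n)]
    neg = [negatives[i] for i in rng.permutation(n)]

    def carve(lst: list[TISWindow]) -> dict[str, list[TISWindow]]:
        n_fe = sizes["feature_estimation"]
        n_val = sizes["validation"]
        n_ann = sizes["ann_training"]
        train = lst[: n_fe + n_val + n_ann]
        return {
            "feature_estimation": train[:n_fe],
            "validation": train[n_fe : n_fe + n_val],
            "ann_training": train[n_fe + n_val :],
            "test": lst[n_fe + n_val + n_ann :],
        }

    p, q = carve(pos), carve(neg)
    return DatasetSplit(
        feature_estimation=p["feature_estimation"] + q["feature_estimation"],
        ann_training=p["ann_training"] + q["ann_training"],
        validation=p["validation"] + q["validation"],
        test=p["test"] + q["test"],
    )


def labels(windows: Sequence[TISWindow]) -> np.ndarray:
    """0/1 label vector (1 = positive)."""
    return np.array([1 if w.label == POSITIVE else 0 for w in windows], dtype=int)


def write_windows_fasta(windows: Iterable[TISWindow], path: str | Path) -> None:
    """Persist windows as FASTA with a structured header id|pos|strand|label."""
    with open(path, "w") as fh:
        for w in windows:
            seq_id, pos, strand = w.origin
            fh.write(f">{seq_id}|{pos}|{strand}|{w.label}\n{w.sequence}\n")


def read_windows_fasta(path: str | Path) -> list[TISWindow]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id, pos, strand, label = rec.id.split("|")
        out.append(
            TISWindow(sequence=str(rec.seq).upper(), label=label, origin=(seq_id, int(pos), strand))
        )
    return out
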