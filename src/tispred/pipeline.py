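"""End-to-end training: windows -> features -> GA selection -> network.

Orchestrates the full procedure: build the labeled sets, split them,
estimate feature parameters on the feature-estimation partition only
(leakage is asserted, not assumed), run the wrapper feature selection on
the network-training partition, train the final network with validation
early stopping, and package everything as a :class:`TrainedModel`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ann import ANNConfig, NeuralNetClassifier
from .dataset import (
    DatasetSplit,
    SplitConfig,
    build_positive_set,
    labels,
    sample_negatives,
    split_dataset,
)
from .errors import ConfigurationError
from .evaluate import evaluate_scores
from .features import WindowFeaturizer, default_catalogue
from .ga_select import GAConfig, GeneticFeatureSelector
from .model import TrainedModel
from .sequence_io import GenomeSequence, WindowConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    window: WindowConfig = field(default_factory=WindowConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    ann: ANNConfig = field(default_factory=ANNConfig)
    negative_strands: tuple[str, ...] = ("+",)
    threshold: float = 0.5


def train_from_windows(
    split: DatasetSplit,
    cfg: PipelineConfig,
    catalogue=None,
) -> tuple[TrainedModel, dict]:
    """Train on a prepared split; returns (model, report).

    The report carries the GA history, stopping epoch, and test-partition
    sensitivity/specificity.
    """
    catalogue = catalogue if catalogue is not None else default_catalogue(cfg.window)

    featurizer = WindowFeaturizer(catalogue=catalogue, window=cfg.window)
    featurizer.fit(split.feature_estimation)
    fe_origins = featurizer.fitted_origins_
    for name, part in split.partitions().items():
        if name == "feature_estimation":
            continue
        overlap = fe_origins & {w.origin for w in part}
        if overlap:
            raise ConfigurationError(
                f"feature-estimation windows leak into {name}: {sorted(overlap)[:3]}"
            )

    X_train = featurizer.transform(split.ann_training)
    y_train = labels(split.ann_training)
    selector = GeneticFeatureSelector(
        catalogue=featurizer.catalogue_,
        population_size=cfg.ga.population_size,
        generations=cfg.ga.generations,
        mutation_rate=cfg.ga.mutation_rate,
        tournament_size=cfg.ga.tournament_size,
        elitism=cfg.ga.elitism,
        fitness_folds=cfg.ga.fitness_folds,
        seed=cfg.ga.seed,
        fitness_ann=cfg.ga.fitness_ann,
    )
    selector.fit(X_train, y_train)
    sel_idx = np.flatnonzero(selector.support_)
    logger.info("selected %d/%d features (fitness %.3f)",
                len(sel_idx), len(catalogue), selector.best_fitness_)

    X_val = featurizer.transform(split.validation)
    net = NeuralNetClassifier(**cfg.ann.__dict__)
    net.fit(X_train[:, sel_idx], y_train,
            X_val[:, sel_idx], labels(split.validation))

    mean, scale = featurizer.params_.normalization
    params = type(featurizer.params_)(
        pwm=featurizer.params_.pwm,
        background=featurizer.params_.background,
        normalization=(mean[sel_idx], scale[sel_idx]),
    )
    model = TrainedModel(
        weights=net.weights_,
        catalogue=[featurizer.catalogue_[i] for i in sel_idx],
        params=params,
        window=cfg.window,
        threshold=cfg.threshold,
        metadata={
            "stopping_epoch": net.best_epoch_,
            "best_validation_loss": net.best_val_loss_,
            "ga_best_fitness": selector.best_fitness_,
            "n_features": int(len(sel_idx)),
        },
    )

    report = {"ga_history": selector.history_, "stopping_epoch": net.best_epoch_}
    if split.test:
        scores = model.score_windows(split.test)
        report["test"] = evaluate_scores(labels(split.test), scores, cfg.threshold)
    return model, report


def train_from_genome(
    genomes: Sequence[GenomeSequence],
    annotation: str | Path,
    cfg: PipelineConfig,
    catalogue=None,
    n_negatives: int | None = None,
) -> tuple[TrainedModel, DatasetSplit, dict]:
    """Full run from genome + annotation: positives, proportional negative
    sampling, split, then :func:`train_from_windows`."""
    positives = build_positive_set(genomes, annotation, cfg.window)
    if not positives:
        raise ConfigurationError("annotation yields no positive windows")
    n = n_negatives if n_negatives is not None else len(positives)
    negatives = sample_negatives(
        genomes, positives, n, seed=cfg.split.seed, cfg=cfg.window,
        strands=cfg.negative_strands,
    )
    split = split_dataset(positives[: len(negatives)], negatives[: len(positives)],
                          cfg.split)
    model, report = train_from_windows(split, cfg, catalogue)
    return model, split, report
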