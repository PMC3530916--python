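import numpy as np
import pytest

from tispred.ann import ANNConfig
from tispred.dataset import SplitConfig, build_positive_set, sample_negatives, split_dataset
from tispred.ga_select import GAConfig
from tispred.pipeline import PipelineConfig, train_from_windows
from tispred.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_synth():
    """A small synthetic genome with planted starts (ground truth known)."""
    cfg = SyntheticConfig(n_sequences=3, sequence_length=20_000, n_genes=30, seed=11)
    genomes, gff, truth = generate(cfg)
    return cfg, genomes, gff, truth


@pytest.fixture(scope="session")
def tiny_model():
    """A quickly trained model for scanner/serialization tests."""
    cfg = SyntheticConfig(n_sequences=2, sequence_length=30_000, n_genes=120, seed=5)
    genomes, gff, _ = generate(cfg)
    pos = build_positive_set(genomes, gff)
    neg = sample_negatives(genomes, pos, len(pos), seed=5)
    sc = SplitConfig(feature_estimation_per_class=30, validation_per_class=18, seed=5)
    split = split_dataset(pos, neg, sc)
    pcfg = PipelineConfig(
        split=sc,
        ga=GAConfig(population_size=6, generations=3, seed=5),
        ann=ANNConfig(max_epochs=150, patience=15, seed=5),
    )
    model, report = train_from_windows(split, pcfg)
    return genomes, model, report


def _signal_run(beta: float, bias: float, seed: int = 7) -> dict:
    """Full pipeline on an independent synthetic draw; returns the test report."""
    cfg = SyntheticConfig(
        n_sequences=5, sequence_length=60_000, n_genes=400,
        consensus_strength=beta, codon_bias_strength=bias, seed=seed,
    )
    genomes, gff, _ = generate(cfg)
    pos = build_positive_set(genomes, gff)
    neg = sample_negatives(genomes, pos, len(pos), seed=seed)
    sc = SplitConfig(feature_estimation_per_class=100, validation_per_class=60, seed=seed)
    split = split_dataset(pos, neg, sc)
    pcfg = PipelineConfig(split=sc, ga=GAConfig(population_size=20, generations=10, seed=seed))
    _, report = train_from_windows(split, pcfg)
    return report["test"]


@pytest.fixture(scope="session")
def signal_runs():
    """End-to-end recovery at decreasing planted-signal strength."""
    return {
        0.9: _signal_run(0.9, 0.9),
        0.5: _signal_run(0.5, 0.5),
        0.0: _signal_run(0.0, 0.0),
    }
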