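"""The trained-model artifact: network weights, selected feature
descriptors, data-derived feature parameters, and metadata, bundled in one
versioned JSON file."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import ConfigurationError
from .features import FeatureDescriptor, FeatureParams, compute_feature_matrix
from .sequence_io import TISWindow, WindowConfig

SCHEMA_VERSION = 1


@dataclass
class TrainedModel:
    weights: dict[str, np.ndarray]
    catalogue: list[FeatureDescriptor]  # the selected descriptors, in order
    params: FeatureParams  # normalization constants restricted to catalogue
    window: WindowConfig = field(default_factory=WindowConfig)
    threshold: float = 0.5
    metadata: dict = field(default_factory=dict)

    def score_windows(self, windows: Sequence[TISWindow]) -> np.ndarray:
        from .ann import forward

        X = compute_feature_matrix(windows, self.catalogue, self.params, self.window)
        return forward(self.weights, X)

    def predict_windows(self, windows: Sequence[TISWindow]) -> np.ndarray:
        return (self.score_windows(windows) >= self.threshold).astype(int)


def _descriptor_to_dict(d: FeatureDescriptor) -> dict:
    return {"name": d.name, "family": d.family, "region": list(d.region) if d.region else None,
            "params": dict(d.params), "fixed": d.fixed}


def _descriptor_from_dict(d: dict) -> FeatureDescriptor:
    return FeatureDescriptor(
        name=d["name"], family=d["family"],
        region=tuple(d["region"]) if d.get("region") else None,
        params=tuple(sorted(d.get("params", {}).items())),
        fixed=bool(d.get("fixed", False)),
    )


def save_catalogue(catalogue: Sequence[FeatureDescriptor], path: str | Path) -> None:
    """Human-editable YAML, one entry per descriptor."""
    with open(path, "w") as fh:
        yaml.safe_dump([_descriptor_to_dict(d) for d in catalogue], fh, sort_keys=False)


def load_catalogue(path: str | Path) -> list[FeatureDescriptor]:
    with open(path) as fh:
        return [_descriptor_from_dict(d) for d in yaml.safe_load(fh)]


def save_model(model: TrainedModel, path: str | Path) -> None:
    mean, scale = model.params.normalization
    doc = {
        "schema_version": SCHEMA_VERSION,
        "weights": {k: v.tolist() for k, v in model.weights.items()},
        "catalogue": [_descriptor_to_dict(d) for d in model.catalogue],
        "params": {
            "pwm": {str(r): probs for r, probs in model.params.pwm.items()},
            "background": model.params.background,
            "normalization": {"mean": mean.tolist(), "scale": scale.tolist()},
        },
        "window": {"window_length": model.window.window_length,
                   "tis_offset": model.window.tis_offset},
        "threshold": model.threshold,
        "metadata": model.metadata,
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> TrainedModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ConfigurationError(
            f"unsupported model schema {doc.get('schema_version')!r}"
        )
    params = FeatureParams(
        pwm={int(r): probs for r, probs in doc["params"]["pwm"].items()},
        background=doc["params"]["background"],
        normalization=(np.asarray(doc["params"]["normalization"]["mean"]),
                       np.asarray(doc["params"]["normalization"]["scale"])),
    )
    return TrainedModel(
        weights={k: np.asarray(v) for k, v in doc["weights"].items()},
        catalogue=[_descriptor_from_dict(d) for d in doc["catalogue"]],
        params=params,
        window=WindowConfig(**doc["window"]),
        threshold=doc["threshold"],
        metadata=doc.get("metadata", {}),
    )
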