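"""Sequence-context features for candidate start codons.

A feature catalogue is a declarative list of descriptors; each descriptor
maps a candidate window to one real value.  Families cover the classic TIS
signals: position weight matrix (PWM) log-odds over the Kozak context,
positional base indicators (e.g. purine at -3, G at +4), k-mer
frequencies (optionally restricted to a reading frame), downstream
open-reading-frame length and in-frame stop indicators, upstream ATG
counts, and G+C content — reaching as far as the window flanks allow
(up to ~150 bp from the candidate).

Positions are signed coordinates relative to the candidate codon with the
Kozak convention: the A of the ATG is +1 (there is no 0), so -3 is three
bases 5' of the A and +4 is the first base 3' of the G.

Data-derived parameters (PWM, background composition, per-feature
normalization constants) are estimated once on a dedicated
feature-estimation partition, never on training/validation/test windows.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigurationError
from .sequence_io import POSITIVE, TISWindow, WindowConfig

BASES = "ACGT"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

FAMILIES = frozenset({
    "positional_onehot", "kmer_frequency", "pwm_score",
    "inframe_stop", "orf_length", "upstream_atg", "gc_content",
})


@dataclass(frozen=True)
class FeatureDescriptor:
    """One feature: a family plus its parameters.

    ``region`` is a signed-coordinate interval (inclusive) relative to the
    A of the candidate codon; families that do not use a region leave it
    None.  ``fixed`` marks membership of the always-on subset that feature
    selection may not remove.
    """

    name: str
    family: str
    region: tuple[int, int] | None = None
    params: tuple[tuple[str, object], ...] = ()
    fixed: bool = False

    def __post_init__(self):
        # canonical order so equal descriptors compare equal after round-trips
        object.__setattr__(self, "params", tuple(sorted(tuple(self.params))))
        if self.region is not None:
            object.__setattr__(self, "region", tuple(self.region))

    def param(self, key: str, default=None):
        return dict(self.params).get(key, default)


@dataclass
class FeatureParams:
    """Data-derived parameters estimated on the feature-estimation partition.

    pwm: {signed position: {base: probability}}; background: {base:
    probability}; normalization: per-feature (location, scale) pairs in
    catalogue order; kmer_class_stats is reserved for per-class k-mer
    tables and is unused by the default catalogue.
    """

    pwm: dict[int, dict[str, float]]
    background: dict[str, float]
    normalization: tuple[np.ndarray, np.ndarray]  # (mean, scale), scale > 0
    kmer_class_stats: dict | None = None


def rel_to_index(r: int, cfg: WindowConfig) -> int:
    """0-based window index of signed position ``r`` (no position 0)."""
    if r == 0:
        raise ConfigurationError("signed positions skip 0; the A of the codon is +1")
    return cfg.tis_offset - 1 + r if r < 0 else cfg.tis_offset - 2 + r


def region_slice(window_seq: str, region: tuple[int, int], cfg: WindowConfig) -> str:
    lo, hi = region
    return window_seq[rel_to_index(lo, cfg) : rel_to_index(hi, cfg) + 1]


# ---------------------------------------------------------------------------
# elementary feature computations


def gc_content(seq: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T); N excluded from both sides.
    All-N regions score 0 by convention."""
    acgt = sum(seq.count(b) for b in BASES)
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def kmer_frequencies(seq: str, k: int, frame: int | None = None) -> dict[str, float]:
    """Overlapping k-mer frequencies over ``seq``.

    With ``frame`` set, only start positions congruent to ``frame`` mod 3
    (counted from the start of ``seq``) are used.  Counts are divided by
    the number of counted positions; k-mers containing N contribute zero
    counts.  Regions shorter than k give an all-zero table.
    """
    if k not in (1, 2, 3):
        raise ConfigurationError(f"k must be 1, 2 or 3, got {k}")
    table = {"".join(t): 0.0 for t in itertools.product(BASES, repeat=k)}
    starts = range(0, len(seq) - k + 1)
    if frame is not None:
        starts = [i for i in starts if i % 3 == frame]
    n = len(starts)
    if n == 0:
        return table
    for i in starts:
        kmer = seq[i : i + k]
        if kmer in table:
            table[kmer] += 1.0
    for kmer in table:
        table[kmer] /= n
    return table


def pwm_score(
    window_seq: str,
    pwm: Mapping[int, Mapping[str, float]],
    background: Mapping[str, float],
    cfg: WindowConfig = WindowConfig(),
) -> float:
    """Sum over PWM positions of log2(p(base|position)/p(base|background)).
    N contributes 0."""
    score = 0.0
    for r, probs in pwm.items():
        base = window_seq[rel_to_index(r, cfg)]
        if base in probs:
            score += math.log2(probs[base] / background[base])
    return score


def orf_and_stop_features(window: TISWindow, cfg: WindowConfig = WindowConfig()) -> tuple[int, int, int]:
    """(codons to first downstream in-frame stop, has downstream in-frame
    stop, upstream in-frame stop count).

    The downstream scan starts at the codon immediately after the candidate
    ATG and proceeds in frame; the count is the number of complete codons
    strictly before the first stop, capped at the number of complete
    downstream codons.  The upstream count scans complete in-frame codons
    5' of the candidate within the window.
    """
    seq = window.sequence
    a0 = cfg.tis_offset - 1
    down = seq[a0 + 3 :]
    n_codons = len(down) // 3
    count = n_codons
    has_stop = 0
    for c in range(n_codons):
        if down[3 * c : 3 * c + 3] in STOP_CODONS:
            count = c
            has_stop = 1
            break
    up = seq[:a0]
    n_up = len(up) // 3
    tail = up[len(up) - 3 * n_up :]  # codons in frame with the ATG
    upstream_stops = sum(1 for c in range(n_up) if tail[3 * c : 3 * c + 3] in STOP_CODONS)
    return count, has_stop, upstream_stops


def upstream_atg_count(window: TISWindow, cfg: WindowConfig = WindowConfig()) -> int:
    """Number of ATG occurrences (any frame) strictly 5' of the candidate."""
    up = window.sequence[: cfg.tis_offset - 1]
    count = 0
    i = up.find("ATG")
    while i != -1:
        count += 1
        i = up.find("ATG", i + 1)
    return count


# ---------------------------------------------------------------------------
# catalogue


def default_catalogue(cfg: WindowConfig = WindowConfig()) -> list[FeatureDescriptor]:
    """The default feature catalogue.

    The fixed subset holds the consensus previously-reported TIS features:
    PWM log-odds over the Kozak span [-10,+5], base indicators at -3 and
    +4, and the downstream in-frame stop/ORF features.  Selectable features
    are compositional and contextual summaries the selector may add.
    """
    up = (-cfg.upstream_length, -1)
    down_start = 4
    down = (down_start, down_start + cfg.downstream_length - 1)
    cat: list[FeatureDescriptor] = [
        FeatureDescriptor("pwm_kozak", "pwm_score", (-10, 5), fixed=True),
        FeatureDescriptor("orf_codons_to_stop", "orf_length", fixed=True),
        FeatureDescriptor("downstream_has_stop", "inframe_stop",
                          params=(("which", "has_stop_downstream"),), fixed=True),
    ]
    for pos in (-3, 4):
        for base in BASES:
            cat.append(FeatureDescriptor(
                f"onehot_{pos:+d}_{base}", "positional_onehot",
                params=(("position", pos), ("base", base)), fixed=True,
            ))
    cat += [
        FeatureDescriptor("gc_upstream", "gc_content", up),
        FeatureDescriptor("gc_downstream", "gc_content", down),
        FeatureDescriptor("upstream_atg_count", "upstream_atg"),
        FeatureDescriptor("upstream_inframe_stops", "inframe_stop",
                          params=(("which", "upstream_stop_count"),)),
    ]
    for base in BASES:
        cat.append(FeatureDescriptor(
            f"freq_up_{base}", "kmer_frequency", up,
            params=(("k", 1), ("kmer", base)),
        ))
        cat.append(FeatureDescriptor(
            f"freq_down_{base}", "kmer_frequency", down,
            params=(("k", 1), ("kmer", base)),
        ))
    for d in ("".join(t) for t in itertools.product(BASES, repeat=2)):
        cat.append(FeatureDescriptor(
            f"freq_down_{d}", "kmer_frequency", down,
            params=(("k", 2), ("kmer", d)),
        ))
    return cat


def validate_catalogue(catalogue: Sequence[FeatureDescriptor], cfg: WindowConfig) -> None:
    """Raise ConfigurationError for duplicate names, unknown families, or
    regions outside the window — once at catalogue time, not per window."""
    names = [d.name for d in catalogue]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate feature names in catalogue")
    for d in catalogue:
        if d.family not in FAMILIES:
            raise ConfigurationError(f"unknown feature family {d.family!r} ({d.name})")
        if d.region is not None:
            lo, hi = d.region
            for r in (lo, hi):
                i = rel_to_index(r, cfg)
                if not 0 <= i < cfg.window_length:
                    raise ConfigurationError(
                        f"descriptor {d.name!r} region {d.region} outside window"
                    )
            if rel_to_index(lo, cfg) > rel_to_index(hi, cfg):
                raise ConfigurationError(f"descriptor {d.name!r} has empty region")
        if d.family == "positional_onehot":
            rel_to_index(int(d.param("position")), cfg)


DEFAULT_PWM_SPAN = (-10, 5)
DEFAULT_PSEUDOCOUNT = 0.25


def estimate_pwm(
    positives: Sequence[TISWindow],
    cfg: WindowConfig,
    span: tuple[int, int] = DEFAULT_PWM_SPAN,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> dict[int, dict[str, float]]:
    """Per-position base probabilities around the codon, from positive
    windows, with additive smoothing.  The invariant A/T/G positions
    (+1..+3) carry no information and are excluded."""
    positions = [r for r in range(span[0], span[1] + 1) if r not in (0, 1, 2, 3)]
    pwm: dict[int, dict[str, float]] = {}
    for r in positions:
        i = rel_to_index(r, cfg)
        counts = {b: pseudocount for b in BASES}
        total = 4 * pseudocount
        for w in positives:
            b = w.sequence[i]
            if b in counts:
                counts[b] += 1.0
                total += 1.0
        pwm[r] = {b: counts[b] / total for b in BASES}
    return pwm


def estimate_background(windows: Sequence[TISWindow]) -> dict[str, float]:
    counts = {b: 1.0 for b in BASES}  # add-one smoothing keeps log-odds finite
    for w in windows:
        for b in BASES:
            counts[b] += w.sequence.count(b)
    total = sum(counts.values())
    return {b: counts[b] / total for b in BASES}


def _raw_value(
    d: FeatureDescriptor,
    window: TISWindow,
    params: FeatureParams,
    cfg: WindowConfig,
    cache: dict,
) -> float:
    if d.family == "gc_content":
        return gc_content(region_slice(window.sequence, d.region, cfg))
    if d.family == "kmer_frequency":
        key = (d.region, d.param("k"), d.param("frame"))
        if key not in cache:
            cache[key] = kmer_frequencies(
                region_slice(window.sequence, d.region, cfg),
                int(d.param("k")),
                d.param("frame"),
            )
        return cache[key][d.param("kmer")]
    if d.family == "pwm_score":
        return pwm_score(window.sequence, params.pwm, params.background, cfg)
    if d.family == "positional_onehot":
        i = rel_to_index(int(d.param("position")), cfg)
        return 1.0 if window.sequence[i] == d.param("base") else 0.0
    if d.family == "orf_length":
        if "orf" not in cache:
            cache["orf"] = orf_and_stop_features(window, cfg)
        return float(cache["orf"][0])
    if d.family == "inframe_stop":
        if "orf" not in cache:
            cache["orf"] = orf_and_stop_features(window, cfg)
        which = d.param("which", "has_stop_downstream")
        return float(cache["orf"][1] if which == "has_stop_downstream" else cache["orf"][2])
    if d.family == "upstream_atg":
        return float(upstream_atg_count(window, cfg))
    raise ConfigurationError(f"unknown family {d.family!r}")


def raw_feature_matrix(
    windows: Sequence[TISWindow],
    catalogue: Sequence[FeatureDescriptor],
    params: FeatureParams,
    cfg: WindowConfig,
) -> np.ndarray:
    X = np.empty((len(windows), len(catalogue)), dtype=float)
    for i, w in enumerate(windows):
        cache: dict = {}
        for j, d in enumerate(catalogue):
            X[i, j] = _raw_value(d, w, params, cfg, cache)
    return X


def estimate_feature_params(
    feature_estimation_windows: Sequence[TISWindow],
    catalogue: Sequence[FeatureDescriptor],
    cfg: WindowConfig = WindowConfig(),
    pwm_span: tuple[int, int] = DEFAULT_PWM_SPAN,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> FeatureParams:
    """Estimate PWM (positives only), background (pooled), and per-feature
    z-normalization constants (pooled) from the feature-estimation windows."""
    if not feature_estimation_windows:
        raise ConfigurationError("feature estimation requires at least one window")
    validate_catalogue(catalogue, cfg)
    positives = [w for w in feature_estimation_windows if w.label == POSITIVE]
    pwm = estimate_pwm(positives or feature_estimation_windows, cfg, pwm_span, pseudocount)
    background = estimate_background(feature_estimation_windows)
    params = FeatureParams(
        pwm=pwm, background=background,
        normalization=(np.zeros(len(catalogue)), np.ones(len(catalogue))),
    )
    X = raw_feature_matrix(feature_estimation_windows, catalogue, params, cfg)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0.0] = 1.0  # constant features stay centred, not inflated
    params.normalization = (mean, scale)
    return params


def compute_features(
    window: TISWindow,
    catalogue: Sequence[FeatureDescriptor],
    params: FeatureParams,
    cfg: WindowConfig = WindowConfig(),
) -> np.ndarray:
    """Normalized feature vector for one window, in catalogue order."""
    return compute_feature_matrix([window], catalogue, params, cfg)[0]


def compute_feature_matrix(
    windows: Sequence[TISWindow],
    catalogue: Sequence[FeatureDescriptor],
    params: FeatureParams,
    cfg: WindowConfig = WindowConfig(),
) -> np.ndarray:
    mean, scale = params.normalization
    X = raw_feature_matrix(windows, catalogue, params, cfg)
    return (X - mean) / scale


class WindowFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer mapping candidate windows to normalized feature vectors.

    ``fit`` estimates the data-derived parameters (PWM from positive
    windows, background composition, per-feature z-normalization) and must
    only ever see the feature-estimation partition; ``transform`` maps any
    windows to the numeric matrix.

    Parameters
    ----------
    catalogue : list of FeatureDescriptor, optional
        Defaults to :func:`default_catalogue`.
    window : WindowConfig
        Window geometry shared with extraction.
    """

    def __init__(self, catalogue=None, window=None,
                 pwm_span=DEFAULT_PWM_SPAN, pseudocount=DEFAULT_PSEUDOCOUNT):
        self.catalogue = catalogue
        self.window = window
        self.pwm_span = pwm_span
        self.pseudocount = pseudocount

    def _resolved(self):
        cfg = self.window or WindowConfig()
        cat = list(self.catalogue) if self.catalogue is not None else default_catalogue(cfg)
        return cat, cfg

    def fit(self, windows: Sequence[TISWindow], y=None):
        cat, cfg = self._resolved()
        self.params_ = estimate_feature_params(
            windows, cat, cfg, self.pwm_span, self.pseudocount
        )
        self.catalogue_ = cat
        self.fitted_origins_ = frozenset(w.origin for w in windows)
        self.n_features_ = len(cat)
        return self

    def transform(self, windows: Sequence[TISWindow]) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise ConfigurationError("WindowFeaturizer is not fitted")
        cat, cfg = self.catalogue_, self.window or WindowConfig()
        return compute_feature_matrix(windows, cat, self.params_, cfg)

    def feature_names(self) -> list[str]:
        return [d.name for d in self.catalogue_]
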