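import itertools
import math

import numpy as np
import pytest

from tispred.errors import ConfigurationError
from tispred.features import (
    FeatureDescriptor,
    WindowFeaturizer,
    compute_features,
    default_catalogue,
    estimate_feature_params,
    gc_content,
    kmer_frequencies,
    orf_and_stop_features,
    pwm_score,
    rel_to_index,
    region_slice,
    upstream_atg_count,
    validate_catalogue,
)
from tispred.sequence_io import POSITIVE, NEGATIVE, TISWindow, WindowConfig
from tispred.synthetic import DEFAULT_CONSENSUS, SyntheticConfig, generate
from tispred.dataset import build_positive_set, sample_negatives

CFG = WindowConfig()
BASES = "ACGT"


def _random_window(rng, label=POSITIVE):
    seq = "".join(rng.choice(list(BASES), size=300))
    seq = seq[:149] + "ATG" + seq[152:]
    return TISWindow(seq, label, ("r", int(rng.integers(1, 10**6)), "+"))


class TestCoordinates:
    def test_kozak_numbering(self):
        # the A of the codon is +1; -3 is three bases 5' of it, +4 the base
        # after the G
        assert rel_to_index(1, CFG) == 149
        assert rel_to_index(3, CFG) == 151
        assert rel_to_index(4, CFG) == 152
        assert rel_to_index(-1, CFG) == 148
        assert rel_to_index(-3, CFG) == 146
        assert rel_to_index(-149, CFG) == 0

    def test_position_zero_rejected(self):
        with pytest.raises(ConfigurationError):
            rel_to_index(0, CFG)


class TestGCContent:
    @pytest.mark.parametrize("seq,expected", [
        ("ATGC", 0.5), ("AAAA", 0.0), ("GGCC", 1.0), ("NNNN", 0.0), ("GNC", 1.0),
    ])
    def test_examples(self, seq, expected):
        assert gc_content(seq) == expected

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGTN"), size=500))
        counted = [b for b in seq if b != "N"]
        expected = sum(b in "GC" for b in counted) / len(counted)
        assert gc_content(seq) == pytest.approx(expected, abs=1e-15)


class TestKmerFrequencies:
    def test_homopolymer_dinucleotides(self):
        t = kmer_frequencies("AAAA", 2)
        assert t["AA"] == 1.0
        assert sum(t.values()) == 1.0

    def test_region_shorter_than_k_gives_zeros(self):
        t = kmer_frequencies("AC", 3)
        assert all(v == 0.0 for v in t.values())

    @pytest.mark.parametrize("k", [1, 2, 3])
    @pytest.mark.parametrize("frame", [None, 0, 1, 2])
    def test_matches_brute_force_oracle(self, k, frame):
        rng = np.random.default_rng(k * 10 + (frame or 0))
        for _ in range(15):
            seq = "".join(rng.choice(list("ACGTN"), size=int(rng.integers(1, 60))))
            table = kmer_frequencies(seq, k, frame)
            starts = [i for i in range(len(seq) - k + 1)
                      if frame is None or i % 3 == frame]
            for kmer in ("".join(t) for t in itertools.product(BASES, repeat=k)):
                n_hits = sum(seq[i:i + k] == kmer for i in starts)
                expected = n_hits / len(starts) if starts else 0.0
                assert table[kmer] == pytest.approx(expected, abs=1e-15)

    def test_frame_counts_sum_to_unrestricted_counts(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list(BASES), size=147))
        n_all = len(seq) - 2
        total = kmer_frequencies(seq, 3)
        by_frame = {f: kmer_frequencies(seq, 3, f) for f in (0, 1, 2)}
        n_f = {f: len([i for i in range(n_all) if i % 3 == f]) for f in (0, 1, 2)}
        for kmer in total:
            framed = sum(by_frame[f][kmer] * n_f[f] for f in (0, 1, 2))
            assert framed == pytest.approx(total[kmer] * n_all, abs=1e-9)


class TestPWMScore:
    def test_uniform_pwm_equal_to_background_scores_zero(self):
        pwm = {r: {b: 0.25 for b in BASES} for r in (-3, -2, -1, 4)}
        bg = {b: 0.25 for b in BASES}
        rng = np.random.default_rng(1)
        for _ in range(10):
            assert pwm_score(_random_window(rng).sequence, pwm, bg, CFG) == 0.0

    def test_consensus_achieves_maximal_score(self):
        rng = np.random.default_rng(2)
        positions = [-5, -4, -3, -2, -1, 4, 5]
        pwm = {}
        consensus = {}
        for r in positions:
            probs = rng.dirichlet(np.ones(4))
            pwm[r] = dict(zip(BASES, probs))
            consensus[r] = BASES[int(np.argmax(probs))]
        bg = {b: 0.25 for b in BASES}
        base_seq = list(_random_window(rng).sequence)
        best = base_seq.copy()
        for r, b in consensus.items():
            best[rel_to_index(r, CFG)] = b
        best_score = pwm_score("".join(best), pwm, bg, CFG)
        for _ in range(1000):
            trial = base_seq.copy()
            for r in positions:
                trial[rel_to_index(r, CFG)] = BASES[int(rng.integers(4))]
            assert pwm_score("".join(trial), pwm, bg, CFG) <= best_score + 1e-12

    def test_score_additive_over_span_split(self):
        rng = np.random.default_rng(4)
        w = _random_window(rng).sequence
        probs = {r: dict(zip(BASES, rng.dirichlet(np.ones(4)))) for r in range(-6, 0)}
        bg = dict(zip(BASES, rng.dirichlet(np.ones(4))))
        left = {r: probs[r] for r in (-6, -5, -4)}
        right = {r: probs[r] for r in (-3, -2, -1)}
        whole = pwm_score(w, probs, bg, CFG)
        assert whole == pytest.approx(
            pwm_score(w, left, bg, CFG) + pwm_score(w, right, bg, CFG), abs=1e-12
        )

    def test_n_contributes_zero(self):
        pwm = {-1: {b: 0.97 if b == "G" else 0.01 for b in BASES}}
        bg = {b: 0.25 for b in BASES}
        seq = "N" * 149 + "ATG" + "A" * 148
        assert pwm_score(seq, pwm, bg, CFG) == 0.0


class TestOrfStopFeatures:
    def test_stop_immediately_after_atg(self):
        seq = "C" * 149 + "ATG" + "TAA" + "C" * 145
        down, has_stop, _ = orf_and_stop_features(TISWindow(seq), CFG)
        assert (down, has_stop) == (0, 1)

    def test_no_downstream_stop_caps_at_complete_codons(self):
        seq = "C" * 149 + "ATG" + "C" * 148
        down, has_stop, _ = orf_and_stop_features(TISWindow(seq), CFG)
        assert (down, has_stop) == (49, 0)  # floor(148/3) complete codons

    def test_matches_brute_force_triplet_scanner(self):
        rng = np.random.default_rng(5)
        stops = {"TAA", "TAG", "TGA"}
        for _ in range(60):
            w = _random_window(rng)
            down, has_stop, up = orf_and_stop_features(w, CFG)
            seq = w.sequence
            down_codons = [seq[152 + 3 * c:155 + 3 * c] for c in range(49)]
            first = next((c for c, cod in enumerate(down_codons) if cod in stops), None)
            assert down == (49 if first is None else first)
            assert has_stop == (0 if first is None else 1)
            upstream = seq[:149]
            tail = upstream[len(upstream) - 3 * (len(upstream) // 3):]
            exp_up = sum(tail[3 * c:3 * c + 3] in stops for c in range(len(tail) // 3))
            assert up == exp_up


class TestUpstreamATG:
    def test_no_upstream_atg(self):
        assert upstream_atg_count(TISWindow("C" * 149 + "ATG" + "C" * 148), CFG) == 0

    def test_two_upstream_atgs(self):
        seq = "ATGATG" + "C" * 143 + "ATG" + "C" * 148
        assert upstream_atg_count(TISWindow(seq), CFG) == 2

    def test_matches_string_count_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(60):
            w = _random_window(rng)
            up = w.sequence[:149]
            expected = sum(up[i:i + 3] == "ATG" for i in range(len(up) - 2))
            assert upstream_atg_count(w, CFG) == expected


@pytest.fixture(scope="module")
def fe_windows():
    rng = np.random.default_rng(21)
    return ([_random_window(rng, POSITIVE) for _ in range(60)]
            + [_random_window(rng, NEGATIVE) for _ in range(60)])


class TestParamEstimation:
    def test_identical_positives_give_near_degenerate_pwm(self):
        w = TISWindow("A" * 149 + "ATG" + "C" * 148, POSITIVE, ("p", 1, "+"))
        windows = [TISWindow(w.sequence, POSITIVE, ("p", i, "+")) for i in range(50)]
        params = estimate_feature_params(windows, default_catalogue(CFG), CFG)
        for r, probs in params.pwm.items():
            expected_base = "A" if r < 0 else "C"
            assert max(probs, key=probs.get) == expected_base
            assert probs[expected_base] > 0.95
            assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_planted_consensus_recovered_from_synthetic_positives(self):
        cfg = SyntheticConfig(n_sequences=2, sequence_length=60_000, n_genes=180,
                              consensus_strength=1.0, seed=13)
        genomes, gff, _ = generate(cfg)
        pos = build_positive_set(genomes, gff)
        params = estimate_feature_params(pos, default_catalogue(CFG), CFG)
        for r, base in DEFAULT_CONSENSUS.items():
            assert max(params.pwm[r], key=params.pwm[r].get) == base

    def test_normalization_gives_zero_mean_unit_variance_on_fit_windows(self, fe_windows):
        featurizer = WindowFeaturizer().fit(fe_windows)
        X = featurizer.transform(fe_windows)
        varying = X.std(axis=0) > 1e-12
        assert np.allclose(X.mean(axis=0), 0.0, atol=1e-6)
        assert np.allclose(X[:, varying].std(axis=0), 1.0, atol=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ConfigurationError):
            estimate_feature_params([], default_catalogue(CFG), CFG)


class TestComputeFeatures:
    def test_deterministic_and_pure(self, fe_windows):
        cat = default_catalogue(CFG)
        params = estimate_feature_params(fe_windows, cat, CFG)
        w = fe_windows[0]
        v1 = compute_features(w, cat, params, CFG)
        v2 = compute_features(w, cat, params, CFG)
        assert np.array_equal(v1, v2)
        assert len(v1) == len(cat)
        assert np.all(np.isfinite(v1))

    def test_identical_windows_identical_vectors(self, fe_windows):
        cat = default_catalogue(CFG)
        params = estimate_feature_params(fe_windows, cat, CFG)
        w = fe_windows[3]
        twin = TISWindow(w.sequence, w.label, ("other", 99, "+"))
        assert np.array_equal(compute_features(w, cat, params, CFG),
                              compute_features(twin, cat, params, CFG))

    def test_kmer_features_match_sliding_count_oracle(self, fe_windows):
        cat = default_catalogue(CFG)
        params = estimate_feature_params(fe_windows, cat, CFG)
        mean, scale = params.normalization
        rng = np.random.default_rng(22)
        kmer_idx = [(j, d) for j, d in enumerate(cat) if d.family == "kmer_frequency"]
        for _ in range(50):
            w = _random_window(rng)
            vec = compute_features(w, cat, params, CFG)
            for j, d in kmer_idx:
                region = region_slice(w.sequence, d.region, CFG)
                k, kmer = int(d.param("k")), d.param("kmer")
                n = len(region) - k + 1
                raw = sum(region[i:i + k] == kmer for i in range(n)) / n
                assert vec[j] == pytest.approx((raw - mean[j]) / scale[j], abs=1e-12)


class TestCatalogueValidation:
    def test_region_outside_window_rejected_at_catalogue_time(self):
        bad = [FeatureDescriptor("oob", "gc_content", (-200, -1))]
        with pytest.raises(ConfigurationError):
            validate_catalogue(bad, CFG)

    def test_duplicate_names_rejected(self):
        cat = default_catalogue(CFG)
        with pytest.raises(ConfigurationError):
            validate_catalogue(cat + [cat[0]], CFG)
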