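"""Chaotic descriptors, cepstra and moments of the activity bank."""

import numpy as np
import pytest

from imupipe.har_features import (
    HARFeatureExtractor,
    HarFeatureConfig,
    embedding_dimension,
    extract_har_features,
    fractal_dimension,
    kurtosis,
    max_lyapunov_exponent,
    mfcc,
    skewness,
)
from imupipe.preprocessing import segment_windows, stack_windows
from imupipe.synthetic import ScenarioSpec, generate_recording


def logistic_map(n=2000, x0=0.4):
    x = np.empty(n)
    x[0] = x0
    for i in range(n - 1):
        x[i + 1] = 4.0 * x[i] * (1.0 - x[i])
    return x


# ---------------------------------------------------------------------------
# independent brute-force oracles (naive loops, no shared code path)
# ---------------------------------------------------------------------------

def higuchi_oracle(x, k_max):
    n = len(x)
    logL, logk = [], []
    for k in range(1, k_max + 1):
        Lm = []
        for m in range(k):
            npts = (n - m - 1) // k
            if npts < 1:
                continue
            length = 0.0
            for i in range(1, npts + 1):
                length += abs(x[m + i * k] - x[m + (i - 1) * k])
            Lm.append(length * (n - 1) / (npts * k) / k)
        logL.append(np.log(np.mean(Lm)))
        logk.append(np.log(1.0 / k))
    return np.polyfit(logk, logL, 1)[0]


def rosenstein_oracle(x, emb_dim, delay, min_tsep, k_max, fit_len):
    m = len(x) - (emb_dim - 1) * delay
    Y = [x[i:i + (emb_dim - 1) * delay + 1:delay] for i in range(m)]
    nn = []
    for i in range(m):
        best, best_j = np.inf, -1
        for j in range(m):
            if abs(i - j) <= min_tsep:
                continue
            d = np.linalg.norm(np.subtract(Y[i], Y[j]))
            if d < best:
                best, best_j = d, j
        nn.append(best_j)
    ks, div = [], []
    for k in range(min(k_max, m - 1) + 1):
        logs = []
        for i in range(m):
            if i + k < m and nn[i] + k < m:
                d = np.linalg.norm(np.subtract(Y[i + k], Y[nn[i] + k]))
                logs.append(np.log(max(d, 1e-12)))
        if len(logs) < 2:
            break
        if k <= fit_len:
            ks.append(k)
            div.append(np.mean(logs))
    return np.polyfit(ks, div, 1)[0]


class TestLyapunov:
    def test_logistic_map_exponent_near_ln2(self):
        g = max_lyapunov_exponent(logistic_map(), emb_dim=2, delay=1)
        assert g == pytest.approx(np.log(2.0), rel=0.10)

    def test_sinusoid_exponent_near_zero(self):
        t = np.arange(2000) / 40.0
        g = max_lyapunov_exponent(np.sin(2 * np.pi * 1.1 * t), emb_dim=2)
        assert abs(g) < 0.02

    def test_constant_input_degenerate_zero(self):
        assert max_lyapunov_exponent(np.full(500, 2.0)) == 0.0

    def test_too_short_input(self):
        with pytest.raises(ValueError):
            max_lyapunov_exponent(np.arange(50.0))

    def test_agrees_with_bruteforce_oracle(self, rng):
        # brute-force O(n^2) loops vs the vectorized path, same parameters
        for _ in range(5):
            x = logistic_map(x0=rng.uniform(0.1, 0.9))[:400]
            ours = max_lyapunov_exponent(x, emb_dim=2, delay=1, min_tsep=4,
                                         k_max=8, fit_len=5)
            ref = rosenstein_oracle(x, 2, 1, 4, 8, 5)
            assert ours == pytest.approx(ref, rel=1e-9)


class TestFractalDimension:
    def test_ramp_dimension_one(self):
        assert fractal_dimension(np.linspace(0, 5, 2000)) == pytest.approx(
            1.0, abs=0.05)

    def test_white_noise_dimension_two(self, rng):
        assert fractal_dimension(rng.standard_normal(2000)) == pytest.approx(
            2.0, abs=0.15)

    def test_constant_degenerate(self):
        assert fractal_dimension(np.full(200, 1.5)) == 1.0

    def test_agrees_with_bruteforce_oracle(self, rng):
        for _ in range(20):
            x = np.cumsum(rng.standard_normal(300)) + rng.standard_normal(300)
            ours = fractal_dimension(x, k_max=10)
            ref = higuchi_oracle(x, 10)
            assert ours == pytest.approx(ref, rel=0.05)

    def test_length_guard(self):
        with pytest.raises(ValueError):
            fractal_dimension(np.arange(50.0), k_max=10)


class TestEmbeddingDimension:
    def test_sinusoid_unfolds_at_two(self):
        t = np.arange(2000) / 40.0
        assert embedding_dimension(np.sin(2 * np.pi * 1.1 * t)) == 2

    def test_white_noise_never_unfolds(self, rng):
        assert embedding_dimension(rng.standard_normal(2000), max_dim=10) == 10

    def test_constant_degenerate(self):
        assert embedding_dimension(np.full(200, 3.0)) == 1


class TestMoments:
    def test_symmetric_sequence_zero_skew(self):
        assert skewness(np.array([-1.0, 0.0, 1.0])) == pytest.approx(0.0)

    def test_gaussian_excess_kurtosis_near_zero(self, rng):
        assert kurtosis(rng.standard_normal(20000)) == pytest.approx(0.0, abs=0.2)

    def test_two_point_kurtosis_minus_two(self):
        assert kurtosis(np.tile([-1.0, 1.0], 50)) == pytest.approx(-2.0)

    def test_degenerate_inputs_zero(self):
        assert skewness(np.full(10, 4.0)) == 0.0
        assert kurtosis(np.full(10, 4.0)) == 0.0


class TestMFCC:
    def test_deterministic(self, rng):
        x = rng.standard_normal(4000)
        a, _ = mfcc(x, 2000.0)
        b, _ = mfcc(x.copy(), 2000.0)
        np.testing.assert_array_equal(a, b)

    def test_all_zero_signal_is_dct_of_constant(self):
        coeffs, _ = mfcc(np.zeros(1000), 2000.0)
        assert np.all(coeffs[:, 0] != 0.0)
        np.testing.assert_allclose(coeffs[:, 1:], 0.0, atol=1e-9)

    def test_positive_gain_shifts_only_coefficient_zero(self, rng):
        x = rng.standard_normal(4000)
        a, _ = mfcc(x, 2000.0)
        b, _ = mfcc(3.7 * x, 2000.0)
        np.testing.assert_allclose(a[:, 1:], b[:, 1:], atol=1e-6)
        shift = b[:, 0] - a[:, 0]
        np.testing.assert_allclose(shift, shift[0], atol=1e-6)

    def test_shorter_than_frame_rejected(self):
        with pytest.raises(ValueError):
            mfcc(np.ones(10), 2000.0)


class TestTranslationInvariance:
    def test_shiftable_features_unchanged_by_offset(self, rng):
        t = np.arange(600) / 40.0
        x = np.sin(2 * np.pi * 1.3 * t) + 0.3 * rng.standard_normal(600)
        shifted = x + 57.0
        assert max_lyapunov_exponent(x, emb_dim=3) == pytest.approx(
            max_lyapunov_exponent(shifted, emb_dim=3), abs=1e-6)
        assert fractal_dimension(x) == pytest.approx(
            fractal_dimension(shifted), abs=1e-6)
        assert embedding_dimension(x) == embedding_dimension(shifted)
        assert skewness(x) == pytest.approx(skewness(shifted), abs=1e-6)
        assert kurtosis(x) == pytest.approx(kurtosis(shifted), abs=1e-6)


class TestExtraction:
    def test_default_layout_has_486_slots(self, walking_stacks):
        fv = extract_har_features(walking_stacks[0])
        # 3 windows x 3 channels x 3 axes x (1 mle + 13 mfcc + fd + ed + skew + kurt)
        assert len(fv.layout) == 3 * 3 * 3 * 18 == 486
        assert len(fv.values) == 486
        assert np.all(np.isfinite(fv.values))

    def test_identical_stacks_identical_vectors(self, walking_stacks):
        ext = HARFeatureExtractor()
        a = ext.fit_transform([walking_stacks[0]])
        b = ext.fit_transform([walking_stacks[0]])
        np.testing.assert_array_equal(a, b)

    def test_constant_recording_yields_finite_defaults(self):
        from imupipe.sensor_io import MultiSensorRecording, RawChannel
        fs, n = 40.0, 600
        t = np.arange(n) / fs
        chans = {name: RawChannel(name, np.full((3, n), 2.0), t, fs)
                 for name in ("acc", "gyr", "mag")}
        rec = MultiSensorRecording(chans, fs=fs)
        stacks = stack_windows(segment_windows(rec), rec=rec)
        X = HARFeatureExtractor().fit_transform(stacks)
        assert np.all(np.isfinite(X))
        # degenerate defaults: mle 0, fd 1, ed 1
        fv = extract_har_features(stacks[0])
        vals = dict(zip(fv.layout, fv.values))
        assert vals["w0.acc.x.mle"] == 0.0
        assert vals["w0.acc.x.fd"] == 1.0
        assert vals["w0.acc.x.ed"] == 1.0

    def test_missing_imu_channel_rejected(self, walking_stacks):
        import copy
        stack = copy.deepcopy(walking_stacks[0])
        for w in stack.windows:
            del w.samples["mag"]
        with pytest.raises(ValueError, match="mag"):
            HARFeatureExtractor().fit_transform([stack])

    def test_no_nan_leaves_module_on_noisy_corpus(self, rng):
        rec = generate_recording(ScenarioSpec(activity="running",
                                              location="vehicle",
                                              duration_s=15, seed=9))
        stacks = stack_windows(segment_windows(rec), rec=rec)
        X = HARFeatureExtractor().fit_transform(stacks)
        assert np.all(np.isfinite(X))
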