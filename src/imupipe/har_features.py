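"""Activity-recognition feature bank.

Six descriptors are computed per 5-s window, per IMU channel, per axis, and
concatenated across the 3-window stack:

* maximum Lyapunov exponent (Rosenstein's small-data method) — divergence
  rate of nearby phase-space trajectories, in nats per sample;
* Mel-frequency cepstral coefficients (frame means);
* fractal dimension (Higuchi's estimator of the length-scaling exponent);
* embedding dimension (Kennel false-nearest-neighbors criterion);
* skewness and excess kurtosis.

Chaotic descriptors operate on the raw (untapered) samples; MFCCs use the
Hamming-tapered copies.  Degenerate inputs (zero variance) map to fixed
finite defaults — no NaN or Inf ever leaves this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.fft import dct, rfft
from scipy.spatial.distance import cdist

from .preprocessing import WindowStack, hamming_window

__all__ = [
    "HarFeatureConfig",
    "FeatureVector",
    "autocorr_delay",
    "mean_period",
    "embed_timeseries",
    "max_lyapunov_exponent",
    "mfcc",
    "mel_filterbank",
    "fractal_dimension",
    "embedding_dimension",
    "skewness",
    "kurtosis",
    "extract_har_features",
    "HARFeatureExtractor",
]

logger = logging.getLogger(__name__)

_VAR_EPS = 1e-12


@dataclass
class HarFeatureConfig:
    """Knobs of the activity bank.

    MFCC framing defaults (1 s frames, 0.5 s hop, 20 filters) suit the
    40 Hz IMU band, where audio-style 25 ms frames would be a single sample.
    """

    n_mfcc: int = 13
    n_filters: int = 20
    frame_s: float = 1.0
    hop_s: float = 0.5
    fnn_max_dim: int = 5
    fnn_rtol: float = 15.0
    fnn_atol: float = 2.0
    higuchi_k_max: int = 10
    mle_k_max: int = 8
    mle_fit_len: int = 5
    per_window: bool = True     # features per 5-s window vs on the 15-s concat


@dataclass
class FeatureVector:
    """Ordered feature values with a slot-by-slot layout manifest."""

    values: np.ndarray
    layout: list[str]
    stack_ref: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.layout):
            raise ValueError("values and layout lengths differ")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite entries")


# ---------------------------------------------------------------------------
# phase-space helpers
# ---------------------------------------------------------------------------

def autocorr_delay(x: np.ndarray, max_lag: int | None = None) -> int:
    """Embedding delay: first zero crossing of the autocorrelation."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if max_lag is None:
        max_lag = max(1, n // 10)
    xc = x - x.mean()
    denom = np.dot(xc, xc)
    if denom < _VAR_EPS:
        return 1
    for lag in range(1, max_lag + 1):
        if np.dot(xc[:-lag], xc[lag:]) / denom <= 0.0:
            return lag
    return max_lag


def mean_period(x: np.ndarray) -> int:
    """Mean period in samples, from the power-spectrum mean frequency."""
    x = np.asarray(x, dtype=float)
    p = np.abs(rfft(x - x.mean())) ** 2
    freqs = np.fft.rfftfreq(len(x))
    total = p[1:].sum()
    if total < _VAR_EPS:
        return 1
    fmean = float((freqs[1:] * p[1:]).sum() / total)
    return max(1, int(round(1.0 / fmean)))


def embed_timeseries(x: np.ndarray, dim: int, delay: int) -> np.ndarray:
    """Delay-coordinate embedding: rows are (x_t, x_{t+tau}, ...)."""
    x = np.asarray(x, dtype=float)
    m = len(x) - (dim - 1) * delay
    if m < 2:
        raise ValueError(f"series of length {len(x)} too short for "
                         f"dim={dim}, delay={delay}")
    return np.column_stack([x[i * delay: i * delay + m] for i in range(dim)])


# ---------------------------------------------------------------------------
# maximum Lyapunov exponent (Rosenstein)
# ---------------------------------------------------------------------------

def max_lyapunov_exponent(x, emb_dim: int = 3, delay: int | None = None,
                          min_tsep: int | None = None, k_max: int = 8,
                          fit_len: int = 5) -> float:
    """Largest Lyapunov exponent in nats per sample, Rosenstein's method.

    Embed the series, pair each point with its nearest neighbor outside a
    temporal exclusion window, track the mean log separation over ``k``
    steps, and fit a line over the initial ``fit_len`` steps; the slope is
    the exponent.  Periodic signals give ~0; for the chaotic r=4 logistic
    map the estimate approaches ln 2 per iteration.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if n < 100:
        raise ValueError(f"need >= 100 samples, got {n}")
    if np.var(x) < _VAR_EPS:
        return 0.0
    if delay is None:
        delay = autocorr_delay(x)
    if min_tsep is None:
        min_tsep = mean_period(x)
    Y = embed_timeseries(x, emb_dim, delay)
    m = len(Y)
    dists = cdist(Y, Y)
    idx = np.arange(m)
    excl = np.abs(idx[:, None] - idx[None, :]) <= min_tsep
    dists[excl] = np.inf
    nn = np.argmin(dists, axis=1)
    valid = np.isfinite(dists[idx, nn])
    k_max = min(k_max, m - 1)
    div = np.full(k_max + 1, np.nan)
    for k in range(k_max + 1):
        ok = valid & (idx + k < m) & (nn + k < m)
        if ok.sum() < 2:
            break
        d = np.linalg.norm(Y[idx[ok] + k] - Y[nn[ok] + k], axis=1)
        div[k] = np.mean(np.log(np.maximum(d, 1e-12)))
    ks = np.nonzero(np.isfinite(div))[0]
    ks = ks[ks <= fit_len]
    if len(ks) < 2:
        return 0.0
    slope = np.polyfit(ks, div[ks], 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# MFCC
# ---------------------------------------------------------------------------

def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, nfft: int, fs: float,
                   fmin: float = 0.0, fmax: float | None = None) -> np.ndarray:
    """Triangular Mel filters evaluated on the rFFT bin frequencies."""
    if fmax is None:
        fmax = fs / 2.0
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_filters + 2)
    hz_pts = _mel_to_hz(mel_pts)
    bins = np.fft.rfftfreq(nfft, d=1.0 / fs)
    fb = np.zeros((n_filters, len(bins)))
    for i in range(n_filters):
        left, center, right = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (bins - left) / max(center - left, 1e-12)
        down = (right - bins) / max(right - center, 1e-12)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def mfcc(x, fs: float, n_coeffs: int = 13, n_filters: int = 26,
         frame_s: float = 0.025, hop_s: float = 0.010,
         eps: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Mel-frequency cepstral coefficients.

    Pipeline: Hamming-windowed frames -> magnitude spectrum -> Mel
    filterbank -> log (floored at ``eps``, so silent frames stay finite) ->
    orthonormal DCT-II.  Returns the (n_frames, n_coeffs) matrix and its
    frame mean.  A positive gain applied to the input shifts only
    coefficient 0 (the log turns gain into an additive constant absorbed by
    the DC basis vector).
    """
    x = np.asarray(x, dtype=float).ravel()
    frame_len = max(2, int(round(frame_s * fs)))
    hop = max(1, int(round(hop_s * fs)))
    if len(x) < frame_len:
        raise ValueError(f"signal of {len(x)} samples shorter than one "
                         f"frame ({frame_len})")
    starts = np.arange(0, len(x) - frame_len + 1, hop)
    frames = np.stack([x[s:s + frame_len] for s in starts])
    frames = frames * hamming_window(frame_len)
    nfft = 1 << int(np.ceil(np.log2(frame_len)))
    spec = np.abs(rfft(frames, n=nfft, axis=1))
    fb = mel_filterbank(n_filters, nfft, fs)
    energies = spec @ fb.T
    log_e = np.log(np.maximum(energies, eps))
    coeffs = dct(log_e, type=2, norm="ortho", axis=1)[:, :n_coeffs]
    return coeffs, coeffs.mean(axis=0)


# ---------------------------------------------------------------------------
# fractal dimension (Higuchi)
# ---------------------------------------------------------------------------

def fractal_dimension(x, k_max: int = 10) -> float:
    """Higuchi estimate of the curve-length scaling exponent.

    Mean normalized curve length L(k) is computed at lags k = 1..k_max; the
    slope of log L(k) against log(1/k) is the dimension.  Smooth curves give
    ~1, white noise ~2; constants return 1.0 (degenerate case).
    """
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if n < 10 * k_max:
        raise ValueError(f"need >= {10 * k_max} samples for k_max={k_max}")
    if np.var(x) < _VAR_EPS:
        return 1.0
    lengths = np.empty(k_max)
    for k in range(1, k_max + 1):
        lm = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((len(idx) - 1) * k)
            lm.append(dist * norm / k)
        lengths[k - 1] = np.mean(lm)
    ks = np.arange(1, k_max + 1)
    slope = np.polyfit(np.log(1.0 / ks), np.log(np.maximum(lengths, 1e-300)), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# embedding dimension (false nearest neighbors)
# ---------------------------------------------------------------------------

def embedding_dimension(x, max_dim: int = 10, rtol: float = 15.0,
                        atol: float = 2.0, delay: int | None = None,
                        min_tsep: int | None = None,
                        threshold: float = 0.01) -> int:
    """Smallest dimension unfolding the series, by false nearest neighbors.

    At each dimension d the nearest neighbor of every delay vector (outside
    a temporal exclusion window) is tested with Kennel's two criteria: the
    extra-coordinate jump relative to the current distance (``rtol``) and
    the resulting distance relative to the series spread (``atol``).  The
    first d where the false fraction drops below ``threshold`` is returned;
    stochastic series never unfold and return ``max_dim``.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if n < 100:
        raise ValueError(f"need >= 100 samples, got {n}")
    sigma = float(np.std(x))
    if sigma ** 2 < _VAR_EPS:
        return 1
    if delay is None:
        delay = autocorr_delay(x)
    if min_tsep is None:
        min_tsep = mean_period(x)
    for d in range(1, max_dim + 1):
        m = n - d * delay
        if m < 10:
            return d
        Yd = embed_timeseries(x, d, delay)[:m]
        dists = cdist(Yd, Yd)
        idx = np.arange(m)
        dists[np.abs(idx[:, None] - idx[None, :]) <= min_tsep] = np.inf
        nn = np.argmin(dists, axis=1)
        ok = np.isfinite(dists[idx, nn])
        r_d = dists[idx, nn][ok]
        extra = np.abs(x[idx[ok] + d * delay] - x[nn[ok] + d * delay])
        # the ratio test is meaningless for distances at machine precision
        # (exact repeats of a periodic signal): such pairs are true neighbors
        floor = 1e-8 * sigma
        with np.errstate(divide="ignore", invalid="ignore"):
            crit1 = (r_d > floor) & (extra / np.maximum(r_d, 1e-300) > rtol)
        crit2 = np.sqrt(r_d ** 2 + extra ** 2) / sigma > atol
        frac = float(np.mean(crit1 | crit2)) if ok.sum() else 1.0
        if frac < threshold:
            return d
    return max_dim


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------

def skewness(x) -> float:
    """Standardized third moment; 0 for degenerate (constant) input."""
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < 3 or np.var(x) < _VAR_EPS:
        return 0.0
    return float(stats.skew(x, bias=True))


def kurtosis(x) -> float:
    """Excess kurtosis (Gaussian -> 0); 0 for degenerate input."""
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < 3 or np.var(x) < _VAR_EPS:
        return 0.0
    return float(stats.kurtosis(x, fisher=True, bias=True))


# ---------------------------------------------------------------------------
# per-stack extraction
# ---------------------------------------------------------------------------

_IMU = ("acc", "gyr", "mag")
_AXES = ("x", "y", "z")


def _series_features(x: np.ndarray, x_weighted: np.ndarray, fs: float,
                     cfg: HarFeatureConfig) -> np.ndarray:
    """The 18 slots for one axis series: mle, 13 mfcc, fd, ed, skew, kurt."""
    out = np.zeros(5 + cfg.n_mfcc)
    if np.var(x) < _VAR_EPS:
        out[0] = 0.0                                    # mle (degenerate)
        _, mf = mfcc(x_weighted, fs, cfg.n_mfcc, cfg.n_filters,
                     cfg.frame_s, cfg.hop_s)
        out[1:1 + cfg.n_mfcc] = mf
        out[1 + cfg.n_mfcc] = 1.0                       # fd
        out[2 + cfg.n_mfcc] = 1.0                       # ed
        return out
    delay = autocorr_delay(x)
    tsep = mean_period(x)
    ed = embedding_dimension(x, max_dim=cfg.fnn_max_dim, rtol=cfg.fnn_rtol,
                             atol=cfg.fnn_atol, delay=delay, min_tsep=tsep)
    out[0] = max_lyapunov_exponent(x, emb_dim=max(2, ed), delay=delay,
                                   min_tsep=tsep, k_max=cfg.mle_k_max,
                                   fit_len=cfg.mle_fit_len)
    _, mf = mfcc(x_weighted, fs, cfg.n_mfcc, cfg.n_filters,
                 cfg.frame_s, cfg.hop_s)
    out[1:1 + cfg.n_mfcc] = mf
    out[1 + cfg.n_mfcc] = fractal_dimension(x, k_max=cfg.higuchi_k_max)
    out[2 + cfg.n_mfcc] = ed
    out[3 + cfg.n_mfcc] = skewness(x)
    out[4 + cfg.n_mfcc] = kurtosis(x)
    return np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)


def _series_layout(prefix: str, cfg: HarFeatureConfig) -> list[str]:
    names = [f"{prefix}.mle"]
    names += [f"{prefix}.mfcc{i:02d}" for i in range(cfg.n_mfcc)]
    names += [f"{prefix}.fd", f"{prefix}.ed", f"{prefix}.skew", f"{prefix}.kurt_excess"]
    return names


def extract_har_features(stack: WindowStack,
                         cfg: HarFeatureConfig | None = None) -> FeatureVector:
    """Activity feature vector for one stack (thin wrapper over the class)."""
    ext = HARFeatureExtractor(cfg=cfg)
    X = ext.fit_transform([stack])
    return FeatureVector(values=X[0], layout=list(ext.feature_names_),
                         stack_ref=stack.recording_id)


class HARFeatureExtractor:
    """Stateless transformer: list of :class:`WindowStack` -> feature matrix.

    Window-level features are cached by object identity during one
    ``transform`` call, so overlapping stacks (stride < stack size) pay for
    each window once.  sklearn-compatible (``fit``/``transform``/
    ``get_params``).
    """

    def __init__(self, cfg: HarFeatureConfig | None = None):
        self.cfg = cfg

    def get_params(self, deep: bool = True) -> dict:
        return {"cfg": self.cfg}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, stacks, y=None):
        return self

    def _window_vector(self, window, cfg: HarFeatureConfig) -> np.ndarray:
        missing = [c for c in _IMU if c not in window.samples]
        if missing:
            raise ValueError(f"activity bank requires channels {_IMU}; "
                             f"missing {missing}")
        parts = []
        for ch in _IMU:
            raw = window.samples[ch]
            weighted = window.weighted(ch)
            for ax in range(raw.shape[0]):
                parts.append(_series_features(raw[ax], weighted[ax],
                                              window.fs, cfg))
        return np.concatenate(parts)

    def transform(self, stacks) -> np.ndarray:
        cfg = self.cfg or HarFeatureConfig()
        cache: dict[int, np.ndarray] = {}
        rows = []
        for stack in stacks:
            if cfg.per_window:
                parts = []
                for w in stack.windows:
                    key = id(w)
                    if key not in cache:
                        cache[key] = self._window_vector(w, cfg)
                    parts.append(cache[key])
                rows.append(np.concatenate(parts))
            else:
                merged = _merge_stack(stack)
                rows.append(self._window_vector(merged, cfg))
        self.feature_names_ = self._layout(stacks[0] if stacks else None, cfg)
        X = np.asarray(rows, dtype=float)
        if X.size and not np.all(np.isfinite(X)):
            logger.warning("non-finite activity features zeroed")
            X = np.nan_to_num(X, nan=0.0, posinf=0.0, neginf=0.0)
        return X

    def fit_transform(self, stacks, y=None) -> np.ndarray:
        return self.fit(stacks, y).transform(stacks)

    def _layout(self, stack, cfg: HarFeatureConfig) -> list[str]:
        n_windows = len(stack.windows) if (stack and cfg.per_window) else 1
        names = []
        for w in range(n_windows):
            prefix_w = f"w{w}" if cfg.per_window else "stack"
            for ch in _IMU:
                for ax in _AXES:
                    names += _series_layout(f"{prefix_w}.{ch}.{ax}", cfg)
        return names

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)


def _merge_stack(stack: WindowStack):
    """A pseudo-window holding the stack's concatenated samples."""
    from .preprocessing import Window
    samples = {ch: stack.concat(ch) for ch in stack.windows[0].samples}
    return Window(start_s=stack.start_s, samples=samples,
                  fs=stack.windows[0].fs, index=-1)
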