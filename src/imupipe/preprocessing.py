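"""Denoising, windowing and window stacking.

Each channel is low-pass filtered with a zero-phase second-order Butterworth
filter, cut into non-overlapping 5-second windows, and three consecutive
windows are stacked into the unit that both feature banks consume.  The
Hamming taper is applied to *copies* of the samples used by spectral
features; time-domain features (step peaks, heading) read the raw samples,
since tapering would distort peak amplitudes near window edges.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .sensor_io import IMU_CHANNELS, MultiSensorRecording

__all__ = [
    "Window",
    "WindowStack",
    "butterworth_denoise",
    "butterworth_gain",
    "hamming_weight",
    "hamming_window",
    "segment_windows",
    "stack_windows",
    "denoise_recording",
]

logger = logging.getLogger(__name__)


def butterworth_denoise(x, order: int = 2, cutoff: float = 0.001,
                        fs: float | None = None) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter.

    ``cutoff`` is a normalized frequency (fraction of Nyquist, in (0, 1))
    unless ``fs`` is given, in which case it is in Hz.  The filter is applied
    forward and backward (``sosfiltfilt``), so the effective magnitude
    response is the squared single-pass response and the phase is zero.
    DC gain is 1: constants pass through unchanged.
    """
    x = np.asarray(x, dtype=float)
    wn = cutoff if fs is None else cutoff / (fs / 2.0)
    if not 0.0 < wn < 1.0:
        raise ValueError(f"cutoff {cutoff} maps to normalized {wn}, outside (0, 1)")
    if x.shape[-1] < 3 * order:
        raise ValueError(f"need at least {3 * order} samples, got {x.shape[-1]}")
    sos = signal.butter(order, wn, btype="low", output="sos")
    padlen = min(3 * (2 * order + 1), x.shape[-1] - 1)
    return signal.sosfiltfilt(sos, x, axis=-1, padlen=padlen)


def butterworth_gain(f: np.ndarray, cutoff: float, order: int = 2,
                     passes: int = 2) -> np.ndarray:
    """Analytic magnitude response of the digital Butterworth low-pass.

    Frequencies are normalized (fraction of Nyquist).  The bilinear design
    places the half-power point exactly at ``cutoff``; a forward-backward
    application squares the response (``passes=2``).
    """
    f = np.asarray(f, dtype=float)
    ratio = np.tan(np.pi * f / 2.0) / np.tan(np.pi * cutoff / 2.0)
    return (1.0 / np.sqrt(1.0 + ratio ** (2 * order))) ** passes


def hamming_weight(n: int, N: int) -> float:
    """Hamming taper value ``0.54 - 0.46 cos(2 pi n / (N-1))`` at index n.

    Evaluated at ``min(n, N-1-n)`` — identical by cosine symmetry — so the
    taper is bitwise symmetric despite floating-point rounding.
    """
    if N < 2:
        raise ValueError("window length must be >= 2")
    if not 0 <= n < N:
        raise IndexError(f"index {n} outside window of length {N}")
    m = min(n, N - 1 - n)
    return 0.54 - 0.46 * np.cos(2.0 * np.pi * m / (N - 1))


def hamming_window(N: int) -> np.ndarray:
    """Vector of :func:`hamming_weight` over a full window."""
    m = np.minimum(np.arange(N), N - 1 - np.arange(N))
    return 0.54 - 0.46 * np.cos(2.0 * np.pi * m / (N - 1))


@dataclass
class Window:
    """One 5-s cut of every channel; ``samples[ch]`` is (n_axes, N)."""

    start_s: float
    samples: dict[str, np.ndarray]
    fs: float
    index: int = 0

    @property
    def n_samples(self) -> int:
        return next(iter(self.samples.values())).shape[1]

    def weighted(self, channel: str) -> np.ndarray:
        """Hamming-tapered copy of one channel (for spectral features)."""
        x = self.samples[channel]
        return x * hamming_window(x.shape[1])


@dataclass
class WindowStack:
    """Three consecutive windows plus the labels they inherit."""

    windows: list[Window]
    activity_label: str | None = None
    location_label: str | None = None
    recording_id: str = ""
    audio: np.ndarray | None = None      # raw audio covering the stack span
    audio_fs: float | None = None
    gps: np.ndarray | None = None        # (2, n) lat/lon over the stack span
    gps_t: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        starts = [w.start_s for w in self.windows]
        if sorted(starts) != starts:
            raise ValueError("stack windows must be time-ordered")

    @property
    def start_s(self) -> float:
        return self.windows[0].start_s

    @property
    def duration_s(self) -> float:
        w = self.windows[-1]
        return w.start_s + w.n_samples / w.fs - self.start_s

    def concat(self, channel: str) -> np.ndarray:
        """Channel samples concatenated across the stack, untapered."""
        return np.concatenate([w.samples[channel] for w in self.windows], axis=1)

    def concat_weighted(self, channel: str) -> np.ndarray:
        return np.concatenate([w.weighted(channel) for w in self.windows], axis=1)


def denoise_recording(rec: MultiSensorRecording, order: int = 2,
                      cutoff: float = 10.0, cutoff_units: str = "hz",
                      channels: tuple = IMU_CHANNELS) -> MultiSensorRecording:
    """Apply :func:`butterworth_denoise` to each IMU channel of a recording."""
    from dataclasses import replace
    new = dict(rec.channels)
    for name in channels:
        if name not in new:
            continue
        ch = new[name]
        fs = ch.rate_hz if cutoff_units == "hz" else None
        new[name] = replace(ch, axes=butterworth_denoise(ch.axes, order, cutoff, fs=fs))
    return replace(rec, channels=new)


def segment_windows(rec: MultiSensorRecording, window_s: float = 5.0) -> list[Window]:
    """Cut a resampled recording into non-overlapping ``window_s`` windows.

    Returns ``floor(duration / window_s)`` windows; a short tail is dropped.
    A recording shorter than one window yields an empty list with a warning.
    """
    if rec.fs is None:
        raise ValueError("recording must be aligned/resampled before windowing")
    fs = rec.fs
    N = int(round(window_s * fs))
    imu = [n for n in IMU_CHANNELS if n in rec.channels]
    n_total = min(rec.channels[n].n_samples for n in imu)
    n_windows = n_total // N
    if n_windows == 0:
        warnings.warn("recording shorter than one window; no windows produced")
        return []
    windows = []
    for k in range(n_windows):
        sl = slice(k * N, (k + 1) * N)
        samples = {n: rec.channels[n].axes[:, sl].copy() for n in imu}
        windows.append(Window(start_s=k * window_s, samples=samples, fs=fs, index=k))
    return windows


def stack_windows(windows: list[Window], size: int = 3, stride: int = 1,
                  rec: MultiSensorRecording | None = None) -> list[WindowStack]:
    """Slide a ``size``-window stack over the window list at ``stride``.

    When ``rec`` is given its labels are inherited and any audio/GPS channel
    is sliced to each stack's time span.
    """
    if len(windows) < size:
        warnings.warn(f"only {len(windows)} windows; need {size} for a stack")
        return []
    stacks = []
    for start in range(0, len(windows) - size + 1, stride):
        group = windows[start:start + size]
        st = WindowStack(windows=list(group))
        if rec is not None:
            st.activity_label = rec.activity_label
            st.location_label = rec.location_label
            st.recording_id = rec.subject_id
            t0, t1 = st.start_s, st.start_s + st.duration_s
            if "audio" in rec.channels:
                ch = rec.channels["audio"]
                m = (ch.timestamps >= t0) & (ch.timestamps < t1)
                st.audio = ch.axes[0, m]
                st.audio_fs = ch.rate_hz
            if "gps" in rec.channels:
                ch = rec.channels["gps"]
                m = (ch.timestamps >= t0) & (ch.timestamps < t1)
                st.gps = ch.axes[:, m]
                st.gps_t = ch.timestamps[m]
        stacks.append(st)
    return stacks
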