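"""Localization feature bank: steps, heading, audio cepstra.

The inertial part is a pedestrian-dead-reckoning front end: detect step
peaks in the acceleration magnitude, time the valley-to-valley interval of
each step, and fuse a magnetometer compass heading with a gyroscope
heading propagated through a unit quaternion.  Audio context (when a
microphone channel is present) contributes MFCC frame means.

Angle conventions: ENU-style yaw, positive counterclockwise, 0 = magnetic
north along the device +x axis when the device is level; all headings are
wrapped to (-pi, pi].  ``atan2`` is used wherever a bare arctangent would
lose the quadrant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .har_features import FeatureVector, mfcc
from .preprocessing import WindowStack

__all__ = [
    "StepEvents",
    "EulerAngles",
    "HeadingState",
    "LocFeatureConfig",
    "acceleration_magnitude",
    "detect_steps",
    "estimate_step_intervals",
    "euler_angles",
    "magnetometer_heading",
    "gyroscope_heading_step",
    "fuse_heading",
    "heading_track",
    "wrap_angle",
    "extract_loc_features",
    "LOCFeatureExtractor",
]

logger = logging.getLogger(__name__)


def wrap_angle(a):
    """Wrap angle(s) to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    out = -((-a + np.pi) % (2.0 * np.pi) - np.pi)
    return float(out) if out.ndim == 0 else out


@dataclass
class StepEvents:
    """Detected step peaks with flanking valleys and their time intervals."""

    peak_indices: np.ndarray
    threshold: float
    valley_pairs: list[tuple[int | None, int | None]] = field(default_factory=list)
    step_intervals_s: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_steps(self) -> int:
        return len(self.peak_indices)


@dataclass
class EulerAngles:
    roll: float
    pitch: float
    yaw: float


@dataclass
class HeadingState:
    """Orientation quaternion plus the three heading readings at time t."""

    q: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))
    h_mag: float = 0.0
    h_gyro: float = 0.0
    h_fused: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        n = np.linalg.norm(self.q)
        if abs(n - 1.0) > 1e-6:
            raise ValueError(f"quaternion norm {n} deviates from 1")


@dataclass
class LocFeatureConfig:
    min_separation_s: float = 0.25
    threshold_mode: str = "abs_mean"      # abs_mean | zero | quantile
    threshold_quantile: float = 0.75
    audio_n_mfcc: int = 13
    audio_n_filters: int = 26
    audio_frame_s: float = 0.025
    audio_hop_s: float = 0.010


# ---------------------------------------------------------------------------
# steps
# ---------------------------------------------------------------------------

def acceleration_magnitude(acc: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of a (3, n) tri-axial window."""
    acc = np.asarray(acc, dtype=float)
    if acc.ndim != 2 or acc.shape[0] != 3:
        raise ValueError(f"expected (3, n) tri-axial array, got {acc.shape}")
    return np.sqrt((acc ** 2).sum(axis=0))


def detect_steps(magnitude: np.ndarray, fs: float,
                 min_separation_s: float = 0.25,
                 threshold_mode: str = "abs_mean",
                 threshold_quantile: float = 0.75,
                 rest_ratio: float = 0.02) -> StepEvents:
    """Step peaks in the gravity-free ("net") acceleration magnitude.

    The magnitude mean is subtracted (removing the gravity offset); peaks of
    the net signal exceeding the threshold are steps.  The default threshold
    is ``mean(|net|)`` — the literal mean of the net signal is identically
    zero by construction.  Peaks closer than ``min_separation_s`` keep only
    the larger one.

    A rest gate suppresses detection when the dynamic component is below
    ``rest_ratio`` of the static magnitude (``mean(|net|)/mean(magnitude)``):
    a stationary subject's sensor noise otherwise produces spurious
    supra-threshold peaks.  Both the gate and the threshold are ratios of
    the signal to itself, so detection is invariant to positive amplitude
    scaling.
    """
    magnitude = np.asarray(magnitude, dtype=float).ravel()
    if len(magnitude) < fs:
        raise ValueError("need at least one second of signal")
    net = magnitude - magnitude.mean()
    if threshold_mode == "abs_mean":
        thr = float(np.mean(np.abs(net)))
    elif threshold_mode == "zero":
        thr = 0.0
    elif threshold_mode == "quantile":
        thr = float(np.quantile(net, threshold_quantile))
    else:
        raise ValueError(f"unknown threshold mode {threshold_mode!r}")
    static = float(np.mean(np.abs(magnitude)))
    at_rest = static > 0 and float(np.mean(np.abs(net))) / static < rest_ratio
    if np.ptp(net) == 0.0 or at_rest:
        return StepEvents(peak_indices=np.array([], dtype=int), threshold=thr)
    distance = max(1, int(round(min_separation_s * fs)))
    peaks, _ = sps.find_peaks(net, height=thr if thr > 0 else None,
                              distance=distance)
    if thr <= 0:
        peaks = peaks[net[peaks] > thr]
    return StepEvents(peak_indices=peaks, threshold=thr)


def estimate_step_intervals(magnitude: np.ndarray, events: StepEvents,
                            fs: float) -> StepEvents:
    """Fill valley pairs and valley-to-valley intervals for each peak.

    The nearest local minimum on each side of a peak is its valley; the
    interval is the valley timestamp difference in seconds.  A peak with no
    valley on one side (sequence boundary) gets an absent (NaN) interval.
    """
    magnitude = np.asarray(magnitude, dtype=float).ravel()
    net = magnitude - magnitude.mean()
    interior = np.arange(1, len(net) - 1)
    is_min = (net[interior] <= net[interior - 1]) & (net[interior] <= net[interior + 1])
    minima = interior[is_min]
    pairs: list[tuple[int | None, int | None]] = []
    intervals = []
    for p in events.peak_indices:
        left_c = minima[minima < p]
        right_c = minima[minima > p]
        left = int(left_c[-1]) if left_c.size else None
        right = int(right_c[0]) if right_c.size else None
        pairs.append((left, right))
        if left is None or right is None:
            intervals.append(np.nan)
        else:
            intervals.append((right - left) / fs)
    events.valley_pairs = pairs
    events.step_intervals_s = np.asarray(intervals, dtype=float)
    return events


# ---------------------------------------------------------------------------
# attitude and heading
# ---------------------------------------------------------------------------

def euler_angles(acc, mag) -> EulerAngles:
    """Roll/pitch from the gravity vector, yaw from the tilt-compensated
    magnetometer: roll = atan2(ay, az), pitch = atan2(-ax, sqrt(ay^2+az^2)),
    yaw = atan2(M_y, M_x) of the leveled field components."""
    ax, ay, az = (float(v) for v in acc)
    if ax == 0.0 and ay == 0.0 and az == 0.0:
        raise ValueError("zero acceleration vector: attitude undefined")
    mx, my, mz = (float(v) for v in mag)
    roll = np.arctan2(ay, az)
    pitch = np.arctan2(-ax, np.hypot(ay, az))
    sr, cr = np.sin(roll), np.cos(roll)
    sp, cp = np.sin(pitch), np.cos(pitch)
    m_y = mx * sr * sp + my * cr - mz * sr * cp
    m_x = mx * cp + mz * sp
    yaw = np.arctan2(m_y, m_x)
    return EulerAngles(roll=float(roll), pitch=float(pitch), yaw=float(yaw))


def _tilt_rotation(roll: float, pitch: float) -> np.ndarray:
    """Rotation taking device-frame vectors into the earth-horizontal frame."""
    sr, cr = np.sin(roll), np.cos(roll)
    sp, cp = np.sin(pitch), np.cos(pitch)
    return np.array([
        [cr, sr * sp, -sr * cp],
        [0.0, cp, sp],
        [sr, -sp * cr, cr * cp],
    ])


def magnetometer_heading(e: EulerAngles, mag) -> float:
    """Compass heading: rotate the field into the horizontal frame, then
    take atan2 of its horizontal components, wrapped to (-pi, pi].

    The rotation yields a 3-vector; the scalar heading is the angle of its
    horizontal projection (standard tilt-compensated compass).
    """
    v = _tilt_rotation(e.roll, e.pitch) @ np.asarray(mag, dtype=float)
    if np.hypot(v[0], v[1]) < 1e-12:
        raise ValueError("zero horizontal field after rotation: heading undefined")
    return float(wrap_angle(np.arctan2(v[1], v[0])))


def _quat_multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    p0, p1, p2, p3 = p
    q0, q1, q2, q3 = q
    return np.array([
        p0 * q0 - p1 * q1 - p2 * q2 - p3 * q3,
        p0 * q1 + p1 * q0 + p2 * q3 - p3 * q2,
        p0 * q2 - p1 * q3 + p2 * q0 + p3 * q1,
        p0 * q3 + p1 * q2 - p2 * q1 + p3 * q0,
    ])


def _euler_rates(gyr, roll: float, pitch: float) -> tuple[float, float, float]:
    """Body angular rates -> Euler angle rates (roll*, pitch*, yaw*)."""
    gx, gy, gz = (float(v) for v in gyr)
    sr, cr = np.sin(roll), np.cos(roll)
    tp = np.tan(pitch)
    cp = np.cos(pitch)
    roll_rate = gx + gy * sr * tp + gz * cr * tp
    pitch_rate = gy * cr - gz * sr
    yaw_rate = gy * sr / cp + gz * cr / cp
    return roll_rate, pitch_rate, yaw_rate


def _euler_to_quat(roll: float, pitch: float, yaw: float) -> np.ndarray:
    cr, sr = np.cos(roll / 2), np.sin(roll / 2)
    cp, sp = np.cos(pitch / 2), np.sin(pitch / 2)
    cy, sy = np.cos(yaw / 2), np.sin(yaw / 2)
    return np.array([
        cr * cp * cy + sr * sp * sy,
        sr * cp * cy - cr * sp * sy,
        cr * sp * cy + sr * cp * sy,
        cr * cp * sy - sr * sp * cy,
    ])


def quat_yaw(q: np.ndarray) -> float:
    """Yaw of a unit quaternion: atan2(2(q0 q3 + q1 q2), 1 - 2(q2^2 + q3^2))."""
    gx = 2.0 * (q[0] * q[3] + q[1] * q[2])
    gy = 1.0 - 2.0 * (q[2] ** 2 + q[3] ** 2)
    return float(np.arctan2(gx, gy))


def gyroscope_heading_step(state: HeadingState, gyr, e: EulerAngles,
                           dt: float) -> HeadingState:
    """Advance the gyro-quaternion by one sample and read off the heading.

    Body rates are mapped to Euler rates using the accelerometer-derived
    roll/pitch, converted over ``dt`` to an incremental rotation quaternion,
    composed with the running orientation (re-normalized each step), and the
    heading is the quaternion yaw via atan2 — a bare ratio of the yaw
    components would lose the quadrant and diverge at 90 degrees.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = np.linalg.norm(state.q)
    if abs(n - 1.0) > 1e-6:
        raise ValueError(f"input quaternion norm {n} deviates from 1")
    rr, pr, yr = _euler_rates(gyr, e.roll, e.pitch)
    dq = _euler_to_quat(rr * dt, pr * dt, yr * dt)
    q = _quat_multiply(state.q, dq)
    q /= np.linalg.norm(q)
    h = quat_yaw(q)
    return HeadingState(q=q, h_mag=state.h_mag, h_gyro=h,
                        h_fused=state.h_fused, t=state.t + dt)


def fuse_heading(h_mag: float, h_gyro: float) -> float:
    """Circular mean of the two headings; falls back to the gyro heading
    when the inputs are antipodal (mean direction undefined)."""
    s = np.sin(h_mag) + np.sin(h_gyro)
    c = np.cos(h_mag) + np.cos(h_gyro)
    if np.hypot(s, c) < 1e-9:
        logger.warning("antipodal headings: falling back to gyro heading")
        return float(wrap_angle(h_gyro))
    return float(wrap_angle(np.arctan2(s, c)))


def heading_track(acc: np.ndarray, gyr: np.ndarray, mag: np.ndarray,
                  fs: float, q0: np.ndarray | None = None,
                  attitude_lowpass_hz: float | None = 0.5) -> dict[str, np.ndarray]:
    """Per-sample magnetometer, gyroscope and fused headings for a stack.

    The gyro quaternion is seeded from the first-sample Euler attitude
    unless ``q0`` is given, so the two heading sources start aligned.

    Gravity and the earth field are quasi-static, while the accelerometer
    also sees gait linear acceleration; feeding that into the tilt estimate
    rectifies into a yaw-dependent compass bias.  The accelerometer and
    magnetometer are therefore low-passed (zero-phase Butterworth at
    ``attitude_lowpass_hz``) before the Euler/compass computation; the gyro
    integration consumes the raw rates.  Pass ``None`` to disable.
    """
    acc = np.asarray(acc, dtype=float)
    gyr = np.asarray(gyr, dtype=float)
    mag = np.asarray(mag, dtype=float)
    if attitude_lowpass_hz is not None and acc.shape[1] > 12:
        from .preprocessing import butterworth_denoise
        acc = butterworth_denoise(acc, order=2, cutoff=attitude_lowpass_hz, fs=fs)
        mag = butterworth_denoise(mag, order=2, cutoff=attitude_lowpass_hz, fs=fs)
    n = acc.shape[1]
    dt = 1.0 / fs
    h_m = np.empty(n)
    h_g = np.empty(n)
    h_f = np.empty(n)
    e0 = euler_angles(acc[:, 0], mag[:, 0])
    state = HeadingState(q=q0 if q0 is not None
                         else _euler_to_quat(e0.roll, e0.pitch, e0.yaw))
    for i in range(n):
        e = euler_angles(acc[:, i], mag[:, i])
        try:
            h_m[i] = magnetometer_heading(e, mag[:, i])
        except ValueError:
            h_m[i] = h_m[i - 1] if i else 0.0
        if i:
            state = gyroscope_heading_step(state, gyr[:, i - 1], e, dt)
        h_g[i] = quat_yaw(state.q)
        h_f[i] = fuse_heading(h_m[i], h_g[i])
    return {"h_mag": h_m, "h_gyro": h_g, "h_fused": h_f, "q": state.q}


def _circular_mean_std(angles: np.ndarray) -> tuple[float, float]:
    s, c = np.sin(angles).mean(), np.cos(angles).mean()
    r = min(1.0, float(np.hypot(s, c)))
    mean = float(np.arctan2(s, c))
    std = float(np.sqrt(max(0.0, -2.0 * np.log(max(r, 1e-300)))))
    return mean, std


# ---------------------------------------------------------------------------
# per-stack extraction
# ---------------------------------------------------------------------------

def extract_loc_features(stack: WindowStack,
                         cfg: LocFeatureConfig | None = None) -> FeatureVector:
    """Localization feature vector for one stack (wrapper over the class)."""
    ext = LOCFeatureExtractor(cfg=cfg)
    X = ext.fit_transform([stack])
    return FeatureVector(values=X[0], layout=list(ext.feature_names_),
                         stack_ref=stack.recording_id)


class LOCFeatureExtractor:
    """Transformer: list of :class:`WindowStack` -> localization features.

    Slots: step count, step-interval mean/std, fused-heading circular
    mean/std and net change, audio MFCC frame means + absence flag, and a
    coarse GPS availability/speed summary.  Steps and headings read the
    untapered samples.
    """

    def __init__(self, cfg: LocFeatureConfig | None = None):
        self.cfg = cfg

    def get_params(self, deep: bool = True) -> dict:
        return {"cfg": self.cfg}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, stacks, y=None):
        return self

    def transform(self, stacks) -> np.ndarray:
        cfg = self.cfg or LocFeatureConfig()
        rows = [self._stack_vector(s, cfg) for s in stacks]
        self.feature_names_ = self._layout(cfg)
        X = np.asarray(rows, dtype=float)
        if X.size and not np.all(np.isfinite(X)):
            logger.warning("non-finite localization features zeroed")
            X = np.nan_to_num(X, nan=0.0, posinf=0.0, neginf=0.0)
        return X

    def fit_transform(self, stacks, y=None) -> np.ndarray:
        return self.fit(stacks, y).transform(stacks)

    def _stack_vector(self, stack: WindowStack, cfg: LocFeatureConfig) -> np.ndarray:
        for ch in ("acc", "gyr", "mag"):
            if ch not in stack.windows[0].samples:
                raise ValueError(f"localization bank requires channel {ch!r}")
        fs = stack.windows[0].fs
        acc = stack.concat("acc")
        gyr = stack.concat("gyr")
        mag = stack.concat("mag")
        magnitude = acceleration_magnitude(acc)
        events = detect_steps(magnitude, fs, cfg.min_separation_s,
                              cfg.threshold_mode, cfg.threshold_quantile)
        events = estimate_step_intervals(magnitude, events, fs)
        iv = events.step_intervals_s
        iv = iv[np.isfinite(iv)]
        step_feats = [float(events.n_steps),
                      float(iv.mean()) if iv.size else 0.0,
                      float(iv.std()) if iv.size else 0.0]

        track = heading_track(acc, gyr, mag, fs)
        hmean, hstd = _circular_mean_std(track["h_fused"])
        unwrapped = np.unwrap(track["h_fused"])
        # net change between 1-s endpoint means: single-sample endpoints
        # carry sensor noise and filter edge transients
        k = max(1, min(int(fs), len(unwrapped) // 4))
        net = float(unwrapped[-k:].mean() - unwrapped[:k].mean())
        heading_feats = [hmean, hstd, net]

        if stack.audio is not None and stack.audio.size >= int(
                round(cfg.audio_frame_s * (stack.audio_fs or 1))):
            _, mf = mfcc(stack.audio, stack.audio_fs, cfg.audio_n_mfcc,
                         cfg.audio_n_filters, cfg.audio_frame_s, cfg.audio_hop_s)
            audio_feats = list(mf) + [1.0]
        else:
            audio_feats = [0.0] * cfg.audio_n_mfcc + [0.0]

        if stack.gps is not None and stack.gps.shape[1] >= 2:
            lat, lon = stack.gps
            t = stack.gps_t
            # local equirectangular projection; 1 deg lat ~ 111.32 km
            y = (lat - lat[0]) * 111320.0
            x = (lon - lon[0]) * 111320.0 * np.cos(np.deg2rad(lat[0]))
            d = np.hypot(np.diff(x), np.diff(y))
            dt = np.diff(t)
            speed = float(np.mean(d[dt > 0] / dt[dt > 0])) if np.any(dt > 0) else 0.0
            gps_feats = [1.0, speed]
        else:
            gps_feats = [0.0, 0.0]

        return np.asarray(step_feats + heading_feats + audio_feats + gps_feats)

    def _layout(self, cfg: LocFeatureConfig) -> list[str]:
        names = ["steps.count", "steps.interval_mean_s", "steps.interval_std_s",
                 "heading.circ_mean", "heading.circ_std", "heading.net_change"]
        names += [f"audio.mfcc{i:02d}" for i in range(cfg.audio_n_mfcc)]
        names += ["audio.present", "gps.available", "gps.speed_mean"]
        return names

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
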