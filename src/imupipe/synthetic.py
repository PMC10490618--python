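"""Labeled multi-sensor scenario generator.

Produces physically coherent recordings for pipeline testing without any
dataset download: gravity plus an activity-specific gait sinusoid on the
accelerometer, a piecewise-constant yaw-rate schedule on the gyroscope, an
earth magnetic field rotated by the integrated heading on the magnetometer
(so the compass and gyro pipelines see the same truth), a location-specific
audio spectrum, and an optional GPS track integrated from heading and
speed.  All randomness flows from one seed through ``numpy.SeedSequence``.

It is not a biomechanical gait simulator and makes no attempt to mimic the
noise statistics of real in-the-wild corpora; what it guarantees is that
the ground truth it knows (step count, net heading change, class identity)
is recoverable by the corresponding pipeline stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .sensor_io import MultiSensorRecording, RawChannel

__all__ = [
    "ScenarioSpec",
    "ACTIVITY_PRESETS",
    "LOCATION_PRESETS",
    "generate_recording",
    "generate_dataset",
    "generate_corpus",
    "class_separation",
]

GRAVITY = 9.81          # m/s^2, along device z when level
B_HORIZONTAL = 22.0     # uT, horizontal earth-field component
B_VERTICAL = -42.0      # uT, vertical component (northern mid-latitudes)

# Activity signatures: gait rate/amplitude in the physiological range for
# each activity; non-gait activities get a low-frequency postural sway
# (sitting) or a broadband postural tremor (standing) so the spectral
# features can tell them apart.
ACTIVITY_PRESETS: dict[str, dict] = {
    "sitting": dict(step_rate_hz=0.0, acc_amplitude=0.0, sway_hz=0.3,
                    sway_amplitude=0.12, tremor_amplitude=0.0, noise_sd=0.03),
    "standing": dict(step_rate_hz=0.0, acc_amplitude=0.0, sway_hz=0.0,
                     sway_amplitude=0.0, tremor_amplitude=0.10, noise_sd=0.05),
    "walking": dict(step_rate_hz=2.0, acc_amplitude=1.5, sway_hz=0.0,
                    sway_amplitude=0.0, tremor_amplitude=0.0, noise_sd=0.10),
    "running": dict(step_rate_hz=2.8, acc_amplitude=4.0, sway_hz=0.0,
                    sway_amplitude=0.0, tremor_amplitude=0.0, noise_sd=0.15),
}

# Location signatures: audio spectral shape (context sounds), GPS
# availability and ground speed.
LOCATION_PRESETS: dict[str, dict] = {
    "home": dict(audio_profile="pink", audio_level=0.10, gps=False, speed_ms=0.0),
    "office": dict(audio_profile="white", audio_level=0.04, gps=False, speed_ms=0.0),
    "street": dict(audio_profile="band_high", audio_level=0.12, gps=True,
                   speed_ms=1.4),
    "vehicle": dict(audio_profile="band_low", audio_level=0.15, gps=True,
                    speed_ms=15.0),
}


@dataclass
class ScenarioSpec:
    """Everything needed to synthesize one labeled recording."""

    activity: str = "walking"
    location: str = "home"
    duration_s: float = 30.0
    fs: float = 40.0
    audio_fs: float = 2000.0
    step_rate_hz: float | None = None       # None -> activity preset
    acc_amplitude: float | None = None
    noise_sd: float | None = None
    mag_noise_sd: float = 0.3
    gyr_noise_sd: float = 0.02
    heading_profile: list[tuple[float, float]] = field(default_factory=list)
    heading_start: float = 0.0
    audio_profile: str | None = None        # None -> location preset
    subject_id: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITY_PRESETS:
            raise ValueError(f"unknown activity {self.activity!r}; "
                             f"known: {sorted(ACTIVITY_PRESETS)}")
        if self.location not in LOCATION_PRESETS:
            raise ValueError(f"unknown location {self.location!r}; "
                             f"known: {sorted(LOCATION_PRESETS)}")
        if self.duration_s < 15.0:
            raise ValueError("duration must cover at least one 3-window stack "
                             "(15 s)")
        rate = self.step_rate_hz
        if rate is None:
            rate = ACTIVITY_PRESETS[self.activity]["step_rate_hz"]
        if not 0.0 <= rate <= 4.0:
            raise ValueError("step rate outside the physiological [0, 4] Hz")


def _shaped_noise(rng, n: int, fs: float, profile: str, level: float) -> np.ndarray:
    white = rng.standard_normal(n)
    if profile == "white":
        out = white
    elif profile == "pink":
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, d=1.0 / fs)
        f[0] = f[1] if n > 1 else 1.0
        out = np.fft.irfft(spec / np.sqrt(f), n=n)
    elif profile == "band_high":
        sos = sps.butter(4, [400.0, 900.0], btype="band", fs=fs, output="sos")
        out = sps.sosfilt(sos, white)
    elif profile == "band_low":
        sos = sps.butter(4, [50.0, 200.0], btype="band", fs=fs, output="sos")
        out = sps.sosfilt(sos, white)
    else:
        raise ValueError(f"unknown audio profile {profile!r}")
    sd = out.std()
    return level * out / (sd if sd > 0 else 1.0)


def _heading_series(spec: ScenarioSpec, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(yaw_rate, yaw) over the recording from the piecewise schedule."""
    rate = np.zeros_like(t)
    if spec.heading_profile:
        t0 = 0.0
        for seg_dur, seg_rate in spec.heading_profile:
            rate[(t >= t0) & (t < t0 + seg_dur)] = seg_rate
            t0 += seg_dur
    yaw = spec.heading_start + np.concatenate(
        [[0.0], np.cumsum(rate[:-1]) / spec.fs])
    return rate, yaw


def generate_recording(spec: ScenarioSpec) -> MultiSensorRecording:
    """Synthesize one recording; same seed gives a bitwise-identical result."""
    act = ACTIVITY_PRESETS[spec.activity]
    loc = LOCATION_PRESETS[spec.location]
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs

    step_rate = act["step_rate_hz"] if spec.step_rate_hz is None else spec.step_rate_hz
    amp = act["acc_amplitude"] if spec.acc_amplitude is None else spec.acc_amplitude
    noise_sd = act["noise_sd"] if spec.noise_sd is None else spec.noise_sd

    yaw_rate, yaw = _heading_series(spec, t)

    acc = rng.normal(0.0, noise_sd, size=(3, n))
    acc[2] += GRAVITY
    if step_rate > 0:
        phase = rng.uniform(0, 2 * np.pi)
        gait = np.sin(2 * np.pi * step_rate * t + phase)
        acc[2] += amp * gait + 0.3 * amp * np.sin(4 * np.pi * step_rate * t + phase)
        acc[0] += 0.4 * amp * np.sin(2 * np.pi * step_rate * t + phase + 0.7)
        acc[1] += 0.4 * amp * np.cos(2 * np.pi * step_rate * t + phase + 1.3)
    if act["sway_amplitude"] > 0:
        acc[0] += act["sway_amplitude"] * np.sin(2 * np.pi * act["sway_hz"] * t)
        acc[1] += act["sway_amplitude"] * np.cos(2 * np.pi * act["sway_hz"] * t)
    if act["tremor_amplitude"] > 0:
        sos = sps.butter(2, [3.0, 8.0], btype="band", fs=fs, output="sos")
        for ax in range(3):
            tremor = sps.sosfilt(sos, rng.standard_normal(n))
            sd = tremor.std()
            acc[ax] += act["tremor_amplitude"] * tremor / (sd if sd > 0 else 1.0)

    gyr = rng.normal(0.0, spec.gyr_noise_sd, size=(3, n))
    gyr[2] += yaw_rate
    if step_rate > 0:
        gyr[0] += 0.05 * amp * np.sin(2 * np.pi * step_rate * t)
        gyr[1] += 0.05 * amp * np.cos(2 * np.pi * step_rate * t)

    mag = rng.normal(0.0, spec.mag_noise_sd, size=(3, n))
    mag[0] += B_HORIZONTAL * np.cos(yaw)
    mag[1] += B_HORIZONTAL * np.sin(yaw)
    mag[2] += B_VERTICAL

    channels = {
        "acc": RawChannel("acc", acc, t.copy(), fs),
        "gyr": RawChannel("gyr", gyr, t.copy(), fs),
        "mag": RawChannel("mag", mag, t.copy(), fs),
    }

    profile = spec.audio_profile or loc["audio_profile"]
    n_audio = int(round(spec.duration_s * spec.audio_fs))
    audio = _shaped_noise(rng, n_audio, spec.audio_fs, profile, loc["audio_level"])
    channels["audio"] = RawChannel(
        "audio", audio[None, :], np.arange(n_audio) / spec.audio_fs, spec.audio_fs)

    if loc["gps"]:
        gps_fs = 1.0
        n_gps = int(np.floor(spec.duration_s * gps_fs)) + 1
        tg = np.arange(n_gps) / gps_fs
        yaw_g = np.interp(tg, t, yaw)
        speed = loc["speed_ms"] * (1.0 + rng.normal(0, 0.05, n_gps))
        dx = np.concatenate([[0.0], np.cumsum(speed[:-1] * np.cos(yaw_g[:-1]))])
        dy = np.concatenate([[0.0], np.cumsum(speed[:-1] * np.sin(yaw_g[:-1]))])
        lat0, lon0 = 37.0, -122.0
        lat = lat0 + dy / 111320.0 + rng.normal(0, 2e-6, n_gps)
        lon = lon0 + dx / (111320.0 * np.cos(np.deg2rad(lat0))) \
            + rng.normal(0, 2e-6, n_gps)
        channels["gps"] = RawChannel("gps", np.vstack([lat, lon]), tg, gps_fs)

    return MultiSensorRecording(
        channels=channels, fs=fs, activity_label=spec.activity,
        location_label=spec.location, subject_id=spec.subject_id)


def generate_dataset(n_per_class: int, classes: list[ScenarioSpec],
                     seed: int | None = None,
                     jitter: float = 0.10) -> list[MultiSensorRecording]:
    """Balanced corpus: ``n_per_class`` recordings per template spec.

    Gait rate, amplitude and noise level are jittered uniformly by
    ``±jitter`` around each template; child seeds are spawned from ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not classes:
        raise ValueError("need at least one class template")
    ss = np.random.SeedSequence(seed)
    out = []
    for ci, template in enumerate(classes):
        act = ACTIVITY_PRESETS[template.activity]
        for k in range(n_per_class):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            def jit(v):
                return v * (1.0 + rng.uniform(-jitter, jitter))
            rate = template.step_rate_hz
            if rate is None:
                rate = act["step_rate_hz"]
            amp = template.acc_amplitude
            if amp is None:
                amp = act["acc_amplitude"]
            nsd = template.noise_sd
            if nsd is None:
                nsd = act["noise_sd"]
            spec = replace(
                template,
                step_rate_hz=jit(rate) if rate else rate,
                acc_amplitude=jit(amp) if amp else amp,
                noise_sd=jit(nsd),
                heading_start=rng.uniform(-np.pi, np.pi),
                subject_id=template.subject_id or f"c{ci}_r{k}",
                seed=int(child.generate_state(1)[0] % (2 ** 31)),
            )
            out.append(generate_recording(spec))
    return out


def generate_corpus(n_recordings: int = 100,
                    activities: tuple = ("sitting", "standing", "walking", "running"),
                    locations: tuple = ("home", "office", "street", "vehicle"),
                    duration_s: float = 30.0, seed: int | None = None,
                    jitter: float = 0.10) -> list[MultiSensorRecording]:
    """Jointly labeled corpus cycling through activity x location pairs."""
    pairs = [(a, l) for a in activities for l in locations]
    templates = []
    for i in range(n_recordings):
        a, l = pairs[i % len(pairs)]
        templates.append(ScenarioSpec(activity=a, location=l,
                                      duration_s=duration_s))
    ss = np.random.SeedSequence(seed)
    out = []
    for i, tpl in enumerate(templates):
        tpl = replace(tpl, subject_id=f"rec{i:03d}")
        out.extend(generate_dataset(1, [tpl], seed=int(ss.generate_state(1)[0]
                                                       % (2 ** 31)) + i,
                                    jitter=jitter))
    return out


def class_separation(X: np.ndarray, y: np.ndarray) -> float:
    """Worst-pair separability: min over class pairs of the best feature's
    standardized mean gap ``|m1 - m2| / pooled sd``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    worst = np.inf
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            Xa, Xb = X[y == a], X[y == b]
            pooled = np.sqrt((Xa.var(axis=0) + Xb.var(axis=0)) / 2.0)
            gap = np.abs(Xa.mean(axis=0) - Xb.mean(axis=0)) / np.maximum(pooled, 1e-12)
            worst = min(worst, float(gap.max()))
    return worst
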