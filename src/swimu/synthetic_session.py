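"""Seeded synthetic swim sessions with ground truth.

No public corpus of lower-back AHRS swim recordings exists, so every stage of
the pipeline is exercised against this generator instead.  It emulates the
signal features the detectors consume, not hydrodynamics:

* **Stroke waveforms.**  For the nonsymmetrical styles (front crawl,
  backstroke) each arm stroke rolls the trunk to one side: roll is a train of
  alternating-sign raised-cosine pulses, one per stroke, with the trunk
  passing through neutral between pulls.  The fraction of a stroke slot
  occupied by the pulse (the duty cycle) is a per-style shape parameter; a
  peaky waveform keeps the stroke peaks outside the per-lap mean +/- k*sigma
  gate at the per-style k values used by the counter.  For the symmetrical
  styles (breaststroke, butterfly) the trunk undulates in pitch: the signal
  rides near its glide value and dips sharply once per stroke cycle, so a
  stroke cycle is the segment between consecutive pitch minima.
* **Turns.**  Tumble and open turns drive pitch toward +/-90 degrees for
  ~1.5 s; bucket and cross-over turns (backstroke) produce only a muted pitch
  excursion (< 20 degrees) so the pitch detector misses them and the
  MAD-outlier + heading-reversal fallback has to recover them.  Heading
  reverses by 180 degrees across every wall event.
* **Stops.**  Pitch descends to about -90 degrees (swimmer standing) and
  holds for at least 3 s.
* **Accelerometer.**  az sits near -1 g for backstroke (supine) and +1 g
  otherwise, with style-specific oscillation amplitudes at the stroke cadence
  chosen so the per-lap channel energies separate the styles: front crawl is
  y-dominant (body roll), butterfly has elevated z (undulation) and x (speed)
  relative to breaststroke.
* **Noise.**  Additive white Gaussian noise on angles (default sd 1 degree)
  and accelerations (default sd 0.05 g); gyro channels are the numerical
  derivative of the clean angles plus noise, magnetometer is an
  earth-field-like function of heading.

Everything is driven by one ``numpy`` Generator, so a fixed seed reproduces
the session bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .imu_io import COLUMNS, ImuSession

__all__ = [
    "STYLES",
    "SYMMETRIC_STYLES",
    "NONSYMMETRIC_STYLES",
    "LapSpec",
    "SessionSpec",
    "TrueEvent",
    "TrueLap",
    "GroundTruth",
    "generate_lap",
    "insert_event",
    "generate_session",
    "default_lap",
    "example_session_spec",
    "generate_lap_corpus",
]

STYLES = ("butterfly", "backstroke", "breaststroke", "front_crawl")
SYMMETRIC_STYLES = frozenset({"butterfly", "breaststroke"})
NONSYMMETRIC_STYLES = frozenset({"front_crawl", "backstroke"})

#: Per-style study conditions for a 25 m pool lap: stroke count (arm strokes
#: for the nonsymmetrical styles, stroke cycles for the symmetrical ones),
#: lap duration, and pulse duty cycle of the stroke waveform.
_LAP_DEFAULTS = {
    "front_crawl": dict(n_strokes=16, duration_s=20.0, duty=0.50, pitch_offset=-5.0),
    "backstroke": dict(n_strokes=16, duration_s=24.0, duty=0.35, pitch_offset=-5.0),
    "breaststroke": dict(n_strokes=10, duration_s=28.0, duty=0.45, pitch_offset=5.0),
    "butterfly": dict(n_strokes=9, duration_s=22.0, duty=0.45, pitch_offset=5.0),
}

#: Accelerometer oscillation amplitudes in g (ax, ay, az) at the stroke
#: cadence, and the gravity-aligned az baseline.  Chosen so the rounded
#: per-lap channel energies (after the 0.5 Hz low-pass and g -> m/s^2
#: conversion) put front crawl, butterfly and breaststroke in separated
#: clusters: front crawl y-dominant, butterfly z- and x-elevated.
_ACC_PROFILE = {
    "front_crawl": dict(amp=(0.4, 1.6, 0.4), az_base=1.0),
    "backstroke": dict(amp=(0.4, 1.4, 0.4), az_base=-1.0),
    "butterfly": dict(amp=(1.1, 0.3, 1.4), az_base=1.0),
    "breaststroke": dict(amp=(0.4, 0.2, 0.5), az_base=1.0),
}

#: Probability that a butterfly lap ends in a turn-approach artifact cycle
#: (last undulation half depth and late), emulating the continuous trunk
#: rotation into the wall that occasionally hides the final stroke.
BUTTERFLY_ARTIFACT_PROB = 0.2

_TURN_VARIANTS = ("tumble", "open", "bucket", "crossover")
_EVENT_KINDS = _TURN_VARIANTS + ("stop",)


# --------------------------------------------------------------------------
# specs and ground truth
# --------------------------------------------------------------------------


@dataclass
class LapSpec:
    """Recipe for one lap of a single style.

    ``n_strokes`` counts arm strokes (roll pulses) for the nonsymmetrical
    styles and stroke cycles (pitch undulations) for the symmetrical ones.
    ``roll_amplitude`` / ``pitch_amplitude`` are the peak deflections of the
    stroke waveform in degrees; ``duty`` is the active fraction of each
    stroke slot.  ``turn_artifact`` corrupts the final undulation of a
    symmetrical lap into a turn-approach artifact.
    """

    style: str
    n_strokes: int
    duration_s: float
    stroke_rate: float | None = None
    roll_amplitude: float = 45.0
    pitch_amplitude: float = 30.0
    pitch_offset: float | None = None
    duty: float | None = None
    turn_artifact: bool = False

    def __post_init__(self) -> None:
        if self.style not in STYLES:
            raise ValueError(f"unknown style {self.style!r}")
        if self.n_strokes < 0:
            raise ValueError("n_strokes must be >= 0")
        if self.duration_s < 0:
            raise ValueError("duration_s must be >= 0")
        if self.roll_amplitude < 0 or self.pitch_amplitude < 0:
            raise ValueError("amplitudes must be nonnegative")
        if self.pitch_offset is None:
            self.pitch_offset = _LAP_DEFAULTS[self.style]["pitch_offset"]
        if self.duty is None:
            self.duty = _LAP_DEFAULTS[self.style]["duty"]
        if self.stroke_rate is None and self.duration_s > 0:
            self.stroke_rate = 60.0 * self.n_strokes / self.duration_s

    @property
    def symmetric(self) -> bool:
        return self.style in SYMMETRIC_STYLES


@dataclass
class SessionSpec:
    """Recipe for a full session: laps joined by wall events.

    ``turn_types`` has one entry per lap boundary, each one of
    tumble / open / bucket / crossover / stop; defaults to all tumble turns.
    A fixed ``seed`` makes the output bit-reproducible.
    """

    laps: list[LapSpec]
    turn_types: list[str] | None = None
    turn_duration_s: float = 1.5
    bucket_duration_s: float = 1.6
    stop_duration_s: float = 5.0
    noise_sd_deg: float = 1.0
    noise_sd_g: float = 0.05
    fs: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.laps:
            raise ValueError("session needs at least one lap")
        n_bound = len(self.laps) - 1
        if self.turn_types is None:
            self.turn_types = ["tumble"] * n_bound
        if len(self.turn_types) != n_bound:
            raise ValueError(
                f"need {n_bound} turn_types for {len(self.laps)} laps, "
                f"got {len(self.turn_types)}"
            )
        for t in self.turn_types:
            if t not in _EVENT_KINDS:
                raise ValueError(f"unknown event kind {t!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionSpec":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        laps = [LapSpec(**lap) for lap in raw.pop("laps")]
        return cls(laps=laps, **raw)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        raw = asdict(self)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


@dataclass
class TrueEvent:
    kind: str  # "turn" | "stop"
    apex_t: float
    start_t: float
    end_t: float
    variant: str = ""


@dataclass
class TrueLap:
    index: int
    style: str
    start_t: float
    end_t: float
    stroke_times: list[float]
    trunk_elevation: float | None = None

    @property
    def stroke_count(self) -> int:
        return len(self.stroke_times)

    @property
    def lap_time(self) -> float:
        return self.end_t - self.start_t


@dataclass
class GroundTruth:
    events: list[TrueEvent] = field(default_factory=list)
    laps: list[TrueLap] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "events": [asdict(e) for e in self.events],
            "laps": [asdict(l) for l in self.laps],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        return cls(
            events=[TrueEvent(**e) for e in raw["events"]],
            laps=[TrueLap(**l) for l in raw["laps"]],
        )


# --------------------------------------------------------------------------
# waveform primitives
# --------------------------------------------------------------------------


def _hann_pulse(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Raised-cosine pulse in [0, 1] supported on [center - w/2, center + w/2]."""
    u = (t - center) / width
    out = np.zeros_like(t)
    m = np.abs(u) < 0.5
    out[m] = 0.5 * (1.0 + np.cos(2.0 * np.pi * u[m]))
    return out


def _smoothstep(n: int) -> np.ndarray:
    """Monotone 0 -> 1 raised-cosine ramp over n samples."""
    x = np.linspace(0.0, 1.0, n)
    return 0.5 * (1.0 - np.cos(np.pi * x))


def generate_lap(
    spec: LapSpec, fs: float, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], dict]:
    """Synthesize the noise-free channels of one lap plus its ground truth.

    Returns ``(channels, truth)`` where ``channels`` maps
    pitch/roll/ax/ay/az to arrays of equal length and ``truth`` carries
    lap-relative ``stroke_times`` (roll-pulse centers for nonsymmetrical
    styles, cycle midpoints for symmetrical ones), ``minima_times`` for the
    symmetrical undulation dips, and the true trunk elevation.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    channels = {k: np.zeros(n) for k in ("pitch", "roll", "ax", "ay", "az")}
    truth: dict = {
        "style": spec.style,
        "stroke_times": [],
        "minima_times": [],
        "trunk_elevation": None,
    }
    if n == 0:
        return channels, truth

    if spec.n_strokes > 0:
        if spec.symmetric:
            # one undulation dip per cycle boundary: n_strokes cycles need
            # n_strokes + 1 minima, all interior to the lap
            w = spec.duration_s / (spec.n_strokes + 1)
            centers = (np.arange(spec.n_strokes + 1) + 0.5) * w
            depths = np.full(len(centers), spec.pitch_amplitude, dtype=float)
            if spec.turn_artifact and len(centers) >= 2:
                depths[-1] *= 0.5
                centers[-1] = min(centers[-1] + 0.25 * w, spec.duration_s - 0.3 * w)
            pitch = np.full(n, float(spec.pitch_offset))
            for c, d in zip(centers, depths):
                pitch -= d * _hann_pulse(t, c, spec.duty * w)
            channels["pitch"] = pitch
            truth["minima_times"] = [float(c) for c in centers]
            truth["stroke_times"] = [
                float(0.5 * (a + b)) for a, b in zip(centers[:-1], centers[1:])
            ]
            truth["trunk_elevation"] = float(spec.pitch_amplitude)
        else:
            slot = spec.duration_s / spec.n_strokes
            centers = (np.arange(spec.n_strokes) + 0.5) * slot
            signs = np.where(np.arange(spec.n_strokes) % 2 == 0, 1.0, -1.0)
            roll = np.zeros(n)
            for c, s in zip(centers, signs):
                roll += s * spec.roll_amplitude * _hann_pulse(t, c, spec.duty * slot)
            channels["roll"] = roll
            channels["pitch"] = np.full(n, float(spec.pitch_offset))
            truth["stroke_times"] = [float(c) for c in centers]
    else:
        channels["pitch"] = np.full(n, float(spec.pitch_offset))

    # accelerometer: gravity baseline plus style-specific stroke-cadence
    # oscillation with ~10% per-lap amplitude jitter
    profile = _ACC_PROFILE[spec.style]
    if spec.n_strokes > 0:
        f0 = (
            (spec.n_strokes + 1) / spec.duration_s
            if spec.symmetric
            else spec.n_strokes / (2.0 * spec.duration_s)
        )
    else:
        f0 = 0.0
    for axis, name in enumerate(("ax", "ay", "az")):
        amp = profile["amp"][axis] * rng.lognormal(0.0, 0.1)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        channels[name] = amp * np.sin(2.0 * np.pi * f0 * t + phase)
    channels["az"] = channels["az"] + profile["az_base"]
    return channels, truth


def insert_event(
    kind: str,
    turn_sign: int = 1,
    duration_s: float | None = None,
    fs: float = 100.0,
    rng: np.random.Generator | None = None,
    stop_hold_s: float = 5.0,
) -> tuple[dict[str, np.ndarray], TrueEvent]:
    """Synthesize the angle fragment of a wall event.

    ``kind`` is one of tumble / open / bucket / crossover / stop.  Tumble and
    open turns drive pitch to ~ +/-85 degrees; bucket and cross-over turns
    stay below the 20 degree swim band; a stop descends to -85 degrees and
    holds ``stop_hold_s`` (>= 3 s by default).  All variants carry a smooth
    180 degree heading reversal in ``heading_delta``.  Times in the returned
    :class:`TrueEvent` are relative to the fragment start.
    """
    if kind not in _EVENT_KINDS:
        raise ValueError(f"unknown event kind {kind!r}")
    if kind == "stop":
        ramp_s = 1.0
        duration_s = 2.0 * ramp_s + stop_hold_s
    elif duration_s is None:
        duration_s = 1.6 if kind in ("bucket", "crossover") else 1.5
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    heading_delta = 180.0 * _smoothstep(n)
    if kind == "stop":
        n_ramp = int(round(1.0 * fs))
        pitch = np.full(n, -85.0)
        pitch[:n_ramp] = -85.0 * _smoothstep(n_ramp)
        pitch[n - n_ramp:] = -85.0 * _smoothstep(n_ramp)[::-1]
        apex = duration_s / 2.0
        ev_kind = "stop"
    else:
        if kind in ("tumble", "open"):
            pitch = turn_sign * 85.0 * _hann_pulse(t, duration_s / 2.0, duration_s)
        else:
            # muted positive bump: the recovery rule expects a pitch maximum
            pitch = 12.0 * _hann_pulse(t, duration_s / 2.0, duration_s)
        apex = duration_s / 2.0
        ev_kind = "turn"
    channels = {
        "pitch": pitch,
        "roll": np.zeros(n),
        "heading_delta": heading_delta,
    }
    truth = TrueEvent(
        kind=ev_kind, apex_t=apex, start_t=0.0, end_t=duration_s, variant=kind
    )
    return channels, truth


# --------------------------------------------------------------------------
# session assembly
# --------------------------------------------------------------------------


def generate_session(spec: SessionSpec) -> tuple[ImuSession, GroundTruth]:
    """Concatenate laps and wall events into a full noisy session.

    Heading alternates between 90 and 270 degrees lap to lap with a smooth
    reversal across each event; az blends linearly between the adjoining
    laps' gravity baselines during events.  The same seed yields an
    identical session.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs

    pieces: list[dict[str, np.ndarray]] = []
    truth = GroundTruth()
    t_off = 0.0
    heading_base = 90.0
    heading_sign = 1.0

    lap_channels = []
    for lap in spec.laps:
        ch, lt = generate_lap(lap, fs, rng)
        lap_channels.append((ch, lt))

    for i, (ch, lt) in enumerate(lap_channels):
        n = len(ch["pitch"])
        frag = dict(ch)
        frag["heading"] = np.full(n, heading_base)
        pieces.append(frag)
        truth.laps.append(
            TrueLap(
                index=i + 1,
                style=lt["style"],
                start_t=t_off,
                end_t=t_off + n / fs,
                stroke_times=[t_off + s for s in lt["stroke_times"]],
                trunk_elevation=lt["trunk_elevation"],
            )
        )
        t_off += n / fs

        if i < len(spec.laps) - 1:
            kind = spec.turn_types[i]
            dur = (
                spec.bucket_duration_s
                if kind in ("bucket", "crossover")
                else spec.turn_duration_s
            )
            ech, ev = insert_event(
                kind,
                turn_sign=1 if lap_channels[i][1]["style"] != "backstroke" else -1,
                duration_s=dur,
                fs=fs,
                rng=rng,
                stop_hold_s=spec.stop_duration_s,
            )
            m = len(ech["pitch"])
            next_base = _ACC_PROFILE[lap_channels[i + 1][1]["style"]]["az_base"]
            prev_base = _ACC_PROFILE[lap_channels[i][1]["style"]]["az_base"]
            blend = np.linspace(prev_base, next_base, m)
            frag = {
                "pitch": ech["pitch"],
                "roll": ech["roll"],
                "heading": np.mod(
                    heading_base + heading_sign * ech["heading_delta"], 360.0
                ),
                "ax": np.zeros(m),
                "ay": np.zeros(m),
                "az": blend,
            }
            pieces.append(frag)
            truth.events.append(
                TrueEvent(
                    kind=ev.kind,
                    apex_t=t_off + ev.apex_t,
                    start_t=t_off + ev.start_t,
                    end_t=t_off + ev.end_t,
                    variant=ev.variant,
                )
            )
            t_off += m / fs
            heading_base = np.mod(heading_base + heading_sign * 180.0, 360.0)
            heading_sign = -heading_sign

    full = {
        key: np.concatenate([p[key] for p in pieces])
        for key in ("pitch", "roll", "heading", "ax", "ay", "az")
    }
    n = len(full["pitch"])
    t = np.arange(n) / fs

    # gyro from the clean angles, magnetometer from heading
    heading_unwrapped = np.degrees(np.unwrap(np.radians(full["heading"])))
    gx = np.gradient(full["roll"], 1.0 / fs)
    gy = np.gradient(full["pitch"], 1.0 / fs)
    gz = np.gradient(heading_unwrapped, 1.0 / fs)
    mx = 0.4 * np.cos(np.radians(full["heading"]))
    my = -0.4 * np.sin(np.radians(full["heading"]))
    mz = np.full(n, 0.25)

    sd, sg = spec.noise_sd_deg, spec.noise_sd_g
    pitch = np.clip(full["pitch"] + rng.normal(0.0, sd, n), -90.0, 90.0)
    roll = np.mod(full["roll"] + rng.normal(0.0, sd, n) + 180.0, 360.0) - 180.0
    heading = np.mod(full["heading"] + rng.normal(0.0, sd, n), 360.0)

    df = pd.DataFrame(
        {
            "t_ms": np.round(t * 1000.0).astype(np.int64),
            "ax": full["ax"] + rng.normal(0.0, sg, n),
            "ay": full["ay"] + rng.normal(0.0, sg, n),
            "az": full["az"] + rng.normal(0.0, sg, n),
            "gx": gx + rng.normal(0.0, 1.0, n),
            "gy": gy + rng.normal(0.0, 1.0, n),
            "gz": gz + rng.normal(0.0, 1.0, n),
            "mx": mx + rng.normal(0.0, 0.01, n),
            "my": my + rng.normal(0.0, 0.01, n),
            "mz": mz + rng.normal(0.0, 0.01, n),
            "pitch": pitch,
            "roll": roll,
            "heading": heading,
        },
        columns=list(COLUMNS),
    )
    meta = {"generator": "swimu.synthetic_session", "seed": spec.seed}
    session = ImuSession.from_dataframe(df, fs_hint=fs, meta=meta)
    return session, truth


# --------------------------------------------------------------------------
# study-condition helpers
# --------------------------------------------------------------------------


def default_lap(
    style: str, rng: np.random.Generator | None = None, turn_artifact: bool | None = None
) -> LapSpec:
    """A lap at the per-style study conditions.

    When ``rng`` is given, butterfly laps draw their turn-approach artifact
    flag with probability :data:`BUTTERFLY_ARTIFACT_PROB` (unless forced via
    ``turn_artifact``).
    """
    d = _LAP_DEFAULTS[style]
    if turn_artifact is None:
        turn_artifact = bool(
            style == "butterfly"
            and rng is not None
            and rng.random() < BUTTERFLY_ARTIFACT_PROB
        )
    return LapSpec(
        style=style,
        n_strokes=d["n_strokes"],
        duration_s=d["duration_s"],
        turn_artifact=turn_artifact,
    )


def example_session_spec(
    seed: int = 0, noise_sd_deg: float = 1.0, artifacts: bool = True
) -> SessionSpec:
    """The canonical mixed 8-lap session: two laps per style.

    Block order front crawl, backstroke, breaststroke, butterfly with stops
    between blocks; the in-block backstroke boundary is a bucket turn (no
    pitch excursion) so the MAD + heading-reversal fallback is exercised.
    ``artifacts=False`` disables the butterfly turn-approach artifact draw
    (used when exact noise-free stroke recovery is the point).
    """
    rng = np.random.default_rng(seed)
    order = ["front_crawl", "backstroke", "breaststroke", "butterfly"]
    artifact = None if artifacts else False
    laps = []
    for style in order:
        laps += [
            default_lap(style, rng, turn_artifact=artifact),
            default_lap(style, rng, turn_artifact=artifact),
        ]
    turn_types = ["tumble", "stop", "bucket", "stop", "open", "stop", "tumble"]
    return SessionSpec(
        laps=laps, turn_types=turn_types, noise_sd_deg=noise_sd_deg, seed=seed
    )


def generate_lap_corpus(
    style: str,
    n_laps: int,
    seed: int = 0,
    noise_sd_deg: float = 1.0,
    noise_sd_g: float = 0.05,
    artifacts: bool = True,
) -> list[tuple[ImuSession, GroundTruth]]:
    """``n_laps`` independent single-lap sessions of one style.

    Each lap is its own seeded session (seed, seed+1, ...), the form the
    stroke-counting and classifier evaluations consume.
    """
    out = []
    artifact = None if artifacts else False
    for i in range(n_laps):
        rng = np.random.default_rng(seed + i)
        spec = SessionSpec(
            laps=[default_lap(style, rng, turn_artifact=artifact)],
            noise_sd_deg=noise_sd_deg,
            noise_sd_g=noise_sd_g,
            seed=seed + i,
        )
        out.append(generate_session(spec))
    return out
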