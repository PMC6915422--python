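"""Per-lap stroke counting from the trunk rotation angles.

Nonsymmetrical styles (front crawl, backstroke) rotate the trunk once per
arm stroke, so the roll signal oscillates and *each* extremum — maxima and
minima alike — is one stroke.  The counter low-pass filters roll (48th-order
Hamming FIR, 3 Hz cutoff), finds local extrema, and keeps those that

* lie outside the per-lap band  mean(A) +/- k * sigma(A)  (the per-style k
  gate; sigma is the sample standard deviation of the filtered signal), and
* reach a minimum body rotation of 20 degrees.

Symmetrical styles (breaststroke, butterfly) undulate in pitch instead; a
stroke cycle is the segment between consecutive pitch minima.  Minima are
found on the 3 Hz-filtered pitch, gated by the same k-sigma band, and the
cycles between surviving minima are resampled to 200 samples.  A mean wave
is built from the central 50% (samples 50-149) of all cycles, and each
cycle whose dynamic-time-warping distance to that template exceeds a
threshold is discarded as an outlier (turn approaches, glides); the kept
cycles are the stroke count.

The default k values are front crawl 2, backstroke 2.36, breaststroke 0.74,
butterfly 1.34.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from .style_classifier import hamming_lowpass

__all__ = [
    "StrokeEvent",
    "StrokeCycle",
    "MeanWaveTemplate",
    "CountingParams",
    "StrokeCountResult",
    "band_mask",
    "detect_roll_strokes",
    "detect_pitch_cycles",
    "build_mean_wave",
    "dtw_distance",
    "reject_outlier_cycles",
    "count_strokes",
]

CYCLE_RESAMPLE_N = 200
_CENTRAL = slice(50, 150)  # central 50% of the 200-sample grid


@dataclass(frozen=True)
class StrokeEvent:
    """One detected arm stroke: a roll extremum with its side and peak value."""

    t: float
    peak_value: float
    polarity: str  # "max" (one side) | "min" (other side)


@dataclass(frozen=True)
class StrokeCycle:
    """One pitch undulation between consecutive minima, resampled to 200."""

    start_t: float
    end_t: float
    pitch_min: float
    pitch_max: float
    resampled: np.ndarray

    @property
    def mid_t(self) -> float:
        return 0.5 * (self.start_t + self.end_t)

    @property
    def central(self) -> np.ndarray:
        return self.resampled[_CENTRAL]


@dataclass(frozen=True)
class MeanWaveTemplate:
    """Pointwise mean of the central 50% of the stroke cycles (100 samples)."""

    wave: np.ndarray
    dtw_reject_threshold: float


@dataclass(frozen=True)
class CountingParams:
    k_by_style: dict = field(
        default_factory=lambda: {
            "front_crawl": 2.0,
            "backstroke": 2.36,
            "breaststroke": 0.74,
            "butterfly": 1.34,
        }
    )
    min_rotation_deg: float = 20.0
    cutoff_hz: float = 3.0
    filter_order: int = 48
    #: minimum separation between detected extrema (suppresses noise doubles)
    min_peak_separation_s: float = 0.25
    #: DTW rejection threshold: max(factor * median cycle-template distance,
    #: floor), unless a fixed threshold is given
    dtw_reject_factor: float = 3.0
    dtw_reject_floor: float = 15.0
    dtw_threshold: float | None = None

    def __post_init__(self) -> None:
        if any(k <= 0 for k in self.k_by_style.values()):
            raise ValueError("k values must be positive")
        for name in ("min_rotation_deg", "cutoff_hz", "min_peak_separation_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class StrokeCountResult:
    """Stroke count plus the supporting detections for the indicator stage."""

    style: str
    count: int
    events: tuple = ()  # kept StrokeEvents (nonsymmetrical)
    rejected_events: tuple = ()  # extrema failing the gates
    cycles: tuple = ()  # all cycles pre-DTW (symmetrical)
    kept_cycles: tuple = ()
    rejected_cycles: tuple = ()
    rejected_minima_times: tuple = ()
    template: MeanWaveTemplate | None = None

    @property
    def detected_times(self) -> list[float]:
        if self.events:
            return [e.t for e in self.events]
        return [c.mid_t for c in self.kept_cycles]

    @property
    def rejected_times(self) -> list[float]:
        out = [e.t for e in self.rejected_events]
        out += list(self.rejected_minima_times)
        out += [c.mid_t for c in self.rejected_cycles]
        return out


# --------------------------------------------------------------------------
# the k-sigma band
# --------------------------------------------------------------------------


def band_mask(A: np.ndarray, k: float) -> np.ndarray:
    """True where a sample lies outside the band mean(A) +/- k * sigma(A).

    sigma is the sample standard deviation (ddof=1); a constant series has
    sigma = 0 and yields no candidates.  Samples outside the band are the
    candidate stroke peaks.
    """
    A = np.asarray(A, dtype=float)
    if len(A) < 2:
        raise ValueError("need at least 2 samples for the k-sigma band")
    sigma = float(np.std(A, ddof=1))
    return np.abs(A - np.mean(A)) > k * sigma


# --------------------------------------------------------------------------
# nonsymmetrical styles: roll extrema
# --------------------------------------------------------------------------


def _local_extrema(x: np.ndarray, fs: float, params: CountingParams):
    dist = max(int(round(params.min_peak_separation_s * fs)), 1)
    maxima, _ = find_peaks(x, distance=dist)
    minima, _ = find_peaks(-x, distance=dist)
    return maxima, minima


def _filtered(x: np.ndarray, fs: float, params: CountingParams) -> np.ndarray:
    return hamming_lowpass(
        np.asarray(x, dtype=float), fs, order=params.filter_order, cutoff=params.cutoff_hz
    )


def detect_roll_strokes(
    roll: np.ndarray,
    fs: float,
    style: str,
    params: CountingParams | None = None,
    return_rejected: bool = False,
):
    """Detect arm strokes as gated roll extrema (front crawl, backstroke).

    Returns the kept :class:`StrokeEvent` list ordered in time; with
    ``return_rejected=True`` also the list of extrema that failed the
    k-sigma band or the 20 degree minimum-rotation gate.
    """
    if style not in ("front_crawl", "backstroke"):
        raise ValueError(f"{style!r} is not a nonsymmetrical style")
    params = params or CountingParams()
    x = _filtered(roll, fs, params)
    maxima, minima = _local_extrema(x, fs, params)
    outside = band_mask(x, params.k_by_style[style])

    kept, rejected = [], []
    for idx, pol in sorted(
        [(i, "max") for i in maxima] + [(i, "min") for i in minima]
    ):
        ev = StrokeEvent(t=idx / fs, peak_value=float(x[idx]), polarity=pol)
        if outside[idx] and abs(x[idx]) >= params.min_rotation_deg:
            kept.append(ev)
        else:
            rejected.append(ev)
    if return_rejected:
        return kept, rejected
    return kept


# --------------------------------------------------------------------------
# symmetrical styles: pitch cycles + DTW outlier rejection
# --------------------------------------------------------------------------


def _resample(seg: np.ndarray, n: int = CYCLE_RESAMPLE_N) -> np.ndarray:
    u = np.linspace(0.0, 1.0, n)
    src = np.linspace(0.0, 1.0, len(seg))
    return np.interp(u, src, seg)


def detect_pitch_cycles(
    pitch: np.ndarray,
    fs: float,
    style: str,
    params: CountingParams | None = None,
    return_rejected: bool = False,
):
    """Cut a symmetrical-style lap into stroke cycles between pitch minima.

    Minima of the 3 Hz-filtered pitch are gated by the k-sigma band (a true
    undulation dip lies well below the band); consecutive surviving minima
    delimit one cycle each, resampled to 200 samples by linear interpolation
    on the time-normalized segment.  Fewer than two surviving minima yield
    an empty list.
    """
    if style not in ("breaststroke", "butterfly"):
        raise ValueError(f"{style!r} is not a symmetrical style")
    params = params or CountingParams()
    x = _filtered(pitch, fs, params)
    _, minima = _local_extrema(x, fs, params)
    outside = band_mask(x, params.k_by_style[style])
    below = x < np.mean(x)  # dips only: a stroke minimum is under the band

    kept_idx = [i for i in minima if outside[i] and below[i]]
    rejected_times = tuple(i / fs for i in minima if i not in set(kept_idx))

    cycles = []
    for a, b in zip(kept_idx[:-1], kept_idx[1:]):
        seg = x[a : b + 1]
        cycles.append(
            StrokeCycle(
                start_t=a / fs,
                end_t=b / fs,
                pitch_min=float(np.min(seg)),
                pitch_max=float(np.max(seg)),
                resampled=_resample(seg),
            )
        )
    if return_rejected:
        return cycles, rejected_times
    return cycles


def build_mean_wave(
    cycles, dtw_reject_threshold: float = float("nan")
) -> MeanWaveTemplate:
    """Pointwise mean of the central 50% of the resampled cycles."""
    cycles = list(cycles)
    if not cycles:
        raise ValueError("cannot build a mean wave from zero cycles")
    wave = np.mean([c.central for c in cycles], axis=0)
    return MeanWaveTemplate(wave=wave, dtw_reject_threshold=dtw_reject_threshold)


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean-flavor dynamic time warping distance.

    Classic DP with squared-difference local cost, symmetric match/insert/
    delete steps and no warping window; returns the square root of the
    optimal accumulated cost.  Identical series give 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("dtw_distance of an empty series")
    n, m = len(a), len(b)
    prev = np.full(m + 1, np.inf)
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur = np.empty(m + 1)
        cur[0] = np.inf
        ai = a[i - 1]
        row_cost = (ai - b) ** 2
        for j in range(1, m + 1):
            cur[j] = row_cost[j - 1] + min(prev[j], prev[j - 1], cur[j - 1])
        prev = cur
    return float(np.sqrt(prev[m]))


def reject_outlier_cycles(
    cycles, template: MeanWaveTemplate, params: CountingParams | None = None
):
    """Split cycles into (kept, rejected) by DTW distance to the mean wave.

    The threshold is ``template.dtw_reject_threshold`` when set, else the
    self-calibrating default max(factor * median distance, floor) — the
    session's own cycle population defines "typical", with the floor keeping
    near-identical clean cycles from rejecting each other.
    """
    params = params or CountingParams()
    cycles = list(cycles)
    if not cycles:
        return [], []
    dists = np.array([dtw_distance(c.central, template.wave) for c in cycles])
    thr = template.dtw_reject_threshold
    if np.isnan(thr):
        if params.dtw_threshold is not None:
            thr = params.dtw_threshold
        else:
            thr = max(
                params.dtw_reject_factor * float(np.median(dists)),
                params.dtw_reject_floor,
            )
    kept = [c for c, d in zip(cycles, dists) if d <= thr]
    rejected = [c for c, d in zip(cycles, dists) if d > thr]
    return kept, rejected


# --------------------------------------------------------------------------
# dispatch
# --------------------------------------------------------------------------


def count_strokes(
    pitch: np.ndarray,
    roll: np.ndarray,
    fs: float,
    style: str,
    params: CountingParams | None = None,
) -> StrokeCountResult:
    """Count strokes in one lap, dispatching on the style's motion component.

    Nonsymmetrical styles count gated roll extrema; symmetrical styles count
    the pitch cycles that survive DTW outlier rejection.  An empty lap
    counts zero; a nonempty lap shorter than the FIR filter raises.
    """
    params = params or CountingParams()
    pitch = np.asarray(pitch, dtype=float)
    roll = np.asarray(roll, dtype=float)
    if len(pitch) == 0 and len(roll) == 0:
        return StrokeCountResult(style=style, count=0)
    if style in ("front_crawl", "backstroke"):
        kept, rejected = detect_roll_strokes(
            roll, fs, style, params, return_rejected=True
        )
        return StrokeCountResult(
            style=style,
            count=len(kept),
            events=tuple(kept),
            rejected_events=tuple(rejected),
        )
    cycles, rejected_minima = detect_pitch_cycles(
        pitch, fs, style, params, return_rejected=True
    )
    if not cycles:
        return StrokeCountResult(
            style=style, count=0, rejected_minima_times=tuple(rejected_minima)
        )
    template = build_mean_wave(cycles)
    kept, rejected = reject_outlier_cycles(cycles, template, params)
    return StrokeCountResult(
        style=style,
        count=len(kept),
        cycles=tuple(cycles),
        kept_cycles=tuple(kept),
        rejected_cycles=tuple(rejected),
        rejected_minima_times=tuple(rejected_minima),
        template=replace(
            template,
            dtw_reject_threshold=template.dtw_reject_threshold,
        ),
    )
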