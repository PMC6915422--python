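"""Turn/stop detection and lap segmentation from the pitch angle.

While swimming, trunk pitch stays inside roughly +/-20 degrees for all four
styles.  A tumble or open turn drives it close to +/-90 degrees; during a
stop the swimmer stands and pitch descends to about -90 degrees and dwells
there.  The detector therefore:

1. finds maximal excursions of |pitch| beyond an apex trigger (default 70
   degrees, i.e. "close to vertical"),
2. classifies each excursion as a stop when the separation between the
   governing local pitch maximum and minimum is at least ``stop_min_s``
   (default 3 s), else as a turn,
3. refines each event's start/end by sliding a 0.5 s averaging window away
   from the apex until the window mean re-enters the +/-20 degree swim band,
4. cuts the session into laps between consecutive events.

Backstroke bucket and cross-over turns may produce no pitch excursion at
all.  Those are recovered from the lap-time pattern: laps whose duration is
more than ``mad_scale`` scaled median absolute deviations from the median
lap time are outlier candidates, and a sustained 180 degree heading reversal
inside such a lap marks the missed turn (apex at the nearest local pitch
maximum).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

from .imu_io import ImuSession

__all__ = [
    "MotionEvent",
    "LapSegment",
    "SegmentationParams",
    "detect_events",
    "refine_boundaries",
    "scaled_mad",
    "lap_time_outliers",
    "recover_missed_turns",
    "segment_laps",
    "segment_session",
]

#: Consistency constant making the MAD estimate sigma for normal data.
MAD_SCALE_FACTOR = 1.4826


@dataclass(frozen=True)
class MotionEvent:
    """A detected turn or stop: apex instant plus refined extent in seconds."""

    kind: str  # "turn" | "stop"
    apex_t: float
    start_t: float
    end_t: float
    apex_pitch: float

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t


@dataclass(frozen=True)
class LapSegment:
    """A swimmable interval between consecutive events (1-based index)."""

    index: int
    start_t: float
    end_t: float
    start_idx: int  # half-open sample span [start_idx, end_idx)
    end_idx: int

    @property
    def lap_time(self) -> float:
        return self.end_t - self.start_t


@dataclass(frozen=True)
class SegmentationParams:
    swim_band_deg: float = 20.0
    apex_trigger_deg: float = 70.0
    stop_min_s: float = 3.0
    refine_window_s: float = 0.5
    mad_scale: float = 3.0
    #: accumulated heading change that counts as a reversal, and the horizon
    #: within which it must accumulate
    reversal_deg: float = 150.0
    reversal_horizon_s: float = 5.0
    #: gap below which adjacent out-of-band excursions merge into one event
    merge_gap_s: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "swim_band_deg",
            "apex_trigger_deg",
            "stop_min_s",
            "refine_window_s",
            "mad_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.swim_band_deg >= self.apex_trigger_deg:
            raise ValueError("swim_band_deg must be below apex_trigger_deg")


# --------------------------------------------------------------------------
# event detection
# --------------------------------------------------------------------------


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index runs where mask is True."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def detect_events(
    pitch: np.ndarray, fs: float, params: SegmentationParams | None = None
) -> list[MotionEvent]:
    """Detect turn/stop events from a uniformly sampled pitch series.

    Each maximal excursion of |pitch| beyond ``apex_trigger_deg`` yields one
    event.  The event is a stop when the separation between the governing
    local pitch maximum and minimum inside the excursion window reaches
    ``stop_min_s``; when the excursion has only one interior extremum (e.g. a
    plateau at -90), the out-of-band dwell time decides.  Events come back
    ordered by apex time with start/end initialized to the excursion window
    (call :func:`refine_boundaries` for the precise extent).
    """
    params = params or SegmentationParams()
    pitch = np.asarray(pitch, dtype=float)
    n = len(pitch)
    if n == 0:
        return []
    out_band = np.abs(pitch) >= params.apex_trigger_deg
    runs = _true_runs(out_band)
    if not runs:
        return []
    # merge runs separated by less than merge_gap_s
    merged = [list(runs[0])]
    gap = int(round(params.merge_gap_s * fs))
    for s, e in runs[1:]:
        if s - merged[-1][1] <= gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    band = np.abs(pitch) >= params.swim_band_deg
    events = []
    for s, e in merged:
        # window: expand to where |pitch| last left / next re-enters the swim band
        ws = s
        while ws > 0 and band[ws - 1]:
            ws -= 1
        we = e
        while we < n and band[we]:
            we += 1
        seg = pitch[ws:we]
        apex_rel = int(np.argmax(np.abs(seg)))
        apex_idx = ws + apex_rel
        maxima, _ = find_peaks(seg)
        minima, _ = find_peaks(-seg)
        dwell = (e - s) / fs  # dwell beyond the apex trigger
        if len(maxima) and len(minima):
            i_max = maxima[np.argmax(seg[maxima])]
            i_min = minima[np.argmin(seg[minima])]
            sep = max(abs(i_max - i_min) / fs, dwell)
        else:
            sep = dwell
        kind = "stop" if sep >= params.stop_min_s else "turn"
        events.append(
            MotionEvent(
                kind=kind,
                apex_t=apex_idx / fs,
                start_t=ws / fs,
                end_t=(we - 1) / fs,
                apex_pitch=float(pitch[apex_idx]),
            )
        )
    events.sort(key=lambda ev: ev.apex_t)
    return events


def _window_means(x: np.ndarray, w: int, trailing: bool) -> np.ndarray:
    """Mean over the window ending (trailing) or starting (leading) at each i.

    Windows are clipped to the signal bounds near the edges.
    """
    n = len(x)
    c = np.concatenate(([0.0], np.cumsum(x)))
    i = np.arange(n)
    if trailing:
        lo = np.maximum(i - w + 1, 0)
        hi = i + 1
    else:
        lo = i
        hi = np.minimum(i + w, n)
    return (c[hi] - c[lo]) / (hi - lo)


def refine_boundaries(
    pitch: np.ndarray,
    fs: float,
    event: MotionEvent,
    params: SegmentationParams | None = None,
) -> MotionEvent:
    """Set an event's start/end at the swim-band re-entry of the window mean.

    ``start_t`` is the latest time at or before the apex where the trailing
    ``refine_window_s`` mean of pitch lies within +/-``swim_band_deg``;
    ``end_t`` is the symmetric leading-window instant after the apex.  When
    the band is never re-entered (event at a session edge) the boundary is
    clipped to the signal bounds.
    """
    params = params or SegmentationParams()
    pitch = np.asarray(pitch, dtype=float)
    n = len(pitch)
    w = max(int(round(params.refine_window_s * fs)), 1)
    apex_idx = int(round(event.apex_t * fs))
    apex_idx = min(max(apex_idx, 0), n - 1)

    trail = _window_means(pitch, w, trailing=True)
    lead = _window_means(pitch, w, trailing=False)
    band = params.swim_band_deg

    ok_before = np.flatnonzero(np.abs(trail[: apex_idx + 1]) <= band)
    start_idx = int(ok_before[-1]) if len(ok_before) else 0
    ok_after = np.flatnonzero(np.abs(lead[apex_idx:]) <= band)
    end_idx = apex_idx + int(ok_after[0]) if len(ok_after) else n - 1

    return replace(event, start_t=start_idx / fs, end_t=end_idx / fs)


# --------------------------------------------------------------------------
# MAD lap-time outliers and missed-turn recovery
# --------------------------------------------------------------------------


def scaled_mad(values) -> float:
    """Scaled median absolute deviation: 1.4826 * median(|x - median(x)|)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("scaled_mad of an empty vector")
    med = np.median(values)
    return float(MAD_SCALE_FACTOR * np.median(np.abs(values - med)))


def lap_time_outliers(lap_times, mad_scale: float = 3.0) -> set[int]:
    """Indices of lap times more than ``mad_scale`` scaled MADs off the median.

    With a zero MAD (e.g. all-but-one equal values) only exact-median laps
    count as inliers.
    """
    lap_times = np.asarray(lap_times, dtype=float)
    if lap_times.size == 0:
        return set()
    med = np.median(lap_times)
    s = scaled_mad(lap_times)
    dev = np.abs(lap_times - med)
    return {int(i) for i in np.flatnonzero(dev > mad_scale * s)}


def recover_missed_turns(
    lap: LapSegment,
    pitch: np.ndarray,
    heading: np.ndarray,
    fs: float,
    params: SegmentationParams | None = None,
) -> MotionEvent | None:
    """Locate a pitch-silent turn inside an outlier lap via heading reversal.

    Searches the lap interior (1 s edge margin) for a window of at most
    ``reversal_horizon_s`` across which the unwrapped heading changes by at
    least ``reversal_deg``; the apex goes at the local pitch maximum nearest
    the reversal midpoint and the boundaries are refined as usual.  Returns
    ``None`` when no reversal exists (a genuinely long lap).
    """
    params = params or SegmentationParams()
    pitch = np.asarray(pitch, dtype=float)
    heading = np.asarray(heading, dtype=float)
    margin = int(round(1.0 * fs))
    s, e = lap.start_idx + margin, lap.end_idx - margin
    if e - s < 2:
        return None
    h = np.degrees(np.unwrap(np.radians(heading[s:e])))
    horizon = max(int(round(params.reversal_horizon_s * fs)), 1)
    if len(h) <= horizon:
        deltas = np.array([h[-1] - h[0]])
        starts = np.array([0])
    else:
        deltas = h[horizon:] - h[:-horizon]
        starts = np.arange(len(deltas))
    best = int(np.argmax(np.abs(deltas)))
    if abs(deltas[best]) < params.reversal_deg:
        return None
    i0 = starts[best]
    i1 = min(i0 + horizon, len(h) - 1)
    mid_level = h[i0] + 0.5 * (h[i1] - h[i0])
    mid = i0 + int(np.argmin(np.abs(h[i0 : i1 + 1] - mid_level)))
    mid_idx = s + mid

    seg = pitch[lap.start_idx : lap.end_idx]
    maxima, _ = find_peaks(seg)
    if len(maxima):
        apex_rel = maxima[np.argmin(np.abs(maxima + lap.start_idx - mid_idx))]
        apex_idx = lap.start_idx + int(apex_rel)
    else:
        lo = max(lap.start_idx, mid_idx - int(2.5 * fs))
        hi = min(lap.end_idx, mid_idx + int(2.5 * fs))
        apex_idx = lo + int(np.argmax(pitch[lo:hi]))
    event = MotionEvent(
        kind="turn",
        apex_t=apex_idx / fs,
        start_t=apex_idx / fs,
        end_t=apex_idx / fs,
        apex_pitch=float(pitch[apex_idx]),
    )
    return refine_boundaries(pitch, fs, event, params)


# --------------------------------------------------------------------------
# lap cutting and the full segmentation pass
# --------------------------------------------------------------------------


def segment_laps(session: ImuSession, events: list[MotionEvent]) -> list[LapSegment]:
    """Cut the session into laps between consecutive events.

    Laps are the maximal intervals between the session start, event
    boundaries (end of one event to start of the next) and the session end;
    zero-length intervals are dropped, so lap times exclude the adjoining
    events' durations.
    """
    fs = session.fs
    n = len(session)
    bounds = [0.0]
    prev_end = -np.inf
    for ev in sorted(events, key=lambda ev: ev.apex_t):
        if ev.start_t < prev_end:
            raise ValueError("overlapping events")
        bounds += [ev.start_t, ev.end_t]
        prev_end = ev.end_t
    bounds.append((n - 1) / fs)

    laps = []
    for i in range(0, len(bounds), 2):
        start_t, end_t = bounds[i], bounds[i + 1]
        if end_t - start_t <= 0:
            continue
        laps.append(
            LapSegment(
                index=len(laps) + 1,
                start_t=start_t,
                end_t=end_t,
                start_idx=int(round(start_t * fs)),
                end_idx=min(int(round(end_t * fs)) + 1, n),
            )
        )
    return laps


def segment_session(
    session: ImuSession,
    params: SegmentationParams | None = None,
    max_recovery_passes: int = 4,
) -> tuple[list[MotionEvent], list[LapSegment]]:
    """The full segmentation pass: detect, refine, cut, recover, re-cut.

    After the pitch-based events are found and refined, lap-time outliers
    (scaled-MAD rule) are scanned for heading reversals; each recovered
    pitch-silent turn splits its lap and the outlier scan repeats, up to
    ``max_recovery_passes`` times or until a fixed point.
    """
    params = params or SegmentationParams()
    pitch = session.pitch
    fs = session.fs
    events = [
        refine_boundaries(pitch, fs, ev, params)
        for ev in detect_events(pitch, fs, params)
    ]
    laps = segment_laps(session, events)
    for _ in range(max_recovery_passes):
        if len(laps) < 3:
            break
        outliers = lap_time_outliers([l.lap_time for l in laps], params.mad_scale)
        recovered = []
        for i in sorted(outliers):
            ev = recover_missed_turns(laps[i], pitch, session.heading, fs, params)
            if ev is not None:
                recovered.append(ev)
        if not recovered:
            break
        events = sorted(events + recovered, key=lambda ev: ev.apex_t)
        laps = segment_laps(session, events)
    return events, laps
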