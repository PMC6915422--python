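"""Per-lap coaching indicators and session reports.

For every lap the report carries: lap time (excluding the adjoining turn or
stop), stroke count and stroke rate, and three posture indicators derived
from the Euler angles:

* **trunk elevation** (symmetrical styles only): max minus min pitch within
  each stroke cycle, averaged over the lap;
* **body balance** (pitch): the overall lap mean for the nonsymmetrical
  styles (the goal is a pitch near 0), or the per-cycle pitch maxima and
  minima statistics for the symmetrical ones;
* **body rotation** (roll): per-stroke roll extrema statistics per side for
  the nonsymmetrical styles (rotation should be equal on both sides), or
  the overall lap mean for the symmetrical ones (ideally near 0).

Min/Max statistics are reported in the dominant motion component of each
style and a plain mean in the nondominant one; indicators that do not apply
(e.g. trunk elevation for front crawl) are explicit nulls with a reason
code, never silently omitted.  Detection quality against ground truth uses
the confusion-matrix accuracy (TP + TN) / (TP + FP + TN + FN) with
one-to-one nearest-neighbor matching inside a 0.3 s window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .imu_io import ImuSession
from .lap_segmentation import (
    LapSegment,
    MotionEvent,
    SegmentationParams,
    segment_session,
)
from .stroke_metrics import CountingParams, StrokeCountResult, count_strokes
from .style_classifier import StyleModel, classify_lap
from .synthetic_session import GroundTruth, SYMMETRIC_STYLES

__all__ = [
    "IndicatorStats",
    "LapReport",
    "SessionReport",
    "stroke_rate",
    "trunk_elevation",
    "body_balance",
    "body_rotation",
    "detection_accuracy",
    "match_events",
    "build_session_report",
    "analyze_session",
    "evaluate_lap_boundaries",
    "evaluate_stroke_counts",
]

REPORT_SCHEMA_VERSION = 1
NA_REASON = "not applicable for this style"


def _sd(values) -> float:
    values = np.asarray(values, dtype=float)
    return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0


@dataclass(frozen=True)
class IndicatorStats:
    """Mean +/- sd of an angle indicator, optionally stroke-resolved."""

    mean: float
    sd: float
    role: str = "overall"  # "overall" | "min" | "max"
    per_stroke: tuple = ()

    @classmethod
    def from_values(cls, values, role: str = "overall") -> "IndicatorStats":
        values = [float(v) for v in values]
        return cls(
            mean=float(np.mean(values)), sd=_sd(values), role=role,
            per_stroke=tuple(values),
        )


# --------------------------------------------------------------------------
# scalar indicators
# --------------------------------------------------------------------------


def stroke_rate(count: int, lap_time_s: float) -> float:
    """Strokes per minute over one lap."""
    if lap_time_s <= 0:
        raise ValueError("lap time must be positive")
    return 60.0 * count / lap_time_s


def trunk_elevation(result: StrokeCountResult) -> IndicatorStats | None:
    """Per-cycle pitch range (max - min), averaged over a symmetrical lap.

    Returns None (reported as n.a.) for the nonsymmetrical styles.
    """
    if result.style not in SYMMETRIC_STYLES:
        return None
    cycles = result.kept_cycles
    if not cycles:
        raise ValueError("no kept stroke cycles for trunk elevation")
    return IndicatorStats.from_values(
        [c.pitch_max - c.pitch_min for c in cycles]
    )


def body_balance(
    pitch: np.ndarray, style: str, result: StrokeCountResult
) -> dict[str, IndicatorStats]:
    """Pitch-based posture indicator.

    Nonsymmetrical: overall lap mean +/- sd.  Symmetrical: statistics of the
    per-cycle pitch maxima and minima (roles "max"/"min").
    """
    pitch = np.asarray(pitch, dtype=float)
    if len(pitch) == 0:
        raise ValueError("empty lap")
    if style not in SYMMETRIC_STYLES:
        return {
            "overall": IndicatorStats(
                mean=float(np.mean(pitch)), sd=_sd(pitch), role="overall"
            )
        }
    cycles = result.kept_cycles
    if not cycles:
        raise ValueError("no kept stroke cycles for body balance")
    return {
        "max": IndicatorStats.from_values([c.pitch_max for c in cycles], "max"),
        "min": IndicatorStats.from_values([c.pitch_min for c in cycles], "min"),
    }


def body_rotation(
    roll: np.ndarray, style: str, result: StrokeCountResult
) -> dict[str, IndicatorStats]:
    """Roll-based rotation indicator, the mirror image of body balance.

    Symmetrical: overall lap mean +/- sd (ideally near 0).  Nonsymmetrical:
    statistics of the stroke-event roll maxima (one side) and minima (the
    other side).
    """
    roll = np.asarray(roll, dtype=float)
    if len(roll) == 0:
        raise ValueError("empty lap")
    if style in SYMMETRIC_STYLES:
        return {
            "overall": IndicatorStats(
                mean=float(np.mean(roll)), sd=_sd(roll), role="overall"
            )
        }
    maxima = [e.peak_value for e in result.events if e.polarity == "max"]
    minima = [e.peak_value for e in result.events if e.polarity == "min"]
    out = {}
    if maxima:
        out["max"] = IndicatorStats.from_values(maxima, "max")
    if minima:
        out["min"] = IndicatorStats.from_values(minima, "min")
    return out


# --------------------------------------------------------------------------
# detection accuracy (confusion-matrix form)
# --------------------------------------------------------------------------


def match_events(
    detected: list[float], truth: list[float], tol: float = 0.3
) -> list[tuple[int, int]]:
    """One-to-one nearest-neighbor matching of event times within ``tol``.

    Candidate pairs are taken greedily in order of increasing |dt|; each
    detection and each truth event is used at most once.
    """
    pairs = sorted(
        (abs(d - t), i, j)
        for i, d in enumerate(detected)
        for j, t in enumerate(truth)
        if abs(d - t) <= tol
    )
    used_d, used_t, out = set(), set(), []
    for _, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        out.append((i, j))
    return out


def detection_accuracy(
    detected: list[float],
    truth: list[float],
    rejected: list[float] = (),
    tol: float = 0.3,
) -> tuple[float, dict]:
    """Confusion-matrix accuracy (TP + TN) / (TP + FP + TN + FN).

    Detections matching a true stroke within ``tol`` are TP; unmatched
    detections FP; unmatched true strokes FN.  ``rejected`` holds candidate
    peaks the counter discarded: those not corresponding to a leftover true
    stroke are TN (correctly rejected).  Empty truth with empty detections
    is accuracy 1 by convention.
    """
    detected, truth, rejected = list(detected), list(truth), list(rejected)
    matches = match_events(detected, truth, tol)
    tp = len(matches)
    fp = len(detected) - tp
    matched_truth = {j for _, j in matches}
    leftover = [t for j, t in enumerate(truth) if j not in matched_truth]
    fn = len(leftover)
    rej_matches = match_events(rejected, leftover, tol)
    tn = len(rejected) - len(rej_matches)
    total = tp + fp + tn + fn
    counts = {"TP": tp, "FP": fp, "TN": tn, "FN": fn}
    if total == 0:
        return 1.0, counts
    return (tp + tn) / total, counts


# --------------------------------------------------------------------------
# reports
# --------------------------------------------------------------------------


def _stats_dict(stats: IndicatorStats | None) -> dict | None:
    if stats is None:
        return None
    return {"mean": stats.mean, "sd": stats.sd, "role": stats.role}


@dataclass
class LapReport:
    index: int
    style: str
    start_t: float
    end_t: float
    lap_time: float
    stroke_count: int
    stroke_rate: float
    trunk_elevation: IndicatorStats | None
    body_balance: dict[str, IndicatorStats]
    body_rotation: dict[str, IndicatorStats]
    event_before_s: float | None = None
    event_after_s: float | None = None
    stroke_times: tuple = ()
    rejected_times: tuple = ()

    def to_dict(self) -> dict:
        d = {
            "index": self.index,
            "style": self.style,
            "start_t": self.start_t,
            "end_t": self.end_t,
            "lap_time": self.lap_time,
            "stroke_count": self.stroke_count,
            "stroke_rate": self.stroke_rate,
            "trunk_elevation": _stats_dict(self.trunk_elevation)
            or {"value": None, "reason": NA_REASON},
            "body_balance": {k: _stats_dict(v) for k, v in self.body_balance.items()},
            "body_rotation": {k: _stats_dict(v) for k, v in self.body_rotation.items()},
            "event_before_s": self.event_before_s,
            "event_after_s": self.event_after_s,
            "stroke_times": list(self.stroke_times),
            "rejected_times": list(self.rejected_times),
        }
        if self.trunk_elevation is not None:
            d["trunk_elevation"] = _stats_dict(self.trunk_elevation)
        return d


@dataclass
class SessionReport:
    meta: dict
    laps: list[LapReport]
    events: list[MotionEvent]
    aggregates: dict = field(default_factory=dict)
    schema_version: int = REPORT_SCHEMA_VERSION

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "meta": self.meta,
            "events": [asdict(e) for e in self.events],
            "laps": [l.to_dict() for l in self.laps],
            "aggregates": self.aggregates,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def to_csv(self, path: str | Path) -> None:
        """Tidy one-row-per-lap summary mirroring the aggregate layout."""
        rows = []
        for l in self.laps:
            row = {
                "lap": l.index,
                "style": l.style,
                "lap_time_s": l.lap_time,
                "stroke_count": l.stroke_count,
                "stroke_rate_spm": l.stroke_rate,
                "trunk_elevation_mean": getattr(l.trunk_elevation, "mean", None),
                "trunk_elevation_sd": getattr(l.trunk_elevation, "sd", None),
            }
            for name, block in (("body_balance", l.body_balance),
                                ("body_rotation", l.body_rotation)):
                for role, st in block.items():
                    row[f"{name}_{role}_mean"] = st.mean
                    row[f"{name}_{role}_sd"] = st.sd
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)


def _aggregate(lap_reports: list[LapReport]) -> dict:
    """Per-style mean +/- sd blocks, recomputable from the lap reports."""
    out: dict = {}
    for style in sorted({l.style for l in lap_reports}):
        laps = [l for l in lap_reports if l.style == style]
        block: dict = {
            "n_laps": len(laps),
            "lap_time": {
                "mean": float(np.mean([l.lap_time for l in laps])),
                "sd": _sd([l.lap_time for l in laps]),
            },
            "stroke_count": {
                "mean": float(np.mean([l.stroke_count for l in laps])),
                "sd": _sd([l.stroke_count for l in laps]),
            },
            "stroke_rate": {
                "mean": float(np.mean([l.stroke_rate for l in laps])),
                "sd": _sd([l.stroke_rate for l in laps]),
            },
        }
        te = [l.trunk_elevation.mean for l in laps if l.trunk_elevation is not None]
        block["trunk_elevation"] = (
            {"mean": float(np.mean(te)), "sd": _sd(te)}
            if te
            else {"value": None, "reason": NA_REASON}
        )
        for name in ("body_balance", "body_rotation"):
            roles: dict = {}
            for role in ("overall", "min", "max"):
                vals = [
                    getattr(l, name)[role].mean
                    for l in laps
                    if role in getattr(l, name)
                ]
                if vals:
                    roles[role] = {"mean": float(np.mean(vals)), "sd": _sd(vals)}
            block[name] = roles
        out[style] = block
    return out


def build_session_report(
    session: ImuSession,
    laps: list[LapSegment],
    events: list[MotionEvent],
    styles: list[str],
    counts: list[StrokeCountResult],
) -> SessionReport:
    """Assemble per-lap artifacts into a session report with aggregates."""
    if not (len(laps) == len(styles) == len(counts)):
        raise ValueError("laps, styles and counts must align")
    events = sorted(events, key=lambda e: e.apex_t)
    pitch, roll = session.pitch, session.roll
    reports = []
    for lap, style, res in zip(laps, styles, counts):
        sl = slice(lap.start_idx, lap.end_idx)
        te = trunk_elevation(res) if res.kept_cycles or style not in SYMMETRIC_STYLES else None
        bb = body_balance(pitch[sl], style, res)
        br = body_rotation(roll[sl], style, res)
        before = next(
            (e.duration for e in reversed(events) if e.end_t <= lap.start_t + 1e-9),
            None,
        )
        after = next(
            (e.duration for e in events if e.start_t >= lap.end_t - 1e-9), None
        )
        reports.append(
            LapReport(
                index=lap.index,
                style=style,
                start_t=lap.start_t,
                end_t=lap.end_t,
                lap_time=lap.lap_time,
                stroke_count=res.count,
                stroke_rate=stroke_rate(res.count, lap.lap_time),
                trunk_elevation=te,
                body_balance=bb,
                body_rotation=br,
                event_before_s=before,
                event_after_s=after,
                stroke_times=tuple(lap.start_t + t for t in res.detected_times),
                rejected_times=tuple(lap.start_t + t for t in res.rejected_times),
            )
        )
    return SessionReport(
        meta=dict(session.meta),
        laps=reports,
        events=events,
        aggregates=_aggregate(reports),
    )


def analyze_session(
    session: ImuSession,
    seg_params: SegmentationParams | None = None,
    counting_params: CountingParams | None = None,
    model: StyleModel | None = None,
) -> SessionReport:
    """Run the full pipeline: segment, classify each lap, count, report."""
    seg_params = seg_params or SegmentationParams()
    counting_params = counting_params or CountingParams()
    events, laps = segment_session(session, seg_params)
    acc = session.acc
    styles, counts = [], []
    for lap in laps:
        sl = slice(lap.start_idx, lap.end_idx)
        style = classify_lap(
            acc[sl, 0], acc[sl, 1], acc[sl, 2], session.fs, model=model
        )
        styles.append(style)
        counts.append(
            count_strokes(
                session.pitch[sl], session.roll[sl], session.fs, style,
                counting_params,
            )
        )
    return build_session_report(session, laps, events, styles, counts)


# --------------------------------------------------------------------------
# evaluation against ground truth (synthetic runs)
# --------------------------------------------------------------------------


def evaluate_lap_boundaries(
    laps: list[LapSegment], truth: GroundTruth, tol_s: float = 1.0
) -> float:
    """Fraction of true laps whose both boundaries are delimited within tol."""
    if not truth.laps:
        return 1.0
    ok = 0
    for tl in truth.laps:
        for lap in laps:
            if abs(lap.start_t - tl.start_t) <= tol_s and abs(
                lap.end_t - tl.end_t
            ) <= tol_s:
                ok += 1
                break
    return ok / len(truth.laps)


def evaluate_stroke_counts(
    results: list[StrokeCountResult],
    lap_offsets: list[float],
    truth: GroundTruth,
    tol: float = 0.3,
) -> tuple[float, dict]:
    """Pooled confusion-matrix stroke accuracy over a corpus of laps.

    ``results[i]`` is the count result of the lap starting at
    ``lap_offsets[i]`` seconds, compared to ``truth.laps[i]``.
    """
    tot = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    for res, off, tl in zip(results, lap_offsets, truth.laps):
        det = [off + t for t in res.detected_times]
        rej = [off + t for t in res.rejected_times]
        _, counts = detection_accuracy(det, tl.stroke_times, rej, tol)
        for k in tot:
            tot[k] += counts[k]
    denom = sum(tot.values())
    acc = (tot["TP"] + tot["TN"]) / denom if denom else 1.0
    return acc, tot
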