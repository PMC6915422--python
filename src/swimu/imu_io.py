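"""Reading, validating and writing 13-column AHRS swim logs.

A session log is a CSV stream, nominally at 100 Hz, with one row per sample:

    t_ms, ax, ay, az, gx, gy, gz, mx, my, mz, pitch, roll, heading

where time is in milliseconds since the start of logging, accelerations are in
g, angular rates in deg/s, magnetometer channels in gauss, and the three
orientation angles in degrees.  The device is worn on the swimmer's lower
back, so pitch is the nose-up tilt of the trunk, roll the rotation about the
longitudinal (swimming-direction) axis, and heading the compass direction of
travel.  Angle conventions: pitch in [-90, 90] (positive nose-up), roll in
[-180, 180) (positive to the swimmer's right), heading in [0, 360).

This module keeps units exactly as logged; g -> m/s^2 conversion happens in
the classifier where the energy features need it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "ImuSample",
    "ImuSession",
    "SessionParseError",
    "SessionValidationError",
    "read_session",
    "write_session",
    "check_uniform_sampling",
    "resample_uniform",
]

#: Fixed column order of the log dialect.
COLUMNS = (
    "t_ms",
    "ax", "ay", "az",
    "gx", "gy", "gz",
    "mx", "my", "mz",
    "pitch", "roll", "heading",
)

#: Relative tolerance on the median inter-sample gap vs. the nominal rate.
FS_CONSISTENCY_TOL = 0.10


class SessionParseError(ValueError):
    """A row of the CSV could not be parsed as 13 numeric fields."""


class SessionValidationError(ValueError):
    """The parsed samples violate a session invariant."""


@dataclass(frozen=True)
class ImuSample:
    """One time-stamped sample of the 9 inertial channels plus orientation."""

    t_ms: int
    acc: tuple[float, float, float]
    gyro: tuple[float, float, float]
    mag: tuple[float, float, float]
    pitch: float
    roll: float
    heading: float


def _wrap_heading(h: np.ndarray) -> np.ndarray:
    return np.mod(h, 360.0)


def _wrap_roll(r: np.ndarray) -> np.ndarray:
    return np.mod(r + 180.0, 360.0) - 180.0


@dataclass
class ImuSession:
    """An ordered, uniformly sampled AHRS recording with session metadata.

    ``data`` holds one row per sample in the fixed :data:`COLUMNS` order;
    ``fs`` is the sampling rate in Hz; ``meta`` carries optional pool length
    and swimmer descriptors.
    """

    data: pd.DataFrame
    fs: float
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        fs_hint: float | None = None,
        meta: dict | None = None,
    ) -> "ImuSession":
        """Validate a raw frame, normalize angles and infer ``fs`` if needed."""
        if list(data.columns) != list(COLUMNS):
            data = data.copy()
            if data.shape[1] != len(COLUMNS):
                raise SessionValidationError(
                    f"expected {len(COLUMNS)} columns, got {data.shape[1]}"
                )
            data.columns = COLUMNS
        if len(data) == 0:
            raise SessionValidationError("no samples")
        values = data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            bad = int(np.argwhere(~np.isfinite(values))[0, 0])
            raise SessionValidationError(f"non-finite value in row {bad}")

        t = data["t_ms"].to_numpy(dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise SessionValidationError("non-monotone timestamps")

        data = data.copy().reset_index(drop=True)
        data["heading"] = _wrap_heading(data["heading"].to_numpy(dtype=float))
        data["roll"] = _wrap_roll(data["roll"].to_numpy(dtype=float))
        pitch = data["pitch"].to_numpy(dtype=float)
        if np.any(np.abs(pitch) > 90.0 + 1e-6):
            warnings.warn("pitch outside [-90, 90]; clipping", stacklevel=2)
        data["pitch"] = np.clip(pitch, -90.0, 90.0)

        if len(t) > 1:
            dt_med = float(np.median(np.diff(t)))
            fs_inferred = 1000.0 / dt_med
        else:
            fs_inferred = fs_hint if fs_hint else 100.0
        fs = float(fs_hint) if fs_hint else fs_inferred
        if fs <= 0:
            raise SessionValidationError("fs must be positive")
        if len(t) > 1 and abs(fs_inferred - fs) > FS_CONSISTENCY_TOL * fs:
            raise SessionValidationError(
                f"median sample gap implies fs={fs_inferred:.2f} Hz, "
                f"inconsistent with fs={fs:.2f} Hz beyond "
                f"{FS_CONSISTENCY_TOL:.0%}"
            )
        return cls(data=data, fs=fs, meta=dict(meta or {}))

    # -- convenience accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def t_s(self) -> np.ndarray:
        """Sample times in seconds since log start."""
        return self.data["t_ms"].to_numpy(dtype=float) / 1000.0

    @property
    def pitch(self) -> np.ndarray:
        return self.data["pitch"].to_numpy(dtype=float)

    @property
    def roll(self) -> np.ndarray:
        return self.data["roll"].to_numpy(dtype=float)

    @property
    def heading(self) -> np.ndarray:
        return self.data["heading"].to_numpy(dtype=float)

    @property
    def acc(self) -> np.ndarray:
        """(n, 3) accelerometer block in g, columns x/y/z."""
        return self.data[["ax", "ay", "az"]].to_numpy(dtype=float)

    @property
    def duration_s(self) -> float:
        t = self.t_s
        return float(t[-1] - t[0]) if len(t) > 1 else 0.0

    def samples(self) -> list[ImuSample]:
        """Materialize the row stream as :class:`ImuSample` records."""
        out = []
        for row in self.data.itertuples(index=False):
            out.append(
                ImuSample(
                    t_ms=int(row.t_ms),
                    acc=(row.ax, row.ay, row.az),
                    gyro=(row.gx, row.gy, row.gz),
                    mag=(row.mx, row.my, row.mz),
                    pitch=row.pitch,
                    roll=row.roll,
                    heading=row.heading,
                )
            )
        return out


def _looks_like_header(line: str) -> bool:
    for tok in line.strip().split(","):
        try:
            float(tok)
        except ValueError:
            return True
    return False


def read_session(
    path: str | Path,
    fs_hint: float | None = None,
    meta: dict | None = None,
) -> ImuSession:
    """Read a 13-column CSV log into a validated :class:`ImuSession`.

    An optional header row is recognized by its first field not parsing as a
    number.  ``fs`` is inferred from the median inter-sample gap when
    ``fs_hint`` is not given.  A JSON metadata sidecar ``<path>.meta.json``
    is loaded into ``meta`` when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise SessionValidationError("no samples")
    header = 0 if _looks_like_header(first) else None
    try:
        df = pd.read_csv(path, header=header, names=COLUMNS, dtype=float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise SessionParseError(f"{path}: {exc}") from exc
    if df.isna().to_numpy().any():
        row = int(df.isna().any(axis=1).to_numpy().argmax())
        raise SessionParseError(
            f"{path}: row {row + (1 if header is not None else 0) + 1} does not "
            f"have {len(COLUMNS)} numeric fields"
        )
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if meta is None and sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return ImuSession.from_dataframe(df, fs_hint=fs_hint, meta=meta)


def write_session(
    session: ImuSession,
    path: str | Path,
    write_meta: bool = True,
) -> None:
    """Write a session back to the 13-column CSV dialect (with header row).

    Values are written at full repr precision, so a read/write round trip is
    numerically lossless well within 1e-6.  Session metadata, if any, goes to
    a ``<path>.meta.json`` sidecar.
    """
    if len(session) == 0:
        raise SessionValidationError("refusing to write an empty session")
    path = Path(path)
    df = session.data.copy()
    df["t_ms"] = df["t_ms"].astype(np.int64)
    df.to_csv(path, index=False, float_format="%.10g")
    if write_meta and session.meta:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(session.meta, indent=1, sort_keys=True))


def check_uniform_sampling(
    session: ImuSession, tol: float = 0.1
) -> tuple[bool, list[int]]:
    """Check that every inter-sample gap matches 1/fs within ``tol``.

    Returns ``(ok, gaps)`` where ``gaps`` lists the indices *i* for which the
    gap between samples i and i+1 is off by more than ``tol/fs`` seconds.
    The fixed-rate FIR filters downstream assume this holds.
    """
    if len(session) < 2:
        raise SessionValidationError("need at least 2 samples")
    dt = np.diff(session.t_s)
    nominal = 1.0 / session.fs
    bad = np.nonzero(np.abs(dt - nominal) > tol * nominal)[0]
    return len(bad) == 0, [int(i) for i in bad]


def resample_uniform(session: ImuSession, fs: float | None = None) -> ImuSession:
    """Linearly resample a (possibly gappy) session onto a uniform grid.

    Offered as an explicit repair for non-uniform logs; never applied
    automatically.  Heading is interpolated on its unwrapped representation
    so 359 -> 1 degree steps do not sweep through 180.
    """
    fs = fs or session.fs
    t = session.t_s
    t_new = np.arange(t[0], t[-1] + 0.5 / fs, 1.0 / fs)
    out = {}
    for col in COLUMNS[1:]:
        y = session.data[col].to_numpy(dtype=float)
        if col == "heading":
            y = np.degrees(np.unwrap(np.radians(y)))
        out[col] = np.interp(t_new, t, y)
    df = pd.DataFrame(out)
    df.insert(0, "t_ms", np.round((t_new - t_new[0]) * 1000.0).astype(np.int64))
    df["heading"] = _wrap_heading(df["heading"].to_numpy())
    return ImuSession.from_dataframe(df, fs_hint=fs, meta=session.meta)
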