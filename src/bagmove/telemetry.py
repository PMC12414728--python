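"""Core telemetry containers and CSV I/O.

Telemetry data are time-stamped planar locations of a single tagged animal:
a record count ``n``, a non-decreasing vector of times and two coordinate
vectors in meters. All downstream modelling (bootstrapping, nearest-neighbor
regression, derived quantities) operates on these containers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Telemetry",
    "TimeGrid",
    "PathOnGrid",
    "read_telemetry_csv",
    "make_grid",
    "write_path_csv",
    "read_path_csv",
]

#: mean Earth radius, used only for the optional lon/lat -> local meters flag
_EARTH_RADIUS_M = 6_371_000.0


class TelemetryInputError(ValueError):
    """Malformed telemetry or geometry input (bad column, row or value)."""


@dataclass(frozen=True)
class Telemetry:
    """Recorded locations of one animal: ``n`` rows of (time, x, y).

    Parameters
    ----------
    times
        Timestamps, non-decreasing after construction. Stored as plain
        floats in the unit of ingestion (``time_unit`` metadata); ISO
        timestamps are normalized to minutes since the earliest record.
    coord1, coord2
        Planar coordinates in meters.
    time_unit
        Unit label recorded at ingestion ("minutes" or "seconds").
    """

    times: np.ndarray
    coord1: np.ndarray
    coord2: np.ndarray
    time_unit: str = "minutes"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        c1 = np.asarray(self.coord1, dtype=float)
        c2 = np.asarray(self.coord2, dtype=float)
        if times.ndim != 1 or times.size < 1:
            raise TelemetryInputError("telemetry needs at least one record")
        if c1.shape != times.shape or c2.shape != times.shape:
            raise TelemetryInputError(
                "coordinate vectors must match the time vector length"
            )
        if not (np.isfinite(times).all() and np.isfinite(c1).all() and np.isfinite(c2).all()):
            raise TelemetryInputError("telemetry contains non-finite values")
        if np.any(np.diff(times) < 0):
            # stable sort keeps file order among equal timestamps
            order = np.argsort(times, kind="stable")
            times, c1, c2 = times[order], c1[order], c2[order]
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "coord1", c1)
        object.__setattr__(self, "coord2", c2)

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def time_range(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def coords(self) -> np.ndarray:
        """Return the n x 2 coordinate matrix."""
        return np.column_stack([self.coord1, self.coord2])


@dataclass(frozen=True)
class TimeGrid:
    """A strictly increasing time grid with a maximum-spacing guarantee."""

    points: np.ndarray
    max_spacing: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size < 1:
            raise ValueError("grid needs at least one point")
        if not np.isfinite(pts).all():
            raise ValueError("grid contains non-finite times")
        diffs = np.diff(pts)
        if np.any(diffs <= 0):
            raise ValueError("grid times must be strictly increasing")
        if self.max_spacing <= 0:
            raise ValueError("max_spacing must be positive")
        if diffs.size and diffs.max() > self.max_spacing * (1 + 1e-12):
            raise ValueError("grid spacing exceeds max_spacing")
        object.__setattr__(self, "points", pts)

    @property
    def m(self) -> int:
        return int(self.points.size)

    @classmethod
    def from_points(cls, points: np.ndarray) -> "TimeGrid":
        """Build a grid from explicit points; max_spacing set to the largest gap."""
        pts = np.asarray(points, dtype=float)
        spacing = float(np.diff(pts).max()) if pts.size > 1 else 1.0
        return cls(pts, spacing)

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.points)
        if d.size == 0:
            return True
        return bool(np.allclose(d, d[0], rtol=rtol, atol=rtol * max(abs(d[0]), 1.0)))


@dataclass(frozen=True)
class PathOnGrid:
    """A continuous movement path evaluated on a time grid (meters)."""

    grid: TimeGrid
    coord1: np.ndarray
    coord2: np.ndarray

    def __post_init__(self) -> None:
        c1 = np.asarray(self.coord1, dtype=float)
        c2 = np.asarray(self.coord2, dtype=float)
        if c1.shape != self.grid.points.shape or c2.shape != self.grid.points.shape:
            raise ValueError("path coordinate vectors must match the grid length")
        if not (np.isfinite(c1).all() and np.isfinite(c2).all()):
            raise ValueError("path contains non-finite coordinates")
        object.__setattr__(self, "coord1", c1)
        object.__setattr__(self, "coord2", c2)

    @property
    def times(self) -> np.ndarray:
        return self.grid.points

    def position_at(self, t: float, snap_tol: float | None = None) -> np.ndarray:
        """Position at the grid point nearest ``t`` (within ``snap_tol``).

        Derived quantities are defined on the fitted grid, so time queries
        snap to the nearest grid point; the default tolerance is half the
        grid's max spacing.
        """
        pts = self.grid.points
        if snap_tol is None:
            snap_tol = self.grid.max_spacing / 2.0
        j = int(np.clip(np.searchsorted(pts, t), 0, pts.size - 1))
        if j > 0 and abs(pts[j - 1] - t) <= abs(pts[j] - t):
            j -= 1
        if abs(pts[j] - t) > snap_tol * (1 + 1e-9):
            raise ValueError(
                f"time {t} is {abs(pts[j] - t):.6g} from the nearest grid point, "
                f"beyond the snap tolerance {snap_tol:.6g}"
            )
        return np.array([self.coord1[j], self.coord2[j]])


def _lonlat_to_local_meters(lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local equirectangular projection about the mean location."""
    lon0, lat0 = float(np.mean(lon)), float(np.mean(lat))
    x = np.radians(lon - lon0) * _EARTH_RADIUS_M * math.cos(math.radians(lat0))
    y = np.radians(lat - lat0) * _EARTH_RADIUS_M
    return x, y


def read_telemetry_csv(
    path,
    time_col: str = "time",
    x_col: str = "coord1",
    y_col: str = "coord2",
    time_unit: str = "minutes",
    lonlat: bool = False,
) -> Telemetry:
    """Read a telemetry table from CSV.

    Parameters
    ----------
    time_unit
        ``"minutes"`` or ``"seconds"`` for numeric time columns, or
        ``"iso8601"`` for timestamp strings, which are converted to minutes
        since the earliest record.
    lonlat
        If True, the coordinate columns are longitude/latitude in degrees and
        are converted to local planar meters with an equirectangular
        projection about the mean location.
    """
    df = pd.read_csv(path)
    for col in (time_col, x_col, y_col):
        if col not in df.columns:
            raise TelemetryInputError(f"missing column {col!r} in {path}")

    if time_unit == "iso8601":
        parsed = pd.to_datetime(df[time_col], errors="coerce", format="mixed")
        bad = np.nonzero(parsed.isna().to_numpy())[0]
        if bad.size:
            raise TelemetryInputError(
                f"unparseable timestamp at data row {bad[0] + 1} in {path}"
            )
        times = (parsed - parsed.min()).dt.total_seconds().to_numpy() / 60.0
        unit = "minutes"
    elif time_unit in ("minutes", "seconds"):
        times = pd.to_numeric(df[time_col], errors="coerce").to_numpy(dtype=float)
        unit = time_unit
    else:
        raise TelemetryInputError(f"unknown time_unit {time_unit!r}")

    x = pd.to_numeric(df[x_col], errors="coerce").to_numpy(dtype=float)
    y = pd.to_numeric(df[y_col], errors="coerce").to_numpy(dtype=float)
    for name, vec in ((time_col, times), (x_col, x), (y_col, y)):
        bad = np.nonzero(~np.isfinite(vec))[0]
        if bad.size:
            raise TelemetryInputError(
                f"non-finite or empty value in column {name!r} "
                f"at data row {bad[0] + 1} in {path}"
            )
    if lonlat:
        x, y = _lonlat_to_local_meters(x, y)
    return Telemetry(times, x, y, time_unit=unit)


def write_telemetry_csv(telemetry: Telemetry, dest) -> None:
    """Write a telemetry table (columns time, coord1, coord2)."""
    pd.DataFrame(
        {"time": telemetry.times, "coord1": telemetry.coord1, "coord2": telemetry.coord2}
    ).to_csv(dest, index=False, float_format="%.10g")


def make_grid(telemetry: Telemetry, step: float) -> TimeGrid:
    """Build a uniform grid over the telemetry time span.

    The grid starts at the first record time and advances by ``step``; the
    last record time is always included as the final point, so the grid never
    extrapolates beyond the data range.
    """
    if step <= 0:
        raise ValueError("grid step must be positive")
    if telemetry.n < 2:
        raise ValueError("need at least two records to build a grid")
    t0, t1 = telemetry.time_range
    pts = np.arange(t0, t1, step)
    if pts.size == 0 or t1 - pts[-1] > 1e-12 * max(abs(t1), 1.0):
        pts = np.append(pts, t1)
    return TimeGrid(pts, max_spacing=step)


def write_path_csv(path_on_grid: PathOnGrid, dest, intervals=None) -> None:
    """Write a fitted path (and optional interval bounds) to CSV.

    ``intervals`` is an optional mapping with keys lower1, upper1, lower2,
    upper2, each a vector of the grid length.
    """
    if path_on_grid.grid.m < 1:
        raise ValueError("cannot write an empty path")
    data = {
        "time": path_on_grid.times,
        "coord1": path_on_grid.coord1,
        "coord2": path_on_grid.coord2,
    }
    if intervals is not None:
        for key in ("lower1", "upper1", "lower2", "upper2"):
            data[key] = np.asarray(intervals[key], dtype=float)
    pd.DataFrame(data).to_csv(dest, index=False, float_format="%.12g")


def read_path_csv(src) -> PathOnGrid:
    """Read a path written by :func:`write_path_csv`."""
    df = pd.read_csv(src)
    for col in ("time", "coord1", "coord2"):
        if col not in df.columns:
            raise TelemetryInputError(f"missing column {col!r} in {src}")
    grid = TimeGrid.from_points(df["time"].to_numpy(dtype=float))
    return PathOnGrid(grid, df["coord1"].to_numpy(dtype=float), df["coord2"].to_numpy(dtype=float))
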