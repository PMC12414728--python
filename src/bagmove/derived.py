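"""Derived quantities: scalar summaries of a continuous movement path.

A fitted path is rarely the end product; ecological insight comes from
summaries such as net displacement over a day, average per-minute
displacement, or the proportion of the monitoring period spent within a
radius of infrastructure (roads, turbines, wetland edge). Point estimates
are computed on the bagged mean path; interval estimates come from the
distribution of the summary across the B bootstrap-member paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .bagging import BaggedModel
from .telemetry import PathOnGrid, TimeGrid

__all__ = [
    "FeatureGeometry",
    "DerivedResult",
    "Quantity",
    "displacement",
    "interval_displacements",
    "min_distance",
    "proportion_within",
    "derived_interval",
    "displacement_quantity",
    "mean_displacement_quantity",
    "proportion_within_quantity",
    "read_points_csv",
    "read_segments_csv",
]


@dataclass(frozen=True)
class FeatureGeometry:
    """Landscape features: points and/or polyline segments, in meters.

    Degenerate (zero-length) segments are treated as points.
    """

    points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    segments: np.ndarray = field(default_factory=lambda: np.empty((0, 2, 2)))

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        segs = np.asarray(self.segments, dtype=float).reshape(-1, 2, 2)
        if pts.size == 0 and segs.size == 0:
            raise ValueError("geometry needs at least one point or segment")
        if not (np.isfinite(pts).all() and np.isfinite(segs).all()):
            raise ValueError("geometry contains non-finite coordinates")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "segments", segs)


def read_points_csv(path, x_col: str = "x", y_col: str = "y") -> FeatureGeometry:
    """Read point features (one x,y row per feature)."""
    df = pd.read_csv(path)
    return FeatureGeometry(points=df[[x_col, y_col]].to_numpy(dtype=float))


def read_segments_csv(path, cols=("x1", "y1", "x2", "y2")) -> FeatureGeometry:
    """Read polyline segment features (x1,y1,x2,y2 per row)."""
    df = pd.read_csv(path)
    arr = df[list(cols)].to_numpy(dtype=float)
    return FeatureGeometry(segments=arr.reshape(-1, 2, 2))


def displacement(path: PathOnGrid, t_a: float, t_b: float) -> float:
    """Net displacement (meters): Euclidean distance between the path
    positions at the grid points nearest ``t_a`` and ``t_b``.

    This is straight-line displacement between the two instants, not path
    length travelled. Query times snap to the nearest grid point within half
    the grid spacing.
    """
    pa = path.position_at(t_a)
    pb = path.position_at(t_b)
    return float(np.hypot(*(pb - pa)))


def interval_displacements(path: PathOnGrid, boundaries) -> tuple[np.ndarray, float]:
    """Net displacement over each consecutive pair of boundary times.

    Returns the vector of displacements plus its arithmetic mean (e.g. the
    average minutely displacement when boundaries are minute marks).
    """
    boundaries = np.asarray(boundaries, dtype=float)
    if boundaries.size < 2:
        raise ValueError("need at least two boundary times")
    if np.any(np.diff(boundaries) <= 0):
        raise ValueError("boundary times must be strictly increasing")
    pos = np.array([path.position_at(t) for t in boundaries])
    d = np.hypot(*(np.diff(pos, axis=0).T))
    return d, float(d.mean())


def _point_segment_distances(xy: np.ndarray, segments: np.ndarray) -> np.ndarray:
    """Distances (q, s) from each query point to each segment, with endpoint
    clamping; zero-length segments degrade to point distances."""
    a = segments[:, 0]  # (s, 2)
    ab = segments[:, 1] - a  # (s, 2)
    denom = np.einsum("sd,sd->s", ab, ab)  # squared lengths
    ap = xy[:, None, :] - a[None, :, :]  # (q, s, 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.einsum("qsd,sd->qs", ap, ab) / denom
    t = np.clip(np.nan_to_num(t, nan=0.0), 0.0, 1.0)
    closest = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    diff = xy[:, None, :] - closest
    return np.sqrt(np.einsum("qsd,qsd->qs", diff, diff))


def min_distances(coords: np.ndarray, geometry: FeatureGeometry) -> np.ndarray:
    """Minimum feature distance for each row of an (n, 2) coordinate array."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    best = np.full(coords.shape[0], np.inf)
    if geometry.points.size:
        d = coords[:, None, :] - geometry.points[None, :, :]
        best = np.minimum(best, np.sqrt(np.einsum("qpd,qpd->qp", d, d)).min(axis=1))
    if geometry.segments.size:
        best = np.minimum(
            best, _point_segment_distances(coords, geometry.segments).min(axis=1)
        )
    return best


def min_distance(point, geometry: FeatureGeometry) -> float:
    """Shortest Euclidean distance from a point to any feature."""
    return float(min_distances(np.asarray(point, dtype=float).reshape(1, 2), geometry)[0])


def proportion_within(path: PathOnGrid, geometry: FeatureGeometry, r: float) -> float:
    """Proportion of time the path spends within radius r of any feature.

    Computed as the fraction of grid points at feature distance <= r; on a
    uniform grid this is the time fraction (Riemann approximation, exact as
    the grid spacing shrinks).
    """
    if r < 0:
        raise ValueError("radius must be non-negative")
    if not path.grid.is_uniform(rtol=1e-3):
        raise ValueError(
            "proportion_within requires a (near-)uniform grid; resample the "
            "path onto a uniform grid first"
        )
    d = min_distances(np.column_stack([path.coord1, path.coord2]), geometry)
    return float(np.mean(d <= r))


@dataclass(frozen=True)
class Quantity:
    """A named scalar functional of a path, with the grid it is evaluated on.

    ``batch``, when provided, evaluates the functional on a whole stack of
    paths at once: it maps an (n_paths, grid.m, 2) coordinate array (on this
    quantity's grid) to n_paths values, and must agree with ``func``.
    """

    name: str
    func: Callable[[PathOnGrid], float]
    grid: TimeGrid
    r: float | None = None
    batch: Callable[[np.ndarray], np.ndarray] | None = None
    # optional per-component view (e.g. per-minute displacements underlying
    # an average): component_func on a path -> (C,) truths, component_batch
    # on an (n_paths, m, 2) stack -> (n_paths, C) values
    component_func: Callable[[PathOnGrid], np.ndarray] | None = None
    component_batch: Callable[[np.ndarray], np.ndarray] | None = None

    def __call__(self, path: PathOnGrid) -> float:
        return float(self.func(path))

    def evaluate_stack(self, preds: np.ndarray) -> np.ndarray:
        """Functional of each path in an (n_paths, m, 2) prediction stack."""
        if self.batch is not None:
            return np.asarray(self.batch(preds), dtype=float)
        return np.array(
            [self.func(PathOnGrid(self.grid, p[:, 0], p[:, 1])) for p in preds]
        )


def displacement_quantity(name: str, t_a: float, t_b: float) -> Quantity:
    """Net displacement between two instants (e.g. day boundaries)."""
    grid = TimeGrid.from_points(np.array([t_a, t_b], dtype=float))
    return Quantity(
        name,
        lambda p: displacement(p, t_a, t_b),
        grid,
        batch=lambda preds: np.hypot(*(preds[:, 1, :] - preds[:, 0, :]).T),
    )


def mean_displacement_quantity(name: str, boundaries) -> Quantity:
    """Average displacement across consecutive boundary times.

    Exposes the per-interval displacements as components, so an evaluation
    can also summarize coverage interval-by-interval (e.g. for every minute
    of the monitoring period) rather than only for the average.
    """
    boundaries = np.asarray(boundaries, dtype=float)
    grid = TimeGrid.from_points(boundaries)
    return Quantity(
        name,
        lambda p: interval_displacements(p, boundaries)[1],
        grid,
        batch=lambda preds: np.linalg.norm(np.diff(preds, axis=1), axis=2).mean(axis=1),
        component_func=lambda p: interval_displacements(p, boundaries)[0],
        component_batch=lambda preds: np.linalg.norm(np.diff(preds, axis=1), axis=2),
    )


def proportion_within_quantity(
    name: str, geometry: FeatureGeometry, r: float, grid: TimeGrid
) -> Quantity:
    """Proportion of time within radius r of features, on a uniform grid."""
    if not grid.is_uniform(rtol=1e-3):
        raise ValueError("proportion_within needs a uniform evaluation grid")

    def batch(preds: np.ndarray) -> np.ndarray:
        flat = preds.reshape(-1, 2)
        d = min_distances(flat, geometry).reshape(preds.shape[0], preds.shape[1])
        return (d <= r).mean(axis=1)

    return Quantity(name, lambda p: proportion_within(p, geometry, r), grid, r=r, batch=batch)


@dataclass(frozen=True)
class DerivedResult:
    """Point estimate and ensemble percentile interval for one quantity.

    The point estimate is the functional of the bagged mean path; bounds are
    empirical quantiles of the functional across the B member paths, so the
    point estimate need not lie inside the interval (though it typically
    does).
    """

    name: str
    estimate: float
    lower: float
    upper: float
    level: float
    ensemble_values: np.ndarray
    r: float | None = None

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")

    def covers(self, truth: float) -> bool:
        return bool(self.lower <= truth <= self.upper)


def derived_interval(
    model: BaggedModel,
    quantity: Quantity,
    level: float = 0.95,
    point: str = "mean_path",
    allow_extrapolation: bool = False,
) -> DerivedResult:
    """Estimate a derived quantity with an ensemble percentile interval.

    The functional is evaluated on each of the B per-bootstrap member paths;
    the interval is the empirical (1-level)/2 .. (1+level)/2 quantile range
    (linear interpolation). ``point`` selects the point estimate: the
    functional of the bagged mean path (default) or the ensemble median.
    """
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    if model.B < 2:
        raise ValueError("need B >= 2 ensemble members for an interval")
    from .bagging import _check_grid_range

    _check_grid_range(model, quantity.grid, allow_extrapolation)
    preds = model.member_predictions(quantity.grid.points)
    return result_from_stack(quantity, preds, level=level, point=point)


def result_from_stack(
    quantity: Quantity, preds: np.ndarray, level: float = 0.95, point: str = "mean_path"
) -> DerivedResult:
    """Build a DerivedResult from an (B, m, 2) ensemble prediction stack."""
    values = quantity.evaluate_stack(preds)
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(values, [alpha, 1.0 - alpha])
    if point == "mean_path":
        # the ensemble mean over the stack IS the bagged mean path
        est = float(quantity.evaluate_stack(preds.mean(axis=0, keepdims=True))[0])
    elif point == "ensemble_median":
        est = float(np.median(values))
    else:
        raise ValueError(f"unknown point estimator {point!r}")
    return DerivedResult(
        quantity.name, est, float(lower), float(upper), level, values, r=quantity.r
    )
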