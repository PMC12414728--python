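"""Bagged (bootstrap-aggregated) movement model.

Fits B nearest-neighbor learners, one per bootstrap resample of the
telemetry, and aggregates them into:

* a bagged expected movement path (pointwise ensemble mean on a time grid),
* an out-of-bag (OOB) residual pool giving an honest estimate of prediction
  error at recorded locations,
* OOB-based prediction intervals for location at any grid time, and
* path realizations drawn from the predictive distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bootstrap import BootstrapSample, default_n_blocks, draw_blocked, draw_iid
from .learners import LearnerSpec, _sorted_window_predict
from .telemetry import PathOnGrid, Telemetry, TimeGrid

__all__ = [
    "BaggedModel",
    "ResidualPool",
    "IntervalPath",
    "fit",
    "predict_mean",
    "oob_residual_pool",
    "prediction_interval",
    "sample_realizations",
]

DEFAULT_B = 100


@dataclass(frozen=True)
class ResidualPool:
    """OOB residuals (observed minus aggregated OOB prediction), per coordinate.

    One entry per telemetry row that was out-of-bag in at least one bootstrap
    sample; the cross-coordinate pairing of each row is preserved.
    """

    residuals1: np.ndarray
    residuals2: np.ndarray
    covered_rows: np.ndarray

    @property
    def size(self) -> int:
        return int(self.residuals1.size)


@dataclass(frozen=True)
class IntervalPath:
    """A bagged mean path with pointwise prediction-interval bounds."""

    center: PathOnGrid
    lower1: np.ndarray
    upper1: np.ndarray
    lower2: np.ndarray
    upper2: np.ndarray
    level: float

    def __post_init__(self) -> None:
        if not (0 < self.level < 1):
            raise ValueError("level must be in (0, 1)")
        for lo, c, hi in (
            (self.lower1, self.center.coord1, self.upper1),
            (self.lower2, self.center.coord2, self.upper2),
        ):
            if np.any(lo > c + 1e-9) or np.any(hi < c - 1e-9):
                raise ValueError("interval bounds must bracket the center path")

    def contains(self, coord1: np.ndarray, coord2: np.ndarray) -> np.ndarray:
        """Pointwise joint containment of a reference path (both coordinates)."""
        return (
            (self.lower1 <= coord1)
            & (coord1 <= self.upper1)
            & (self.lower2 <= coord2)
            & (coord2 <= self.upper2)
        )


@dataclass(frozen=True)
class BaggedModel:
    """B fitted learners on bootstrap resamples of one telemetry table."""

    telemetry: Telemetry
    learner: LearnerSpec
    samples: tuple[BootstrapSample, ...]
    # per member: (in-bag times sorted, in-bag (n,2) coords in the same order)
    member_states: tuple[tuple[np.ndarray, np.ndarray], ...]
    scheme: str = "iid"
    n_blocks: int = 1

    @property
    def B(self) -> int:
        return len(self.samples)

    def member_predictions(self, times: np.ndarray) -> np.ndarray:
        """Ensemble predictions at arbitrary times: array (B, len(times), 2)."""
        times = np.asarray(times, dtype=float)
        weighted = self.learner.kind == "weighted_knn"
        out = np.empty((self.B, times.size, 2))
        for b, (t_sorted, v_sorted) in enumerate(self.member_states):
            out[b] = _sorted_window_predict(
                t_sorted, v_sorted, self.learner.k, times, weighted=weighted
            )
        return out

    def member_paths(self, grid: TimeGrid) -> list[PathOnGrid]:
        preds = self.member_predictions(grid.points)
        return [PathOnGrid(grid, preds[b, :, 0], preds[b, :, 1]) for b in range(self.B)]


def fit(
    telemetry: Telemetry,
    learner: LearnerSpec,
    B: int = DEFAULT_B,
    scheme: str = "iid",
    n_blocks: int | None = None,
    rng: np.random.Generator | None = None,
) -> BaggedModel:
    """Fit the bagged movement model.

    Parameters
    ----------
    scheme
        ``"iid"`` for the conventional bootstrap, ``"blocked"`` for the
        within-block stratified bootstrap over contiguous time blocks.
    n_blocks
        Block count for the blocked scheme; defaults to a target block size
        of ~20 records.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    if scheme not in ("iid", "blocked"):
        raise ValueError(f"unknown bootstrap scheme {scheme!r}")
    if learner.k > telemetry.n:
        raise ValueError(f"k={learner.k} exceeds n={telemetry.n}")
    if rng is None:
        rng = np.random.default_rng()
    if n_blocks is None:
        n_blocks = default_n_blocks(telemetry.n)

    times = telemetry.times
    coords = telemetry.coords()
    samples: list[BootstrapSample] = []
    states: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(B):
        s = (
            draw_blocked(times, n_blocks, rng)
            if scheme == "blocked"
            else draw_iid(telemetry.n, rng)
        )
        idx = s.indices
        order = np.argsort(times[idx], kind="stable")
        samples.append(s)
        states.append((times[idx][order], coords[idx][order]))
    return BaggedModel(
        telemetry, learner, tuple(samples), tuple(states), scheme=scheme, n_blocks=n_blocks
    )


def _check_grid_range(model: BaggedModel, grid: TimeGrid, allow_extrapolation: bool) -> None:
    t0, t1 = model.telemetry.time_range
    if allow_extrapolation:
        return
    if grid.points[0] < t0 - 1e-9 or grid.points[-1] > t1 + 1e-9:
        raise ValueError(
            f"grid [{grid.points[0]}, {grid.points[-1]}] extends beyond the "
            f"telemetry range [{t0}, {t1}]; pass allow_extrapolation=True to "
            "evaluate the (constant) nearest-neighbor extension"
        )


def predict_mean(
    model: BaggedModel, grid: TimeGrid, allow_extrapolation: bool = False
) -> PathOnGrid:
    """Bagged expected path: pointwise mean of the B member paths."""
    _check_grid_range(model, grid, allow_extrapolation)
    mean = model.member_predictions(grid.points).mean(axis=0)
    return PathOnGrid(grid, mean[:, 0], mean[:, 1])


def oob_residual_pool(model: BaggedModel) -> ResidualPool:
    """Aggregated OOB residuals: observed minus mean-over-members-where-OOB.

    One residual pair per telemetry row left out of at least one bootstrap
    sample (aggregation first, then a single residual per row).
    """
    n = model.telemetry.n
    times = model.telemetry.times
    pred_sum = np.zeros((n, 2))
    pred_cnt = np.zeros(n)
    weighted = model.learner.kind == "weighted_knn"
    for s, (t_sorted, v_sorted) in zip(model.samples, model.member_states):
        if s.oob.size == 0:
            continue
        pred_sum[s.oob] += _sorted_window_predict(
            t_sorted, v_sorted, model.learner.k, times[s.oob], weighted=weighted
        )
        pred_cnt[s.oob] += 1
    covered = np.nonzero(pred_cnt > 0)[0]
    if covered.size == 0:
        raise ValueError(
            "no telemetry row was out-of-bag in any bootstrap sample; "
            "increase the ensemble size B"
        )
    agg = pred_sum[covered] / pred_cnt[covered, None]
    obs = model.telemetry.coords()[covered]
    resid = obs - agg
    return ResidualPool(resid[:, 0], resid[:, 1], covered)


def prediction_interval(
    model: BaggedModel,
    grid: TimeGrid,
    level: float = 0.95,
    pool: ResidualPool | None = None,
    allow_extrapolation: bool = False,
) -> IntervalPath:
    """OOB-residual prediction interval for location at each grid time.

    Per coordinate, bounds are the bagged mean shifted by the empirical
    (1-level)/2 and (1+level)/2 quantiles of the OOB residual pool
    (linear-interpolation quantiles).
    """
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    if pool is None:
        pool = oob_residual_pool(model)
    center = predict_mean(model, grid, allow_extrapolation=allow_extrapolation)
    alpha = (1.0 - level) / 2.0
    q1 = np.quantile(pool.residuals1, [alpha, 1.0 - alpha])
    q2 = np.quantile(pool.residuals2, [alpha, 1.0 - alpha])
    # residual quantiles of either sign; clip so bounds bracket the center
    lo1, hi1 = min(q1[0], 0.0), max(q1[1], 0.0)
    lo2, hi2 = min(q2[0], 0.0), max(q2[1], 0.0)
    return IntervalPath(
        center,
        center.coord1 + lo1,
        center.coord1 + hi1,
        center.coord2 + lo2,
        center.coord2 + hi2,
        level,
    )


def sample_realizations(
    model: BaggedModel,
    grid: TimeGrid,
    mode: str = "ensemble",
    M: int = 10,
    rng: np.random.Generator | None = None,
    allow_extrapolation: bool = False,
) -> list[PathOnGrid]:
    """Realizations of potential paths from the predictive distribution.

    ``ensemble`` mode returns the first M per-bootstrap member paths
    (deterministic); ``oob_perturbed`` returns the bagged mean path plus
    residual pairs resampled with replacement from the OOB pool at each grid
    time, preserving each pooled row's (coord1, coord2) pairing.
    """
    _check_grid_range(model, grid, allow_extrapolation)
    if mode == "ensemble":
        if M > model.B:
            raise ValueError(f"M={M} exceeds ensemble size B={model.B}")
        preds = model.member_predictions(grid.points)
        return [PathOnGrid(grid, preds[b, :, 0], preds[b, :, 1]) for b in range(M)]
    if mode == "oob_perturbed":
        if rng is None:
            rng = np.random.default_rng()
        pool = oob_residual_pool(model)
        center = predict_mean(model, grid, allow_extrapolation=allow_extrapolation)
        out = []
        for _ in range(M):
            rows = rng.integers(0, pool.size, size=grid.m)
            out.append(
                PathOnGrid(
                    grid,
                    center.coord1 + pool.residuals1[rows],
                    center.coord2 + pool.residuals2[rows],
                )
            )
        return out
    raise ValueError(f"unknown realization mode {mode!r}")
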