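"""Time -> coordinate regressors behind a uniform plugin interface.

Two k-nearest-neighbor variants are provided: the plain KNN regressor
(unweighted mean of the k temporally nearest records) and an
inverse-distance-weighted variant that upweights nearer neighbors. Because
the feature is one-dimensional (time), the k nearest neighbors always form a
contiguous window in time order, so predictions are computed with a
vectorized sliding-window search rather than a generic neighbor index.

Tie-breaking is fixed so results are byte-reproducible: distance ties are
broken in favor of the earlier time, then the lower row index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bootstrap import default_n_blocks, draw_blocked, draw_iid
from .telemetry import Telemetry

__all__ = [
    "LearnerSpec",
    "FittedLearner",
    "knn_predict",
    "weighted_knn_predict",
    "select_k",
    "LEARNER_KINDS",
]

LEARNER_KINDS = ("knn", "weighted_knn")

#: default neighbor count when select_k is not invoked
DEFAULT_K = 5


def _neighbor_indices(sorted_times: np.ndarray, k: int, queries: np.ndarray) -> np.ndarray:
    """Indices (q, k) of the k nearest training rows for each query.

    The training array is sorted by (time, original index), so the k nearest
    rows form (up to equal-time runs) a contiguous window. The window with
    the smallest worst-case distance gives the k-th neighbor distance d*;
    the window is then aligned so it contains every row strictly nearer than
    d*, and any equal-time run cut by the window is taken as its lowest-index
    prefix. This realizes the tie-break: distance ties go to the earlier
    time, then the lower row index.
    """
    n = sorted_times.size
    q = queries.size
    rows = np.arange(q)
    if k > n:
        raise ValueError(f"k={k} exceeds training size {n}")
    pos = np.searchsorted(sorted_times, queries, side="left")
    if k == n:
        s1 = np.zeros(q, dtype=np.intp)
    else:
        lo = np.clip(pos - k, 0, n - k)
        hi = np.clip(pos, 0, n - k)
        cand = np.minimum(lo[:, None] + np.arange(k + 1)[None, :], hi[:, None])
        cost = np.maximum(
            queries[:, None] - sorted_times[cand],
            sorted_times[cand + (k - 1)] - queries[:, None],
        )
        best = np.argmin(cost, axis=1)  # first minimum -> leftmost window
        s1 = cand[rows, best]
        dstar = cost[rows, best]
        # align the window to contain all rows strictly nearer than d*
        # (a leftmost window can exclude them across an equal-time run)
        r0 = np.maximum(s1 - k, 0)
        scan = r0[:, None] + np.arange(3 * k)[None, :]
        inb = scan < n
        inner = (
            np.abs(sorted_times[np.minimum(scan, n - 1)] - queries[:, None])
            < dstar[:, None]
        ) & inb
        has_inner = inner.any(axis=1)
        i1 = r0 + (3 * k - 1) - np.argmax(inner[:, ::-1], axis=1)
        s1 = np.where(has_inner, np.maximum(s1, i1 - k + 1), s1)
    # lowest-index prefix of the equal-time run cut at the window's left edge
    t_left = sorted_times[s1]
    a_l = np.searchsorted(sorted_times, t_left, side="left")
    b_l = np.searchsorted(sorted_times, t_left, side="right")
    count_l = np.minimum(b_l - s1, k)
    ar = np.arange(k)[None, :]
    return np.where(
        ar < count_l[:, None],
        a_l[:, None] + ar,
        b_l[:, None] + (ar - count_l[:, None]),
    )


def _sorted_window_predict(
    sorted_times: np.ndarray,
    sorted_values: np.ndarray,
    k: int,
    queries: np.ndarray,
    weighted: bool = False,
) -> np.ndarray:
    """Predict at ``queries`` given training data pre-sorted by time.

    ``sorted_values`` may be (n,) or (n, c) for c response columns sharing
    the same neighbor structure.
    """
    queries = np.atleast_1d(np.asarray(queries, dtype=float))
    idx = _neighbor_indices(sorted_times, k, queries)
    vals = sorted_values[idx]  # (q, k) or (q, k, c)
    if not weighted:
        return vals.mean(axis=1)
    dist = np.abs(sorted_times[idx] - queries[:, None])  # (q, k)
    zero = dist == 0.0
    any_zero = zero.any(axis=1)
    with np.errstate(divide="ignore"):
        w = np.where(zero, 0.0, 1.0 / np.where(zero, 1.0, dist))
    # rows with an exact time match interpolate: unweighted mean of the
    # zero-distance neighbors only
    w[any_zero] = zero[any_zero].astype(float)
    w /= w.sum(axis=1, keepdims=True)
    if vals.ndim == 3:
        return np.einsum("qk,qkc->qc", w, vals)
    return np.einsum("qk,qk->q", w, vals)


@dataclass(frozen=True)
class LearnerSpec:
    """Learner choice: algorithm kind and neighbor count k."""

    kind: str = "knn"
    k: int = DEFAULT_K

    def __post_init__(self) -> None:
        if self.kind not in LEARNER_KINDS:
            raise ValueError(f"unknown learner kind {self.kind!r}; options: {LEARNER_KINDS}")
        if self.k < 1:
            raise ValueError("k must be at least 1")

    def fit(self, times: np.ndarray, values: np.ndarray) -> "FittedLearner":
        """Fit on training rows (values may be (n,) or (n, c))."""
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if times.size == 0:
            raise ValueError("empty training set")
        if self.k > times.size:
            raise ValueError(f"k={self.k} exceeds training size {times.size}")
        order = np.argsort(times, kind="stable")
        return FittedLearner(self, times[order], values[order])


@dataclass(frozen=True)
class FittedLearner:
    """A fitted learner state: training rows sorted by time."""

    spec: LearnerSpec
    times_sorted: np.ndarray
    values_sorted: np.ndarray

    def predict(self, queries: np.ndarray) -> np.ndarray:
        return _sorted_window_predict(
            self.times_sorted,
            self.values_sorted,
            self.spec.k,
            queries,
            weighted=self.spec.kind == "weighted_knn",
        )


def knn_predict(train_times, train_values, k: int, query: float) -> float:
    """Mean of the k training values temporally nearest to ``query``."""
    fitted = LearnerSpec("knn", k).fit(train_times, train_values)
    return float(fitted.predict(np.array([query]))[0])


def weighted_knn_predict(train_times, train_values, k: int, query: float) -> float:
    """Inverse-distance-weighted mean of the k temporally nearest values.

    A neighbor at zero distance short-circuits to the unweighted mean of all
    zero-distance neighbors (exact interpolation at training times).
    """
    fitted = LearnerSpec("weighted_knn", k).fit(train_times, train_values)
    return float(fitted.predict(np.array([query]))[0])


def select_k(
    telemetry: Telemetry,
    k_grid,
    B: int = 20,
    scheme: str = "blocked",
    n_blocks: int | None = None,
    rng: np.random.Generator | None = None,
    kind: str = "knn",
) -> int:
    """Choose k by pooled out-of-bag RMSE over both coordinates.

    For each candidate k a small bagged ensemble (the same B bootstrap
    samples for every k, for a paired comparison) is fit; each record's OOB
    prediction is the average over ensemble members that left it out, and the
    k minimizing the pooled root-mean-square OOB residual is returned (ties
    go to the smallest k).
    """
    k_grid = sorted(set(int(k) for k in np.atleast_1d(k_grid)))
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    n = telemetry.n
    for k in k_grid:
        if not (1 <= k <= n):
            raise ValueError(f"k={k} invalid for n={n}")
    if len(k_grid) == 1:
        return k_grid[0]
    if rng is None:
        rng = np.random.default_rng()
    if n_blocks is None:
        n_blocks = default_n_blocks(n)

    times = telemetry.times
    coords = telemetry.coords()  # (n, 2)
    samples = [
        draw_blocked(times, n_blocks, rng) if scheme == "blocked" else draw_iid(n, rng)
        for _ in range(B)
    ]
    fitted_per_sample = []
    for s in samples:
        idx = s.indices
        order = np.argsort(times[idx], kind="stable")
        fitted_per_sample.append((times[idx][order], coords[idx][order], s.oob))

    best_k, best_rmse = None, np.inf
    for k in k_grid:
        pred_sum = np.zeros((n, 2))
        pred_cnt = np.zeros(n)
        for t_sorted, v_sorted, oob in fitted_per_sample:
            if oob.size == 0:
                continue
            pred_sum[oob] += _sorted_window_predict(
                t_sorted, v_sorted, k, times[oob], weighted=kind == "weighted_knn"
            )
            pred_cnt[oob] += 1
        covered = pred_cnt > 0
        if not covered.any():
            raise ValueError("no out-of-bag coverage; increase B")
        resid = coords[covered] - pred_sum[covered] / pred_cnt[covered, None]
        rmse = float(np.sqrt(np.mean(resid**2)))
        if rmse < best_rmse - 1e-15:
            best_k, best_rmse = k, rmse
    return int(best_k)
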