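"""Frequentist evaluation harness: bias and coverage probability by simulation.

For a scenario (true path x error level x sample size), the harness fixes
one true movement path, generates R independent telemetry datasets from it,
fits the bagged model to each, and summarizes each derived quantity by its
expected estimate, absolute bias and the coverage probability (CP) of its
confidence interval — the exact fraction of replicates whose interval
contains the truth.

Replicates draw from independent random streams spawned deterministically
from the scenario seed, so results do not depend on execution order and
extending R leaves earlier replicates unchanged.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bagging
from .derived import (
    FeatureGeometry,
    Quantity,
    derived_interval,
    displacement_quantity,
    mean_displacement_quantity,
    proportion_within_quantity,
    result_from_stack,
)
from .learners import LearnerSpec, select_k
from .simulate import (
    AbruptPathConfig,
    CirclesPathConfig,
    ErrorModel,
    abrupt_path,
    abrupt_roadways,
    circles_path,
    circles_turbines,
    sample_telemetry,
)
from .telemetry import PathOnGrid, TimeGrid

__all__ = [
    "QuantitySpec",
    "Scenario",
    "QuantityResult",
    "EvaluationReport",
    "run_scenario",
    "format_report",
    "table1_scenarios",
    "table2_scenarios",
]

_GEOMETRIES = {"roadways": abrupt_roadways, "turbines": circles_turbines}


@dataclass(frozen=True)
class QuantitySpec:
    """Serializable description of one derived quantity to evaluate.

    kinds: ``displacement`` (params t_a, t_b), ``mean_displacement``
    (params boundaries as [start, stop, step]), ``proportion_within``
    (params r, geometry name or explicit arrays, grid_step for the
    evaluation grid).
    """

    name: str
    kind: str
    params: dict = field(default_factory=dict)

    def build(self, true_path: PathOnGrid) -> Quantity:
        p = self.params
        if self.kind == "displacement":
            return displacement_quantity(self.name, float(p["t_a"]), float(p["t_b"]))
        if self.kind == "mean_displacement":
            start, stop, step = p["boundaries"]
            bounds = np.arange(float(start), float(stop) + float(step) / 2, float(step))
            return mean_displacement_quantity(self.name, bounds)
        if self.kind == "proportion_within":
            geom = p["geometry"]
            geometry = _GEOMETRIES[geom]() if isinstance(geom, str) else FeatureGeometry(**geom)
            step = float(p.get("grid_step", true_path.grid.max_spacing))
            t = true_path.times
            pts = np.arange(t[0], t[-1] + step / 2, step)
            return proportion_within_quantity(
                self.name, geometry, float(p["r"]), TimeGrid(pts, step)
            )
        raise ValueError(f"unknown quantity kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {"name": self.name, "kind": self.kind, "params": self.params}


@dataclass(frozen=True)
class Scenario:
    """One cell of a simulation study: path, error level, n, model settings."""

    name: str
    path: str  # "abrupt" | "circles"
    error: str | ErrorModel  # preset name or explicit model
    n: int
    R: int = 500
    quantities: tuple[QuantitySpec, ...] = ()
    learner_kind: str = "knn"
    k: int | None = None
    k_grid: tuple[int, ...] | None = (3, 5, 9, 15)
    B: int = 100
    B_select: int = 20
    scheme: str = "blocked"
    n_blocks: int | None = None
    level: float = 0.95
    seed: int = 0
    path_config: dict = field(default_factory=dict)
    # interval construction for derived quantities: quantiles across the
    # bootstrap ensemble ("ensemble"), across OOB-residual-perturbed
    # realizations of the bagged mean path ("oob_perturbed"), or across
    # perturbed member paths combining both uncertainty sources
    # ("predictive")
    ci_mode: str = "ensemble"

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("R must be at least 1")
        if self.path not in ("abrupt", "circles"):
            raise ValueError(f"unknown path kind {self.path!r}")
        if self.ci_mode not in ("ensemble", "oob_perturbed", "predictive"):
            raise ValueError(f"unknown ci_mode {self.ci_mode!r}")
        if self.k is None and not self.k_grid:
            raise ValueError("need either a fixed k or a non-empty k_grid")
        object.__setattr__(self, "quantities", tuple(
            q if isinstance(q, QuantitySpec) else QuantitySpec(**q) for q in self.quantities
        ))
        if self.k_grid is not None:
            object.__setattr__(self, "k_grid", tuple(int(k) for k in self.k_grid))

    @property
    def error_model(self) -> ErrorModel:
        return ErrorModel.preset(self.error) if isinstance(self.error, str) else self.error

    def build_path_config(self):
        cls = AbruptPathConfig if self.path == "abrupt" else CirclesPathConfig
        return cls(**self.path_config)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["quantities"] = [q.to_dict() for q in self.quantities]
        if isinstance(self.error, ErrorModel):
            d["error"] = dataclasses.asdict(self.error)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        if isinstance(d.get("error"), dict):
            d["error"] = ErrorModel(**d["error"])
        d["quantities"] = tuple(
            QuantitySpec(**q) if isinstance(q, dict) else q for q in d.get("quantities", ())
        )
        if d.get("k_grid") is not None:
            d["k_grid"] = tuple(d["k_grid"])
        return cls(**d)


@dataclass
class QuantityResult:
    """Aggregated frequentist summary of one derived quantity."""

    name: str
    truth: float
    estimates: np.ndarray
    lowers: np.ndarray
    uppers: np.ndarray
    level: float
    # per-replicate coverage indicator; fractional when the quantity is
    # summarized component-wise (e.g. coverage over all minutes)
    covers: np.ndarray | None = None

    @property
    def mean_estimate(self) -> float:
        return float(np.mean(self.estimates))

    @property
    def abs_bias(self) -> float:
        return abs(self.truth - self.mean_estimate)

    @property
    def coverage(self) -> float:
        if self.covers is not None:
            return float(np.mean(self.covers))
        return float(np.mean((self.lowers <= self.truth) & (self.truth <= self.uppers)))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "truth": self.truth,
            "mean_estimate": self.mean_estimate,
            "abs_bias": self.abs_bias,
            "coverage": self.coverage,
            "level": self.level,
            "estimates": self.estimates.tolist(),
            "lowers": self.lowers.tolist(),
            "uppers": self.uppers.tolist(),
            "covers": None if self.covers is None else self.covers.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuantityResult":
        covers = d.get("covers")
        return cls(
            d["name"],
            d["truth"],
            np.asarray(d["estimates"], dtype=float),
            np.asarray(d["lowers"], dtype=float),
            np.asarray(d["uppers"], dtype=float),
            d["level"],
            covers=None if covers is None else np.asarray(covers, dtype=float),
        )


@dataclass
class EvaluationReport:
    """Results of one scenario: per-quantity summaries plus diagnostics."""

    scenario: dict
    results: dict[str, QuantityResult]
    diagnostics: dict = field(default_factory=dict)
    n_failed: int = 0

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "results": {k: v.to_dict() for k, v in self.results.items()},
            "diagnostics": self.diagnostics,
            "n_failed": self.n_failed,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(
            d["scenario"],
            {k: QuantityResult.from_dict(v) for k, v in d["results"].items()},
            d.get("diagnostics", {}),
            d.get("n_failed", 0),
        )

    @classmethod
    def from_json(cls, s: str) -> "EvaluationReport":
        return cls.from_dict(json.loads(s))


def run_scenario(
    scenario: Scenario, rng=None, progress: bool = False
) -> EvaluationReport:
    """Run a full simulation scenario.

    One true path is fixed from the scenario seed and shared by all R
    replicate datasets, so every quantity has a constant true value. Each
    replicate samples telemetry, selects k by OOB error (if a k_grid is
    given), fits the bagged model, and records each quantity's point
    estimate and confidence interval.

    ``rng`` is accepted for interface symmetry but the scenario seed governs
    all randomness (pass a different seed for a different run).
    """
    ss = np.random.SeedSequence(scenario.seed)
    children = ss.spawn(scenario.R + 1)
    path_rng = np.random.default_rng(children[0])
    config = scenario.build_path_config()
    true_path = (
        abrupt_path(config, path_rng) if scenario.path == "abrupt" else circles_path(config, path_rng)
    )
    error = scenario.error_model

    quantities = [spec.build(true_path) for spec in scenario.quantities]
    truths = {q.name: float(q(true_path)) for q in quantities}
    comp_truths = {
        q.name: np.asarray(q.component_func(true_path), dtype=float)
        for q in quantities
        if q.component_func is not None
    }

    # all quantity grids concatenated: one ensemble-prediction pass per
    # replicate, sliced per quantity
    slices, offset = [], 0
    for q in quantities:
        slices.append(slice(offset, offset + q.grid.m))
        offset += q.grid.m
    all_times = (
        np.concatenate([q.grid.points for q in quantities]) if quantities else np.empty(0)
    )

    per_q = {q.name: {"est": [], "lo": [], "hi": [], "cov": []} for q in quantities}
    alpha = (1.0 - scenario.level) / 2.0
    selected_ks: list[int] = []
    window_empty = 0
    n_failed = 0
    for r in range(scenario.R):
        rep_rng = np.random.default_rng(children[r + 1])
        try:
            tel = sample_telemetry(true_path, scenario.n, error, rep_rng)
            if scenario.path == "abrupt":
                in_window = np.sum(
                    (tel.times > config.t_move_start) & (tel.times < config.t_move_end)
                )
                window_empty += int(in_window == 0)
            if scenario.k is not None:
                k = scenario.k
            else:
                k_grid = [k for k in scenario.k_grid if k <= scenario.n]
                k = select_k(
                    tel,
                    k_grid,
                    B=scenario.B_select,
                    scheme=scenario.scheme,
                    n_blocks=scenario.n_blocks,
                    rng=rep_rng,
                    kind=scenario.learner_kind,
                )
            selected_ks.append(k)
            model = bagging.fit(
                tel,
                LearnerSpec(scenario.learner_kind, k),
                B=scenario.B,
                scheme=scenario.scheme,
                n_blocks=scenario.n_blocks,
                rng=rep_rng,
            )
            preds = model.member_predictions(all_times)
            center = preds.mean(axis=0)  # bagged mean path on all grids
            if scenario.ci_mode == "ensemble":
                stack = preds
            else:
                pool = bagging.oob_residual_pool(model)
                rows = rep_rng.integers(0, pool.size, size=(scenario.B, center.shape[0]))
                noise = np.stack([pool.residuals1[rows], pool.residuals2[rows]], axis=2)
                base = center[None, :, :] if scenario.ci_mode == "oob_perturbed" else preds
                stack = base + noise
            for q, sl in zip(quantities, slices):
                values = q.evaluate_stack(stack[:, sl, :])
                lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
                est = float(q.evaluate_stack(center[None, sl, :])[0])
                per_q[q.name]["est"].append(est)
                per_q[q.name]["lo"].append(float(lo))
                per_q[q.name]["hi"].append(float(hi))
                if q.component_batch is not None:
                    # component-wise coverage: one interval per component
                    # (e.g. per minute), averaged over components
                    comp = q.component_batch(stack[:, sl, :])
                    lo_c, hi_c = np.quantile(comp, [alpha, 1.0 - alpha], axis=0)
                    tc = comp_truths[q.name]
                    cov = float(np.mean((lo_c <= tc) & (tc <= hi_c)))
                else:
                    cov = float(lo <= truths[q.name] <= hi)
                per_q[q.name]["cov"].append(cov)
        except Exception:  # noqa: BLE001 - replicate failures are counted, not fatal
            n_failed += 1
        if progress and (r + 1) % 50 == 0:
            print(f"  [{scenario.name}] replicate {r + 1}/{scenario.R}")

    results = {
        name: QuantityResult(
            name,
            truths[name],
            np.asarray(v["est"]),
            np.asarray(v["lo"]),
            np.asarray(v["hi"]),
            scenario.level,
            covers=np.asarray(v["cov"]),
        )
        for name, v in per_q.items()
    }
    n_ok = scenario.R - n_failed
    diagnostics: dict = {
        "selected_k_counts": {
            int(k): int(c) for k, c in zip(*np.unique(selected_ks, return_counts=True))
        }
        if selected_ks
        else {},
    }
    if scenario.path == "abrupt":
        w = config.t_move_end - config.t_move_start
        diagnostics["dispersal_window_minutes"] = w
        diagnostics["prob_no_record_in_window"] = float(
            (1.0 - w / config.horizon) ** scenario.n
        )
        diagnostics["observed_frac_no_record_in_window"] = (
            window_empty / n_ok if n_ok else float("nan")
        )
    return EvaluationReport(
        scenario=scenario.to_dict(), results=results, diagnostics=diagnostics, n_failed=n_failed
    )


def _report_rows(reports) -> pd.DataFrame:
    if isinstance(reports, EvaluationReport):
        reports = [reports]
    rows = []
    for rep in reports:
        sc = rep.scenario
        for name, qr in rep.results.items():
            rows.append(
                {
                    "scenario": sc.get("name", ""),
                    "location_error": sc.get("error", ""),
                    "n": sc.get("n", ""),
                    "quantity": name,
                    "truth": qr.truth,
                    "mean_estimate": qr.mean_estimate,
                    "abs_bias": qr.abs_bias,
                    "CP": qr.coverage,
                }
            )
    return pd.DataFrame(rows)


def format_report(reports, style: str = "csv") -> str:
    """Render one report (or a list) as text.

    Styles: ``table1``/``table2`` (fixed-width summary table, one row per
    scenario with E[est] | |bias| | CP blocks per quantity), ``csv`` (long
    format), ``json`` (full round-trippable dump).
    """
    if style == "json":
        if isinstance(reports, EvaluationReport):
            return reports.to_json(indent=1)
        return json.dumps([r.to_dict() for r in reports], indent=1)
    df = _report_rows(reports)
    if style == "csv":
        buf = io.StringIO()
        df.to_csv(buf, index=False, float_format="%.6g")
        return buf.getvalue()
    if style in ("table1", "table2"):
        if df.empty:
            return "Location err. | n | quantity | E[est] | |bias| | CP\n"
        wide = df.pivot_table(
            index=["scenario", "location_error", "n"],
            columns="quantity",
            values=["mean_estimate", "abs_bias", "CP"],
            sort=False,
        )
        return wide.to_string(float_format=lambda x: f"{x:.4g}") + "\n"
    raise ValueError(f"unknown report style {style!r}")


# ---------------------------------------------------------------------------
# Bundled scenario grids mirroring the two simulation studies
# ---------------------------------------------------------------------------

_DAY = 1440.0


def _abrupt_quantities(include_proportion: bool = True) -> tuple[QuantitySpec, ...]:
    qs = [
        QuantitySpec("d8", "displacement", {"t_a": 7 * _DAY, "t_b": 8 * _DAY}),
    ]
    if include_proportion:
        qs.append(
            QuantitySpec(
                "p200",
                "proportion_within",
                {"r": 200.0, "geometry": "roadways", "grid_step": 5.0},
            )
        )
    return tuple(qs)


def _circles_quantities() -> tuple[QuantitySpec, ...]:
    return (
        QuantitySpec("dbar", "mean_displacement", {"boundaries": [0.0, 1500.0, 60.0]}),
        QuantitySpec(
            "p100",
            "proportion_within",
            {"r": 100.0, "geometry": "turbines", "grid_step": 1.0},
        ),
    )


def table1_scenarios(
    R: int = 500, seed: int = 20_25, include_proportion: bool = True
) -> list[Scenario]:
    """The 2x2 abrupt-stepwise grid: {high, low} error x n in {300, 100}."""
    out = []
    for i, (err, n) in enumerate([("high", 300), ("high", 100), ("low", 300), ("low", 100)]):
        out.append(
            Scenario(
                name=f"abrupt_{err}_n{n}",
                path="abrupt",
                error=err,
                n=n,
                R=R,
                quantities=_abrupt_quantities(include_proportion),
                learner_kind="knn",
                k_grid=(3, 5, 9, 15),
                B=100,
                scheme="blocked",
                seed=seed + i,
            )
        )
    return out


def table2_scenarios(R: int = 500, seed: int = 40_25) -> list[Scenario]:
    """The 2x2 drifting-circles grid: {high, low} error x n in {150, 30}."""
    out = []
    for i, (err, n) in enumerate([("high", 150), ("high", 30), ("low", 150), ("low", 30)]):
        out.append(
            Scenario(
                name=f"circles_{err}_n{n}",
                path="circles",
                error=err,
                n=n,
                R=R,
                quantities=_circles_quantities(),
                learner_kind="weighted_knn",
                k=3,
                k_grid=None,
                B=100,
                scheme="blocked",
                seed=seed + i,
            )
        )
    return out
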