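"""Post-processing summaries of a fitted exposure-response surface.

All summaries are quantile-based contrasts or slices of h:

* overall mixture effect ``delta = h(q_0.75 * 1) - h(q_0.25 * 1)`` — every
  exposure moved jointly between its marginal quartiles;
* overall effect curve — h with all exposures jointly at quantile ``q``,
  centered at the median (the value at q = 0.50 is identically zero);
* univariate and bivariate exposure-response functions — one exposure varied
  on a grid with the others held at their medians (bivariate: a second
  exposure conditioned at its 25th/50th/75th percentile);
* single-variable risks — per exposure, the 25th-to-75th percentile contrast
  with every other exposure fixed at a chosen quantile.

Each summary accepts either a fitted model (via :class:`FitEvaluator`,
posterior-credible intervals) or the true surface (via
:class:`OracleEvaluator`, exact values with degenerate intervals).  The
design-aware variants are produced by evaluating posterior-mean summaries
inside each bootstrap replicate and aggregating across replicates
(replication-based intervals); grids are shared with the naive fit so curves
are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .bkmr import PosteriorDraws, posterior_h
from .resample import AggregatedEstimate, ReplicateResult, aggregate_scalar

__all__ = [
    "FitEvaluator",
    "OracleEvaluator",
    "exposure_quantiles",
    "estimate_delta",
    "estimate_delta_replicates",
    "overall_effect_curve",
    "univariate_response",
    "bivariate_response",
    "single_variable_risks",
    "make_replicate_summarizer",
    "aggregate_replicate_curves",
]


def exposure_quantiles(z: np.ndarray, probs: Sequence[float]) -> np.ndarray:
    """Empirical (linear-interpolation) quantiles per exposure: (len(probs), m)."""
    probs = np.asarray(list(probs), dtype=float)
    if np.any(probs <= 0) or np.any(probs >= 1):
        raise ValueError("quantile levels must lie in (0, 1)")
    return np.quantile(np.atleast_2d(z), probs, axis=0)


@dataclass
class FitEvaluator:
    """Evaluate h draws from a fitted model at arbitrary query points."""

    draws: PosteriorDraws
    y: np.ndarray
    z: np.ndarray
    x: np.ndarray | None = None
    mode: str = "sample"
    seed: int = 0

    interval_kind = "posterior-credible"

    def h(self, z_query: np.ndarray) -> np.ndarray:
        return posterior_h(self.draws, self.y, self.z, z_query, x=self.x,
                           mode=self.mode, seed=self.seed)


@dataclass
class OracleEvaluator:
    """Evaluate the true surface directly (bypasses any fit; exact tests)."""

    h_fun: Callable[[np.ndarray], np.ndarray]

    interval_kind = "oracle"

    def h(self, z_query: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(self.h_fun(np.atleast_2d(z_query)),
                                        dtype=float))


def _summarize_draws(values: np.ndarray, interval_kind: str):
    """Mean and equal-tailed 95% bounds of a (T,) or (T, G) draw array."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    point = values.mean(axis=0)
    if values.shape[0] == 1:          # oracle / degenerate: zero-width interval
        return point, point.copy(), point.copy()
    lo, hi = np.percentile(values, [2.5, 97.5], axis=0)
    return point, lo, hi


def _delta_draws(evaluator, z_data, lower: float, upper: float) -> np.ndarray:
    q = exposure_quantiles(z_data, [lower, upper])
    h = evaluator.h(q)                 # (T, 2), jointly drawn
    return h[:, 1] - h[:, 0]


def estimate_delta(evaluator, z_data: np.ndarray, lower: float = 0.25,
                   upper: float = 0.75) -> AggregatedEstimate:
    """Overall mixture effect from a single fit (or the oracle surface)."""
    d = _delta_draws(evaluator, z_data, lower, upper)
    point, lo, hi = (float(v[0]) for v in _summarize_draws(d, evaluator.interval_kind))
    return AggregatedEstimate(point=point, lo=lo, hi=hi,
                              interval_kind=evaluator.interval_kind)


def estimate_delta_replicates(results: Sequence[ReplicateResult],
                              key: str = "delta") -> AggregatedEstimate:
    """Aggregate per-replicate posterior-mean deltas into a replication-based
    estimate."""
    return aggregate_scalar([r.summaries[key] for r in results],
                            interval_kind="replication-based")


def overall_effect_curve(evaluator, z_data: np.ndarray,
                         grid: Sequence[float] | None = None) -> pd.DataFrame:
    """h with all exposures jointly at quantile q, centered at q = 0.50."""
    if grid is None:
        grid = np.round(np.arange(0.25, 0.751, 0.05), 10)
    grid = np.asarray(list(grid), dtype=float)
    if not np.any(np.isclose(grid, 0.5)):
        raise ValueError("grid must include the reference quantile 0.50")
    q = exposure_quantiles(z_data, grid)
    h = evaluator.h(q)                                     # (T, G)
    ref = int(np.argmin(np.abs(grid - 0.5)))
    centered = h - h[:, [ref]]
    point, lo, hi = _summarize_draws(centered, evaluator.interval_kind)
    return pd.DataFrame({"quantile": grid, "estimate": point, "lo": lo, "hi": hi,
                         "interval_kind": evaluator.interval_kind})


def _median_background(z_data: np.ndarray) -> np.ndarray:
    return np.quantile(np.atleast_2d(z_data), 0.5, axis=0)


def univariate_response(evaluator, z_data: np.ndarray, j: int,
                        grid: np.ndarray | None = None,
                        grid_size: int = 25) -> pd.DataFrame:
    """h along exposure ``j`` with the other exposures at their medians."""
    z_data = np.atleast_2d(z_data)
    m = z_data.shape[1]
    if not 0 <= j < m:
        raise IndexError(f"exposure index {j} out of range for m={m}")
    if grid is None:
        grid = np.linspace(z_data[:, j].min(), z_data[:, j].max(), grid_size)
    grid = np.asarray(grid, dtype=float)
    q = np.tile(_median_background(z_data), (grid.size, 1))
    q[:, j] = grid
    h = evaluator.h(q)
    point, lo, hi = _summarize_draws(h, evaluator.interval_kind)
    return pd.DataFrame({"exposure": j + 1, "z": grid, "estimate": point,
                         "lo": lo, "hi": hi,
                         "interval_kind": evaluator.interval_kind})


def bivariate_response(evaluator, z_data: np.ndarray, j: int, k: int,
                       cond_quantiles: Sequence[float] = (0.25, 0.5, 0.75),
                       grid: np.ndarray | None = None,
                       grid_size: int = 25) -> pd.DataFrame:
    """h along exposure ``j`` conditional on exposure ``k`` at each quantile,
    remaining exposures at their medians.  Curve separation across the
    conditioning quantiles is the interaction diagnostic."""
    if j == k:
        raise ValueError("focal and conditioning exposures must differ")
    z_data = np.atleast_2d(z_data)
    if grid is None:
        grid = np.linspace(z_data[:, j].min(), z_data[:, j].max(), grid_size)
    grid = np.asarray(grid, dtype=float)
    frames = []
    for cq in cond_quantiles:
        q = np.tile(_median_background(z_data), (grid.size, 1))
        q[:, j] = grid
        q[:, k] = np.quantile(z_data[:, k], cq)
        h = evaluator.h(q)
        point, lo, hi = _summarize_draws(h, evaluator.interval_kind)
        frames.append(pd.DataFrame({
            "exposure": j + 1, "cond_exposure": k + 1, "cond_quantile": cq,
            "z": grid, "estimate": point, "lo": lo, "hi": hi,
            "interval_kind": evaluator.interval_kind}))
    return pd.concat(frames, ignore_index=True)


def single_variable_risks(evaluator, z_data: np.ndarray, q_fixed: float = 0.5,
                          lower: float = 0.25,
                          upper: float = 0.75) -> pd.DataFrame:
    """Per-exposure 25th-to-75th percentile contrast, all other exposures
    fixed at the ``q_fixed`` quantile."""
    z_data = np.atleast_2d(z_data)
    m = z_data.shape[1]
    background = np.quantile(z_data, q_fixed, axis=0)
    queries = []
    for j in range(m):
        for p in (lower, upper):
            row = background.copy()
            row[j] = np.quantile(z_data[:, j], p)
            queries.append(row)
    h = evaluator.h(np.array(queries))               # (T, 2m)
    contrasts = h[:, 1::2] - h[:, 0::2]              # (T, m)
    point, lo, hi = _summarize_draws(contrasts, evaluator.interval_kind)
    return pd.DataFrame({"exposure": np.arange(1, m + 1), "q_fixed": q_fixed,
                         "estimate": point, "lo": lo, "hi": hi,
                         "interval_kind": evaluator.interval_kind})


def make_replicate_summarizer(
    kinds: Sequence[str] = ("delta",),
    overall_grid: Sequence[float] | None = None,
    univariate_grids: dict[int, np.ndarray] | None = None,
    q_fixed: float = 0.5,
) -> Callable[[PosteriorDraws, pd.DataFrame], dict]:
    """Build the per-replicate summary callback for the design-aware workflow.

    Quantile-defined points are taken from each replicate's own (already
    weight-resampled) data; z-space grids for univariate curves are fixed
    up front so every replicate shares them with the naive fit.
    """
    valid = {"delta", "overall_curve", "univariate", "single_var_risk"}
    unknown = set(kinds) - valid
    if unknown:
        raise ValueError(f"unknown summary kinds: {sorted(unknown)}")

    def summarize(draws: PosteriorDraws, data: pd.DataFrame) -> dict:
        m = draws.m
        zcols = [f"z{i + 1}" for i in range(m)]
        z = data[zcols].to_numpy()
        y = data["y"].to_numpy()
        ev = FitEvaluator(draws, y, z, mode="mean")
        out: dict = {}
        if "delta" in kinds:
            out["delta"] = float(_delta_draws(ev, z, 0.25, 0.75).mean())
        if "overall_curve" in kinds:
            curve = overall_effect_curve(ev, z, grid=overall_grid)
            out["overall_curve"] = curve["estimate"].to_numpy()
        if "univariate" in kinds:
            for j, grid in (univariate_grids or {}).items():
                res = univariate_response(ev, z, j, grid=grid)
                out[f"univariate_{j + 1}"] = res["estimate"].to_numpy()
        if "single_var_risk" in kinds:
            res = single_variable_risks(ev, z, q_fixed=q_fixed)
            out["single_var_risk"] = res["estimate"].to_numpy()
        return out

    return summarize


def aggregate_replicate_curves(results: Sequence[ReplicateResult],
                               key: str) -> pd.DataFrame:
    """Pointwise aggregation of a named per-replicate curve summary."""
    from .resample import aggregate_functional
    curves = np.stack([np.asarray(r.summaries[key], dtype=float)
                       for r in results])
    return aggregate_functional(curves, interval_kind="replication-based")
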