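"""Design-aware workflow: weight-proportional, PSU-preserving resampling.

The naive workflow fits the kernel machine once to the raw sample.  The
design-aware workflow instead redraws the analysis set so the model sees an
approximation of the population-weighted empirical distribution:

1. PSU stage — within each stratum, draw as many PSUs as the sample contains
   there, with replacement, with probability proportional to the PSU's total
   (default) or mean survey weight.
2. Unit stage — within each drawn PSU, resample units with replacement with
   probability proportional to their weights ``w``.  A PSU drawn twice
   contributes two independent unit resamples under replicate-unique labels.

The per-stratum draw slots inherit the original PSUs' takes (in label order),
so every replicate dataset has exactly the original size ``n`` and per-stratum
PSU counts.  The model is refit on each of ``B`` replicates with a shorter
chain; scalar summaries are aggregated across replicates by their empirical
mean with percentile (2.5/97.5) replication-based intervals, functional
summaries pointwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .bkmr import BKMRConfig, PosteriorDraws, mcmc_fit
from .design import SurveySample

__all__ = [
    "ResamplePlan",
    "ReplicateResult",
    "AggregatedEstimate",
    "resample_design_aware",
    "run_design_aware",
    "aggregate_scalar",
    "aggregate_functional",
]

log = logging.getLogger(__name__)

_REPLICATE_CHAIN = BKMRConfig(iters=2500, burnin=1000, thin=2)


@dataclass(frozen=True)
class ResamplePlan:
    b: int = 50
    psu_prob_rule: str = "sum_weights"       # or "mean_weights"
    replicate_config: BKMRConfig = field(default_factory=lambda: _REPLICATE_CHAIN)
    min_success: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.b < 1:
            raise ValueError("b must be >= 1")
        if self.psu_prob_rule not in ("sum_weights", "mean_weights"):
            raise ValueError(f"unknown psu_prob_rule {self.psu_prob_rule!r}")


@dataclass
class ReplicateResult:
    index: int
    draws: PosteriorDraws | None
    summaries: dict                      # name -> scalar or 1-d array
    pips: np.ndarray | None = None
    fingerprint: str = ""                # hash of the resampled row multiset


@dataclass
class AggregatedEstimate:
    point: float
    lo: float
    hi: float
    interval_kind: str                   # "replication-based" | "posterior-credible"

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError("interval bounds out of order")
        if not (self.lo <= self.point <= self.hi):
            warnings.warn("point estimate falls outside its interval")


def resample_design_aware(sample: SurveySample | pd.DataFrame,
                          rng: np.random.Generator,
                          psu_prob_rule: str = "sum_weights") -> pd.DataFrame:
    """One weight-proportional, PSU-preserving resample of a survey sample.

    Returns a dataframe of the same size with a ``psu`` column relabeled so
    that repeated draws of one PSU stay distinct clusters.
    """
    df = sample.data if isinstance(sample, SurveySample) else sample
    for col in ("stratum", "psu", "w"):
        if col not in df.columns:
            raise ValueError(f"sample is missing required column {col!r}")
    if df["w"].isna().any():
        raise ValueError("missing weights")

    pieces = []
    new_label = 0
    for s, sdf in df.groupby("stratum", sort=True):
        psus = np.sort(sdf["psu"].unique())
        if psus.size == 0:
            raise ValueError(f"empty stratum {s}")
        groups = {c: sdf[sdf["psu"] == c] for c in psus}
        agg = np.array([groups[c]["w"].sum() for c in psus]) \
            if psu_prob_rule == "sum_weights" \
            else np.array([groups[c]["w"].mean() for c in psus])
        probs = agg / agg.sum()
        takes = [len(groups[c]) for c in psus]    # slot j inherits take j
        drawn = rng.choice(psus.size, size=psus.size, replace=True, p=probs)
        for slot, gi in enumerate(drawn):
            gdf = groups[psus[gi]]
            unit_w = gdf["w"].to_numpy()
            unit_p = unit_w / unit_w.sum()
            rows = rng.choice(len(gdf), size=takes[slot], replace=True, p=unit_p)
            piece = gdf.iloc[rows].copy()
            new_label += 1
            piece["source_psu"] = piece["psu"].to_numpy()
            piece["psu"] = new_label
            pieces.append(piece)
    out = pd.concat(pieces, ignore_index=True)
    assert len(out) == len(df)
    return out


class _ReplicateWorker:
    """One resample-refit-summarize step; picklable for parallel execution."""

    def __init__(self, sample, plan, summarize, keep_draws):
        self.sample, self.plan = sample, plan
        self.summarize, self.keep_draws = summarize, keep_draws

    def __call__(self, b: int, child: np.random.SeedSequence):
        import hashlib
        plan, m = self.plan, self.sample.m
        rs_seed, fit_seed = child.spawn(2)
        try:
            data = resample_design_aware(
                self.sample, np.random.default_rng(rs_seed),
                plan.psu_prob_rule)
            zcols = [f"z{j + 1}" for j in range(m)]
            draws = mcmc_fit(data["y"].to_numpy(), data[zcols].to_numpy(),
                             config=plan.replicate_config,
                             seed=np.random.default_rng(fit_seed))
            summaries = self.summarize(draws, data) \
                if self.summarize is not None else {}
            bad = [k for k, v in summaries.items()
                   if not np.all(np.isfinite(np.asarray(v, dtype=float)))]
            if bad:
                raise FloatingPointError(f"non-finite summaries: {bad}")
            pips = draws.delta.mean(axis=0) if draws.varsel else np.ones(m)
            ids = data["unit_id"].to_numpy() if "unit_id" in data.columns \
                else data.index.to_numpy()
            fp = hashlib.sha1(np.sort(ids).tobytes()).hexdigest()[:12]
            return ReplicateResult(index=b,
                                   draws=draws if self.keep_draws else None,
                                   summaries=summaries, pips=pips,
                                   fingerprint=fp)
        except Exception:  # noqa: BLE001 - replicate failures are recoverable
            log.warning("replicate %d failed; skipping", b, exc_info=True)
            return None


def run_design_aware(
    sample: SurveySample,
    plan: ResamplePlan,
    summarize: Callable[[PosteriorDraws, pd.DataFrame], dict] | None = None,
    keep_draws: bool = False,
    n_jobs: int = 1,
) -> list[ReplicateResult]:
    """Refit the model on ``plan.b`` weight-proportional resamples.

    Each replicate gets an independent child stream spawned from ``plan.seed``
    (one for the resample, one for the chain), so results are reproducible and
    identical whether run serially or in parallel (``n_jobs`` workers via
    joblib).  ``summarize(draws, data)`` is called per replicate on the
    resampled dataset; failures are logged and skipped, and the run aborts if
    fewer than ``min_success`` of replicates succeed.
    """
    master = np.random.SeedSequence(plan.seed)
    children = master.spawn(plan.b)
    worker = _ReplicateWorker(sample, plan, summarize, keep_draws)
    if n_jobs == 1:
        raw = [worker(b, child) for b, child in enumerate(children)]
    else:
        from joblib import Parallel, delayed
        raw = Parallel(n_jobs=n_jobs)(
            delayed(worker)(b, child) for b, child in enumerate(children))
    results = [r for r in raw if r is not None]
    if len(results) < plan.min_success * plan.b:
        raise RuntimeError(
            f"only {len(results)}/{plan.b} replicates succeeded "
            f"(floor {plan.min_success:.0%})")
    return results


def aggregate_scalar(values: Sequence[float],
                     interval_kind: str = "replication-based") -> AggregatedEstimate:
    """Empirical mean with linear-interpolation 2.5/97.5 percentile interval."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    lo, hi = np.percentile(v, [2.5, 97.5])
    return AggregatedEstimate(point=float(v.mean()), lo=float(lo), hi=float(hi),
                              interval_kind=interval_kind)


def aggregate_functional(curves: np.ndarray,
                         interval_kind: str = "replication-based") -> pd.DataFrame:
    """Column-wise aggregation of a (B, G) matrix of curves on a shared grid."""
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    rows = [aggregate_scalar(curves[:, g], interval_kind)
            for g in range(curves.shape[1])]
    return pd.DataFrame({"estimate": [r.point for r in rows],
                         "lo": [r.lo for r in rows],
                         "hi": [r.hi for r in rows],
                         "interval_kind": interval_kind})
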