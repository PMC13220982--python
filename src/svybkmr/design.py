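"""Stratified two-stage cluster sampling with informative or SRS selection.

First stage: within each stratum, ``k_h`` PSUs are drawn by simple random
sampling without replacement.  Second stage: within each selected PSU either

* ``"srs"`` — ``m_c`` units drawn by SRS without replacement, or
* ``"pps"`` — units drawn without replacement with probabilities proportional
  to a shifted positive function of the first exposure,
  ``p_ic ∝ max(Z1_i - min_c Z1 + 1e-6, 0)``,

so that under the informative regime inclusion depends on an exposure that
drives the outcome.  Approximate inclusion probabilities follow the standard
two-stage product form ``pi_i ≈ (k_h / C_h) * Pr(i | c)`` with
``Pr(i|c) = m_c / N_c`` (SRS) or ``min(1, m_c * p_ic)`` (PPS, normalized
``p_ic``).  Base weights are ``1/pi`` and are rescaled to mean one within the
sample; no trimming is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .population import TruePopulation

__all__ = [
    "SamplingDesign",
    "SurveySample",
    "select_psus",
    "allocate_takes",
    "within_psu_probs_pps",
    "inclusion_probs_srs",
    "inclusion_probs_pps",
    "make_weights",
    "draw_sample",
    "read_sample",
]

_PPS_SHIFT = 1e-6


@dataclass(frozen=True)
class SamplingDesign:
    n_total: int = 300
    k_h: int = 4
    regime: str = "srs"
    seed: int = 0

    def __post_init__(self):
        if self.regime not in ("srs", "pps"):
            raise ValueError(f"regime must be 'srs' or 'pps', got {self.regime!r}")
        if self.n_total < 1 or self.k_h < 1:
            raise ValueError("n_total and k_h must be positive")


@dataclass
class SurveySample:
    """Sampled rows plus the design bookkeeping the downstream workflows need."""

    data: pd.DataFrame          # unit_id, stratum, psu, z*, y, p_within, pi, w_base, w
    design: SamplingDesign
    takes: dict                 # psu label -> realized within-PSU take m_c

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def m(self) -> int:
        return sum(c.startswith("z") for c in self.data.columns)

    def z_matrix(self) -> np.ndarray:
        cols = [f"z{j + 1}" for j in range(self.m)]
        return self.data[cols].to_numpy()

    def write(self, path: str | Path) -> None:
        # %.17g keeps the round trip exact at full double precision
        self.data.to_csv(path, index=False, float_format="%.17g")


def read_sample(path: str | Path, design: SamplingDesign | None = None) -> SurveySample:
    df = pd.read_csv(path, float_precision="round_trip")
    takes = df.groupby("psu").size().to_dict()
    return SurveySample(data=df, design=design or SamplingDesign(n_total=len(df)),
                        takes=takes)


def select_psus(population: TruePopulation, design: SamplingDesign,
                rng: np.random.Generator) -> dict[int, np.ndarray]:
    """SRSWOR of ``k_h`` PSUs per stratum; returns stratum -> sorted PSU labels."""
    strata = population.psu_strata()
    out: dict[int, np.ndarray] = {}
    for s in range(1, population.config.n_strata + 1):
        pool = np.flatnonzero(strata == s) + 1
        if len(pool) < design.k_h:
            raise ValueError(
                f"stratum {s} has {len(pool)} PSUs, fewer than k_h={design.k_h}")
        out[s] = np.sort(rng.choice(pool, size=design.k_h, replace=False))
    return out


def allocate_takes(n_total: int, selected: list[int]) -> dict[int, int]:
    """Per-PSU takes: base ``floor(n_total / #PSUs)``; the remainder goes one
    unit each to the first selected PSUs in label order."""
    selected = sorted(selected)
    k = len(selected)
    base, extra = divmod(n_total, k)
    return {psu: base + (1 if i < extra else 0) for i, psu in enumerate(selected)}


def within_psu_probs_pps(z1_cluster: np.ndarray) -> np.ndarray:
    """Normalized shifted-positive selection probabilities within one PSU."""
    z1 = np.asarray(z1_cluster, dtype=float)
    if z1.size == 0:
        raise ValueError("empty cluster")
    p = np.maximum(z1 - z1.min() + _PPS_SHIFT, 0.0)
    return p / p.sum()


def inclusion_probs_srs(k_h: int, c_h: int, m_c: int, n_c: int) -> float:
    """pi = (k_h/C_h) * m_c/N_c for SRS within PSU."""
    return (k_h / c_h) * (m_c / n_c)


def inclusion_probs_pps(k_h: int, c_h: int, m_c: int, p_ic: np.ndarray) -> np.ndarray:
    """pi_i = (k_h/C_h) * min(1, m_c * p_ic) with normalized p_ic."""
    pr = np.minimum(1.0, m_c * np.asarray(p_ic, dtype=float))
    pi = (k_h / c_h) * pr
    assert np.all(pi > 0) and np.all(pi <= 1.0 + 1e-12)
    return pi


def make_weights(pi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Base weights 1/pi and their mean-one rescaling (no trimming)."""
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0) or np.any(pi > 1):
        raise ValueError("inclusion probabilities must lie in (0, 1]")
    w_base = 1.0 / pi
    w = w_base / w_base.mean()
    return w_base, w


def _pps_wor_draw(rng: np.random.Generator, p: np.ndarray, m: int) -> np.ndarray:
    """Weighted without-replacement draw by exponential keys (Efraimidis-Spirakis):
    the ``m`` smallest Exp(rate=p) arrival times form the sample."""
    keys = rng.exponential(1.0, size=p.size) / p
    return np.argpartition(keys, m - 1)[:m]


def draw_sample(population: TruePopulation, design: SamplingDesign) -> SurveySample:
    """Draw one stratified two-stage sample and attach pi, base and rescaled weights."""
    rng = np.random.default_rng(design.seed)
    cfg = population.config
    c_h = cfg.n_psu // cfg.n_strata
    selected_by_stratum = select_psus(population, design, rng)
    all_selected = sorted(int(p) for ps in selected_by_stratum.values() for p in ps)
    takes = allocate_takes(design.n_total, all_selected)

    psu_index: dict[int, np.ndarray] = {
        int(c): np.flatnonzero(population.psu_id == c) for c in all_selected}
    rows, p_within_all, pi_all = [], [], []
    for c in all_selected:
        idx = psu_index[c]
        n_c = idx.size
        m_c = takes[c]
        if m_c > n_c:
            raise ValueError(f"take m_c={m_c} exceeds PSU {c} size {n_c}")
        if design.regime == "srs":
            chosen_local = rng.choice(n_c, size=m_c, replace=False)
            p_within = np.full(m_c, m_c / n_c)
            pi = np.full(m_c, inclusion_probs_srs(design.k_h, c_h, m_c, n_c))
        else:
            p_ic = within_psu_probs_pps(population.z[idx, 0])
            chosen_local = _pps_wor_draw(rng, p_ic, m_c)
            p_within = p_ic[chosen_local]
            pi = inclusion_probs_pps(design.k_h, c_h, m_c, p_within)
        rows.append(idx[chosen_local])
        p_within_all.append(p_within)
        pi_all.append(pi)

    chosen = np.concatenate(rows)
    pi = np.concatenate(pi_all)
    w_base, w = make_weights(pi)

    df = pd.DataFrame({"unit_id": chosen + 1,
                       "stratum": population.stratum_id[chosen],
                       "psu": population.psu_id[chosen]})
    for j in range(cfg.m):
        df[f"z{j + 1}"] = population.z[chosen, j]
    df["y"] = population.y[chosen]
    df["p_within"] = np.concatenate(p_within_all)
    df["pi"] = pi
    df["w_base"] = w_base
    df["w"] = w
    assert len(df) == design.n_total
    return SurveySample(data=df, design=design, takes=takes)
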