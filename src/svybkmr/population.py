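"""Finite-population simulator with a known nonlinear exposure-response surface.

A synthetic superpopulation consists of ``n_pop`` individuals carrying ``m``
standardized exposures drawn from a mean-zero multivariate normal with an
exchangeable correlation structure.  The outcome is

    Y_i = h(Z_i) + u_{c(i)} + eps_i,

where ``h`` is a fixed polynomial surface with main effects, curvature and one
interaction, ``u_c`` is a cluster (PSU) random effect calibrated to a target
intraclass correlation, and ``eps_i`` is unit-level Gaussian noise.  Because
``h`` is known, the overall mixture effect

    delta* = h(q_{0.75}) - h(q_{0.25})

(all exposures moved jointly between their marginal quartiles) is available in
closed form and serves as the ground truth for the Monte-Carlo evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PopulationConfig",
    "HFunctionSpec",
    "TruePopulation",
    "EstimandSpec",
    "make_exchangeable_cov",
    "h_spec_for",
    "h_true",
    "icc_to_sigma_u2",
    "sigma_u2_to_icc",
    "generate_population",
    "true_overall_effect",
    "read_population",
]

# base polynomial: 1.0*Z1*Z2 + 0.5*Z1^2 - 0.6*Z2^2 + 0.30*Z3 + 0.25*Z3^2,
# plus 0.1*Zk for k >= 4 in the ten-exposure surface
_BASE_COEFS = {
    "z1z2": 1.0,
    "z1_sq": 0.5,
    "z2_sq": -0.6,
    "z3": 0.30,
    "z3_sq": 0.25,
}
_TAIL_COEF = 0.1


@dataclass(frozen=True)
class HFunctionSpec:
    """Specification of the true exposure-response surface.

    Coefficients are stored as data rather than baked into the evaluation so
    that tests can inject degenerate surfaces (e.g. a flat one).
    """

    id: str = "h3"
    m: int = 3
    coefs: dict = field(default_factory=lambda: dict(_BASE_COEFS))
    tail_coef: float = _TAIL_COEF

    def as_callable(self) -> Callable[[np.ndarray], np.ndarray]:
        return lambda z: h_true(z, self)


def h_spec_for(m: int) -> HFunctionSpec:
    """Return the canonical surface for ``m`` exposures (3 or 10)."""
    if m == 3:
        return HFunctionSpec(id="h3", m=3)
    if m == 10:
        return HFunctionSpec(id="h10", m=10)
    raise ValueError(f"no canonical surface for m={m}; expected 3 or 10")


def h_true(z: np.ndarray, spec: HFunctionSpec) -> np.ndarray:
    """Evaluate the true surface at one point (shape ``(m,)``) or many ``(n, m)``."""
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    if single:
        z = z[None, :]
    if z.shape[1] != spec.m:
        raise ValueError(f"expected {spec.m} exposure columns, got {z.shape[1]}")
    c = spec.coefs
    out = (
        c["z1z2"] * z[:, 0] * z[:, 1]
        + c["z1_sq"] * z[:, 0] ** 2
        + c["z2_sq"] * z[:, 1] ** 2
        + c["z3"] * z[:, 2]
        + c["z3_sq"] * z[:, 2] ** 2
    )
    if spec.m > 3:
        out = out + spec.tail_coef * z[:, 3:].sum(axis=1)
    return out[0] if single else out


def make_exchangeable_cov(m: int, rho: float) -> np.ndarray:
    """Exchangeable (compound-symmetric) correlation matrix.

    Positive definiteness requires both eigenvalues ``1 + (m-1)*rho`` and
    ``1 - rho`` to be strictly positive, i.e. ``-1/(m-1) < rho < 1``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > 1:
        lo = -1.0 / (m - 1)
        if not (rho > lo and rho < 1.0):
            raise ValueError(
                f"rho={rho} outside the positive-definite range for m={m}: "
                f"requires 1+(m-1)*rho > 0 and 1-rho > 0, "
                f"i.e. {lo:.6g} < rho < 1 "
                f"(smallest eigenvalue would be {min(1 + (m - 1) * rho, 1 - rho):.6g})"
            )
    cov = np.full((m, m), float(rho))
    np.fill_diagonal(cov, 1.0)
    return cov


def icc_to_sigma_u2(icc: float, sigma_eps2: float = 1.0) -> float:
    """Cluster variance implied by a target ICC: sigma_u2 = icc/(1-icc)*sigma_eps2."""
    if not 0.0 <= icc < 1.0:
        raise ValueError(f"icc must lie in [0, 1), got {icc}")
    if sigma_eps2 <= 0:
        raise ValueError("sigma_eps2 must be positive")
    return icc / (1.0 - icc) * sigma_eps2


def sigma_u2_to_icc(sigma_u2: float, sigma_eps2: float = 1.0) -> float:
    """Inverse of :func:`icc_to_sigma_u2`."""
    return sigma_u2 / (sigma_u2 + sigma_eps2)


@dataclass(frozen=True)
class PopulationConfig:
    n_pop: int = 20_000
    m: int = 3
    rho: float = 0.0
    icc: float = 0.0
    sigma_eps2: float = 1.0
    n_psu: int = 120
    n_strata: int = 6
    seed: int = 0

    def __post_init__(self):
        make_exchangeable_cov(self.m, self.rho)  # validates rho
        if self.n_strata < 1 or self.n_psu < self.n_strata:
            raise ValueError("need n_psu >= n_strata >= 1")
        if not 0.0 <= self.icc < 1.0:
            raise ValueError("icc must lie in [0, 1)")
        if self.sigma_eps2 <= 0:
            raise ValueError("sigma_eps2 must be positive")


def _psu_sizes(n_pop: int, n_psu: int) -> np.ndarray:
    """Contiguous block sizes: the first ``n_pop % n_psu`` PSUs take one extra unit."""
    base = n_pop // n_psu
    extra = n_pop % n_psu
    sizes = np.full(n_psu, base, dtype=int)
    sizes[:extra] += 1
    return sizes


@dataclass
class TruePopulation:
    """A realized finite population plus the truth metadata needed for scoring."""

    z: np.ndarray            # (n_pop, m) exposures
    psu_id: np.ndarray       # 1..n_psu
    stratum_id: np.ndarray   # 1..n_strata
    u: np.ndarray            # cluster effect, constant within PSU
    eps: np.ndarray
    y: np.ndarray
    h_values: np.ndarray
    sigma_u2: float
    config: PopulationConfig
    h_spec: HFunctionSpec

    @property
    def n_pop(self) -> int:
        return self.y.shape[0]

    def psu_strata(self) -> np.ndarray:
        """Stratum of each PSU label 1..n_psu under the cyclic assignment."""
        c = np.arange(1, self.config.n_psu + 1)
        return (c - 1) % self.config.n_strata + 1

    def to_frame(self) -> pd.DataFrame:
        cols = {"unit_id": np.arange(1, self.n_pop + 1),
                "stratum": self.stratum_id, "psu": self.psu_id}
        for j in range(self.z.shape[1]):
            cols[f"z{j + 1}"] = self.z[:, j]
        cols.update(u=self.u, eps=self.eps, h_true=self.h_values, y=self.y)
        return pd.DataFrame(cols)

    def write(self, csv_path: str | Path) -> None:
        """Write the population as CSV with a JSON truth sidecar."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False, float_format="%.17g")
        meta = {
            "config": asdict(self.config),
            "sigma_u2": self.sigma_u2,
            "h_spec": {"id": self.h_spec.id, "m": self.h_spec.m,
                       "coefs": self.h_spec.coefs, "tail_coef": self.h_spec.tail_coef},
            "delta_star": true_overall_effect(self.h_spec, EstimandSpec()),
        }
        csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def generate_population(
    config: PopulationConfig, spec: HFunctionSpec | None = None
) -> TruePopulation:
    """Draw one finite population under ``config``.

    Units are partitioned into ``n_psu`` contiguous, near-equal blocks (the
    first ``n_pop % n_psu`` blocks take one extra unit) and PSU ``c`` belongs
    to stratum ``((c-1) mod n_strata) + 1``.
    """
    if spec is None:
        spec = h_spec_for(config.m)
    if spec.m != config.m:
        raise ValueError("h-surface dimension does not match config.m")
    rng = np.random.default_rng(config.seed)
    cov = make_exchangeable_cov(config.m, config.rho)
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((config.n_pop, config.m)) @ chol.T

    sizes = _psu_sizes(config.n_pop, config.n_psu)
    psu_id = np.repeat(np.arange(1, config.n_psu + 1), sizes)
    stratum_of_psu = (np.arange(config.n_psu)) % config.n_strata + 1
    stratum_id = stratum_of_psu[psu_id - 1]

    sigma_u2 = icc_to_sigma_u2(config.icc, config.sigma_eps2)
    u_psu = rng.normal(0.0, np.sqrt(sigma_u2), size=config.n_psu) if sigma_u2 > 0 \
        else np.zeros(config.n_psu)
    u = u_psu[psu_id - 1]
    eps = rng.normal(0.0, np.sqrt(config.sigma_eps2), size=config.n_pop)

    h_values = h_true(z, spec)
    y = h_values + u + eps
    return TruePopulation(z=z, psu_id=psu_id, stratum_id=stratum_id, u=u, eps=eps,
                          y=y, h_values=h_values, sigma_u2=sigma_u2,
                          config=config, h_spec=spec)


def read_population(csv_path: str | Path) -> TruePopulation:
    """Reload a population written by :meth:`TruePopulation.write`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, float_precision="round_trip")
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    config = PopulationConfig(**meta["config"])
    hs = meta["h_spec"]
    spec = HFunctionSpec(id=hs["id"], m=hs["m"], coefs=hs["coefs"],
                         tail_coef=hs["tail_coef"])
    zcols = [c for c in df.columns if c.startswith("z")]
    return TruePopulation(
        z=df[zcols].to_numpy(), psu_id=df["psu"].to_numpy(),
        stratum_id=df["stratum"].to_numpy(), u=df["u"].to_numpy(),
        eps=df["eps"].to_numpy(), y=df["y"].to_numpy(),
        h_values=df["h_true"].to_numpy(), sigma_u2=meta["sigma_u2"],
        config=config, h_spec=spec)


@dataclass
class EstimandSpec:
    """Quantile pair defining the overall mixture effect delta*.

    ``quantile_source`` selects between exact standard-normal marginal
    quantiles (the superpopulation target; exposures are standard normal by
    construction) and empirical quantiles of a realized finite population.
    """

    lower_q: float = 0.25
    upper_q: float = 0.75
    quantile_source: str = "theoretical-normal"

    def __post_init__(self):
        if not (0.0 < self.lower_q < self.upper_q < 1.0):
            raise ValueError("need 0 < lower_q < upper_q < 1")
        if self.quantile_source not in ("theoretical-normal", "population-empirical"):
            raise ValueError(f"unknown quantile_source {self.quantile_source!r}")


def true_overall_effect(
    spec: HFunctionSpec,
    estimand: EstimandSpec | None = None,
    population: TruePopulation | None = None,
) -> float:
    """True overall effect delta* = h(q_upper vector) - h(q_lower vector)."""
    if estimand is None:
        estimand = EstimandSpec()
    if estimand.quantile_source == "theoretical-normal":
        lo = np.full(spec.m, stats.norm.ppf(estimand.lower_q))
        hi = np.full(spec.m, stats.norm.ppf(estimand.upper_q))
    else:
        if population is None:
            raise ValueError("population required for population-empirical quantiles")
        lo = np.quantile(population.z, estimand.lower_q, axis=0)
        hi = np.quantile(population.z, estimand.upper_q, axis=0)
    return float(h_true(hi, spec) - h_true(lo, spec))
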