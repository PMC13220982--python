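"""Bayesian kernel machine regression with spike-and-slab variable selection.

Model
-----
    Y_i = X_i beta + h(Z_i) + eps_i,        eps_i ~ N(0, sigma2)
    h ~ GP(0, tau * K_r),                   tau = lam * sigma2

with the component-scaled Gaussian (RBF) kernel

    K_r(z, z') = exp( - sum_m r_m (z_m - z'_m)^2 ),   r_m >= 0.

Marginalizing h gives Y ~ N(X beta, sigma2 * (I + lam K_r)), which is the
working likelihood for all MCMC moves.  Variable selection couples each kernel
scale to a Bernoulli inclusion indicator: r_m = 0 iff delta_m = 0, so an
excluded exposure drops out of the kernel entirely.

Sampler
-------
Per iteration: one randomly chosen exposure scale r_m is updated by a mixed
reversible move (birth/death toggle of delta_m with a uniform slab draw on
birth; log-scale random walk when included), lam by a log-scale random-walk
Metropolis step, and beta / sigma2 by conjugate Gibbs steps against the
marginalized likelihood (flat prior on beta, inverse-gamma on sigma2).
Factorizations are symmetric positive-definite decompositions with a small
diagonal jitter; the kernel's weighted squared-distance matrix is cached and
updated rank-wise so a single-component proposal costs one factorization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg

__all__ = [
    "BKMRConfig",
    "KernelParams",
    "PosteriorDraws",
    "rbf_kernel",
    "marginal_loglik",
    "mcmc_fit",
    "posterior_h",
    "compute_pips",
    "group_pips",
    "conditional_pips",
    "compute_rhat",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class BKMRConfig:
    """MCMC settings and prior hyperparameters.

    Defaults follow the main-analysis chain schedule (4000 iterations, burn-in
    2000, thinning 2 -> 1000 retained draws); ``replicate_chain()`` returns the
    shorter schedule used inside bootstrap refits.
    """

    iters: int = 4000
    burnin: int = 2000
    thin: int = 2
    varsel: bool = True
    # priors / proposal tuning
    a_sigma: float = 1e-3        # inverse-gamma shape on sigma2
    b_sigma: float = 1e-3        # inverse-gamma rate on sigma2
    lam_shape: float = 1.0       # gamma prior on lam = tau/sigma2
    lam_rate: float = 0.1
    p_delta: float = 0.5         # Bernoulli inclusion prior
    slab_max: float = 100.0      # uniform slab upper bound for r_m
    birth_max: float = 10.0      # birth proposals drawn from U(0, birth_max)
    step_r: float = 0.3          # log-random-walk sd for r_m
    step_lam: float = 0.5        # log-random-walk sd for lam
    jitter: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        t, rem = divmod(self.iters - self.burnin, self.thin)
        if t <= 0 or rem != 0:
            raise ValueError(
                f"(iters - burnin)/thin must be a positive integer; got "
                f"({self.iters} - {self.burnin})/{self.thin}")

    @property
    def n_retained(self) -> int:
        return (self.iters - self.burnin) // self.thin

    def replicate_chain(self, iters: int = 2500, burnin: int = 1000,
                        thin: int = 2) -> "BKMRConfig":
        """Shorter chain schedule for bootstrap-replicate refits."""
        from dataclasses import replace
        return replace(self, iters=iters, burnin=burnin, thin=thin)


@dataclass
class KernelParams:
    """One state of the kernel-machine parameters."""

    r: np.ndarray         # (m,) kernel scales, >= 0
    lam: float            # GP-to-noise variance ratio, > 0
    sigma2: float         # residual variance, > 0
    beta: np.ndarray      # adjustment coefficients
    delta: np.ndarray | None = None   # (m,) inclusion indicators

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if np.any(self.r < 0):
            raise ValueError("kernel scales r must be nonnegative")
        if self.lam <= 0 or self.sigma2 <= 0:
            raise ValueError("lam and sigma2 must be positive")
        if self.delta is None:
            self.delta = (self.r > 0).astype(int)


def rbf_kernel(z_a: np.ndarray, z_b: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Component-scaled Gaussian kernel matrix exp(-sum_m r_m (a_m-b_m)^2)."""
    z_a = np.atleast_2d(np.asarray(z_a, dtype=float))
    z_b = np.atleast_2d(np.asarray(z_b, dtype=float))
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("kernel scales r must be nonnegative")
    if z_a.shape[1] != r.size or z_b.shape[1] != r.size:
        raise ValueError("column counts must match length of r")
    d2 = (z_a[:, None, :] - z_b[None, :, :]) ** 2
    return np.exp(-(d2 @ r))


def marginal_loglik(y: np.ndarray, x: np.ndarray, z: np.ndarray,
                    params: KernelParams, jitter: float = 0.0) -> float:
    """Log density of Y ~ N(X beta, sigma2 (I + lam K_r)).

    Reference implementation via one dense SPD factorization; the sampler uses
    an equivalent cached-update path.
    """
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = y.size
    v = params.lam * rbf_kernel(z, z, params.r)
    v[np.diag_indices(n)] += 1.0 + jitter
    try:
        cho = linalg.cho_factor(v, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:  # pragma: no cover - jitter guards this
        raise linalg.LinAlgError(f"ill-conditioned kernel system: {exc}") from exc
    logdet = 2.0 * np.log(np.diag(cho[0])).sum()
    resid = y - x @ params.beta
    quad = resid @ linalg.cho_solve(cho, resid, check_finite=False)
    return float(-0.5 * (n * (_LOG2PI + np.log(params.sigma2)) + logdet
                         + quad / params.sigma2))


@dataclass
class PosteriorDraws:
    """Retained MCMC draws plus the standardization transform and diagnostics."""

    r: np.ndarray          # (T, m)
    delta: np.ndarray      # (T, m) int
    lam: np.ndarray        # (T,)
    sigma2: np.ndarray     # (T,)
    beta: np.ndarray       # (T, p)
    z_mean: np.ndarray
    z_sd: np.ndarray
    varsel: bool
    config: BKMRConfig | None = None
    acceptance: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.r.shape[0]

    @property
    def m(self) -> int:
        return self.r.shape[1]


class _ChainState:
    """Cached factorization of V = I + lam*K for the current kernel state."""

    __slots__ = ("s", "k", "chol", "logdet", "ty", "tx")

    def __init__(self, s, k, chol, logdet, ty, tx):
        self.s, self.k, self.chol, self.logdet, self.ty, self.tx = \
            s, k, chol, logdet, ty, tx


def _factor(k: np.ndarray, lam: float, jitter: float, y, x):
    n = k.shape[0]
    v = lam * k
    v[np.diag_indices(n)] += 1.0 + jitter
    chol = linalg.cholesky(v, lower=True, check_finite=False, overwrite_a=True)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    ty = linalg.solve_triangular(chol, y, lower=True, check_finite=False)
    tx = linalg.solve_triangular(chol, x, lower=True, check_finite=False)
    return chol, logdet, ty, tx


def _loglik(n: int, logdet: float, quad: float, sigma2: float) -> float:
    return -0.5 * (n * (_LOG2PI + np.log(sigma2)) + logdet + quad / sigma2)


def mcmc_fit(y: np.ndarray, z: np.ndarray, x: np.ndarray | None = None,
             config: BKMRConfig | None = None,
             seed: int | np.random.Generator | None = None) -> PosteriorDraws:
    """Fit the kernel machine by MCMC and return retained draws.

    Exposures are centered and scaled internally; the transform is stored on
    the returned draws so surface queries can be posed on the original scale.
    ``seed`` overrides ``config.seed`` and may be a Generator (used by the
    replicate machinery to hand each refit an independent stream).
    """
    cfg = config or BKMRConfig()
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(cfg.seed if seed is None else seed)

    y = np.asarray(y, dtype=float)
    z_raw = np.atleast_2d(np.asarray(z, dtype=float))
    n, m = z_raw.shape
    if y.size != n:
        raise ValueError("y and z disagree on the number of units")
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(z_raw)):
        raise ValueError("missing or non-finite values in y or z")
    x = np.ones((n, 1)) if x is None else np.atleast_2d(np.asarray(x, dtype=float))
    p = x.shape[1]

    z_mean = z_raw.mean(axis=0)
    z_sd = z_raw.std(axis=0)
    z_sd = np.where(z_sd > 0, z_sd, 1.0)
    zs = (z_raw - z_mean) / z_sd

    # pairwise squared differences per component; S = sum_m r_m * D[m]
    d = (zs[:, None, :] - zs[None, :, :]) ** 2
    d = np.moveaxis(d, 2, 0).copy()          # (m, n, n), contiguous per component

    # initial state
    r = np.full(m, 0.1)
    delta = np.ones(m, dtype=int)
    lam = 10.0
    beta = np.linalg.lstsq(x, y, rcond=None)[0]
    sigma2 = max(float(np.var(y - x @ beta)) / 2.0, 1e-4)

    s = np.tensordot(r, d, axes=1)
    k = np.exp(-s)
    chol, logdet, ty, tx = _factor(k, lam, cfg.jitter, y, x)
    st = _ChainState(s, k, chol, logdet, ty, tx)

    def quad_for(beta_vec):
        t = st.ty - st.tx @ beta_vec
        return float(t @ t)

    if not np.isfinite(_loglik(n, st.logdet, quad_for(beta), sigma2)):
        raise FloatingPointError("non-finite likelihood at initialization")

    t_keep = cfg.n_retained
    out_r = np.empty((t_keep, m))
    out_delta = np.empty((t_keep, m), dtype=int)
    out_lam = np.empty(t_keep)
    out_sigma2 = np.empty(t_keep)
    out_beta = np.empty((t_keep, p))
    acc = {"r_walk": [0, 0], "r_birth": [0, 0], "r_death": [0, 0], "lam": [0, 0]}

    log_birth_corr = np.log(cfg.birth_max / cfg.slab_max) \
        + np.log(cfg.p_delta / (1.0 - cfg.p_delta))

    kept = 0
    for it in range(cfg.iters):
        resid_quad = quad_for(beta)
        ll = _loglik(n, st.logdet, resid_quad, sigma2)

        # --- one component of r: mixed birth/death/random-walk move ---
        j = int(rng.integers(m))
        move = None
        r_prop = None
        if cfg.varsel:
            if delta[j] == 1:
                if rng.random() < 0.5:
                    move, r_prop = "r_death", 0.0
                else:
                    move = "r_walk"
                    r_prop = r[j] * np.exp(cfg.step_r * rng.standard_normal())
            else:
                if rng.random() < 0.5:
                    move = "r_birth"
                    r_prop = rng.uniform(0.0, cfg.birth_max)
        else:
            move = "r_walk"
            r_prop = max(r[j], 1e-3) * np.exp(cfg.step_r * rng.standard_normal())

        if move is not None and r_prop is not None and r_prop <= cfg.slab_max:
            acc[move][1] += 1
            s_new = st.s + (r_prop - r[j]) * d[j]
            k_new = np.exp(-s_new)
            chol_n, logdet_n, ty_n, tx_n = _factor(k_new, lam, cfg.jitter, y, x)
            t = ty_n - tx_n @ beta
            ll_new = _loglik(n, logdet_n, float(t @ t), sigma2)
            if move == "r_walk":
                log_alpha = ll_new - ll + np.log(r_prop / r[j])
            elif move == "r_birth":
                log_alpha = ll_new - ll + log_birth_corr
            else:  # death
                log_alpha = ll_new - ll - log_birth_corr
            if np.log(rng.random()) < log_alpha:
                acc[move][0] += 1
                r[j] = r_prop
                delta[j] = 1 if r_prop > 0 else 0
                st = _ChainState(s_new, k_new, chol_n, logdet_n, ty_n, tx_n)
                ll = ll_new

        # --- lam: log-scale random walk against Gamma(lam_shape, lam_rate) ---
        lam_prop = lam * np.exp(cfg.step_lam * rng.standard_normal())
        acc["lam"][1] += 1
        chol_n, logdet_n, ty_n, tx_n = _factor(st.k, lam_prop, cfg.jitter, y, x)
        t = ty_n - tx_n @ beta
        ll_new = _loglik(n, logdet_n, float(t @ t), sigma2)
        log_prior = (cfg.lam_shape - 1.0) * np.log(lam_prop / lam) \
            - cfg.lam_rate * (lam_prop - lam)
        log_alpha = ll_new - ll + log_prior + np.log(lam_prop / lam)
        if np.log(rng.random()) < log_alpha:
            acc["lam"][0] += 1
            lam = lam_prop
            st = _ChainState(st.s, st.k, chol_n, logdet_n, ty_n, tx_n)

        # --- beta: conjugate Gibbs under a flat prior ---
        a_mat = st.tx.T @ st.tx
        b_vec = st.tx.T @ st.ty
        a_inv_chol = np.linalg.cholesky(np.linalg.inv(a_mat)) if p > 1 else None
        if p == 1:
            mean_b = b_vec[0] / a_mat[0, 0]
            beta = np.array([mean_b + np.sqrt(sigma2 / a_mat[0, 0])
                             * rng.standard_normal()])
        else:
            mean_b = np.linalg.solve(a_mat, b_vec)
            beta = mean_b + np.sqrt(sigma2) * (a_inv_chol @
                                               rng.standard_normal(p))

        # --- sigma2: conjugate inverse-gamma Gibbs ---
        quad = quad_for(beta)
        sigma2 = (cfg.b_sigma + 0.5 * quad) / rng.gamma(cfg.a_sigma + 0.5 * n)

        if it >= cfg.burnin and (it - cfg.burnin) % cfg.thin == 0:
            out_r[kept] = r
            out_delta[kept] = delta
            out_lam[kept] = lam
            out_sigma2[kept] = sigma2
            out_beta[kept] = beta
            kept += 1

    acceptance = {k_: (v[0] / v[1] if v[1] else np.nan) for k_, v in acc.items()}
    return PosteriorDraws(r=out_r, delta=out_delta, lam=out_lam, sigma2=out_sigma2,
                          beta=out_beta, z_mean=z_mean, z_sd=z_sd,
                          varsel=cfg.varsel, config=cfg, acceptance=acceptance)


def posterior_h(draws: PosteriorDraws, y: np.ndarray, z: np.ndarray,
                z_new: np.ndarray, x: np.ndarray | None = None,
                mode: str = "sample",
                seed: int | np.random.Generator | None = None,
                jitter: float = 1e-8) -> np.ndarray:
    """Draws (or conditional means) of h at ``z_new``, one row per retained draw.

    For each retained parameter draw, h(z_new) | Y is Gaussian with mean
    ``lam K* V^{-1} (Y - X beta)`` and covariance
    ``sigma2 lam (K** - lam K* V^{-1} K*')`` where ``V = I + lam K``.
    ``mode="sample"`` draws from that conditional (propagating GP uncertainty,
    needed for credible intervals); ``mode="mean"`` returns conditional means
    only (sufficient for posterior-mean summaries, and cheaper).
    """
    if mode not in ("sample", "mean"):
        raise ValueError("mode must be 'sample' or 'mean'")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(0 if seed is None else seed)
    y = np.asarray(y, dtype=float)
    z = np.atleast_2d(np.asarray(z, dtype=float))
    z_new = np.atleast_2d(np.asarray(z_new, dtype=float))
    n = y.size
    x = np.ones((n, 1)) if x is None else np.atleast_2d(np.asarray(x, dtype=float))

    zs = (z - draws.z_mean) / draws.z_sd
    zs_new = (z_new - draws.z_mean) / draws.z_sd
    d = np.moveaxis((zs[:, None, :] - zs[None, :, :]) ** 2, 2, 0).copy()
    d_star = np.moveaxis((zs_new[:, None, :] - zs[None, :, :]) ** 2, 2, 0).copy()
    d_ss = np.moveaxis((zs_new[:, None, :] - zs_new[None, :, :]) ** 2, 2, 0).copy()

    t_draws, p_new = draws.n_draws, zs_new.shape[0]
    out = np.empty((t_draws, p_new))
    for t in range(t_draws):
        r, lam, sigma2, beta = draws.r[t], draws.lam[t], draws.sigma2[t], draws.beta[t]
        k = np.exp(-np.tensordot(r, d, axes=1))
        v = lam * k
        v[np.diag_indices(n)] += 1.0 + jitter
        chol = linalg.cholesky(v, lower=True, check_finite=False, overwrite_a=True)
        k_star = np.exp(-np.tensordot(r, d_star, axes=1))
        resid = y - x @ beta
        u1 = linalg.solve_triangular(chol, resid, lower=True, check_finite=False)
        u2 = linalg.solve_triangular(chol, k_star.T, lower=True, check_finite=False)
        mean = lam * (u2.T @ u1)
        if mode == "mean":
            out[t] = mean
            continue
        k_ss = np.exp(-np.tensordot(r, d_ss, axes=1))
        cov = sigma2 * lam * (k_ss - lam * (u2.T @ u2))
        cov[np.diag_indices(p_new)] += sigma2 * lam * jitter + 1e-12
        cchol = np.linalg.cholesky(cov)
        out[t] = mean + cchol @ rng.standard_normal(p_new)
    return out


def compute_pips(draws: PosteriorDraws) -> np.ndarray:
    """Per-exposure posterior inclusion probabilities (mean of delta draws)."""
    if not draws.varsel:
        warnings.warn("variable selection was off; PIPs are 1 by definition")
        return np.ones(draws.m)
    return draws.delta.mean(axis=0)


def group_pips(draws: PosteriorDraws,
               groups: Sequence[Sequence[int]]) -> np.ndarray:
    """Per-group inclusion probability: P(at least one member included).

    Groups are disjoint 0-based index sets; singletons reproduce the member
    PIPs exactly.
    """
    seen: set[int] = set()
    for g in groups:
        if len(g) == 0:
            raise ValueError("empty group")
        gs = set(int(j) for j in g)
        if gs & seen:
            raise ValueError("groups must be disjoint")
        if not gs <= set(range(draws.m)):
            raise ValueError("group index out of range")
        seen |= gs
    return np.array([draws.delta[:, list(g)].any(axis=1).mean() for g in groups])


def conditional_pips(draws: PosteriorDraws) -> np.ndarray:
    """Matrix cpip[i, j] = P(delta_i = 1 | delta_j = 1) over retained draws.

    Columns whose conditioning exposure is never included are NaN (undefined),
    not zero.
    """
    delta = draws.delta
    m = draws.m
    out = np.full((m, m), np.nan)
    for j in range(m):
        mask = delta[:, j] == 1
        if mask.any():
            out[:, j] = delta[mask].mean(axis=0)
    return out


def compute_rhat(chains: Sequence[np.ndarray]) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    Each chain is split in half; returns sqrt((W + B/n) / W) over the split
    halves, which is exactly 1 for identical chains and always >= 1.  NaN
    when the within-chain variance is zero.
    """
    chains = [np.asarray(c, dtype=float) for c in chains]
    if len(chains) < 2:
        raise ValueError("need at least two chains")
    length = chains[0].size
    if any(c.size != length for c in chains) or length < 4:
        raise ValueError("chains must share a length of at least 4")
    half = length // 2
    split = [c[:half] for c in chains] + [c[half:2 * half] for c in chains]
    arr = np.stack(split)                       # (2m, half)
    w = arr.var(axis=1, ddof=1).mean()
    if w == 0:
        return np.nan
    b_over_n = arr.mean(axis=1).var(ddof=1)
    return float(np.sqrt((w + b_over_n) / w))
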