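"""Bayesian Gaussian regression with AR1 errors, sampled from scratch.

Two models share a Metropolis-within-Gibbs sampler built on the exact
observed-data likelihood of a stationary AR1 error process:

* individual model:  y_t = alpha + tau*X_t + eps_t for one participant,
* population model:  y_it = alpha + tau*X_it + a_i + b_i*X_it + eps_it with
  a_i ~ Normal(0, sigma_a^2), b_i ~ Normal(0, sigma_b^2) and AR1(rho, sigma)
  errors within participant (rho, sigma shared across participants).

"Non-informative" priors are made concrete as: flat on (alpha, tau), Jeffreys
p(sigma^2) ∝ 1/sigma^2 on the innovation variance, uniform over a fixed grid
on rho (updated by griddy Gibbs — deterministic support, no step-size
tuning), and half-Cauchy(0, 5) on the hierarchical SDs sigma_a, sigma_b
(updated by random-walk Metropolis on the log scale).

Missing days cost nothing: because AR1 is Markov, the log density of the
observed subvector factorizes into gap-aware conditionals with correlation
rho**gap, so the likelihood is exact and O(n) — no imputation, no dense
covariance solve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortDataset, ParticipantSeries

RHO_GRID_BOUND = 0.995
LOG_2PI = math.log(2.0 * math.pi)


class IdentifiabilityError(ValueError):
    """Raised when a series cannot identify the treatment effect."""


@dataclass
class MCMCConfig:
    """Sampler settings; defaults follow the study's sampling protocol
    (two chains, 5000 burn-in steps, 10,000 kept iterations per chain)."""

    n_chains: int = 2
    burn_in: int = 5000
    kept_iterations: int = 10000
    rho_grid_size: int = 399
    seed: int = 0
    rho_grid: Optional[np.ndarray] = None  # explicit grid overrides size
    random_slope: bool = True  # population model: random intercept + slope

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.burn_in < 0 or self.kept_iterations < 1:
            raise ValueError("chain/burn-in/iteration counts must be positive")
        if self.rho_grid is None:
            if self.rho_grid_size < 1:
                raise ValueError("rho_grid_size must be positive")
            self.rho_grid = np.linspace(
                -RHO_GRID_BOUND, RHO_GRID_BOUND, self.rho_grid_size
            )
        else:
            self.rho_grid = np.atleast_1d(np.asarray(self.rho_grid, dtype=float))
            if np.any(np.abs(self.rho_grid) >= 1.0):
                raise ValueError("rho grid must lie inside (-1, 1)")

    def chain_seeds(self) -> List[int]:
        """Fixed master-seed splitting rule (SeedSequence spawn keys)."""
        state = np.random.SeedSequence(self.seed).generate_state(self.n_chains)
        return [int(s) for s in state]


@dataclass
class PosteriorDraws:
    """Named MCMC draws with shape (chain, iteration) per parameter."""

    draws: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.draws.values()}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent draw shapes: {shapes}")

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_iterations(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def parameters(self) -> List[str]:
        return list(self.draws)

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated (summaries always pool chains)."""
        return self.draws[name].reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.draws.items():
            for c in range(arr.shape[0]):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iteration": np.arange(arr.shape[1]),
                            "parameter": name,
                            "value": arr[c],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# AR1 likelihood
# ---------------------------------------------------------------------------

def ar1_loglik(
    values: Sequence[float],
    days: Sequence[int],
    mean: Sequence[float],
    rho: float,
    sigma: float,
) -> float:
    """Exact log density of irregularly observed stationary AR1 data.

    The process has covariance (sigma^2/(1-rho^2)) * rho**|day difference|.
    Computed in O(n) by conditioning each observation on its predecessor:
    with gap g, corr = rho**g and conditional variance v*(1 - rho**(2g)),
    v = sigma^2/(1-rho^2).
    """
    if abs(rho) >= 1.0:
        raise ValueError("|rho| must be < 1 for a stationary AR1 process")
    if sigma <= 0.0:
        raise ValueError("sigma must be positive")
    y = np.asarray(values, dtype=float)
    d = np.asarray(days, dtype=float)
    mu = np.asarray(mean, dtype=float)
    if not (y.shape == d.shape == mu.shape):
        raise ValueError("values, days and mean must have equal length")
    if y.size == 0:
        return 0.0
    if np.any(np.diff(d) <= 0):
        raise ValueError("day indices must be strictly increasing")
    e = y - mu
    v = sigma * sigma / (1.0 - rho * rho)
    ll = -0.5 * (LOG_2PI + math.log(v) + e[0] * e[0] / v)
    if e.size > 1:
        gaps = np.diff(d)
        r = np.power(rho, gaps)  # gaps are integer-valued, safe for rho < 0
        cond_var = v * (1.0 - r * r)
        resid = e[1:] - r * e[:-1]
        ll += -0.5 * np.sum(LOG_2PI + np.log(cond_var) + resid * resid / cond_var)
    return float(ll)


class _GapGrid:
    """Per-series cache of rho-grid quantities that depend only on the gaps.

    Enables the griddy Gibbs update of rho to evaluate the full conditional
    over the whole grid with three matrix-vector products per iteration.
    """

    def __init__(self, grid: np.ndarray, days: np.ndarray):
        self.grid = grid
        self.n = len(days)
        self.v = 1.0 / (1.0 - grid * grid)  # unit-innovation stationary var
        gaps = np.diff(np.asarray(days, dtype=float))
        self.gaps = gaps
        if gaps.size:
            self.P = np.power(grid[:, None], gaps[None, :])
            self.P2 = self.P * self.P
            cond = self.v[:, None] * (1.0 - self.P2)
            self.W = 1.0 / cond
            self.WP = self.W * self.P
            self.WP2 = self.W * self.P2
            self.logdet = np.log(self.v) + np.sum(np.log(cond), axis=1)
        else:
            self.P = np.zeros((grid.size, 0))
            self.W = self.WP = self.WP2 = self.P
            self.logdet = np.log(self.v)

    def loglik_grid(self, e: np.ndarray, sigma2: float) -> np.ndarray:
        """Log likelihood of residual vector e at every grid point."""
        quad = e[0] * e[0] * (1.0 - self.grid * self.grid)
        if e.size > 1:
            e1, e0 = e[1:], e[:-1]
            quad = quad + self.W @ (e1 * e1) - 2.0 * (self.WP @ (e1 * e0)) + self.WP2 @ (e0 * e0)
        return -0.5 * (self.n * (LOG_2PI + math.log(sigma2)) + self.logdet + quad / sigma2)

    def whiten(self, g: int, arr: np.ndarray) -> np.ndarray:
        """Apply the AR1 whitening transform at grid index g to a vector
        (or to each column of a matrix); whitened noise is iid sigma^2."""
        v = self.v[g]
        out = np.empty_like(arr, dtype=float)
        out[0] = arr[0] / math.sqrt(v)
        if arr.shape[0] > 1:
            r = self.P[g]
            denom = np.sqrt(v * (1.0 - r * r))
            if arr.ndim == 1:
                out[1:] = (arr[1:] - r * arr[:-1]) / denom
            else:
                out[1:] = (arr[1:] - r[:, None] * arr[:-1]) / denom[:, None]
        return out


def _sample_grid_index(rng: np.random.Generator, logp: np.ndarray) -> int:
    p = np.exp(logp - np.max(logp))
    p /= p.sum()
    return int(rng.choice(len(p), p=p))


def _draw_sigma2(rng: np.random.Generator, n: int, ssr: float) -> float:
    # Jeffreys p(sigma^2) ∝ 1/sigma^2  =>  sigma^2 | rest ~ InvGamma(n/2, SSR/2)
    g = rng.gamma(0.5 * n, 1.0)
    return max(0.5 * ssr / g, 1e-300)


def _extract_series(series: ParticipantSeries, outcome_name: str):
    days, y, x = series.observed(outcome_name)
    if len(y) < 4:
        raise IdentifiabilityError(
            f"participant {series.participant_id}: need >= 4 observed outcomes, "
            f"got {len(y)}"
        )
    if np.all(x == 1.0) or np.all(x == 0.0):
        raise IdentifiabilityError(
            f"participant {series.participant_id}: effect not identifiable — all "
            "observed outcomes fall in a single phase type"
        )
    return days, y, x


# ---------------------------------------------------------------------------
# Individual-level model
# ---------------------------------------------------------------------------

def fit_individual(
    series: ParticipantSeries,
    outcome_name: str = "stress_today",
    config: Optional[MCMCConfig] = None,
) -> PosteriorDraws:
    """Fit y_t = alpha + tau*X_t + AR1 noise to one participant's series.

    Gibbs sweep: (alpha, tau) jointly from the conjugate GLS normal under a
    flat prior; sigma^2 from its inverse-gamma conditional (Jeffreys prior);
    rho by griddy Gibbs over the configured grid (uniform prior).
    """
    config = config or MCMCConfig()
    days, y, x = _extract_series(series, outcome_name)
    X = np.column_stack([np.ones_like(y), x])
    cache = _GapGrid(config.rho_grid, days)
    n = len(y)

    total = config.burn_in + config.kept_iterations
    names = ("alpha", "tau", "rho", "sigma")
    out = {k: np.empty((config.n_chains, config.kept_iterations)) for k in names}

    for c, chain_seed in enumerate(config.chain_seeds()):
        rng = np.random.default_rng(chain_seed)
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        e = y - X @ beta
        sigma2 = max(float(e @ e) / max(n - 2, 1), 1e-12)
        g = int(np.argmin(np.abs(config.rho_grid)))
        for it in range(total):
            # (alpha, tau) | sigma2, rho — conjugate GLS normal
            Xw = cache.whiten(g, X)
            yw = cache.whiten(g, y)
            A = Xw.T @ Xw
            bvec = Xw.T @ yw
            Ainv = np.linalg.inv(A)
            beta_hat = Ainv @ bvec
            beta = beta_hat + np.linalg.cholesky(sigma2 * Ainv) @ rng.standard_normal(2)
            # sigma^2 | beta, rho
            e = y - X @ beta
            ew = cache.whiten(g, e)
            sigma2 = _draw_sigma2(rng, n, float(ew @ ew))
            # rho | beta, sigma2 — griddy Gibbs
            g = _sample_grid_index(rng, cache.loglik_grid(e, sigma2))
            if it >= config.burn_in:
                k = it - config.burn_in
                out["alpha"][c, k] = beta[0]
                out["tau"][c, k] = beta[1]
                out["rho"][c, k] = config.rho_grid[g]
                out["sigma"][c, k] = math.sqrt(sigma2)
    return PosteriorDraws(out)


# ---------------------------------------------------------------------------
# Population-level (multilevel) model
# ---------------------------------------------------------------------------

def _log_halfcauchy(s: float, scale: float = 5.0) -> float:
    return -math.log1p((s / scale) ** 2)


def fit_population(
    dataset: CohortDataset,
    outcome_name: str = "stress_today",
    config: Optional[MCMCConfig] = None,
) -> PosteriorDraws:
    """Fit the hierarchical model pooling all participants of a dataset.

    y_it = alpha + tau*X_it + a_i + b_i*X_it + eps_it, with a_i ~ N(0,
    sigma_a^2), b_i ~ N(0, sigma_b^2) (b_i dropped when
    ``config.random_slope`` is False) and AR1(rho, sigma) errors within
    participant.  Returns draws for alpha, tau, rho, sigma, sigma_a
    (, sigma_b) and the per-participant deviations a[pid] (, b[pid]).
    """
    config = config or MCMCConfig()
    usable = []
    for p in dataset:
        try:
            days, y, x = _extract_series(p, outcome_name)
        except IdentifiabilityError:
            continue
        usable.append((p.participant_id, days, y, x))
    if len(usable) < 2:
        raise IdentifiabilityError(
            "population model needs >= 2 participants with both phases "
            "observed; use fit_individual for a single series"
        )

    grid = config.rho_grid
    caches = [_GapGrid(grid, days) for _, days, _, _ in usable]
    Xs = [np.column_stack([np.ones_like(y), x]) for _, _, y, x in usable]
    ys = [y for _, _, y, _ in usable]
    xs = [x for _, _, _, x in usable]
    N = len(usable)
    n_tot = sum(len(y) for y in ys)
    slope = config.random_slope

    names = ["alpha", "tau", "rho", "sigma", "sigma_a"] + (["sigma_b"] if slope else [])
    names += [f"a[{pid}]" for pid, *_ in usable]
    if slope:
        names += [f"b[{pid}]" for pid, *_ in usable]
    out = {k: np.empty((config.n_chains, config.kept_iterations)) for k in names}
    total = config.burn_in + config.kept_iterations

    for c, chain_seed in enumerate(config.chain_seeds()):
        rng = np.random.default_rng(chain_seed)
        # initialize from pooled OLS
        Xall = np.vstack(Xs)
        yall = np.concatenate(ys)
        beta, _, _, _ = np.linalg.lstsq(Xall, yall, rcond=None)
        a = np.zeros(N)
        b = np.zeros(N)
        sigma2 = max(float(np.var(yall - Xall @ beta)), 1e-12)
        sa, sb = 0.5, 0.5
        g = int(np.argmin(np.abs(grid)))
        step = 0.3  # RW-Metropolis step on log hierarchical SDs

        for it in range(total):
            # --- fixed effects (alpha, tau) | rest: GLS normal
            A = np.zeros((2, 2))
            bvec = np.zeros(2)
            for i in range(N):
                resid = ys[i] - a[i] - b[i] * xs[i]
                Xw = caches[i].whiten(g, Xs[i])
                rw = caches[i].whiten(g, resid)
                A += Xw.T @ Xw
                bvec += Xw.T @ rw
            Ainv = np.linalg.inv(A)
            beta = Ainv @ bvec + np.linalg.cholesky(sigma2 * Ainv) @ rng.standard_normal(2)

            # --- random effects per participant: conjugate normal
            for i in range(N):
                resid = ys[i] - Xs[i] @ beta
                rw = caches[i].whiten(g, resid)
                if slope:
                    Zw = caches[i].whiten(g, Xs[i])  # [1, x] columns
                    M = Zw.T @ Zw / sigma2 + np.diag([1.0 / (sa * sa), 1.0 / (sb * sb)])
                    Minv = np.linalg.inv(M)
                    mean = Minv @ (Zw.T @ rw / sigma2)
                    gi = mean + np.linalg.cholesky(Minv) @ rng.standard_normal(2)
                    a[i], b[i] = gi
                else:
                    zw = caches[i].whiten(g, np.ones_like(resid))
                    prec = float(zw @ zw) / sigma2 + 1.0 / (sa * sa)
                    mean = float(zw @ rw) / sigma2 / prec
                    a[i] = mean + rng.standard_normal() / math.sqrt(prec)

            # --- sigma^2 | rest
            ssr = 0.0
            es = []
            for i in range(N):
                e = ys[i] - Xs[i] @ beta - a[i] - b[i] * xs[i]
                es.append(e)
                ew = caches[i].whiten(g, e)
                ssr += float(ew @ ew)
            sigma2 = _draw_sigma2(rng, n_tot, ssr)

            # --- hierarchical SDs: RW Metropolis on log scale, half-Cauchy(0,5)
            sa = _update_scale(rng, a, sa, step)
            if slope:
                sb = _update_scale(rng, b, sb, step)

            # --- rho | rest: griddy Gibbs on the whole-data conditional
            logp = np.zeros(grid.size)
            for i in range(N):
                logp += caches[i].loglik_grid(es[i], sigma2)
            g = _sample_grid_index(rng, logp)

            if it >= config.burn_in:
                k = it - config.burn_in
                out["alpha"][c, k] = beta[0]
                out["tau"][c, k] = beta[1]
                out["rho"][c, k] = grid[g]
                out["sigma"][c, k] = math.sqrt(sigma2)
                out["sigma_a"][c, k] = sa
                if slope:
                    out["sigma_b"][c, k] = sb
                for i, (pid, *_rest) in enumerate(usable):
                    out[f"a[{pid}]"][c, k] = a[i]
                    if slope:
                        out[f"b[{pid}]"][c, k] = b[i]
    return PosteriorDraws(out)


def _update_scale(
    rng: np.random.Generator, effects: np.ndarray, current: float, step: float
) -> float:
    """One Metropolis update of a hierarchical SD with half-Cauchy(0,5) prior."""

    def logpost(s: float) -> float:
        n = len(effects)
        return (
            -n * math.log(s)
            - float(effects @ effects) / (2.0 * s * s)
            + _log_halfcauchy(s)
            + math.log(s)  # Jacobian of the log transform
        )

    prop = current * math.exp(step * rng.standard_normal())
    if math.log(rng.random()) < logpost(prop) - logpost(current):
        return prop
    return current


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceReport:
    """Split-R-hat and effective sample size per parameter."""

    rhat: Dict[str, float]
    ess: Dict[str, float]
    undefined: List[str] = field(default_factory=list)

    def worst_rhat(self) -> float:
        finite = [v for v in self.rhat.values() if np.isfinite(v)]
        return max(finite) if finite else float("nan")


def diagnose(draws: PosteriorDraws) -> ConvergenceReport:
    """Split-R-hat (rank-normalized) and bulk ESS via arviz.

    Parameters whose chains are (numerically) constant have no defined R-hat
    and are listed in ``undefined`` instead of silently passing.
    """
    import arviz as az

    if draws.n_chains < 2 and draws.n_iterations < 200:
        raise ValueError("diagnostics need >= 2 chains or >= 200 draws")
    rhat: Dict[str, float] = {}
    ess: Dict[str, float] = {}
    undefined: List[str] = []
    for name in draws.parameters():
        arr = draws.draws[name]
        if np.ptp(arr) == 0.0:
            undefined.append(name)
            continue
        idata = az.convert_to_dataset(arr, group="posterior")
        r = float(az.rhat(idata)["x"].values)
        e = float(az.ess(idata)["x"].values)
        if not np.isfinite(r):
            undefined.append(name)
        else:
            rhat[name] = r
            ess[name] = e
    return ConvergenceReport(rhat=rhat, ess=ess, undefined=undefined)
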