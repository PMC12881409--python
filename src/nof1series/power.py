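"""Power and sample size for series of N-of-1 trials with AR1 errors.

The design question: how many participants (split over the ABAB and BABA
sequences) and how many observed daily outcomes per weekly phase are needed
to detect a standardized treatment effect Delta with a given power?

Power is defined operationally through the analysis of the aggregated
series: each simulated replicate is analyzed by generalized least squares
with fixed participant intercepts, a shared treatment effect, and the AR1
working correlation of the design (rho known, residual scale estimated);
power is the fraction of replicates with a two-sided p-value below alpha.
``analytic_power`` is the matching closed-form normal approximation using
the exact GLS variance of the treatment contrast; the two must agree within
Monte-Carlo error.

``residual_sd`` is the marginal (stationary) SD of the AR1 error process —
the scale the standardized effect refers to.  By default the AR1 correlation
acts on the *observation order* (successive documented responses have
correlation rho, the convention of standard AR1 regression software applied
to a response sequence); ``correlation_basis="calendar"`` instead uses
rho**|day difference| between observed study days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import stats

from .cohort import TrialSchedule


@dataclass
class DesignSpec:
    participants_per_sequence: int = 6
    n_phases: int = 4
    phase_length_days: int = 7
    obs_per_phase: int = 4
    residual_sd: float = 2.41
    autocorrelation: float = 0.8
    standardized_effect: float = 0.3
    alpha: float = 0.05
    n_sims: int = 2000
    obs_placement: str = "first"  # or "random": observed days within a phase
    correlation_basis: str = "observation"  # or "calendar"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.participants_per_sequence < 1:
            raise ValueError("participants_per_sequence must be positive")
        if not -1.0 < self.autocorrelation < 1.0:
            raise ValueError("autocorrelation must be in (-1, 1)")
        if not 0 < self.obs_per_phase <= self.phase_length_days:
            raise ValueError("obs_per_phase must be in 1..phase_length_days")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.obs_placement not in ("first", "random"):
            raise ValueError("obs_placement must be 'first' or 'random'")
        if self.correlation_basis not in ("observation", "calendar"):
            raise ValueError("correlation_basis must be 'observation' or 'calendar'")

    @property
    def effect_points(self) -> float:
        """Treatment effect in scale points: Delta * residual SD."""
        return self.standardized_effect * self.residual_sd


def _observed_days(spec: DesignSpec, rng=None) -> np.ndarray:
    """Observed study-day indices: obs_per_phase days in each phase."""
    days = []
    for ph in range(spec.n_phases):
        start = ph * spec.phase_length_days
        if spec.obs_placement == "first" or rng is None:
            within = np.arange(spec.obs_per_phase)
        else:
            within = np.sort(
                rng.choice(spec.phase_length_days, spec.obs_per_phase, replace=False)
            )
        days.extend(start + within + 1)
    return np.asarray(days, dtype=int)


def _design_blocks(spec: DesignSpec, rng=None):
    """Per-sequence (treatment indicator, whitening Cholesky factor).

    The AR1 correlation among the observed days is R[j,k] = rho**|d_j-d_k|;
    whitening by chol(R)^-1 makes the GLS fit an OLS fit.
    """
    days = _observed_days(spec, rng)
    if spec.correlation_basis == "calendar":
        lags = days.astype(float)
    else:
        lags = np.arange(days.size, dtype=float)
    blocks = []
    for sequence in ("ABAB", "BABA"):
        sched = TrialSchedule(sequence, spec.phase_length_days, spec.n_phases)
        x = np.array([1.0 if sched.phase_of_day(int(d)) == "A" else 0.0 for d in days])
        dist = np.abs(lags[:, None] - lags[None, :])
        R = spec.autocorrelation ** dist
        L = np.linalg.cholesky(R)
        Linv = np.linalg.inv(L)
        blocks.append((x, Linv))
    return blocks


def _whitened_design(spec: DesignSpec, rng=None):
    """Stacked whitened design matrix for all participants.

    Columns: one intercept dummy per participant, then the shared treatment
    indicator.  Whitened noise is iid with SD residual_sd.
    """
    blocks = _design_blocks(spec, rng)
    m = spec.participants_per_sequence
    n_obs = blocks[0][0].size
    N = 2 * m
    X = np.zeros((N * n_obs, N + 1))
    xw_all = np.zeros(N * n_obs)
    row = 0
    for s, (x, Linv) in enumerate(blocks):
        xw = Linv @ x
        ones_w = Linv @ np.ones(n_obs)
        for j in range(m):
            i = s * m + j
            X[row : row + n_obs, i] = ones_w
            X[row : row + n_obs, N] = xw
            xw_all[row : row + n_obs] = xw
            row += n_obs
    return X, xw_all, blocks, n_obs


def analytic_power(spec: DesignSpec) -> float:
    """Normal-approximation power of the two-sided GLS test.

    Phi(|delta|/SE - z_{1-alpha/2}) + Phi(-|delta|/SE - z_{1-alpha/2}) with
    SE from the GLS variance of the treatment contrast under the design's
    AR1 covariance.
    """
    X, _, _, _ = _whitened_design(spec)
    XtX_inv = np.linalg.inv(X.T @ X)
    se = spec.residual_sd * math.sqrt(XtX_inv[-1, -1])
    z = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    ncp = abs(spec.effect_points) / se
    return float(stats.norm.cdf(ncp - z) + stats.norm.cdf(-ncp - z))


def treatment_se(spec: DesignSpec) -> float:
    """GLS standard error of the treatment effect estimate (points)."""
    X, _, _, _ = _whitened_design(spec)
    XtX_inv = np.linalg.inv(X.T @ X)
    return spec.residual_sd * math.sqrt(XtX_inv[-1, -1])


def simulate_power(spec: DesignSpec) -> Tuple[float, float]:
    """Monte-Carlo power with its binomial standard error.

    Each replicate simulates AR1 errors for every participant, adds the
    treatment effect, fits the aggregated GLS model (participant intercepts
    + shared effect, known AR1 correlation, residual scale estimated) and
    tests the effect two-sided at ``spec.alpha``.  Because whitening the
    known correlation turns the model into OLS on iid noise, replicates are
    fully vectorized.
    """
    rng = np.random.default_rng(spec.seed)
    X, xw_all, _, n_obs = _whitened_design(spec, rng)
    n_rows, p = X.shape
    df = n_rows - p
    # projections for the t statistic of the last (treatment) column
    XtX_inv = np.linalg.inv(X.T @ X)
    w = (XtX_inv @ X.T)[-1]  # tau_hat = w @ y_w
    Q, _ = np.linalg.qr(X)
    se_unit = math.sqrt(XtX_inv[-1, -1])

    # whitened mean: participant intercepts are 0 wlog (they are estimated),
    # treatment contributes delta * whitened indicator
    mean_w = spec.effect_points * xw_all

    tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
    rejections = 0
    chunk = max(1, min(spec.n_sims, int(2e7 // max(n_rows, 1))))
    done = 0
    while done < spec.n_sims:
        k = min(chunk, spec.n_sims - done)
        Yw = mean_w + spec.residual_sd * rng.standard_normal((k, n_rows))
        tau_hat = Yw @ w
        fitted_norm2 = np.sum((Yw @ Q) ** 2, axis=1)
        rss = np.sum(Yw * Yw, axis=1) - fitted_norm2
        sigma_hat = np.sqrt(rss / df)
        tstat = tau_hat / (sigma_hat * se_unit)
        rejections += int(np.sum(np.abs(tstat) > tcrit))
        done += k
    power = rejections / spec.n_sims
    mc_se = math.sqrt(max(power * (1.0 - power), 1e-12) / spec.n_sims)
    return power, mc_se


def required_recruitment(base_n: int, dropout_rate: float) -> int:
    """Inflate an analyzable sample size for dropout, rounding to nearest."""
    if base_n < 1:
        raise ValueError("base_n must be positive")
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError("dropout_rate must be in [0, 1)")
    return int(math.floor(base_n / (1.0 - dropout_rate) + 0.5))
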