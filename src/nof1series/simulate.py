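"""Synthetic cohorts of N-of-1 stress series.

The generator inverts the analysis model: for participant i on study day t
with treatment indicator X_t,

    y_t = alpha_i + tau_i * X_t + w * weekend_t + eps_t,
    eps_t = rho * eps_{t-1} + eta_t,   eta_t ~ Normal(0, sigma^2),

with eps_1 drawn from the stationary distribution Normal(0, sigma^2/(1-rho^2)),
alpha_i ~ Normal(alpha0, sigma_a^2) and tau_i ~ Normal(tau_bar, sigma_b^2)
(negative tau = stress reduction under intervention).  Observed values are
optionally rounded to integers (half away from zero) and clipped to the 1-10
response scale; each day is independently missing (MCAR); the daily
performed-exercise flag agrees with the assigned phase with probability
``adherence_prob`` (errors symmetric in both phase types).

Defaults emulate the study conditions the analysis targets: 28-day trials
with weekly alternating phases, within-person lag-1 autocorrelation 0.8,
marginal residual SD 2.41 (innovation SD 2.41*sqrt(1-rho^2)), slightly lower
weekend stress, ~47% of daily entries missing, ~92% protocol adherence.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import (
    STRESS_MAX,
    STRESS_MIN,
    ARMS,
    CohortDataset,
    ParticipantSeries,
    PRORecord,
    TrialSchedule,
    assign_sequence,
)

#: marginal SD of the AR1 error process assumed at the design stage (points)
DESIGN_RESIDUAL_SD = 2.41
#: lag-1 autocorrelation assumed at the design stage
DESIGN_AUTOCORRELATION = 0.8


def innovation_sd_from_marginal(marginal_sd: float, rho: float) -> float:
    """Innovation SD of a stationary AR1 with given marginal SD."""
    return marginal_sd * math.sqrt(1.0 - rho * rho)


@dataclass
class GenParams:
    """Cohort generator settings (all stress quantities in scale points)."""

    n_participants: int = 76
    baseline_mean: float = 4.0
    baseline_sd_between: float = 1.0
    mean_effect: float = -0.18
    effect_sd_between: float = 1.0
    ar_coefficient: float = DESIGN_AUTOCORRELATION
    innovation_sd: Optional[float] = None  # derived from marginal SD 2.41 if None
    weekend_offset: float = -0.5
    missing_prob: float = 0.47
    adherence_prob: float = 0.919
    integer_rounding: bool = True
    clip_to_scale: bool = True
    weekend_days: tuple = (6, 0)  # day_index mod 7; default days 6,7 of each week
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must satisfy |rho| < 1 (stationarity)")
        if not 0.0 <= self.missing_prob < 1.0:
            raise ValueError("missing_prob must be in [0, 1)")
        if not 0.0 < self.adherence_prob <= 1.0:
            raise ValueError("adherence_prob must be in (0, 1]")
        if self.n_participants < 0:
            raise ValueError("n_participants must be non-negative")
        if self.innovation_sd is None:
            self.innovation_sd = innovation_sd_from_marginal(
                DESIGN_RESIDUAL_SD, self.ar_coefficient
            )
        if self.innovation_sd < 0:
            raise ValueError("innovation_sd must be non-negative")


def _round_half_away(v: np.ndarray) -> np.ndarray:
    return np.sign(v) * np.floor(np.abs(v) + 0.5)


def _ar1_path(rng: np.random.Generator, n: int, rho: float, sigma: float) -> np.ndarray:
    eps = np.empty(n)
    if sigma == 0.0:
        eps[:] = 0.0
        return eps
    eps[0] = rng.normal(0.0, sigma / math.sqrt(1.0 - rho * rho))
    eta = rng.normal(0.0, sigma, size=n - 1)
    for t in range(1, n):
        eps[t] = rho * eps[t - 1] + eta[t - 1]
    return eps


def generate_participant(
    params: GenParams,
    schedule: TrialSchedule,
    participant_seed: int,
    participant_id: Optional[str] = None,
    arm: Optional[str] = None,
) -> ParticipantSeries:
    """Simulate one participant's series under the given schedule.

    The returned series carries ``truth`` with the simulated intercept,
    effect and the latent AR1 residuals of both outcomes (used by recovery
    tests and :func:`true_effect_table`).
    """
    if schedule.total_days < 2:
        raise ValueError("degenerate schedule: need at least 2 study days")
    rng = np.random.default_rng(participant_seed)
    n = schedule.total_days
    days = np.arange(1, n + 1)
    x = np.array([1.0 if schedule.phase_of_day(d) == "A" else 0.0 for d in days])
    weekend = np.isin(days % 7, np.asarray(params.weekend_days)).astype(float)

    alpha_i = rng.normal(params.baseline_mean, params.baseline_sd_between)
    tau_i = rng.normal(params.mean_effect, params.effect_sd_between)

    latents, observed = {}, {}
    residuals = {}
    for name in ("stress_today", "stress_next"):
        eps = _ar1_path(rng, n, params.ar_coefficient, params.innovation_sd)
        latent = alpha_i + tau_i * x + params.weekend_offset * weekend + eps
        y = latent.copy()
        if params.integer_rounding:
            y = _round_half_away(y)
        if params.clip_to_scale:
            y = np.clip(y, STRESS_MIN, STRESS_MAX)
        latents[name] = latent
        residuals[name] = eps
        observed[name] = y

    missing = rng.random(n) < params.missing_prob
    adherent = rng.random(n) < params.adherence_prob

    pid = participant_id if participant_id is not None else f"P{participant_seed}"
    records = []
    for t in range(n):
        if missing[t]:
            records.append(PRORecord(pid, int(days[t]), schedule.phase_of_day(int(days[t]))))
            continue
        in_a = x[t] == 1.0
        performed = in_a if adherent[t] else not in_a
        records.append(
            PRORecord(
                pid,
                int(days[t]),
                schedule.phase_of_day(int(days[t])),
                performed=bool(performed),
                stress_today=float(observed["stress_today"][t]),
                stress_next=float(observed["stress_next"][t]),
                check_range=params.clip_to_scale,
            )
        )
    truth = {
        "alpha": float(alpha_i),
        "tau": float(tau_i),
        "latent": {k: v.copy() for k, v in latents.items()},
        "latent_residuals": {k: v.copy() for k, v in residuals.items()},
        "missing": missing.copy(),
        "adherent": adherent.copy(),
    }
    return ParticipantSeries(pid, schedule, records, arm=arm, truth=truth)


def generate_cohort(params: GenParams, schedule_template: Optional[TrialSchedule] = None) -> CohortDataset:
    """Simulate a cohort; sequences alternate in enrollment order.

    Per-participant seeds derive deterministically from the master seed via
    numpy's SeedSequence, so the same ``params.seed`` always reproduces the
    same dataset.
    """
    ss = np.random.SeedSequence(params.seed)
    child_states = ss.generate_state(max(params.n_participants, 1))
    participants = []
    for i in range(params.n_participants):
        sched = assign_sequence(i)
        if schedule_template is not None:
            sched = TrialSchedule(
                sched.sequence,
                schedule_template.phase_length_days,
                schedule_template.n_phases,
            )
        participants.append(
            generate_participant(
                params,
                sched,
                int(child_states[i]),
                participant_id=f"P{i + 1:03d}",
                arm=ARMS[i % 2],
            )
        )
    return CohortDataset(participants)


def true_effect_table(cohort: CohortDataset) -> pd.DataFrame:
    """Ground-truth individual effects tau_i of a synthetic cohort."""
    rows = []
    for p in cohort:
        if p.truth is None:
            raise ValueError(
                f"participant {p.participant_id} has no stored ground truth; "
                "true_effect_table only applies to synthetic cohorts"
            )
        rows.append({"participant_id": p.participant_id, "tau_true": p.truth["tau"]})
    return pd.DataFrame(rows, columns=["participant_id", "tau_true"])


def write_truth_json(cohort: CohortDataset, path) -> None:
    """Sidecar JSON of simulated per-participant parameters."""
    payload = {
        p.participant_id: {"alpha": p.truth["alpha"], "tau": p.truth["tau"]}
        for p in cohort
        if p.truth is not None
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
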