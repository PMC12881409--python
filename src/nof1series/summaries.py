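"""Posterior effect summaries, responder classification and reduction curves.

The treatment effect tau is on the stress scale (points); negative values
mean stress reduction under intervention.  A clinically relevant effect is a
reduction of at least ``clinical_threshold`` points (default 0.5), and a
participant is a responder when the posterior probability of that reduction,
rounded to ``probability_rounding`` decimals, reaches
``responder_prob_threshold`` (default 70%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ar1 import PosteriorDraws


@dataclass(frozen=True)
class AnalysisConfig:
    clinical_threshold: float = 0.5
    responder_prob_threshold: float = 0.70
    probability_rounding: int = 2

    def __post_init__(self) -> None:
        if self.clinical_threshold <= 0:
            raise ValueError("clinical_threshold must be positive")
        if not 0.0 < self.responder_prob_threshold < 1.0:
            raise ValueError("responder_prob_threshold must be in (0, 1)")


@dataclass(frozen=True)
class EffectSummary:
    posterior_mean: float
    credible_interval_95: Tuple[float, float]
    p_any_reduction: float
    p_clinically_relevant: float
    responder: bool

    def as_dict(self) -> dict:
        lo, hi = self.credible_interval_95
        return {
            "posterior_mean": self.posterior_mean,
            "ci_lower": lo,
            "ci_upper": hi,
            "p_any_reduction": self.p_any_reduction,
            "p_clinically_relevant": self.p_clinically_relevant,
            "responder": self.responder,
        }


def classify_responder(
    p_clinically_relevant: float, config: Optional[AnalysisConfig] = None
) -> bool:
    """Responder rule: round the probability first, then compare (inclusive).

    Rounding to 2 decimals is what makes a posterior probability of 69.75%
    count as the 70% threshold being reached.
    """
    config = config or AnalysisConfig()
    if not 0.0 <= p_clinically_relevant <= 1.0:
        raise ValueError("probability must be in [0, 1]")
    rounded = round(p_clinically_relevant, config.probability_rounding)
    return rounded >= config.responder_prob_threshold


def summarize_effect(
    draws, config: Optional[AnalysisConfig] = None, parameter: str = "tau"
) -> EffectSummary:
    """Posterior mean, equal-tailed 95% CI and one-sided reduction
    probabilities of the treatment effect, pooled over chains.

    ``draws`` may be a PosteriorDraws or a bare array of effect draws.
    """
    config = config or AnalysisConfig()
    if isinstance(draws, PosteriorDraws):
        if parameter not in draws.draws:
            raise ValueError(f"parameter {parameter!r} not present in draws")
        tau = draws.pooled(parameter)
    else:
        tau = np.asarray(draws, dtype=float).reshape(-1)
    if tau.size == 0:
        raise ValueError("empty draws")
    lo, hi = np.quantile(tau, [0.025, 0.975])
    p_any = float(np.mean(tau < 0.0))
    p_clin = float(np.mean(tau <= -config.clinical_threshold))
    return EffectSummary(
        posterior_mean=float(np.mean(tau)),
        credible_interval_95=(float(lo), float(hi)),
        p_any_reduction=p_any,
        p_clinically_relevant=p_clin,
        responder=classify_responder(p_clin, config),
    )


def reduction_curve(draws, grid: Sequence[float], parameter: str = "tau") -> pd.DataFrame:
    """Cumulative posterior probability P(reduction > x) over a grid.

    Reduction is -tau, so positive curve values mean a stress decrease.  The
    curve is non-increasing; at x=0 it equals P(any reduction).
    """
    g = np.asarray(grid, dtype=float)
    if g.size == 0:
        raise ValueError("empty grid")
    if np.any(np.diff(g) < 0):
        raise ValueError("grid must be ordered")
    if isinstance(draws, PosteriorDraws):
        tau = draws.pooled(parameter)
    else:
        tau = np.asarray(draws, dtype=float).reshape(-1)
    if tau.size == 0:
        raise ValueError("empty draws")
    reduction = -tau
    probs = np.array([np.mean(reduction > x) for x in g])
    return pd.DataFrame({"x": g, "probability": probs})


def cohort_effect_table(
    summaries: Dict[str, EffectSummary],
    arms: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Per-participant summary table, sorted by posterior mean.

    Adds an ``arm`` column when a participant->arm mapping is given; the
    attached ``.attrs`` carry responder counts per arm and the counts of
    negative/positive posterior means.
    """
    if not summaries:
        raise ValueError("need at least one summary")
    rows = []
    for pid, s in summaries.items():
        row = {"participant_id": pid, **s.as_dict()}
        if arms is not None:
            row["arm"] = arms.get(pid)
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("posterior_mean", ignore_index=True)
    if arms is not None:
        responders_per_arm = (
            table[table["responder"]].groupby("arm", dropna=False).size().to_dict()
        )
    else:
        responders_per_arm = {None: int(table["responder"].sum())}
    table.attrs["responders_per_arm"] = responders_per_arm
    table.attrs["n_responders"] = int(table["responder"].sum())
    table.attrs["n_negative_mean"] = int((table["posterior_mean"] < 0).sum())
    table.attrs["n_positive_mean"] = int((table["posterior_mean"] > 0).sum())
    return table
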