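"""Questionnaire scoring with per-instrument missing-item rules.

Every instrument is described by a :class:`ScaleDefinition` (item count,
response range, reverse-coded items, the rule deciding when too many items
are missing, and the score transform).  Scoring reverse-codes first, imputes
each missing item with the row-wise mean of the answered (reverse-coded)
items, then applies the transform — so a definition is pure config and any
deviation from the shipped instrument versions is correctable without code
changes.

Shipped definitions (registry ``INSTRUMENTS``) follow the standard German
short forms: WPCS (COPSOQ work-privacy conflict, 5 items), CBI personal
burnout (6 items), PSS-10, SWLS, Over-Commitment (6 items) and the ERI
short form (3 effort / 7 reward items); the SUS has its own scorer with the
classical odd/even scoring rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np


@dataclass(frozen=True)
class ScaleDefinition:
    name: str
    n_items: int
    item_range: Tuple[float, float]
    reverse_items: frozenset = frozenset()  # 1-based indices
    max_missing_count: Optional[int] = None
    min_answered_fraction: Optional[float] = None
    transform: str = "sum"  # sum | mean | pos_scale_0_100
    output_range: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError("n_items must be positive")
        if any(not 1 <= i <= self.n_items for i in self.reverse_items):
            raise ValueError("reverse_items must be 1-based indices within n_items")
        if (self.max_missing_count is None) == (self.min_answered_fraction is None):
            raise ValueError(
                "exactly one of max_missing_count / min_answered_fraction required"
            )
        if self.transform not in ("sum", "mean", "pos_scale_0_100"):
            raise ValueError(f"unknown transform {self.transform!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "ScaleDefinition":
        d = dict(d)
        d["item_range"] = tuple(d["item_range"])
        if d.get("output_range") is not None:
            d["output_range"] = tuple(d["output_range"])
        d["reverse_items"] = frozenset(d.get("reverse_items", ()))
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "ScaleDefinition":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class ScaleResult:
    score: Optional[float]
    n_imputed: int
    valid: bool


INSTRUMENTS: Dict[str, ScaleDefinition] = {
    "wpcs": ScaleDefinition(
        name="wpcs", n_items=5, item_range=(0, 4),
        min_answered_fraction=0.5, transform="pos_scale_0_100",
        output_range=(0, 100),
    ),
    "cbi": ScaleDefinition(
        name="cbi", n_items=6, item_range=(0, 4),
        min_answered_fraction=0.5, transform="pos_scale_0_100",
        output_range=(0, 100),
    ),
    "pss": ScaleDefinition(
        name="pss", n_items=10, item_range=(0, 4),
        reverse_items=frozenset({4, 5, 7, 8}),
        max_missing_count=1, transform="sum", output_range=(0, 40),
    ),
    "swls": ScaleDefinition(
        name="swls", n_items=5, item_range=(1, 7),
        max_missing_count=1, transform="sum", output_range=(5, 35),
    ),
    "oc": ScaleDefinition(
        name="oc", n_items=6, item_range=(1, 4),
        reverse_items=frozenset({1, 4}),
        max_missing_count=2, transform="sum", output_range=(6, 24),
    ),
}

#: ERI short form item counts: 3 effort and 7 reward items, 4-point Likert.
ERI_N_EFFORT, ERI_N_REWARD = 3, 7
ERI_ITEM_RANGE = (1, 4)


def _check_range(values: Sequence[Optional[float]], rng: Tuple[float, float], name: str):
    lo, hi = rng
    for i, v in enumerate(values, start=1):
        if v is not None and not lo <= v <= hi:
            raise ValueError(f"{name} item {i}: value {v} outside [{lo}, {hi}]")


def _impute_row_mean(values, reverse, rng):
    """Reverse-code, then replace missing items by the row mean of the
    answered reverse-coded items.  Returns (items array, n_imputed)."""
    lo, hi = rng
    coded = [
        None if v is None else (lo + hi - v if (i + 1) in reverse else float(v))
        for i, v in enumerate(values)
    ]
    answered = [v for v in coded if v is not None]
    row_mean = float(np.mean(answered))
    n_imputed = sum(v is None for v in coded)
    full = np.array([row_mean if v is None else v for v in coded])
    return full, n_imputed


def score_scale(
    responses: Sequence[Optional[float]], definition: ScaleDefinition
) -> ScaleResult:
    """Score one respondent's row under the instrument's missing-item rule."""
    if len(responses) != definition.n_items:
        raise ValueError(
            f"{definition.name}: expected {definition.n_items} responses, "
            f"got {len(responses)}"
        )
    _check_range(responses, definition.item_range, definition.name)
    n_missing = sum(v is None for v in responses)
    n_answered = definition.n_items - n_missing
    if definition.max_missing_count is not None:
        valid = n_missing <= definition.max_missing_count
    else:
        valid = n_answered / definition.n_items >= definition.min_answered_fraction
    if not valid or n_answered == 0:
        return ScaleResult(score=None, n_imputed=0, valid=False)

    items, n_imputed = _impute_row_mean(
        responses, definition.reverse_items, definition.item_range
    )
    lo, hi = definition.item_range
    if definition.transform == "sum":
        score = float(items.sum())
    elif definition.transform == "mean":
        score = float(items.mean())
    else:  # pos_scale_0_100: mean of items rescaled to 0..100
        score = float(np.mean((items - lo) / (hi - lo) * 100.0))
    return ScaleResult(score=score, n_imputed=n_imputed, valid=True)


def score_eri(
    effort_responses: Sequence[Optional[float]],
    reward_responses: Sequence[Optional[float]],
    max_missing_total: int = 1,
    item_range: Tuple[float, float] = ERI_ITEM_RANGE,
) -> ScaleResult:
    """Effort-reward imbalance ratio sum(E) / (sum(R) * c), c = n_E/n_R.

    Row-mean imputation is applied separately within the effort and reward
    blocks; the row is invalid with more than ``max_missing_total`` missing
    items overall.  A ratio of 1 marks balance, >1 an unfavorable excess of
    effort over reward.
    """
    _check_range(effort_responses, item_range, "eri effort")
    _check_range(reward_responses, item_range, "eri reward")
    n_missing = sum(v is None for v in effort_responses) + sum(
        v is None for v in reward_responses
    )
    if n_missing > max_missing_total:
        return ScaleResult(score=None, n_imputed=0, valid=False)
    if all(v is None for v in effort_responses) or all(
        v is None for v in reward_responses
    ):
        return ScaleResult(score=None, n_imputed=0, valid=False)
    effort, ni_e = _impute_row_mean(effort_responses, frozenset(), item_range)
    reward, ni_r = _impute_row_mean(reward_responses, frozenset(), item_range)
    c = len(effort) / len(reward)
    score = float(effort.sum() / (reward.sum() * c))
    return ScaleResult(score=score, n_imputed=ni_e + ni_r, valid=True)


def score_sus(responses: Sequence[Optional[float]]) -> ScaleResult:
    """System Usability Scale: 10 items on 1-5, score 0-100.

    Odd items contribute (value - 1), even items (5 - value); the sum is
    multiplied by 2.5.  Any missing item invalidates the row (no imputation
    rule exists for the SUS).
    """
    if len(responses) != 10:
        raise ValueError(f"SUS has 10 items, got {len(responses)}")
    _check_range(responses, (1, 5), "sus")
    if any(v is None for v in responses):
        return ScaleResult(score=None, n_imputed=0, valid=False)
    total = sum(
        (v - 1.0) if (i + 1) % 2 == 1 else (5.0 - v) for i, v in enumerate(responses)
    )
    return ScaleResult(score=float(total * 2.5), n_imputed=0, valid=True)
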