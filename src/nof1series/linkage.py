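"""Protocol-adherence accounting and anonymous longitudinal record linkage.

Adherence: a documented day is protocol-adherent when the exercise was
performed in an intervention (A) phase or not performed in a control (B)
phase.

Linkage: surveys collected at different times are joined without any
identifying data via a self-generated identification code (SGIC) built from
stable personal facts (mother's name, birthplace, sex at birth, older
siblings, parental house number and postal code).  Codes are matched exactly
first, then fuzzily at optimal-string-alignment distance <= 1; ties are
flagged as ambiguous rather than auto-matched.
"""

from __future__ import annotations

import unicodedata
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .cohort import CohortDataset


# ---------------------------------------------------------------------------
# Adherence
# ---------------------------------------------------------------------------

@dataclass
class AdherenceReport:
    """Adherent/documented counts per (arm, phase-type) cell plus overall."""

    cells: Dict[Tuple[Optional[str], str], Tuple[int, int]]
    adherent_total: int
    documented_total: int

    @property
    def overall_fraction(self) -> float:
        return self.adherent_total / self.documented_total

    def cell_fraction(self, arm: Optional[str], phase: str) -> float:
        adherent, documented = self.cells[(arm, phase)]
        return adherent / documented

    def as_rows(self) -> List[dict]:
        rows = []
        for (arm, phase), (adh, doc) in sorted(
            self.cells.items(), key=lambda kv: (str(kv[0][0]), kv[0][1])
        ):
            rows.append(
                {
                    "arm": arm,
                    "phase": phase,
                    "adherent": adh,
                    "documented": doc,
                    "fraction": adh / doc,
                }
            )
        return rows


def compute_adherence(dataset: CohortDataset) -> AdherenceReport:
    """Adherence fractions over all documented records carrying a flag."""
    cells: Dict[Tuple[Optional[str], str], List[int]] = {}
    total_adh = total_doc = 0
    for p in dataset:
        for r in p.records:
            if r.performed is None:
                continue
            adherent = r.performed if r.phase == "A" else not r.performed
            key = (p.arm, r.phase)
            cell = cells.setdefault(key, [0, 0])
            cell[0] += int(adherent)
            cell[1] += 1
            total_adh += int(adherent)
            total_doc += 1
    if total_doc == 0:
        raise ValueError("no documented records with a performed flag")
    return AdherenceReport(
        cells={k: (v[0], v[1]) for k, v in cells.items()},
        adherent_total=total_adh,
        documented_total=total_doc,
    )


# ---------------------------------------------------------------------------
# Self-generated identification codes
# ---------------------------------------------------------------------------

_SEX_SYMBOLS = {
    "f": "F", "female": "F", "w": "F", "weiblich": "F",
    "m": "M", "male": "M", "maennlich": "M", "männlich": "M",
    "x": "X", "d": "X", "diverse": "X", "divers": "X", "other": "X",
}


@dataclass(frozen=True)
class SGICAnswers:
    mother_first_name: str
    birthplace: str
    sex_at_birth: str
    older_siblings: int
    parent_house_number: str
    parent_postal_code: str

    def __post_init__(self) -> None:
        if self.older_siblings < 0:
            raise ValueError("older_siblings must be non-negative")


def _fold_letters(text: str, n: int) -> Tuple[str, bool]:
    """First n letters, uppercased and diacritics-folded; '_'-padded."""
    folded = unicodedata.normalize("NFKD", text)
    letters = [c.upper() for c in folded if c.isalpha() and not unicodedata.combining(c)]
    padded = len(letters) < n
    out = "".join(letters[:n]).ljust(n, "_")
    return out, padded


def _last_digit(text: str) -> Tuple[str, bool]:
    digits = [c for c in str(text) if c.isdigit()]
    if not digits:
        return "_", True
    return digits[-1], False


def build_sgic(answers: SGICAnswers, include_sex: bool = True) -> str:
    """Deterministic identification code from the six SGIC prompts.

    Layout: mother's first two letters + birthplace's first two letters +
    sex symbol (F/M/X; dropped when ``include_sex`` is False) + older-sibling
    count as one digit (capped at 9) + last digit of the parental house
    number + last digit of the parental postal code.  Fields too short to
    fill their slots are '_'-padded and a warning is emitted.
    """
    mother, pad1 = _fold_letters(answers.mother_first_name, 2)
    place, pad2 = _fold_letters(answers.birthplace, 2)
    sex = _SEX_SYMBOLS.get(answers.sex_at_birth.strip().lower(), "X")
    siblings = str(min(answers.older_siblings, 9))
    house, pad3 = _last_digit(answers.parent_house_number)
    postal, pad4 = _last_digit(answers.parent_postal_code)
    if pad1 or pad2 or pad3 or pad4:
        warnings.warn("SGIC answers too short; code padded with '_'", stacklevel=2)
    middle = sex if include_sex else ""
    return mother + place + middle + siblings + house + postal


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def osa_distance(a: str, b: str) -> int:
    """Optimal string alignment distance (edits + adjacent transpositions)."""
    la, lb = len(a), len(b)
    prev2: List[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        prev2, prev = prev, cur
    return prev[lb]


def hamming_distance(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("Hamming distance needs equal-length codes")
    return sum(c1 != c2 for c1, c2 in zip(a, b))


@dataclass
class LinkageResult:
    """Disjoint partition of follow-up codes after two-stage matching."""

    exact: List[Tuple[str, str]] = field(default_factory=list)
    fuzzy: List[Tuple[str, str, int]] = field(default_factory=list)
    ambiguous: List[str] = field(default_factory=list)
    unmatched: List[str] = field(default_factory=list)
    duplicate_baselines: List[str] = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return len(self.exact) + len(self.fuzzy)


def match_codes(
    baseline_codes: Sequence[str],
    followup_codes: Sequence[str],
    max_distance: int = 1,
    metric: str = "osa",
) -> LinkageResult:
    """Two-stage linkage of follow-up codes against baseline codes.

    Stage 1 removes exact matches.  Stage 2 matches each remaining follow-up
    to the remaining baselines at distance <= ``max_distance``; a follow-up
    with more than one candidate at the minimal distance is reported as
    ambiguous (manual confirmation territory), never auto-matched.
    Duplicated baseline codes cannot identify anyone and are excluded and
    reported.
    """
    dist = {"osa": osa_distance, "hamming": hamming_distance}[metric]
    result = LinkageResult()

    seen: Dict[str, int] = {}
    for code in baseline_codes:
        seen[code] = seen.get(code, 0) + 1
    result.duplicate_baselines = sorted(c for c, k in seen.items() if k > 1)
    available = {c for c, k in seen.items() if k == 1}

    pending = []
    for code in followup_codes:
        if code in available:
            result.exact.append((code, code))
            available.discard(code)
        else:
            pending.append(code)

    for code in pending:
        candidates = [(dist(code, b), b) for b in sorted(available)]
        candidates = [(d, b) for d, b in candidates if d <= max_distance]
        if not candidates:
            result.unmatched.append(code)
            continue
        dmin = min(d for d, _ in candidates)
        best = [b for d, b in candidates if d == dmin]
        if len(best) > 1:
            result.ambiguous.append(code)
        else:
            result.fuzzy.append((best[0], code, dmin))
            available.discard(best[0])
    return result


@dataclass(frozen=True)
class LinkageRates:
    exact_fraction: float
    total_fraction: float

    @property
    def exact_percent(self) -> float:
        return round(100.0 * self.exact_fraction, 1)

    @property
    def total_percent(self) -> float:
        return round(100.0 * self.total_fraction, 1)


def linkage_rate(result: LinkageResult, n_followups: int) -> LinkageRates:
    """Exact and total (exact+fuzzy) matching rates among follow-ups."""
    if n_followups == 0:
        raise ValueError("n_followups must be positive")
    if n_followups < result.n_matched:
        raise ValueError("n_followups smaller than the matched count")
    return LinkageRates(
        exact_fraction=len(result.exact) / n_followups,
        total_fraction=result.n_matched / n_followups,
    )
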