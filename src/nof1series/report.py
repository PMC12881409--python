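"""Descriptive summaries and the end-to-end analysis pipeline.

``summarize_arms`` pools documented observations across participants within
each (arm, outcome, phase-type) cell — so n counts total documented PROs —
and reports the intervention-minus-control mean difference per arm and
outcome.  ``summarize_followup`` tabulates categorical follow-up answers
with per-arm and pooled counts/percentages.  ``run_pipeline`` drives
generate/ingest -> individual fits -> population fit -> summaries ->
adherence -> CSV/JSON artifacts from a single YAML/JSON config.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .ar1 import IdentifiabilityError, MCMCConfig, fit_individual, fit_population
from .cohort import OUTCOME_NAMES, CohortDataset, read_pro_csv, write_pro_csv
from .linkage import compute_adherence
from .simulate import GenParams, generate_cohort, write_truth_json
from .summaries import AnalysisConfig, cohort_effect_table, reduction_curve, summarize_effect

logger = logging.getLogger("nof1series")

AGREEMENT_CATEGORIES = ("Somewhat agree", "Agree")


def round_half_away(value: float, decimals: int = 1) -> float:
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)


def percent_text(value: float) -> str:
    """Prose-style percentage: 1 decimal, trailing zeros trimmed (58, 47.1)."""
    r = round_half_away(value, 1)
    return f"{r:.1f}".rstrip("0").rstrip(".")


@dataclass
class ArmPhaseSummary:
    """Pooled cell statistics plus per-arm intervention-control differences."""

    cells: pd.DataFrame  # arm, outcome, phase, mean, sd, n
    differences: pd.DataFrame  # arm, outcome, dif
    intervention_documented_fraction: float

    def cell(self, arm: str, outcome: str, phase: str) -> pd.Series:
        m = self.cells
        sel = m[(m.arm == arm) & (m.outcome == outcome) & (m.phase == phase)]
        if sel.empty:
            raise KeyError((arm, outcome, phase))
        return sel.iloc[0]


def summarize_arms(dataset: CohortDataset, outcomes: Sequence[str] = OUTCOME_NAMES) -> ArmPhaseSummary:
    """Mean/SD/count of documented outcomes pooled within each cell.

    Dif is the intervention-cell mean minus the control-cell mean; empty
    cells are reported as missing (NaN), never as zero.
    """
    rows = []
    for arm in sorted({p.arm for p in dataset}, key=str):
        for outcome in outcomes:
            values = {"A": [], "B": []}
            for p in dataset:
                if p.arm != arm:
                    continue
                for r in p.records:
                    v = r.outcome(outcome)
                    if v is not None:
                        values[r.phase].append(v)
            for phase in ("A", "B"):
                arr = np.asarray(values[phase], dtype=float)
                rows.append(
                    {
                        "arm": arm,
                        "outcome": outcome,
                        "phase": phase,
                        "mean": float(arr.mean()) if arr.size else float("nan"),
                        "sd": float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
                        "n": int(arr.size),
                    }
                )
    cells = pd.DataFrame(rows)
    difs = []
    for (arm, outcome), grp in cells.groupby(["arm", "outcome"], dropna=False):
        by_phase = grp.set_index("phase")
        difs.append(
            {
                "arm": arm,
                "outcome": outcome,
                "dif": float(by_phase.loc["A", "mean"] - by_phase.loc["B", "mean"]),
            }
        )
    n_a = int(cells[cells.phase == "A"]["n"].sum())
    n_total = int(cells["n"].sum())
    return ArmPhaseSummary(
        cells=cells,
        differences=pd.DataFrame(difs),
        intervention_documented_fraction=n_a / n_total if n_total else float("nan"),
    )


@dataclass
class FollowupSummary:
    """Counts and percentages per (item, arm, category) plus pooled shares."""

    table: pd.DataFrame  # item, arm, category, n, percent

    def pooled_share(self, item: str, categories: Sequence[str]) -> float:
        """Pooled fraction of answers to ``item`` in the given categories."""
        sel = self.table[self.table.item == item]
        if sel.empty:
            raise KeyError(item)
        total = sel["n"].sum()
        hit = sel[sel.category.isin(list(categories))]["n"].sum()
        return float(hit / total)

    def pooled_agreement(self, item: str) -> float:
        return self.pooled_share(item, AGREEMENT_CATEGORIES)

    def arm_share(self, item: str, arm: str, categories: Sequence[str]) -> float:
        sel = self.table[(self.table.item == item) & (self.table.arm == arm)]
        if sel.empty:
            raise KeyError((item, arm))
        return float(sel[sel.category.isin(list(categories))]["n"].sum() / sel["n"].sum())


def summarize_followup(
    responses: pd.DataFrame,
    categories_per_item: Optional[Dict[str, Sequence[str]]] = None,
) -> FollowupSummary:
    """Tabulate categorical follow-up responses.

    ``responses`` is long-format with columns item, arm, category and
    optionally n (pre-aggregated counts; default 1 per row).  When a closed
    category list is supplied per item, unknown categories raise.
    """
    df = responses.copy()
    if "n" not in df.columns:
        df["n"] = 1
    if categories_per_item is not None:
        for item, grp in df.groupby("item"):
            allowed = set(categories_per_item.get(item, ()))
            unknown = sorted(set(grp.category) - allowed)
            if unknown:
                raise ValueError(f"item {item!r}: unknown categories {unknown}")
    agg = (
        df.groupby(["item", "arm", "category"], dropna=False)["n"]
        .sum()
        .reset_index()
    )
    agg["percent"] = agg["n"] / agg.groupby(["item", "arm"])["n"].transform("sum") * 100.0
    return FollowupSummary(table=agg)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _load_config(path) -> dict:
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def run_pipeline(config_path, output_dir: Optional[str] = None) -> dict:
    """Execute the full analysis described by a YAML/JSON config.

    Config keys: ``input_csv`` (ingest) or ``synthetic`` (GenParams fields),
    ``outcomes`` (default both), ``mcmc`` (MCMCConfig fields), ``analysis``
    (AnalysisConfig fields), ``population`` (bool, default true), ``seed``,
    ``output_dir``.  Per-participant fit failures are logged and reported,
    not fatal (all available data are analyzed regardless of completeness).
    Returns a manifest dict of written artifacts; artifacts are byte-stable
    given config + seed.
    """
    cfg = _load_config(config_path)
    out_dir = Path(output_dir or cfg.get("output_dir", "nof1_report"))
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    try:
        seed = int(cfg.get("seed", 0))
        import nof1series
        logger.info("nof1series %s, seed %d", nof1series.__version__, seed)

        if "input_csv" in cfg:
            dataset = read_pro_csv(cfg["input_csv"])
            logger.info("ingested %d participants from %s", len(dataset), cfg["input_csv"])
        elif "synthetic" in cfg:
            params = GenParams(**{**cfg["synthetic"], "seed": seed})
            dataset = generate_cohort(params)
            write_pro_csv(dataset, out_dir / "cohort.csv")
            write_truth_json(dataset, out_dir / "cohort_truth.json")
            logger.info("generated synthetic cohort of %d participants", len(dataset))
        else:
            raise ValueError("config needs either 'input_csv' or 'synthetic'")

        outcomes = cfg.get("outcomes", list(OUTCOME_NAMES))
        mcmc = MCMCConfig(**{**cfg.get("mcmc", {}), "seed": seed})
        analysis = AnalysisConfig(**cfg.get("analysis", {}))
        arms = {p.participant_id: p.arm for p in dataset}

        manifest: dict = {"output_dir": str(out_dir), "failed_fits": {}}
        for outcome in outcomes:
            summaries, failed = {}, []
            for p in dataset:
                try:
                    draws = fit_individual(p, outcome, mcmc)
                except IdentifiabilityError as exc:
                    failed.append(p.participant_id)
                    logger.warning("skipping %s (%s): %s", p.participant_id, outcome, exc)
                    continue
                summaries[p.participant_id] = summarize_effect(draws, analysis)
            if summaries:
                table = cohort_effect_table(summaries, arms)
                path = out_dir / f"individual_effects_{outcome}.csv"
                table.to_csv(path, index=False)
                manifest[f"individual_effects_{outcome}"] = str(path)
                manifest[f"responders_{outcome}"] = table.attrs["responders_per_arm"]
            manifest["failed_fits"][outcome] = failed

            if cfg.get("population", True) and len(dataset) >= 2:
                try:
                    pop = fit_population(dataset, outcome, mcmc)
                except IdentifiabilityError as exc:
                    logger.warning("population fit failed (%s): %s", outcome, exc)
                    continue
                s = summarize_effect(pop, analysis)
                grid = np.round(np.arange(-1.0, 2.0001, 0.05), 10)
                curve = reduction_curve(pop, grid)
                curve_path = out_dir / f"reduction_curve_{outcome}.csv"
                curve.to_csv(curve_path, index=False)
                manifest[f"population_summary_{outcome}"] = s.as_dict()
                manifest[f"reduction_curve_{outcome}"] = str(curve_path)

        arm_summary = summarize_arms(dataset, outcomes)
        arm_summary.cells.to_csv(out_dir / "arm_phase_cells.csv", index=False)
        arm_summary.differences.to_csv(out_dir / "arm_phase_differences.csv", index=False)
        manifest["intervention_documented_fraction"] = (
            arm_summary.intervention_documented_fraction
        )

        try:
            adherence = compute_adherence(dataset)
            manifest["adherence_overall"] = adherence.overall_fraction
            pd.DataFrame(adherence.as_rows()).to_csv(
                out_dir / "adherence.csv", index=False
            )
        except ValueError as exc:
            logger.warning("adherence skipped: %s", exc)

        with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        logger.info("pipeline complete: %s", out_dir)
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()
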