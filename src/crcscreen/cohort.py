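"""Deterministic cohort engine: expected screening and CRC outcomes.

The model follows each annual would-be-screened cohort of size ``B`` through
one year.  A fraction uses colonoscopy, a fraction FIT, the remainder goes
unscreened.  Prevalent cancers (prevalence ``pi``) are screen-detected with
probability equal to the modality's sensitivity (times diagnostic-colonoscopy
adherence for FIT).  Cancers left undiagnosed — colonoscopy false negatives,
FIT false negatives, FIT true positives lost to diagnostic nonadherence, and
cancers among the unscreened — present clinically within the horizon with
probability ``q``, the symptomatic fraction, which is calibrated in closed
form to a published baseline symptom-detected count.  Detected cases draw a
stage at diagnosis from the detection route's stage distribution.  Annual
cohorts are disjoint: nobody is screened twice and undiagnosed cancers do
not carry over between years.

All quantities are expectations kept as real numbers; reporting rounds to
whole persons.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .params import (
    BASELINE_SYMPTOM_DETECTED,
    Modality,
    ParameterSet,
    Route,
    STAGES,
    SymptomaticDetectionParams,
)
from .schedules import UptakeSchedule, canonical_schedules

__all__ = [
    "CohortOutcomes",
    "ScenarioComparison",
    "OUTCOME_NAMES",
    "run_cohort",
    "undiagnosed_pool",
    "calibrate_symptomatic_fraction",
    "with_calibrated_q",
    "compare",
    "run_all_published_scenarios",
    "outcomes_to_tidy_frame",
    "outcomes_to_json",
    "round_half_away",
]

#: 3-year-total outcome names, the common vocabulary of the cohort engine,
#: the microsimulation oracle, the sensitivity module and the reports.
OUTCOME_NAMES = (
    "screened_colonoscopy",
    "screened_fit",
    "screened_total",
    "unscreened",
    "screen_detected_colonoscopy",
    "screen_detected_fit",
    "screen_detected",
    "symptom_detected",
    "total_cases",
    "stage_I_cases",
    "stage_II_cases",
    "stage_III_cases",
    "stage_IV_cases",
    "early_stage_cases",
    "late_stage_cases",
    "undiagnosed_remaining",
    "diagnostic_colonoscopies",
)


def round_half_away(x: float) -> int:
    """Round half away from zero, the convention of the published tables."""
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


@dataclass(frozen=True)
class CohortOutcomes:
    """Per-year expected counts for one scenario; arrays have length = horizon."""

    scenario_id: str
    screened_colonoscopy: np.ndarray
    screened_fit: np.ndarray
    unscreened: np.ndarray
    screen_detected_colonoscopy: np.ndarray
    screen_detected_fit: np.ndarray
    symptom_detected: np.ndarray
    undiagnosed_remaining: np.ndarray
    stage_cases: np.ndarray  # shape (horizon, 4), stages I..IV
    diagnostic_colonoscopies: np.ndarray  # FIT positives completing follow-up

    @property
    def horizon_years(self) -> int:
        return len(self.screened_colonoscopy)

    @property
    def screened_total(self) -> np.ndarray:
        return self.screened_colonoscopy + self.screened_fit

    @property
    def screen_detected(self) -> np.ndarray:
        return self.screen_detected_colonoscopy + self.screen_detected_fit

    @property
    def total_cases(self) -> np.ndarray:
        return self.screen_detected + self.symptom_detected

    @property
    def early_stage_cases(self) -> np.ndarray:
        return self.stage_cases[:, 0] + self.stage_cases[:, 1]

    @property
    def late_stage_cases(self) -> np.ndarray:
        return self.stage_cases[:, 2] + self.stage_cases[:, 3]

    @property
    def early_stage_fraction(self) -> float:
        """3-year stage I+II share of all diagnosed cases."""
        return float(self.early_stage_cases.sum() / self.total_cases.sum())

    def totals(self) -> dict[str, float]:
        """3-year totals for every outcome in :data:`OUTCOME_NAMES`."""
        stage_totals = self.stage_cases.sum(axis=0)
        return {
            "screened_colonoscopy": float(self.screened_colonoscopy.sum()),
            "screened_fit": float(self.screened_fit.sum()),
            "screened_total": float(self.screened_total.sum()),
            "unscreened": float(self.unscreened.sum()),
            "screen_detected_colonoscopy": float(self.screen_detected_colonoscopy.sum()),
            "screen_detected_fit": float(self.screen_detected_fit.sum()),
            "screen_detected": float(self.screen_detected.sum()),
            "symptom_detected": float(self.symptom_detected.sum()),
            "total_cases": float(self.total_cases.sum()),
            **{
                f"stage_{s.value}_cases": float(t)
                for s, t in zip(STAGES, stage_totals)
            },
            "early_stage_cases": float(stage_totals[0] + stage_totals[1]),
            "late_stage_cases": float(stage_totals[2] + stage_totals[3]),
            "undiagnosed_remaining": float(self.undiagnosed_remaining.sum()),
            "diagnostic_colonoscopies": float(self.diagnostic_colonoscopies.sum()),
        }


@dataclass(frozen=True)
class ScenarioComparison:
    """Outcome differences of a comparator scenario against a reference.

    ``table`` has one row per outcome with the reference and comparator
    values, the absolute difference (comparator - reference) and the percent
    difference relative to the reference (NaN where the reference is zero;
    rendered as "NA", never as infinity).
    """

    reference_id: str
    comparator_id: str
    table: pd.DataFrame

    def absolute(self, outcome: str) -> float:
        return float(self.table.loc[outcome, "absolute_difference"])

    def percent(self, outcome: str) -> float:
        return float(self.table.loc[outcome, "percent_difference"])


def _year_components(
    params: ParameterSet, schedule: UptakeSchedule, year: int
) -> dict[str, float]:
    """Expected counts for one annual cohort (unscreened renormalized)."""
    pop = params.population
    colo = params.tests[Modality.COLONOSCOPY]
    fit = params.tests[Modality.FIT]
    B = pop.annual_baseline_screeners
    pi = pop.prevalence_crc

    n_colo = B * schedule.p_colonoscopy(year)
    n_fit = B * schedule.p_fit(year)
    n_unscr = B * schedule.p_unscreened_normalized(year)

    det_colo = n_colo * pi * colo.screen_detection_probability
    det_fit = n_fit * pi * fit.screen_detection_probability
    # undiagnosed prevalent cancers: false negatives, FIT positives lost to
    # follow-up, and the unscreened
    undiag = (
        n_colo * pi * (1.0 - colo.screen_detection_probability)
        + n_fit * pi * (1.0 - fit.screen_detection_probability)
        + n_unscr * pi
    )
    positivity = fit.positivity_rate if fit.positivity_rate is not None else 0.0
    diag_colos = n_fit * positivity * fit.diagnostic_adherence
    out = {
        "screened_colonoscopy": n_colo,
        "screened_fit": n_fit,
        "unscreened": n_unscr,
        "screen_detected_colonoscopy": det_colo,
        "screen_detected_fit": det_fit,
        "undiagnosed_pool": undiag,
        "diagnostic_colonoscopies": diag_colos,
    }
    for name, value in out.items():
        if value < -1e-9:
            raise ValueError(f"negative expected count for {name}: {value}")
    return out


def undiagnosed_pool(params: ParameterSet, schedule: UptakeSchedule) -> float:
    """Total undiagnosed prevalent cancers over the horizon (before symptoms)."""
    return sum(
        _year_components(params, schedule, y)["undiagnosed_pool"]
        for y in range(1, schedule.horizon_years + 1)
    )


def run_cohort(params: ParameterSet, schedule: UptakeSchedule) -> CohortOutcomes:
    """Run the deterministic cohort model for one scenario.

    Requires a concrete symptomatic fraction ``q``; calibrate first (see
    :func:`with_calibrated_q`) or supply one in the parameter set.
    """
    if schedule.horizon_years != params.population.horizon_years:
        raise ValueError(
            f"schedule horizon {schedule.horizon_years} != population horizon "
            f"{params.population.horizon_years}"
        )
    q = params.symptomatic.q_undiagnosed
    if q is None:
        raise ValueError(
            "symptomatic fraction q is not set; calibrate with "
            "with_calibrated_q() or supply symptomatic.q_undiagnosed"
        )
    horizon = schedule.horizon_years
    cols = {
        name: np.zeros(horizon)
        for name in (
            "screened_colonoscopy",
            "screened_fit",
            "unscreened",
            "screen_detected_colonoscopy",
            "screen_detected_fit",
            "symptom_detected",
            "undiagnosed_remaining",
            "diagnostic_colonoscopies",
        )
    }
    stage_cases = np.zeros((horizon, 4))
    p_stage = {route: np.asarray(params.stages[route].p_stage) for route in Route}
    for year in range(1, horizon + 1):
        comp = _year_components(params, schedule, year)
        symptom = q * comp["undiagnosed_pool"]
        i = year - 1
        cols["screened_colonoscopy"][i] = comp["screened_colonoscopy"]
        cols["screened_fit"][i] = comp["screened_fit"]
        cols["unscreened"][i] = comp["unscreened"]
        cols["screen_detected_colonoscopy"][i] = comp["screen_detected_colonoscopy"]
        cols["screen_detected_fit"][i] = comp["screen_detected_fit"]
        cols["symptom_detected"][i] = symptom
        cols["undiagnosed_remaining"][i] = comp["undiagnosed_pool"] - symptom
        cols["diagnostic_colonoscopies"][i] = comp["diagnostic_colonoscopies"]
        stage_cases[i] = (
            comp["screen_detected_colonoscopy"] * p_stage[Route.SCREEN_COLONOSCOPY]
            + comp["screen_detected_fit"] * p_stage[Route.SCREEN_FIT]
            + symptom * p_stage[Route.CLINICAL]
        )
    return CohortOutcomes(scenario_id=schedule.scenario_id, stage_cases=stage_cases, **cols)


def calibrate_symptomatic_fraction(
    params: ParameterSet,
    target_symptom_detected: float = BASELINE_SYMPTOM_DETECTED,
    schedule: UptakeSchedule | None = None,
) -> SymptomaticDetectionParams:
    """Closed-form calibration of the symptomatic fraction ``q``.

    The model is linear in ``q``, so ``q = target / undiagnosed pool`` under
    the calibration schedule (the baseline schedule by default).  The result
    is clamped to [0, 1] with a warning if clamping occurs.
    """
    if target_symptom_detected < 0:
        raise ValueError("target_symptom_detected must be >= 0")
    if schedule is None:
        schedule = canonical_schedules()["baseline"]
    pool = undiagnosed_pool(params, schedule)
    if pool <= 0:
        if target_symptom_detected > 0:
            raise ValueError("undiagnosed pool is zero but the target is positive")
        return SymptomaticDetectionParams(q_undiagnosed=0.0, source="calibrated")
    q = target_symptom_detected / pool
    if q > 1.0:
        warnings.warn(
            f"calibrated q = {q:.4f} exceeds 1; clamped to 1 "
            "(target larger than the undiagnosed pool)",
            stacklevel=2,
        )
        q = 1.0
    return SymptomaticDetectionParams(q_undiagnosed=q, source="calibrated")


def with_calibrated_q(
    params: ParameterSet,
    target_symptom_detected: float = BASELINE_SYMPTOM_DETECTED,
    schedule: UptakeSchedule | None = None,
) -> ParameterSet:
    """Convenience: return ``params`` with a freshly calibrated ``q``."""
    sym = calibrate_symptomatic_fraction(params, target_symptom_detected, schedule)
    return ParameterSet(
        tests=params.tests,
        stages=params.stages,
        population=params.population,
        symptomatic=sym,
        ci_ranges=params.ci_ranges,
    )


def compare(reference: CohortOutcomes, comparator: CohortOutcomes) -> ScenarioComparison:
    """Absolute and percent outcome differences, comparator minus reference."""
    if reference.horizon_years != comparator.horizon_years:
        raise ValueError("cannot compare outcomes with different horizons")
    ref, cmp_ = reference.totals(), comparator.totals()
    rows = []
    for name in OUTCOME_NAMES:
        absolute = cmp_[name] - ref[name]
        percent = 100.0 * absolute / ref[name] if ref[name] != 0 else float("nan")
        rows.append(
            {
                "outcome": name,
                "reference": ref[name],
                "comparator": cmp_[name],
                "absolute_difference": absolute,
                "percent_difference": percent,
            }
        )
    table = pd.DataFrame(rows).set_index("outcome")
    return ScenarioComparison(
        reference_id=reference.scenario_id,
        comparator_id=comparator.scenario_id,
        table=table,
    )


def run_all_published_scenarios(
    params: ParameterSet,
    target_symptom_detected: float = BASELINE_SYMPTOM_DETECTED,
) -> tuple[dict[str, CohortOutcomes], dict[str, ScenarioComparison]]:
    """Baseline + four pandemic scenarios, with the published comparisons.

    ``q`` is calibrated once on the baseline schedule (unless the parameter
    set carries a user-supplied value) and reused for every scenario.
    Comparisons: each scenario against baseline, scenario 3 against 1, and
    scenario 4 against 2.
    """
    schedules = canonical_schedules()
    if params.symptomatic.q_undiagnosed is None or params.symptomatic.source == "calibrated":
        params = with_calibrated_q(params, target_symptom_detected, schedules["baseline"])
    outcomes = {sid: run_cohort(params, sched) for sid, sched in schedules.items()}
    comparisons = {
        f"{sid}_vs_baseline": compare(outcomes["baseline"], outcomes[sid])
        for sid in ("scenario_1", "scenario_2", "scenario_3", "scenario_4")
    }
    comparisons["scenario_3_vs_scenario_1"] = compare(
        outcomes["scenario_1"], outcomes["scenario_3"]
    )
    comparisons["scenario_4_vs_scenario_2"] = compare(
        outcomes["scenario_2"], outcomes["scenario_4"]
    )
    return outcomes, comparisons


# --------------------------------------------------------------------------
# export


def outcomes_to_tidy_frame(outcomes: Mapping[str, CohortOutcomes]) -> pd.DataFrame:
    """One row per scenario x outcome x year (plus a 3-year ``total`` row)."""
    per_year_fields = (
        "screened_colonoscopy",
        "screened_fit",
        "unscreened",
        "screen_detected_colonoscopy",
        "screen_detected_fit",
        "symptom_detected",
        "undiagnosed_remaining",
        "diagnostic_colonoscopies",
    )
    records = []
    for sid, out in outcomes.items():
        for name in per_year_fields:
            values = getattr(out, name)
            for year, value in enumerate(values, start=1):
                records.append(
                    {"scenario_id": sid, "outcome": name, "year": year, "value": value}
                )
        for year in range(1, out.horizon_years + 1):
            for stage, value in zip(STAGES, out.stage_cases[year - 1]):
                records.append(
                    {
                        "scenario_id": sid,
                        "outcome": f"stage_{stage.value}_cases",
                        "year": year,
                        "value": value,
                    }
                )
        for name, value in out.totals().items():
            records.append(
                {"scenario_id": sid, "outcome": name, "year": "total", "value": value}
            )
    return pd.DataFrame.from_records(records)


def outcomes_to_json(
    outcomes: Mapping[str, CohortOutcomes], path: str | Path | None = None
) -> str:
    """JSON export of per-year arrays and 3-year totals (rounded-free)."""
    payload = {}
    for sid, out in outcomes.items():
        payload[sid] = {
            "per_year": {
                "screened_colonoscopy": out.screened_colonoscopy.tolist(),
                "screened_fit": out.screened_fit.tolist(),
                "unscreened": out.unscreened.tolist(),
                "screen_detected_colonoscopy": out.screen_detected_colonoscopy.tolist(),
                "screen_detected_fit": out.screen_detected_fit.tolist(),
                "symptom_detected": out.symptom_detected.tolist(),
                "undiagnosed_remaining": out.undiagnosed_remaining.tolist(),
                "stage_cases": out.stage_cases.tolist(),
                "diagnostic_colonoscopies": out.diagnostic_colonoscopies.tolist(),
            },
            "totals": out.totals(),
        }
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
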