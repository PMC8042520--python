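"""Individual-level Monte-Carlo oracle for the cohort engine.

Simulates synthetic persons with exactly the statistical structure the
deterministic cohort model assumes — categorical modality choice, Bernoulli
cancer prevalence, Bernoulli test sensitivity, Bernoulli diagnostic
adherence, Bernoulli symptomatic presentation, categorical stage draw — and
scales the resulting counts to cohort size.  Replicate means converge to the
cohort engine's expectations, which makes the simulator a brute-force
validation oracle; the person-level table doubles as a synthetic dataset for
downstream demos.

The marginal FIT positivity (the published 7%) mixes true positives among
cancers with false positives among non-cancers, so the no-cancer positive
rate is derived as ``(positivity - prevalence x sensitivity) / (1 -
prevalence)``.

Persons are simulated in numpy arrays (one RNG stream per replicate,
``default_rng(seed + replicate)``), which is distributionally identical to a
per-person loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import OUTCOME_NAMES, run_cohort
from .params import Modality, ParameterSet, Route, STAGES
from .schedules import UptakeSchedule

__all__ = ["MicrosimResult", "simulate_cohort", "export_person_table"]

_PERSON_COLUMNS = (
    "replicate",
    "year",
    "modality",
    "has_crc",
    "fit_positive",
    "completed_diagnostic",
    "detection",
    "stage",
)


@dataclass(frozen=True)
class MicrosimResult:
    """Replicate summaries (cohort scale) and an optional person-level table."""

    scenario_id: str
    seed: int
    n_persons_per_year: int
    n_replicates: int
    replicates: pd.DataFrame  # rows = replicates, columns = OUTCOME_NAMES
    person_table: pd.DataFrame | None = None

    @property
    def mean(self) -> pd.Series:
        return self.replicates.mean(axis=0)

    @property
    def standard_error(self) -> pd.Series:
        if self.n_replicates < 2:
            return pd.Series(0.0, index=self.replicates.columns)
        return self.replicates.std(axis=0, ddof=1) / np.sqrt(self.n_replicates)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "se": self.standard_error})


def _fit_false_positive_rate(params: ParameterSet) -> float:
    """No-cancer FIT positive rate keeping the marginal positivity on target."""
    fit = params.tests[Modality.FIT]
    if fit.positivity_rate is None:
        return 0.0
    pi = params.population.prevalence_crc
    fpr = (fit.positivity_rate - pi * fit.sensitivity_crc) / (1.0 - pi)
    if not (0.0 <= fpr <= 1.0):
        raise ValueError(
            f"implied no-cancer FIT positive rate {fpr:.4f} outside [0, 1]; "
            "positivity, sensitivity and prevalence are inconsistent"
        )
    return fpr


def _draw_stages(rng: np.random.Generator, n: int, p_stage: np.ndarray) -> np.ndarray:
    """Categorical stage draw (0..3) for n detected cases."""
    return np.searchsorted(np.cumsum(p_stage), rng.random(n), side="right").clip(0, 3)


def _simulate_replicate(
    params: ParameterSet,
    schedule: UptakeSchedule,
    n_per_year: int,
    rng: np.random.Generator,
    keep_persons: bool,
) -> tuple[dict[str, float], list[pd.DataFrame]]:
    colo = params.tests[Modality.COLONOSCOPY]
    fit = params.tests[Modality.FIT]
    pi = params.population.prevalence_crc
    q = params.symptomatic.q_undiagnosed
    assert q is not None
    fpr = _fit_false_positive_rate(params)
    scale = params.population.annual_baseline_screeners / n_per_year
    p_stage = {r: np.asarray(params.stages[r].p_stage, dtype=float) for r in Route}

    counts = {name: 0.0 for name in OUTCOME_NAMES}
    person_frames: list[pd.DataFrame] = []
    for year in range(1, schedule.horizon_years + 1):
        p_colo = schedule.p_colonoscopy(year)
        p_fit = schedule.p_fit(year)
        u = rng.random(n_per_year)
        is_colo = u < p_colo
        is_fit = (~is_colo) & (u < p_colo + p_fit)
        is_unscr = ~(is_colo | is_fit)
        has_crc = rng.random(n_per_year) < pi

        detected_screen = np.zeros(n_per_year, dtype=bool)
        fit_positive = np.zeros(n_per_year, dtype=bool)
        completed_diag = np.zeros(n_per_year, dtype=bool)

        # colonoscopy arm: detection = sensitivity draw among cancers
        colo_draw = rng.random(n_per_year) < colo.sensitivity_crc
        detected_screen |= is_colo & has_crc & colo_draw

        # FIT arm: positivity split by cancer status, then follow-up adherence
        pos_prob = np.where(has_crc, fit.sensitivity_crc, fpr)
        fit_positive = is_fit & (rng.random(n_per_year) < pos_prob)
        completed_diag = fit_positive & (
            rng.random(n_per_year) < fit.diagnostic_adherence
        )
        detected_screen |= completed_diag & has_crc

        undiagnosed = has_crc & ~detected_screen
        symptomatic = undiagnosed & (rng.random(n_per_year) < q)

        stage_idx = np.full(n_per_year, -1, dtype=np.int8)
        for mask, route in (
            (is_colo & detected_screen, Route.SCREEN_COLONOSCOPY),
            (is_fit & detected_screen, Route.SCREEN_FIT),
            (symptomatic, Route.CLINICAL),
        ):
            k = int(mask.sum())
            if k:
                stage_idx[mask] = _draw_stages(rng, k, p_stage[route])

        diagnosed = detected_screen | symptomatic
        counts["screened_colonoscopy"] += is_colo.sum() * scale
        counts["screened_fit"] += is_fit.sum() * scale
        counts["unscreened"] += is_unscr.sum() * scale
        counts["screen_detected_colonoscopy"] += (is_colo & detected_screen).sum() * scale
        counts["screen_detected_fit"] += (is_fit & detected_screen).sum() * scale
        counts["symptom_detected"] += symptomatic.sum() * scale
        counts["undiagnosed_remaining"] += (undiagnosed & ~symptomatic).sum() * scale
        counts["diagnostic_colonoscopies"] += completed_diag.sum() * scale
        for i, stage in enumerate(STAGES):
            counts[f"stage_{stage.value}_cases"] += (
                (diagnosed & (stage_idx == i)).sum() * scale
            )

        if keep_persons:
            modality = np.where(is_colo, "colonoscopy", np.where(is_fit, "fit", "none"))
            detection = np.where(
                detected_screen, "screen", np.where(symptomatic, "symptom", "none")
            )
            stage_labels = np.array(["", "I", "II", "III", "IV"])[stage_idx + 1]
            person_frames.append(
                pd.DataFrame(
                    {
                        "year": year,
                        "modality": modality,
                        "has_crc": has_crc,
                        "fit_positive": np.where(is_fit, fit_positive, pd.NA),
                        "completed_diagnostic": np.where(is_fit, completed_diag, pd.NA),
                        "detection": detection,
                        "stage": np.where(stage_idx >= 0, stage_labels, pd.NA),
                    }
                )
            )

    counts["screened_total"] = counts["screened_colonoscopy"] + counts["screened_fit"]
    counts["screen_detected"] = (
        counts["screen_detected_colonoscopy"] + counts["screen_detected_fit"]
    )
    counts["total_cases"] = counts["screen_detected"] + counts["symptom_detected"]
    counts["early_stage_cases"] = counts["stage_I_cases"] + counts["stage_II_cases"]
    counts["late_stage_cases"] = counts["stage_III_cases"] + counts["stage_IV_cases"]
    return counts, person_frames


def simulate_cohort(
    params: ParameterSet,
    schedule: UptakeSchedule,
    n_persons_per_year: int = 200_000,
    seed: int = 0,
    n_replicates: int = 50,
    keep_person_table: bool = False,
) -> MicrosimResult:
    """Monte-Carlo simulation of the cohort model at person level.

    Counts are scaled by ``annual_baseline_screeners / n_persons_per_year``
    so replicate summaries are on cohort scale.  Replicate ``r`` uses the
    independent stream ``default_rng(seed + r)``; results are fully
    deterministic given ``(seed, n_persons_per_year, n_replicates)``.  When
    ``keep_person_table`` is set, the first replicate's person records are
    retained.
    """
    if n_persons_per_year < 1:
        raise ValueError("n_persons_per_year must be >= 1")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if params.symptomatic.q_undiagnosed is None:
        raise ValueError("symptomatic fraction q is not set; calibrate first")
    rows = []
    person_table: pd.DataFrame | None = None
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed + rep)
        counts, frames = _simulate_replicate(
            params, schedule, n_persons_per_year, rng, keep_person_table and rep == 0
        )
        rows.append(counts)
        if keep_person_table and rep == 0:
            person_table = pd.concat(frames, ignore_index=True)
            person_table.insert(0, "replicate", 0)
    replicates = pd.DataFrame(rows, columns=list(OUTCOME_NAMES))
    return MicrosimResult(
        scenario_id=schedule.scenario_id,
        seed=seed,
        n_persons_per_year=n_persons_per_year,
        n_replicates=n_replicates,
        replicates=replicates,
        person_table=person_table,
    )


def export_person_table(result: MicrosimResult, path: str | Path) -> Path:
    """Write the retained person-level table as CSV (deterministic bytes).

    Columns: replicate, year, modality (colonoscopy/fit/none), has_crc,
    fit_positive and completed_diagnostic (empty unless modality = fit),
    detection (screen/symptom/none), stage (I-IV, empty if undetected).
    """
    if result.person_table is None:
        raise ValueError(
            "person table was not retained; rerun simulate_cohort with "
            "keep_person_table=True"
        )
    path = Path(path)
    table = result.person_table.reindex(columns=list(_PERSON_COLUMNS))
    table.to_csv(path, index=False)
    return path


def oracle_check(
    params: ParameterSet,
    schedule: UptakeSchedule,
    n_persons_per_year: int = 200_000,
    seed: int = 0,
    n_replicates: int = 50,
    n_se: float = 3.0,
) -> pd.DataFrame:
    """Compare microsim means against the deterministic engine, outcome-wise.

    Returns a frame with the cohort expectation, microsim mean, Monte-Carlo
    SE and a boolean ``within`` flag (|mean - expected| <= n_se x SE, with
    an absolute floor of 1e-9 persons for exactly-deterministic outcomes).
    """
    expected = pd.Series(run_cohort(params, schedule).totals())
    sim = simulate_cohort(params, schedule, n_persons_per_year, seed, n_replicates)
    diff = (sim.mean - expected).abs()
    tol = n_se * sim.standard_error + 1e-9
    return pd.DataFrame(
        {
            "expected": expected,
            "mean": sim.mean,
            "se": sim.standard_error,
            "within": diff <= tol,
        }
    )
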