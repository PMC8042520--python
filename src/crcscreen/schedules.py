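"""Per-year modality uptake schedules for the pandemic screening scenarios.

A schedule gives, for each model year, the fractions of the annual
would-be-screened cohort completing colonoscopy, completing FIT, or going
unscreened.  The five published schedules (baseline plus four COVID-19
scenarios) are stored verbatim as whole-percent values; they are canonical
for reproducing the published results.  ``schedule_from_profile`` and
``apply_fit_expansion`` are generative utilities for constructing new
scenarios from a monthly screening-volume dispersion profile and a
FIT-outreach rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "DispersionProfile",
    "FitExpansionRule",
    "UptakeSchedule",
    "ScheduleError",
    "canonical_schedules",
    "scenario_1_profile",
    "scenario_2_profile",
    "schedule_from_profile",
    "apply_fit_expansion",
    "three_year_average",
    "schedules_to_frame",
    "save_schedules_csv",
    "save_schedules_yaml",
]

SCENARIO_IDS = ("baseline", "scenario_1", "scenario_2", "scenario_3", "scenario_4")


class ScheduleError(ValueError):
    """An uptake schedule or dispersion profile violates its invariants."""


@dataclass(frozen=True)
class DispersionProfile:
    """Timeline of screening-volume multipliers applied to baseline volume.

    ``segments`` is an ordered sequence of ``(duration_months, multiplier)``
    pairs; durations must be positive integers summing to the model horizon
    in months, multipliers lie in [0, 1] (1 = prepandemic volume).
    """

    segments: tuple[tuple[int, float], ...]
    horizon_months: int = 36

    def __post_init__(self) -> None:
        total = 0
        for months, mult in self.segments:
            if int(months) != months or months <= 0:
                raise ScheduleError(f"segment duration must be a positive int, got {months}")
            if not (0.0 <= mult <= 1.0):
                raise ScheduleError(f"volume multiplier {mult} outside [0, 1]")
            total += int(months)
        if total != self.horizon_months:
            raise ScheduleError(
                f"profile spans {total} months, expected {self.horizon_months}"
            )

    def monthly_multipliers(self) -> list[float]:
        """Expand segments to one multiplier per calendar month."""
        out: list[float] = []
        for months, mult in self.segments:
            out.extend([float(mult)] * int(months))
        return out


@dataclass(frozen=True)
class FitExpansionRule:
    """Organized FIT outreach applied to the would-be-unscreened pool.

    ``fit_completion_rate`` is the fraction of each year's unscreened pool
    that completes FIT instead; the default 22.5% is the median FIT
    completion achieved by a large integrated health system's mailed
    outreach programme.
    """

    fit_completion_rate: float = 0.225

    def __post_init__(self) -> None:
        if not (0.0 <= self.fit_completion_rate <= 1.0):
            raise ScheduleError(
                f"fit_completion_rate {self.fit_completion_rate} outside [0, 1]"
            )


@dataclass(frozen=True)
class UptakeSchedule:
    """Per-year (colonoscopy, FIT, unscreened) uptake fractions.

    Printed whole-percent rows may over- or under-sum by a point; yearly sums
    are therefore accepted in [0.99, 1.01] and the cohort engine recomputes
    the unscreened remainder as 1 - colonoscopy - FIT.
    """

    scenario_id: str
    years: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.years:
            raise ScheduleError("schedule must cover at least one year")
        for y, triple in enumerate(self.years, start=1):
            if len(triple) != 3:
                raise ScheduleError(f"year {y}: need (colonoscopy, fit, unscreened)")
            for name, p in zip(("colonoscopy", "fit", "unscreened"), triple):
                if not (0.0 <= p <= 1.0):
                    raise ScheduleError(
                        f"{self.scenario_id} year {y}: {name} fraction {p} outside [0, 1]"
                    )
            total = sum(triple)
            if not (0.99 <= total <= 1.01):
                raise ScheduleError(
                    f"{self.scenario_id} year {y}: fractions sum to {total:.3f}"
                )

    @property
    def horizon_years(self) -> int:
        return len(self.years)

    def p_colonoscopy(self, year: int) -> float:
        return self.years[year - 1][0]

    def p_fit(self, year: int) -> float:
        return self.years[year - 1][1]

    def p_unscreened_normalized(self, year: int) -> float:
        """Unscreened remainder 1 - colonoscopy - FIT (rounding-safe)."""
        c, f, _ = self.years[year - 1]
        u = 1.0 - c - f
        return u if u > 1e-12 else 0.0


def canonical_schedules() -> dict[str, UptakeSchedule]:
    """The five published schedules, whole-percent cells stored verbatim.

    Year rows only; the published year-1-to-3 average row is recomputed by
    :func:`three_year_average`, never stored.
    """
    cells = {
        "baseline": [(0.85, 0.15, 0.0)] * 3,
        "scenario_1": [(0.42, 0.08, 0.50), (0.58, 0.08, 0.34), (0.64, 0.08, 0.29)],
        "scenario_2": [(0.42, 0.08, 0.50), (0.42, 0.08, 0.50), (0.64, 0.08, 0.29)],
        "scenario_3": [(0.42, 0.17, 0.40), (0.58, 0.22, 0.19), (0.64, 0.21, 0.15)],
        "scenario_4": [(0.42, 0.17, 0.40), (0.42, 0.27, 0.31), (0.64, 0.21, 0.15)],
    }
    return {
        sid: UptakeSchedule(scenario_id=sid, years=tuple(rows))
        for sid, rows in cells.items()
    }


def scenario_1_profile() -> DispersionProfile:
    """Short disruption: 3 mo normal, 3 mo shutdown, 9 mo at 50%, 21 mo at 75%."""
    return DispersionProfile(segments=((3, 1.0), (3, 0.0), (9, 0.5), (21, 0.75)))


def scenario_2_profile() -> DispersionProfile:
    """Prolonged disruption: 3 mo normal, 3 mo shutdown, 18 mo at 50%, 12 mo at 75%."""
    return DispersionProfile(segments=((3, 1.0), (3, 0.0), (18, 0.5), (12, 0.75)))


def schedule_from_profile(
    profile: DispersionProfile,
    baseline_mix: tuple[float, float] = (0.85, 0.15),
    fit_multiplier_override: float | Sequence[float] | None = None,
    scenario_id: str = "custom",
) -> UptakeSchedule:
    """Duration-weight a monthly dispersion profile into yearly uptake rows.

    Each calendar year's modality uptake is the mean over that year's months
    of (baseline modality share x that month's volume multiplier).  If
    ``fit_multiplier_override`` is given (a single value or one value per
    profile segment), FIT uses it in place of the segment multiplier — this
    reproduces published scenarios in which FIT stays flat while colonoscopy
    volume recovers.  The unscreened fraction is the remainder.
    """
    if profile.horizon_months % 12 != 0:
        raise ScheduleError("profile horizon must be a whole number of years")
    monthly = profile.monthly_multipliers()
    if fit_multiplier_override is None:
        monthly_fit = monthly
    elif isinstance(fit_multiplier_override, (int, float)):
        monthly_fit = [float(fit_multiplier_override)] * len(monthly)
    else:
        override = list(fit_multiplier_override)
        if len(override) != len(profile.segments):
            raise ScheduleError(
                "fit_multiplier_override needs one value per profile segment"
            )
        monthly_fit = []
        for (months, _), mult in zip(profile.segments, override):
            monthly_fit.extend([float(mult)] * int(months))
    colo_share, fit_share = baseline_mix
    rows = []
    for year_start in range(0, profile.horizon_months, 12):
        vol = monthly[year_start : year_start + 12]
        vol_fit = monthly_fit[year_start : year_start + 12]
        p_colo = colo_share * sum(vol) / 12.0
        p_fit = fit_share * sum(vol_fit) / 12.0
        if p_colo + p_fit > 1.0 + 1e-12:
            raise ScheduleError("modality fractions exceed 1 for a year")
        rows.append((p_colo, p_fit, 1.0 - p_colo - p_fit))
    return UptakeSchedule(scenario_id=scenario_id, years=tuple(rows))


def apply_fit_expansion(
    schedule: UptakeSchedule,
    rule: FitExpansionRule,
    scenario_id: str | None = None,
) -> UptakeSchedule:
    """Move ``rate x p_unscreened`` from unscreened to FIT, per year.

    Colonoscopy uptake and the yearly total are conserved.
    """
    rows = []
    for c, f, u in schedule.years:
        moved = rule.fit_completion_rate * u
        rows.append((c, f + moved, u - moved))
    return UptakeSchedule(
        scenario_id=scenario_id or f"{schedule.scenario_id}+fit_expansion",
        years=tuple(rows),
    )


def three_year_average(schedule: UptakeSchedule) -> tuple[float, float, float]:
    """Unweighted mean of the yearly (colonoscopy, FIT, unscreened) rows."""
    n = schedule.horizon_years
    return tuple(sum(row[i] for row in schedule.years) / n for i in range(3))  # type: ignore[return-value]


# --------------------------------------------------------------------------
# serialization


def schedules_to_frame(schedules: Iterable[UptakeSchedule]) -> pd.DataFrame:
    records = []
    for sched in schedules:
        for year, (c, f, u) in enumerate(sched.years, start=1):
            records.append(
                {
                    "scenario_id": sched.scenario_id,
                    "year": year,
                    "p_colonoscopy": c,
                    "p_fit": f,
                    "p_unscreened": u,
                }
            )
    return pd.DataFrame.from_records(records)


def save_schedules_csv(schedules: Iterable[UptakeSchedule], path: str | Path) -> None:
    schedules_to_frame(schedules).to_csv(path, index=False)


def save_schedules_yaml(schedules: Iterable[UptakeSchedule], path: str | Path) -> None:
    data = {
        sched.scenario_id: [list(row) for row in sched.years] for sched in schedules
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_schedule_yaml(path: str | Path) -> dict[str, UptakeSchedule]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ScheduleError(f"{path}: expected a mapping of scenario_id -> rows")
    return {
        sid: UptakeSchedule(scenario_id=sid, years=tuple(tuple(r) for r in rows))
        for sid, rows in data.items()
    }
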