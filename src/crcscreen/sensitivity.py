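"""One-way and probabilistic sensitivity analysis over the published CI ranges.

The source publication prints 95% CIs for its test-characteristic and
prevalence inputs but reports no sensitivity analysis; this module is the
package's own extension built on those ranges.  One-way analysis sets each
parameter to its CI bounds in turn (tornado ordering by outcome swing);
probabilistic analysis draws every CI-bearing proportion from a beta
distribution whose 2.5th/97.5th percentiles match the printed CI and
propagates the draws through the cohort engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import run_cohort, with_calibrated_q
from .params import BASELINE_SYMPTOM_DETECTED, ParameterSet
from .schedules import UptakeSchedule

__all__ = ["SensitivityResult", "one_way", "probabilistic", "fit_beta_to_ci"]

#: Parameters varied by default: all CI-bearing proportions that are not
#: stage proportions (stage distributions carry no published uncertainty).
VARIABLE_PARAMETERS = (
    "colonoscopy_sensitivity",
    "crc_prevalence",
    "fit_diagnostic_adherence",
    "fit_positivity",
    "fit_sensitivity",
)


@dataclass(frozen=True)
class SensitivityResult:
    """Outcome response of one parameter swept across its CI range."""

    parameter: str
    low: float
    base: float
    high: float
    outcome: str
    outcome_at_low: float
    outcome_at_base: float
    outcome_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.outcome_at_high - self.outcome_at_low)


def _resolve_q(params: ParameterSet, schedule: UptakeSchedule) -> ParameterSet:
    if params.symptomatic.q_undiagnosed is None:
        return with_calibrated_q(params, BASELINE_SYMPTOM_DETECTED)
    return params


def _outcome(params: ParameterSet, schedule: UptakeSchedule, outcome: str) -> float:
    totals = run_cohort(params, schedule).totals()
    try:
        return totals[outcome]
    except KeyError:
        raise KeyError(
            f"unknown outcome {outcome!r}; choose one of {sorted(totals)}"
        ) from None


def one_way(
    params: ParameterSet,
    outcome: str,
    schedule: UptakeSchedule,
    parameters: tuple[str, ...] = VARIABLE_PARAMETERS,
    recalibrate_q: bool = False,
) -> list[SensitivityResult]:
    """One-way sweeps, returned in tornado order (descending swing, then name).

    Each parameter is set to its low and high CI bound with everything else
    at base case.  The symptomatic fraction ``q`` is held at its base
    (calibrated) value unless ``recalibrate_q`` is set, in which case it is
    re-calibrated to the baseline target for every perturbed parameter set.
    """
    base_params = _resolve_q(params, schedule)
    base_value = _outcome(base_params, schedule, outcome)
    results = []
    for name in parameters:
        ci = params.ci_ranges.get(name)
        if ci is None:
            raise KeyError(f"parameter {name!r} has no ci_range")
        lo, hi = ci
        point = params.point_value(name)
        if hi - lo < 1e-12:
            # degenerate range: both bounds coincide with the point, swing 0
            values = {lo: base_value, hi: base_value}
        else:
            values = {}
            for bound in (lo, hi):
                perturbed = base_params.with_value(name, bound)
                if recalibrate_q:
                    perturbed = with_calibrated_q(perturbed, BASELINE_SYMPTOM_DETECTED)
                values[bound] = _outcome(perturbed, schedule, outcome)
        results.append(
            SensitivityResult(
                parameter=name,
                low=lo,
                base=point,
                high=hi,
                outcome=outcome,
                outcome_at_low=values[lo],
                outcome_at_base=base_value,
                outcome_at_high=values[hi],
            )
        )
    return sorted(results, key=lambda r: (-r.swing, r.parameter))


def tornado_frame(results: list[SensitivityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "low": r.low,
                "base": r.base,
                "high": r.high,
                "outcome": r.outcome,
                "outcome_at_low": r.outcome_at_low,
                "outcome_at_base": r.outcome_at_base,
                "outcome_at_high": r.outcome_at_high,
                "swing": r.swing,
            }
            for r in results
        ]
    )


def fit_beta_to_ci(low: float, high: float) -> tuple[float, float]:
    """Beta shape parameters whose 2.5/97.5 percentiles match (low, high).

    Solved numerically by least squares on (log a, log b) from a
    normal-approximation start.  A bound of exactly 1 (or 0) is nudged
    inside the open interval, since a proper beta cannot place an extreme
    percentile exactly on the boundary.
    """
    if not (0.0 <= low < high <= 1.0):
        raise ValueError(f"CI bounds ({low}, {high}) must satisfy 0 <= low < high <= 1")
    lo = max(low, 1e-9)
    hi = min(high, 1.0 - 1e-9)
    mean = 0.5 * (lo + hi)
    sd = (hi - lo) / 3.92
    kappa = max(mean * (1.0 - mean) / sd**2 - 1.0, 2.0)
    x0 = np.log([mean * kappa, (1.0 - mean) * kappa])

    def residuals(log_ab: np.ndarray) -> np.ndarray:
        a, b = np.exp(log_ab)
        return np.array(
            [stats.beta.ppf(0.025, a, b) - lo, stats.beta.ppf(0.975, a, b) - hi]
        )

    sol = optimize.least_squares(residuals, x0, xtol=1e-12, ftol=1e-12)
    a, b = np.exp(sol.x)
    return float(a), float(b)


def probabilistic(
    params: ParameterSet,
    schedule: UptakeSchedule,
    n_draws: int = 2000,
    seed: int = 0,
    parameters: tuple[str, ...] = VARIABLE_PARAMETERS,
    return_draws: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Probabilistic sensitivity analysis (PSA) via beta-distributed inputs.

    Every parameter in ``parameters`` with a non-degenerate CI range is
    drawn from its CI-matched beta distribution; degenerate ranges stay at
    their point value.  One deterministic cohort run per draw.  Returns a
    summary frame (mean, 2.5/50/97.5 percentiles per outcome); with
    ``return_draws``, also the per-draw outcome table.  Deterministic for a
    given seed.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    base_params = _resolve_q(params, schedule)
    rng = np.random.default_rng(seed)
    samples: dict[str, np.ndarray] = {}
    for name in parameters:
        ci = params.ci_ranges.get(name)
        if ci is None:
            raise KeyError(f"parameter {name!r} has no ci_range")
        lo, hi = ci
        if hi - lo < 1e-12:
            continue  # degenerate range: parameter stays at its point value
        a, b = fit_beta_to_ci(lo, hi)
        samples[name] = rng.beta(a, b, size=n_draws)
    rows = []
    for i in range(n_draws):
        drawn = base_params
        for name, values in samples.items():
            drawn = drawn.with_value(name, float(values[i]))
        rows.append(run_cohort(drawn, schedule).totals())
    draws = pd.DataFrame(rows)
    summary = pd.DataFrame(
        {
            "mean": draws.mean(),
            "p2.5": draws.quantile(0.025),
            "p50": draws.quantile(0.50),
            "p97.5": draws.quantile(0.975),
        }
    )
    if return_draws:
        return summary, draws
    return summary
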