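"""Model parameters: test characteristics, stage distributions, population inputs.

All defaults are the published base-case values of the underlying decision
model: colonoscopy sensitivity 95% (95% CI 90-100), CRC prevalence among
screeners 0.8% (0.7-0.9), FIT sensitivity 79% (69-85), FIT positivity 7%
(6.3-7.7), adherence to diagnostic colonoscopy after a positive FIT 65%
(52-78), three stage-at-diagnosis distributions (screening colonoscopy,
screening FIT, clinical presentation), and a would-be-screened cohort of
1,563,556 persons/year over a 3-year horizon split 85/15 between colonoscopy
and FIT.

Every confidence interval is retained (degenerate low=point=high where the
source gives none) so the sensitivity module can vary all parameters
uniformly.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "Modality",
    "Route",
    "Stage",
    "TestPerformance",
    "StageDistribution",
    "PopulationParams",
    "SymptomaticDetectionParams",
    "ParameterSet",
    "ParameterError",
    "default_parameters",
    "load_parameters",
    "save_parameters",
    "BASELINE_SYMPTOM_DETECTED",
]

#: Published baseline count of symptom-detected CRC cases over the 3-year
#: horizon; the default calibration target for the symptomatic pathway.
BASELINE_SYMPTOM_DETECTED = 576.0


class ParameterError(ValueError):
    """A parameter value or combination violates the model's invariants."""


class Modality(str, enum.Enum):
    COLONOSCOPY = "colonoscopy"
    FIT = "fit"


class Route(str, enum.Enum):
    """Detection route that determines the stage-at-diagnosis distribution."""

    SCREEN_COLONOSCOPY = "screen_colonoscopy"
    SCREEN_FIT = "screen_fit"
    CLINICAL = "clinical"


class Stage(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


STAGES = (Stage.I, Stage.II, Stage.III, Stage.IV)


def _check_proportion(name: str, value: float, lo: float = 0.0, hi: float = 1.0) -> None:
    if not (lo <= value <= hi) or math.isnan(value):
        raise ParameterError(f"{name} must lie in [{lo}, {hi}], got {value!r}")


@dataclass(frozen=True)
class TestPerformance:
    """Screening-test characteristics for one modality.

    ``sensitivity_crc`` is P(test positive | prevalent CRC); for FIT,
    ``positivity_rate`` is the marginal positive rate across all screened
    persons and ``diagnostic_adherence`` the probability a positive is
    followed by a completed diagnostic colonoscopy.  Colonoscopy is itself
    diagnostic, so its adherence is 1 and it has no positivity rate.
    """

    modality: Modality
    sensitivity_crc: float
    diagnostic_adherence: float = 1.0
    positivity_rate: float | None = None

    def __post_init__(self) -> None:
        _check_proportion(f"{self.modality.value} sensitivity_crc", self.sensitivity_crc)
        _check_proportion(
            f"{self.modality.value} diagnostic_adherence", self.diagnostic_adherence
        )
        if self.positivity_rate is not None:
            _check_proportion(f"{self.modality.value} positivity_rate", self.positivity_rate)
        if self.sensitivity_crc * self.diagnostic_adherence > 1.0:
            raise ParameterError("sensitivity_crc x diagnostic_adherence exceeds 1")

    @property
    def screen_detection_probability(self) -> float:
        """P(screen-detected | prevalent CRC, screened with this modality)."""
        return self.sensitivity_crc * self.diagnostic_adherence


@dataclass(frozen=True)
class StageDistribution:
    """AJCC stage I-IV proportions for one detection route."""

    route: Route
    p_stage: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.p_stage) != 4:
            raise ParameterError(f"{self.route.value}: need 4 stage proportions")
        for stage, p in zip(STAGES, self.p_stage):
            _check_proportion(f"{self.route.value} stage {stage.value}", p)
        total = sum(self.p_stage)
        if abs(total - 1.0) > 0.005:
            raise ParameterError(
                f"{self.route.value}: stage proportions sum to {total:.3f}, not 1"
            )

    @property
    def early_stage_fraction(self) -> float:
        """Stage I + II share."""
        return self.p_stage[0] + self.p_stage[1]


@dataclass(frozen=True)
class PopulationParams:
    """Size and composition of the annual would-be-screened cohort."""

    annual_baseline_screeners: float = 1_563_556.0
    horizon_years: int = 3
    prevalence_crc: float = 0.008
    baseline_modality_mix: tuple[float, float] = (0.85, 0.15)  # (colonoscopy, fit)

    def __post_init__(self) -> None:
        if self.annual_baseline_screeners <= 0:
            raise ParameterError("annual_baseline_screeners must be positive")
        if self.horizon_years < 1:
            raise ParameterError("horizon_years must be >= 1")
        if not (0.0 < self.prevalence_crc < 1.0):
            raise ParameterError("prevalence_crc must lie in (0, 1)")
        mix_sum = sum(self.baseline_modality_mix)
        if abs(mix_sum - 1.0) > 1e-9:
            raise ParameterError(f"baseline_modality_mix sums to {mix_sum}, not 1")
        for share in self.baseline_modality_mix:
            _check_proportion("baseline modality share", share)


@dataclass(frozen=True)
class SymptomaticDetectionParams:
    """Fraction of undiagnosed prevalent cancers presenting clinically.

    The generating proportion is not published; by default it is calibrated
    (closed form, see :func:`crcscreen.cohort.calibrate_symptomatic_fraction`)
    so that the baseline scenario reproduces the published symptom-detected
    count.  ``q_undiagnosed`` of ``None`` means "not yet calibrated".
    """

    q_undiagnosed: float | None = None
    source: str = "calibrated"  # or "user_supplied"

    def __post_init__(self) -> None:
        if self.q_undiagnosed is not None:
            _check_proportion("q_undiagnosed", self.q_undiagnosed)
        if self.source not in ("calibrated", "user_supplied"):
            raise ParameterError(f"unknown symptomatic source {self.source!r}")


@dataclass(frozen=True)
class ParameterSet:
    """Complete, validated input set for the cohort model."""

    tests: Mapping[Modality, TestPerformance]
    stages: Mapping[Route, StageDistribution]
    population: PopulationParams
    symptomatic: SymptomaticDetectionParams
    ci_ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for modality in Modality:
            if modality not in self.tests:
                raise ParameterError(f"missing TestPerformance for {modality.value}")
            if self.tests[modality].modality is not modality:
                raise ParameterError(f"tests[{modality.value}] has mismatched modality")
        for route in Route:
            if route not in self.stages:
                raise ParameterError(f"missing StageDistribution for {route.value}")
            if self.stages[route].route is not route:
                raise ParameterError(f"stages[{route.value}] has mismatched route")
        for name, (lo, hi) in self.ci_ranges.items():
            point = self.point_value(name)
            if not (lo <= point <= hi):
                raise ParameterError(
                    f"ci_range for {name}: point {point} outside [{lo}, {hi}]"
                )

    # -- named scalar access used by ci_ranges and the sensitivity module ----

    def point_value(self, name: str) -> float:
        getter = _PARAM_GETTERS.get(name)
        if getter is None:
            raise ParameterError(f"unknown parameter name {name!r}")
        return getter(self)

    def with_value(self, name: str, value: float) -> "ParameterSet":
        """Return a copy with the named scalar parameter replaced.

        The stored ci_range is widened minimally if the new point falls
        outside it (a range must always contain its point), which keeps
        perturbed sets — e.g. PSA tail draws — valid.
        """
        setter = _PARAM_SETTERS.get(name)
        if setter is None:
            raise ParameterError(f"unknown parameter name {name!r}")
        base = self
        rng = self.ci_ranges.get(name)
        if rng is not None and not (rng[0] <= value <= rng[1]):
            ci = dict(self.ci_ranges)
            ci[name] = (min(rng[0], value), max(rng[1], value))
            base = replace(self, ci_ranges=ci)
        return setter(base, value)

    def with_q(self, q: float, source: str = "calibrated") -> "ParameterSet":
        return replace(
            self, symptomatic=SymptomaticDetectionParams(q_undiagnosed=q, source=source)
        )


def _set_test(ps: ParameterSet, modality: Modality, **kw: Any) -> ParameterSet:
    tests = dict(ps.tests)
    tests[modality] = replace(tests[modality], **kw)
    return replace(ps, tests=tests)


_PARAM_GETTERS = {
    "colonoscopy_sensitivity": lambda ps: ps.tests[Modality.COLONOSCOPY].sensitivity_crc,
    "fit_sensitivity": lambda ps: ps.tests[Modality.FIT].sensitivity_crc,
    "fit_positivity": lambda ps: ps.tests[Modality.FIT].positivity_rate,
    "fit_diagnostic_adherence": lambda ps: ps.tests[Modality.FIT].diagnostic_adherence,
    "crc_prevalence": lambda ps: ps.population.prevalence_crc,
}
_PARAM_SETTERS = {
    "colonoscopy_sensitivity": lambda ps, v: _set_test(
        ps, Modality.COLONOSCOPY, sensitivity_crc=v
    ),
    "fit_sensitivity": lambda ps, v: _set_test(ps, Modality.FIT, sensitivity_crc=v),
    "fit_positivity": lambda ps, v: _set_test(ps, Modality.FIT, positivity_rate=v),
    "fit_diagnostic_adherence": lambda ps, v: _set_test(
        ps, Modality.FIT, diagnostic_adherence=v
    ),
    "crc_prevalence": lambda ps, v: replace(
        ps, population=replace(ps.population, prevalence_crc=v)
    ),
}

# stage-proportion names (degenerate CI ranges; not varied in PSA)
for _route, _key in (
    (Route.SCREEN_COLONOSCOPY, "stage_colonoscopy"),
    (Route.SCREEN_FIT, "stage_fit"),
    (Route.CLINICAL, "stage_clinical"),
):
    for _i, _stage in enumerate(STAGES):
        _PARAM_GETTERS[f"{_key}_{_stage.value}"] = (
            lambda ps, r=_route, i=_i: ps.stages[r].p_stage[i]
        )


def default_parameters() -> ParameterSet:
    """The published base-case parameter set, CI ranges included."""
    tests = {
        Modality.COLONOSCOPY: TestPerformance(
            modality=Modality.COLONOSCOPY, sensitivity_crc=0.95
        ),
        Modality.FIT: TestPerformance(
            modality=Modality.FIT,
            sensitivity_crc=0.79,
            diagnostic_adherence=0.65,
            positivity_rate=0.07,
        ),
    }
    stages = {
        Route.SCREEN_COLONOSCOPY: StageDistribution(
            route=Route.SCREEN_COLONOSCOPY, p_stage=(0.34, 0.36, 0.19, 0.11)
        ),
        Route.SCREEN_FIT: StageDistribution(
            route=Route.SCREEN_FIT, p_stage=(0.367, 0.347, 0.217, 0.069)
        ),
        Route.CLINICAL: StageDistribution(
            route=Route.CLINICAL, p_stage=(0.18, 0.34, 0.23, 0.25)
        ),
    }
    ci_ranges: dict[str, tuple[float, float]] = {
        "colonoscopy_sensitivity": (0.90, 1.00),
        "crc_prevalence": (0.007, 0.009),
        "fit_sensitivity": (0.69, 0.85),
        "fit_positivity": (0.063, 0.077),
        "fit_diagnostic_adherence": (0.52, 0.78),
    }
    # degenerate ranges for stage proportions keep the sensitivity API uniform
    for key, dist in (
        ("stage_colonoscopy", stages[Route.SCREEN_COLONOSCOPY]),
        ("stage_fit", stages[Route.SCREEN_FIT]),
        ("stage_clinical", stages[Route.CLINICAL]),
    ):
        for stage, p in zip(STAGES, dist.p_stage):
            ci_ranges[f"{key}_{stage.value}"] = (p, p)
    return ParameterSet(
        tests=tests,
        stages=stages,
        population=PopulationParams(),
        symptomatic=SymptomaticDetectionParams(),
        ci_ranges=ci_ranges,
    )


# --------------------------------------------------------------------------
# serialization


def parameters_to_dict(params: ParameterSet) -> dict[str, Any]:
    colo = params.tests[Modality.COLONOSCOPY]
    fit = params.tests[Modality.FIT]
    pop = params.population

    def ci(name: str) -> list[float] | None:
        rng = params.ci_ranges.get(name)
        return [float(rng[0]), float(rng[1])] if rng is not None else None

    return {
        "colonoscopy": {
            "sensitivity": colo.sensitivity_crc,
            "sensitivity_ci": ci("colonoscopy_sensitivity"),
        },
        "fit": {
            "sensitivity": fit.sensitivity_crc,
            "sensitivity_ci": ci("fit_sensitivity"),
            "positivity": fit.positivity_rate,
            "positivity_ci": ci("fit_positivity"),
            "diagnostic_adherence": fit.diagnostic_adherence,
            "diagnostic_adherence_ci": ci("fit_diagnostic_adherence"),
        },
        "population": {
            "annual_baseline_screeners": pop.annual_baseline_screeners,
            "horizon_years": pop.horizon_years,
            "prevalence_crc": pop.prevalence_crc,
            "prevalence_crc_ci": ci("crc_prevalence"),
            "baseline_modality_mix": {
                "colonoscopy": pop.baseline_modality_mix[0],
                "fit": pop.baseline_modality_mix[1],
            },
        },
        "stage_distribution": {
            route.value: {
                stage.value: p
                for stage, p in zip(STAGES, params.stages[route].p_stage)
            }
            for route in Route
        },
        "symptomatic": {
            "q_undiagnosed": params.symptomatic.q_undiagnosed,
            "source": params.symptomatic.source,
        },
    }


def _deep_merge(base: dict[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    out = dict(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def parameters_from_dict(data: Mapping[str, Any]) -> ParameterSet:
    """Build a ParameterSet from a (possibly partial) config mapping.

    Unspecified fields fall back to the published defaults; invariant
    violations raise :class:`ParameterError` naming the offending field.
    """
    merged = _deep_merge(parameters_to_dict(default_parameters()), data)
    known = {"colonoscopy", "fit", "population", "stage_distribution", "symptomatic"}
    unknown = set(merged) - known
    if unknown:
        raise ParameterError(f"unknown top-level config keys: {sorted(unknown)}")

    def as_ci(section: Mapping[str, Any], key: str) -> tuple[float, float] | None:
        rng = section.get(key)
        if rng is None:
            return None
        if len(rng) != 2:
            raise ParameterError(f"{key} must be a [low, high] pair")
        return (float(rng[0]), float(rng[1]))

    colo_cfg, fit_cfg = merged["colonoscopy"], merged["fit"]
    pop_cfg, sym_cfg = merged["population"], merged["symptomatic"]
    tests = {
        Modality.COLONOSCOPY: TestPerformance(
            modality=Modality.COLONOSCOPY,
            sensitivity_crc=float(colo_cfg["sensitivity"]),
        ),
        Modality.FIT: TestPerformance(
            modality=Modality.FIT,
            sensitivity_crc=float(fit_cfg["sensitivity"]),
            diagnostic_adherence=float(fit_cfg["diagnostic_adherence"]),
            positivity_rate=float(fit_cfg["positivity"]),
        ),
    }
    stages = {}
    for route in Route:
        block = merged["stage_distribution"][route.value]
        try:
            p = tuple(float(block[s.value]) for s in STAGES)
        except KeyError as exc:
            raise ParameterError(
                f"stage_distribution.{route.value}: missing stage {exc}"
            ) from exc
        stages[route] = StageDistribution(route=route, p_stage=p)
    mix = pop_cfg["baseline_modality_mix"]
    population = PopulationParams(
        annual_baseline_screeners=float(pop_cfg["annual_baseline_screeners"]),
        horizon_years=int(pop_cfg["horizon_years"]),
        prevalence_crc=float(pop_cfg["prevalence_crc"]),
        baseline_modality_mix=(float(mix["colonoscopy"]), float(mix["fit"])),
    )
    q = sym_cfg.get("q_undiagnosed")
    symptomatic = SymptomaticDetectionParams(
        q_undiagnosed=None if q is None else float(q),
        source=sym_cfg.get("source", "calibrated"),
    )
    ci_ranges: dict[str, tuple[float, float]] = {}
    for name, section, key in (
        ("colonoscopy_sensitivity", colo_cfg, "sensitivity_ci"),
        ("fit_sensitivity", fit_cfg, "sensitivity_ci"),
        ("fit_positivity", fit_cfg, "positivity_ci"),
        ("fit_diagnostic_adherence", fit_cfg, "diagnostic_adherence_ci"),
        ("crc_prevalence", pop_cfg, "prevalence_crc_ci"),
    ):
        rng = as_ci(section, key)
        if rng is not None:
            ci_ranges[name] = rng
    for key, route in (
        ("stage_colonoscopy", Route.SCREEN_COLONOSCOPY),
        ("stage_fit", Route.SCREEN_FIT),
        ("stage_clinical", Route.CLINICAL),
    ):
        for stage, p in zip(STAGES, stages[route].p_stage):
            ci_ranges[f"{key}_{stage.value}"] = (p, p)
    return ParameterSet(
        tests=tests,
        stages=stages,
        population=population,
        symptomatic=symptomatic,
        ci_ranges=ci_ranges,
    )


def load_parameters(path: str | Path) -> ParameterSet:
    """Load a YAML (or JSON — a YAML subset) config file.

    Fields absent from the file fall back to the published defaults.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"parameter file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ParameterError(f"{path}: top level must be a mapping")
    return parameters_from_dict(data)


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write the full parameter set as canonical YAML (stable key order)."""
    with open(path, "w") as fh:
        yaml.safe_dump(parameters_to_dict(params), fh, sort_keys=True)
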