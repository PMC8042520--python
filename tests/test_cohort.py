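"""Deterministic cohort engine: oracles, calibration, comparisons, invariants."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from crcscreen import (
    PopulationParams,
    UptakeSchedule,
    calibrate_symptomatic_fraction,
    compare,
    default_parameters,
    run_all_published_scenarios,
    run_cohort,
    with_calibrated_q,
)
from crcscreen.cohort import OUTCOME_NAMES, round_half_away, undiagnosed_pool
from crcscreen.params import ParameterSet

B = 1_563_556.0

# independent closed-form oracle for the baseline undiagnosed pool:
# colonoscopy false negatives + FIT false negatives and nonadherent true
# positives, per year, times three disjoint annual cohorts
BASELINE_POOL = 3 * (
    B * 0.85 * 0.008 * (1 - 0.95) + B * 0.15 * 0.008 * (1 - 0.79 * 0.65)
)


def _with_population(params, **kw):
    import dataclasses

    return dataclasses.replace(params, population=PopulationParams(**kw))


def test_baseline_screened_total_is_exact(calibrated_params, schedules):
    """1,563,556 annual screeners over 3 years screen 4,690,668 people."""
    out = run_cohort(calibrated_params, schedules["baseline"])
    assert round_half_away(out.totals()["screened_total"]) == 4_690_668


def test_fit_detection_rate_per_100k_screeners():
    """100,000 FIT screeners x 0.8% prevalence x 79% sensitivity x 65%
    follow-up adherence yield 410.8 screen-detected cases."""
    params = _with_population(
        default_parameters(), annual_baseline_screeners=100_000, horizon_years=1
    ).with_q(0.0)
    sched = UptakeSchedule(scenario_id="all_fit", years=((0.0, 1.0, 0.0),))
    out = run_cohort(params, sched)
    assert out.totals()["screen_detected_fit"] == pytest.approx(410.8, abs=1e-9)


def test_no_screening_no_symptoms_no_cases(params):
    sched = UptakeSchedule(scenario_id="none", years=((0.0, 0.0, 1.0),) * 3)
    out = run_cohort(params.with_q(0.0), sched)
    assert out.totals()["total_cases"] == 0.0
    assert out.totals()["screened_total"] == 0.0


def test_calibration_closed_form(params, schedules):
    """q = target / undiagnosed pool, against the hand-computed pool."""
    assert undiagnosed_pool(params, schedules["baseline"]) == pytest.approx(
        BASELINE_POOL, rel=1e-12
    )
    sym = calibrate_symptomatic_fraction(params, 576.0)
    assert sym.q_undiagnosed == pytest.approx(576.0 / BASELINE_POOL, rel=1e-12)


def test_calibration_zero_target(params):
    assert calibrate_symptomatic_fraction(params, 0.0).q_undiagnosed == 0.0


def test_calibration_is_linear_below_clamp(params):
    q1 = calibrate_symptomatic_fraction(params, 100.0).q_undiagnosed
    q2 = calibrate_symptomatic_fraction(params, 200.0).q_undiagnosed
    assert q2 == pytest.approx(2 * q1, rel=1e-12)


def test_calibration_clamps_with_warning(params):
    with pytest.warns(UserWarning, match="clamped"):
        sym = calibrate_symptomatic_fraction(params, 1e9)
    assert sym.q_undiagnosed == 1.0


def test_calibrated_baseline_reproduces_symptom_target(calibrated_params, schedules):
    out = run_cohort(calibrated_params, schedules["baseline"])
    assert out.totals()["symptom_detected"] == pytest.approx(576.0, rel=1e-12)


def test_run_cohort_requires_q(params, schedules):
    with pytest.raises(ValueError, match="q"):
        run_cohort(params, schedules["baseline"])


def test_horizon_mismatch_rejected(calibrated_params):
    sched = UptakeSchedule(scenario_id="short", years=((0.85, 0.15, 0.0),) * 2)
    with pytest.raises(ValueError, match="horizon"):
        run_cohort(calibrated_params, sched)


def test_compare_self_is_all_zero(calibrated_params, schedules):
    out = run_cohort(calibrated_params, schedules["scenario_1"])
    comp = compare(out, out)
    assert (comp.table["absolute_difference"] == 0).all()
    nonzero_ref = comp.table["reference"] != 0
    assert (comp.table.loc[nonzero_ref, "percent_difference"] == 0).all()


def test_compare_zero_reference_reports_nan_not_inf(calibrated_params, schedules):
    base = run_cohort(calibrated_params, schedules["baseline"])  # unscreened = 0
    other = run_cohort(calibrated_params, schedules["scenario_1"])
    comp = compare(base, other)
    assert np.isnan(comp.percent("unscreened"))


def test_compare_sign_convention(calibrated_params, schedules):
    """Comparator below reference gives negative differences."""
    base = run_cohort(calibrated_params, schedules["baseline"])
    s1 = run_cohort(calibrated_params, schedules["scenario_1"])
    comp = compare(base, s1)
    assert comp.absolute("screened_total") < 0
    assert comp.percent("screened_total") < 0


def test_outcome_accounting_identities(calibrated_params, schedules):
    """Totals satisfy the model's accounting identities in every scenario."""
    for sched in schedules.values():
        out = run_cohort(calibrated_params, sched)
        t = out.totals()
        assert t["screened_total"] == pytest.approx(
            t["screened_colonoscopy"] + t["screened_fit"], rel=1e-12
        )
        assert t["total_cases"] == pytest.approx(
            t["screen_detected"] + t["symptom_detected"], rel=1e-12
        )
        stage_sum = sum(t[f"stage_{s}_cases"] for s in ("I", "II", "III", "IV"))
        assert stage_sum == pytest.approx(t["total_cases"], abs=0.5)
        assert t["early_stage_cases"] + t["late_stage_cases"] == pytest.approx(
            t["total_cases"], abs=0.5
        )
        assert all(v >= 0 for v in t.values())


def test_run_all_published_scenarios(params):
    outcomes, comparisons = run_all_published_scenarios(params)
    assert set(outcomes) == {
        "baseline",
        "scenario_1",
        "scenario_2",
        "scenario_3",
        "scenario_4",
    }
    # baseline early-stage share ~69.8% of all cases
    assert 100 * outcomes["baseline"].early_stage_fraction == pytest.approx(69.8, abs=0.1)
    # prolonged disruption screens fewer people than the short one
    assert (
        outcomes["scenario_2"].totals()["screened_total"]
        < outcomes["scenario_1"].totals()["screened_total"]
    )
    # FIT-detected cases carry the FIT stage distribution: early share exactly
    # the sum of the stage I and II inputs
    out = outcomes["baseline"]
    fit_early = 0.367 + 0.347
    assert comparisons["scenario_4_vs_scenario_2"].reference_id == "scenario_2"
    total_fit = out.totals()["screen_detected_fit"]
    fit_stage_early = total_fit * fit_early
    assert fit_stage_early == pytest.approx(total_fit * 0.714, rel=1e-9)


def test_linearity_in_cohort_size(params, schedules):
    """All outcomes are homogeneous of degree 1 in the annual cohort size."""
    small = _with_population(
        params, annual_baseline_screeners=B, horizon_years=3
    ).with_q(0.1)
    big = _with_population(
        params, annual_baseline_screeners=7 * B, horizon_years=3
    ).with_q(0.1)
    t_small = run_cohort(small, schedules["scenario_3"]).totals()
    t_big = run_cohort(big, schedules["scenario_3"]).totals()
    for name in OUTCOME_NAMES:
        if t_small[name] == 0:
            assert t_big[name] == 0
        else:
            assert t_big[name] / t_small[name] == pytest.approx(7.0, rel=1e-12)


# --------------------------------------------------------------------------
# randomized invariant suite


@st.composite
def random_schedules(draw):
    years = []
    for _ in range(3):
        c = draw(st.floats(0.0, 1.0, allow_nan=False))
        f = draw(st.floats(0.0, 1.0, allow_nan=False))
        if c + f > 1.0:
            c, f = c / (c + f), f / (c + f)
        years.append((c, f, max(0.0, 1.0 - c - f)))
    return UptakeSchedule(scenario_id="h", years=tuple(years))


@st.composite
def random_parameter_sets(draw):
    params = default_parameters()
    params = params.with_value(
        "crc_prevalence", draw(st.floats(0.001, 0.05, allow_nan=False))
    )
    params = params.with_value(
        "colonoscopy_sensitivity", draw(st.floats(0.5, 1.0, allow_nan=False))
    )
    params = params.with_value(
        "fit_sensitivity", draw(st.floats(0.3, 1.0, allow_nan=False))
    )
    params = params.with_value(
        "fit_diagnostic_adherence", draw(st.floats(0.1, 1.0, allow_nan=False))
    )
    return params.with_q(draw(st.floats(0.0, 1.0, allow_nan=False)))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(params=random_parameter_sets(), sched=random_schedules())
def test_conservation_of_persons_and_cases(params, sched):
    """Screened + unscreened person-years equal cohort size x horizon, and
    screen-detected + symptom-detected + remaining-undiagnosed cancers equal
    prevalence x cohort person-years."""
    out = run_cohort(params, sched)
    t = out.totals()
    pop = params.population
    person_years = pop.annual_baseline_screeners * pop.horizon_years
    assert t["screened_total"] + t["unscreened"] == pytest.approx(
        person_years, rel=1e-9
    )
    assert (
        t["screen_detected"] + t["symptom_detected"] + t["undiagnosed_remaining"]
    ) == pytest.approx(person_years * pop.prevalence_crc, rel=1e-9)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    params=random_parameter_sets(),
    sched=random_schedules(),
    shift=st.floats(0.0, 1.0, allow_nan=False),
)
def test_fit_uptake_monotonicity(params, sched, shift):
    """Moving unscreened people to FIT never loses detected or early cases."""
    moved_years = tuple(
        (c, f + shift * u, (1 - shift) * u) for c, f, u in sched.years
    )
    moved = UptakeSchedule(scenario_id="m", years=moved_years)
    t0 = run_cohort(params, sched).totals()
    t1 = run_cohort(params, moved).totals()
    assert t1["total_cases"] >= t0["total_cases"] - 1e-9
    assert t1["early_stage_cases"] >= t0["early_stage_cases"] - 1e-9


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    params=random_parameter_sets(),
    sched=random_schedules(),
    bump=st.floats(0.0, 0.3, allow_nan=False),
)
def test_sensitivity_monotonicity(params, sched, bump):
    """Raising either test's sensitivity never decreases screen-detected cases."""
    t0 = run_cohort(params, sched).totals()
    better_fit = params.with_value(
        "fit_sensitivity", min(1.0, params.point_value("fit_sensitivity") + bump)
    )
    better_colo = params.with_value(
        "colonoscopy_sensitivity",
        min(1.0, params.point_value("colonoscopy_sensitivity") + bump),
    )
    assert (
        run_cohort(better_fit, sched).totals()["screen_detected"]
        >= t0["screen_detected"] - 1e-9
    )
    assert (
        run_cohort(better_colo, sched).totals()["screen_detected"]
        >= t0["screen_detected"] - 1e-9
    )


@settings(max_examples=200, deadline=None, derandomize=True)
@given(sched=random_schedules(), q=st.floats(0.0, 1.0, allow_nan=False))
def test_stage_mix_bound(sched, q):
    """With the published stage tables, the overall early-stage share lies
    between the clinical early share (0.52) and the FIT early share (0.714)."""
    params = default_parameters().with_q(q)
    out = run_cohort(params, sched)
    total = out.totals()["total_cases"]
    assume(total > 0)
    frac = out.early_stage_fraction
    assert 0.52 - 1e-9 <= frac <= 0.714 + 1e-9
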