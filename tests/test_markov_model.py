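import copy
import dataclasses

import numpy as np
import pytest

from conftest import short_config
from sintcea.markov_model import (
    CONVENTIONS,
    STATE_ORDER,
    ConfigurationError,
    CostInputs,
    HealthState,
    ModelConfig,
    PatientProfile,
    RegimenComponent,
    StrategyDefinition,
    TreatmentLine,
    UtilityInputs,
    accrue,
    build_cycle_transitions,
    carboplatin_dose,
    icer,
    per_cycle_drug_cost,
    run_base_case,
    run_cohort,
    run_strategy,
)
from sintcea.survival_models import ParametricSurvival, survival

COL = {s: i for i, s in enumerate(STATE_ORDER)}


def null_line(name="null"):
    eps = 1e-12
    return TreatmentLine(
        name=name,
        os_curve=ParametricSurvival("exponential", (eps,)),
        pfs_curve=ParametricSurvival("exponential", (eps,)),
        disc_prob=0.0,
        regimen=[],
    )


def null_strategy():
    return StrategyDefinition(
        "null", null_line("l1"), null_line("l2"), null_line("l3"), "sintilimab_gp"
    )


# ---------------------------------------------------------------------------
# dosing and drug cost
# ---------------------------------------------------------------------------


class TestDosing:
    def test_calvert_formula(self):
        assert carboplatin_dose(5.0, 70.0) == pytest.approx(475.0)

    def test_calvert_low_clearance_limit(self):
        assert carboplatin_dose(5.0, 1e-9) == pytest.approx(125.0)

    def test_calvert_rejects_nonpositive(self):
        with pytest.raises(ConfigurationError):
            carboplatin_dose(0.0, 70.0)
        with pytest.raises(ConfigurationError):
            carboplatin_dose(5.0, -1.0)

    def test_flat_and_bsa_component_costs(self, fixture_inputs):
        costs = fixture_inputs.costs
        patient = fixture_inputs.patient
        sin = TreatmentLine(
            "sin", *_curves(), 0.0, [RegimenComponent("sintilimab", 1.0, "flat")]
        )
        assert per_cycle_drug_cost(sin, costs, patient) == pytest.approx(334.82)
        doc = TreatmentLine(
            "doc", *_curves(), 0.0, [RegimenComponent("docetaxel", 1.0, "per_bsa")]
        )
        assert per_cycle_drug_cost(doc, costs, patient) == pytest.approx(39.53)
        # per-m2 components scale with BSA relative to the reference patient
        bigger = PatientProfile(bsa=2.0, crcl=70.0)
        assert per_cycle_drug_cost(doc, costs, bigger) == pytest.approx(
            39.53 * 2.0 / 1.72
        )
        empty = TreatmentLine("none", *_curves(), 0.0, [])
        assert per_cycle_drug_cost(empty, costs, patient) == 0.0

    def test_carboplatin_scales_with_calvert_dose(self, fixture_inputs):
        carbo = TreatmentLine(
            "carbo", *_curves(), 0.0, [RegimenComponent("carboplatin", 1.0, "per_calvert")]
        )
        costs = fixture_inputs.costs
        ref = per_cycle_drug_cost(carbo, costs, PatientProfile(crcl=70.0))
        assert ref == pytest.approx(1.30)
        doubled = per_cycle_drug_cost(carbo, costs, PatientProfile(crcl=165.0))
        assert doubled == pytest.approx(1.30 * (5 * 190) / (5 * 95))

    def test_cap_removes_chemo_after_six_cycles(self, fixture_inputs):
        line1 = fixture_inputs.strategies["first_line_sintilimab"].line1
        costs, patient = fixture_inputs.costs, fixture_inputs.patient
        early = per_cycle_drug_cost(line1, costs, patient, cycle_on_line=0)
        late = per_cycle_drug_cost(line1, costs, patient, cycle_on_line=6)
        assert early == pytest.approx(334.82 + 70.53 + 8.80)
        assert late == pytest.approx(334.82)

    def test_missing_price_is_configuration_error(self, fixture_inputs):
        line = TreatmentLine(
            "x", *_curves(), 0.0, [RegimenComponent("unobtainium", 1.0, "flat")]
        )
        with pytest.raises(ConfigurationError):
            per_cycle_drug_cost(line, fixture_inputs.costs, fixture_inputs.patient)


def _curves():
    c = ParametricSurvival("exponential", (0.01,))
    return c, c


# ---------------------------------------------------------------------------
# transition rows
# ---------------------------------------------------------------------------


class TestCycleTransitions:
    def test_zero_hazard_identity_row(self):
        cfg = ModelConfig()
        row = build_cycle_transitions(null_strategy(), HealthState.PFS, 0, 0, cfg)
        assert row[HealthState.PFS] == pytest.approx(1.0, abs=1e-9)
        assert sum(row.values()) == pytest.approx(1.0)

    def test_two_state_exponential_closed_form(self):
        lam = 0.05
        exp = ParametricSurvival("exponential", (lam,))
        line = TreatmentLine("l", exp, exp, 0.0, [])
        strat = StrategyDefinition("two-state", line, line, line, "sintilimab_gp")
        cfg = ModelConfig()
        for k in (0, 5, 40):
            row = build_cycle_transitions(strat, HealthState.PFS, k, k, cfg)
            assert row[HealthState.DEATH] == pytest.approx(-np.expm1(-lam))
            assert row[HealthState.FDP] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("conv", CONVENTIONS)
    @pytest.mark.parametrize(
        "state", [HealthState.PFS, HealthState.FDP, HealthState.SDP]
    )
    def test_rows_sum_to_one(self, fixture_inputs, conv, state):
        cfg = dataclasses.replace(fixture_inputs.config, convention=conv)
        strat = fixture_inputs.strategies["first_line_sintilimab"]
        for age, cycle in [(0, 0), (3, 7), (10, 30)]:
            row = build_cycle_transitions(strat, state, age, cycle, cfg)
            assert sum(row.values()) == pytest.approx(1.0, abs=1e-12)
            assert all(0.0 <= p <= 1.0 for p in row.values())

    def test_fixture_first_cycle_row_against_brute_force(self, fixture_inputs):
        """Cycle-0 row of first-line sintilimab-GP recomputed directly from
        survivor-function ratios (independent of the engine's tp tables)."""
        strat = fixture_inputs.strategies["first_line_sintilimab"]
        cfg = fixture_inputs.config
        os_c, pfs_c = strat.line1.os_curve, strat.line1.pfs_curve
        qd = 1.0 - survival(os_c, 1.0) / survival(os_c, 0.0)
        qpd = 1.0 - survival(pfs_c, 1.0) / survival(pfs_c, 0.0)
        qp = max(0.0, qpd - qd)
        alive = 1.0 - qd - qp
        qdisc = strat.line1.disc_prob * alive
        row = build_cycle_transitions(strat, HealthState.PFS, 0, 0, cfg)
        assert row[HealthState.DEATH] == pytest.approx(qd, rel=1e-12)
        assert row[HealthState.FDP] == pytest.approx(qp, rel=1e-12)
        assert row[HealthState.DISC_L1] == pytest.approx(qdisc, rel=1e-12)
        assert row[HealthState.PFS] == pytest.approx(alive - qdisc, rel=1e-12)

    def test_anchored_downstream_mortality_uses_line2_curve(self, fixture_inputs):
        """Under the anchored convention, end-stage occupants die by the
        second-line OS curve evaluated on their line-2 clock."""
        strat = fixture_inputs.strategies["second_line_sintilimab"]
        cfg = fixture_inputs.config
        os2 = strat.line2.os_curve
        age = 12
        qd = 1.0 - survival(os2, age + 1.0) / survival(os2, age)
        row = build_cycle_transitions(strat, HealthState.END_STAGE, age, 30, cfg)
        assert row[HealthState.DEATH] == pytest.approx(qd, rel=1e-12)

    def test_sequential_downstream_mortality_uses_line3_curve(self, fixture_inputs):
        strat = fixture_inputs.strategies["second_line_sintilimab"]
        cfg = dataclasses.replace(fixture_inputs.config, convention="sequential")
        os3 = strat.line3.os_curve
        age = 12
        qd = 1.0 - survival(os3, age + 1.0) / survival(os3, age)
        row = build_cycle_transitions(strat, HealthState.END_STAGE, age, 30, cfg)
        assert row[HealthState.DEATH] == pytest.approx(qd, rel=1e-12)


# ---------------------------------------------------------------------------
# cohort trace
# ---------------------------------------------------------------------------


class TestCohortTrace:
    def test_zero_hazard_cohort_stays_in_pfs(self):
        cfg = short_config(24)
        trace = run_cohort(null_strategy(), cfg)
        np.testing.assert_allclose(trace.occupancy[:, COL[HealthState.PFS]], 1.0)

    def test_two_state_exponential_occupancy(self):
        lam = 0.05
        exp = ParametricSurvival("exponential", (lam,))
        line = TreatmentLine("l", exp, exp, 0.0, [])
        strat = StrategyDefinition("two-state", line, line, line, "sintilimab_gp")
        cfg = short_config(30)
        trace = run_cohort(strat, cfg)
        k = np.arange(31)
        np.testing.assert_allclose(
            trace.occupancy[:, COL[HealthState.PFS]], np.exp(-lam * k), rtol=1e-10
        )

    @pytest.mark.parametrize("conv", CONVENTIONS)
    def test_toy_chain_matches_matrix_power_oracle(self, exponential_toy, conv):
        """With memoryless (exponential) curves the scalar transition rows are
        age-independent, so the trace must equal the occupancy vector
        propagated by plain matrix powers of the one-cycle transition matrix
        built from build_cycle_transitions (dual-implementation oracle)."""
        cfg = dataclasses.replace(short_config(3), convention=conv)
        n_states = len(STATE_ORDER)
        mat = np.zeros((n_states, n_states))
        for state in STATE_ORDER:
            row = build_cycle_transitions(exponential_toy, state, 4, 2, cfg)
            for dest, p in row.items():
                mat[COL[state], COL[dest]] += p
        v = np.zeros(n_states)
        v[COL[HealthState.PFS]] = 1.0
        trace = run_cohort(exponential_toy, cfg)
        for k in range(4):
            np.testing.assert_allclose(trace.occupancy[k], v, atol=1e-12)
            v = v @ mat

    @pytest.mark.parametrize("conv", CONVENTIONS)
    @pytest.mark.parametrize("key", ["first_line_sintilimab", "second_line_sintilimab"])
    def test_conservation_and_death_monotone(self, fixture_inputs, conv, key):
        cfg = dataclasses.replace(fixture_inputs.config, convention=conv)
        trace = run_cohort(fixture_inputs.strategies[key], cfg)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        death = trace.occupancy[:, COL[HealthState.DEATH]]
        assert np.all(np.diff(death) >= -1e-12)
        assert np.all(trace.occupancy >= -1e-12)

    @pytest.mark.parametrize("key", ["first_line_sintilimab", "second_line_sintilimab"])
    def test_cohort_nearly_absorbed_at_horizon(self, fixture_inputs, key):
        trace = run_cohort(fixture_inputs.strategies[key], fixture_inputs.config)
        assert trace.occupancy[-1, COL[HealthState.DEATH]] > 0.99


# ---------------------------------------------------------------------------
# accrual
# ---------------------------------------------------------------------------


def _unit_utilities():
    return UtilityInputs(1.0, 1.0, 1.0, 1.0, {"sintilimab_gp": 0.0, "gp": 0.0})


def _zero_costs():
    return CostInputs(
        drug_prices={}, routine_followup=0.0, bsc=0.0, palliative=0.0,
        ae_first_line={"sintilimab_gp": 0.0, "gp": 0.0},
    )


class TestAccrual:
    def test_qaly_conservation_without_death_or_discounting(self):
        """Utility one everywhere, no mortality, no discounting: total QALYs
        equal the undiscounted person-time, which covers one year up to the
        integer-cycle rounding of the horizon."""
        cfg = dataclasses.replace(
            short_config(18), discount_rate=0.0
        )  # 18 cycles ~ 1 year
        strat = null_strategy()
        trace = run_cohort(strat, cfg)
        out = accrue(trace, _zero_costs(), _unit_utilities(), strat, cfg)
        assert out.total_qalys == pytest.approx(18 * cfg.cycle_years, rel=1e-9)
        assert out.total_qalys == pytest.approx(1.0, abs=cfg.cycle_years)

    def test_discounting_strictly_shrinks_totals(self, fixture_inputs):
        _, at5 = run_strategy(fixture_inputs, "first_line_sintilimab")
        undisc = copy.deepcopy(fixture_inputs)
        undisc.config = dataclasses.replace(undisc.config, discount_rate=0.0)
        _, at0 = run_strategy(undisc, "first_line_sintilimab")
        assert at5.total_qalys < at0.total_qalys
        assert at5.total_cost < at0.total_cost

    @pytest.mark.parametrize("key", ["first_line_sintilimab", "second_line_sintilimab"])
    def test_decomposition_sums_to_totals(self, base_case, key):
        out = base_case["reference" if key == "first_line_sintilimab" else "comparator"]
        assert sum(out.qalys_by_state.values()) == pytest.approx(
            out.total_qalys, abs=1e-6
        )
        assert sum(out.costs_by_state.values()) == pytest.approx(
            out.total_cost, abs=1e-6
        )
        assert out.qalys_by_state["DEATH"] == 0.0

    def test_raising_utility_raises_qalys(self, fixture_inputs, base_case):
        bumped = copy.deepcopy(fixture_inputs)
        bumped.utilities.u_fdp = 0.9
        _, out = run_strategy(bumped, "second_line_sintilimab")
        assert out.total_qalys > base_case["comparator"].total_qalys

    def test_raising_price_raises_cost(self, fixture_inputs, base_case):
        bumped = copy.deepcopy(fixture_inputs)
        bumped.costs.drug_prices["sintilimab"] *= 2.0
        for key, ref in (("reference", "first_line_sintilimab"),
                         ("comparator", "second_line_sintilimab")):
            _, out = run_strategy(bumped, ref)
            assert out.total_cost > base_case[key].total_cost
            assert out.total_qalys == pytest.approx(base_case[key].total_qalys)

    def test_half_cycle_correction_is_second_order(self, fixture_inputs):
        hcc = copy.deepcopy(fixture_inputs)
        hcc.config = dataclasses.replace(hcc.config, half_cycle_correction=True)
        _, with_hcc = run_strategy(hcc, "first_line_sintilimab")
        _, without = run_strategy(fixture_inputs, "first_line_sintilimab")
        assert with_hcc.total_qalys == pytest.approx(without.total_qalys, rel=0.05)
        assert with_hcc.total_qalys != without.total_qalys


# ---------------------------------------------------------------------------
# ICER
# ---------------------------------------------------------------------------


def _outcome(cost, qalys):
    from sintcea.markov_model import Outcomes

    return Outcomes("x", cost, qalys, {}, {}, qalys)


class TestIcer:
    def test_plain_division(self):
        res = icer(_outcome(10000.0, 1.0), _outcome(11842.0, 1.15))
        assert res.value == pytest.approx(1842.0 / 0.15)
        assert res.flag == ""

    def test_undefined_when_equal_effect(self):
        res = icer(_outcome(10000.0, 1.0), _outcome(10000.0, 1.0))
        assert res.flag == "undefined"
        assert np.isnan(res.value)

    def test_dominance_flags(self):
        assert icer(_outcome(1000.0, 1.0), _outcome(900.0, 1.1)).flag == "dominant"
        assert icer(_outcome(1000.0, 1.0), _outcome(1100.0, 0.9)).flag == "dominated"

    def test_identical_strategies_give_undefined_icer(self, fixture_inputs):
        sym = copy.deepcopy(fixture_inputs)
        clone = copy.deepcopy(sym.strategies["first_line_sintilimab"])
        clone.name = "clone"
        sym.strategies["second_line_sintilimab"] = clone
        res = run_base_case(sym)
        assert res["icer"].flag == "undefined"

    def test_cost_effective_via_net_monetary_benefit(self):
        res = icer(_outcome(10000.0, 1.0), _outcome(11000.0, 1.1))
        assert res.cost_effective(35663.0)
        assert not res.cost_effective(5000.0)
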