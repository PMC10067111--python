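"""Semi-Markov cohort engine for the sequential-treatment model.

The model follows a cohort of patients with advanced squamous NSCLC through
five main health states

    PFS -> FDP -> SDP -> END_STAGE -> DEATH

(progression-free on first-line therapy, first and second disease
progression, end-stage disease on best supportive care, death), plus three
single-cycle "discontinued therapy" tunnel states fed by adverse-event
discontinuation on each active treatment line.  Two strategies are compared:
sintilimab + gemcitabine/platinum first line followed by docetaxel, or
gemcitabine/platinum first line followed by second-line sintilimab; both
share third-line anlotinib.

Transition probabilities are derived from parametric survival curves fitted
to the source trials.  The fitted inputs do not uniquely determine the clock
convention of such a model, so the engine supports three:

``anchored`` (default)
    After first progression, mortality in every downstream state follows the
    *second-line* OS curve on the time-since-second-line clock, preserving
    the randomized second-line OS evidence (those trial OS curves already
    reflect real-world downstream therapy).  Progression-excess hazards
    (PFS-event hazard minus death hazard) are indexed on model time.
``sequential``
    Strict per-line semi-Markov: each line's OS/PFS curves are evaluated on
    that line's residence clock, reset at FDP/SDP entry; end-stage mortality
    continues the anlotinib OS on the line-3 clock.
``stage-indexed``
    Every hazard is evaluated on model time (the convention of
    stage-indexed probability tables in common decision-tree software).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .survival_models import ParametricSurvival

__all__ = [
    "HealthState",
    "RegimenComponent",
    "TreatmentLine",
    "StrategyDefinition",
    "PatientProfile",
    "CostInputs",
    "UtilityInputs",
    "ModelConfig",
    "ModelInputs",
    "CohortTrace",
    "Outcomes",
    "IcerResult",
    "ConsistencyError",
    "ConfigurationError",
    "carboplatin_dose",
    "per_cycle_drug_cost",
    "build_cycle_transitions",
    "run_cohort",
    "accrue",
    "run_strategy",
    "run_base_case",
    "icer",
]

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25

#: Reference patient to which the fixture's unit drug prices are indexed
#: (mean body surface area and creatinine clearance of the modeled cohort).
REFERENCE_BSA = 1.72
REFERENCE_CRCL = 70.0
REFERENCE_AUC = 5.0

CONVENTIONS = ("anchored", "sequential", "stage-indexed")


class ConsistencyError(RuntimeError):
    """Internal cohort bookkeeping violated mass conservation."""


class ConfigurationError(ValueError):
    """A required model input is missing or out of range."""


class HealthState(str, Enum):
    PFS = "PFS"
    FDP = "FDP"
    SDP = "SDP"
    END_STAGE = "END_STAGE"
    DEATH = "DEATH"
    DISC_L1 = "DISC_L1"
    DISC_L2 = "DISC_L2"
    DISC_L3 = "DISC_L3"


#: Column order of the occupancy matrix in :class:`CohortTrace`.
STATE_ORDER = [
    HealthState.PFS,
    HealthState.FDP,
    HealthState.SDP,
    HealthState.END_STAGE,
    HealthState.DEATH,
    HealthState.DISC_L1,
    HealthState.DISC_L2,
    HealthState.DISC_L3,
]
_COL = {s: i for i, s in enumerate(STATE_ORDER)}


# ---------------------------------------------------------------------------
# input containers
# ---------------------------------------------------------------------------


@dataclass
class RegimenComponent:
    """One drug within a per-cycle regimen.

    ``scaling`` maps the listed unit price (indexed to the reference patient)
    to the modeled patient: ``flat`` (fixed dose), ``per_bsa`` (dose
    proportional to body surface area) or ``per_calvert`` (carboplatin dose
    from the Calvert formula).  ``max_cycles`` caps how many cycles on the
    line the component is given (e.g. chemotherapy backbone capped while an
    antibody continues as maintenance).
    """

    drug: str
    units: float = 1.0
    scaling: str = "flat"
    max_cycles: Optional[int] = None
    auc: float = REFERENCE_AUC

    def __post_init__(self):
        if self.scaling not in ("flat", "per_bsa", "per_calvert"):
            raise ConfigurationError(f"unknown scaling {self.scaling!r}")
        if self.units < 0:
            raise ConfigurationError("regimen units must be non-negative")


@dataclass
class TreatmentLine:
    name: str
    os_curve: ParametricSurvival
    pfs_curve: ParametricSurvival
    disc_prob: float
    regimen: list = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 <= self.disc_prob <= 1.0:
            raise ConfigurationError(
                f"discontinuation probability for {self.name} must be in [0, 1]"
            )


@dataclass
class StrategyDefinition:
    name: str
    line1: TreatmentLine
    line2: TreatmentLine
    line3: TreatmentLine
    ae_key: str  # first-line AE cost / disutility lookup key

    @property
    def lines(self):
        return (self.line1, self.line2, self.line3)


@dataclass
class PatientProfile:
    bsa: float = REFERENCE_BSA
    crcl: float = REFERENCE_CRCL

    def __post_init__(self):
        if self.bsa <= 0 or self.crcl <= 0:
            raise ConfigurationError("BSA and creatinine clearance must be positive")


@dataclass
class CostInputs:
    """Unit prices (2021 USD) and general management costs.

    ``drug_prices`` are per the Table-1 unit dose at the reference patient;
    ``ae_first_line`` maps a strategy's first-line regimen key to its one-off
    grade-III/IV adverse-event management cost.
    """

    drug_prices: dict
    routine_followup: float
    bsc: float
    palliative: float
    ae_first_line: dict

    def __post_init__(self):
        for key, val in list(self.drug_prices.items()) + list(self.ae_first_line.items()):
            if val < 0:
                raise ConfigurationError(f"cost {key!r} must be non-negative")
        for key in ("routine_followup", "bsc", "palliative"):
            if getattr(self, key) < 0:
                raise ConfigurationError(f"cost {key!r} must be non-negative")


@dataclass
class UtilityInputs:
    u_pfs: float
    u_fdp: float
    u_sdp: float
    u_endstage: float
    ae_disutility: dict

    def __post_init__(self):
        for key in ("u_pfs", "u_fdp", "u_sdp", "u_endstage"):
            val = getattr(self, key)
            if not 0.0 <= val <= 1.0:
                raise ConfigurationError(f"utility {key} must be in [0, 1], got {val}")
        for key, val in self.ae_disutility.items():
            if val < 0:
                raise ConfigurationError(f"disutility {key!r} must be non-negative")


@dataclass
class ModelConfig:
    cycle_length_days: float = 21.0
    horizon_years: float = 20.0
    discount_rate: float = 0.05
    wtp: float = 35663.0
    convention: str = "anchored"
    survival_time_unit: str = "cycle"
    half_cycle_correction: bool = False
    death_cycle_fraction: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.discount_rate <= 1.0:
            raise ConfigurationError("discount rate must be in [0, 1]")
        if self.convention not in CONVENTIONS:
            raise ConfigurationError(
                f"convention must be one of {CONVENTIONS}, got {self.convention!r}"
            )
        if self.survival_time_unit not in ("cycle", "month"):
            raise ConfigurationError("survival_time_unit must be 'cycle' or 'month'")
        if not 0.0 <= self.death_cycle_fraction <= 1.0:
            raise ConfigurationError("death_cycle_fraction must be in [0, 1]")
        if self.n_cycles < 1:
            raise ConfigurationError("horizon must cover at least one cycle")

    @property
    def cycle_length_months(self) -> float:
        return self.cycle_length_days / DAYS_PER_MONTH

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR

    @property
    def n_cycles(self) -> int:
        return math.ceil(self.horizon_years * DAYS_PER_YEAR / self.cycle_length_days)

    @property
    def curve_time_per_cycle(self) -> float:
        """One model cycle expressed on the survival curves' time scale."""
        return 1.0 if self.survival_time_unit == "cycle" else self.cycle_length_months


@dataclass
class ModelInputs:
    """Complete, validated model input bundle (Table-1 equivalent)."""

    strategies: dict
    costs: CostInputs
    utilities: UtilityInputs
    patient: PatientProfile
    config: ModelConfig
    parameters: list = field(default_factory=list)  # sensitivity.ParameterSpec items


# ---------------------------------------------------------------------------
# dosing and per-cycle drug cost
# ---------------------------------------------------------------------------


def carboplatin_dose(auc_target: float, crcl: float) -> float:
    """Carboplatin dose in mg by the Calvert formula: AUC x (CrCl + 25)."""
    if auc_target <= 0 or crcl <= 0:
        raise ConfigurationError("AUC target and creatinine clearance must be positive")
    return auc_target * (crcl + 25.0)


def _component_scale(comp: RegimenComponent, patient: PatientProfile) -> float:
    if comp.scaling == "flat":
        return 1.0
    if comp.scaling == "per_bsa":
        return patient.bsa / REFERENCE_BSA
    return carboplatin_dose(comp.auc, patient.crcl) / carboplatin_dose(
        comp.auc, REFERENCE_CRCL
    )


def per_cycle_drug_cost(
    line: TreatmentLine,
    costs: CostInputs,
    patient: PatientProfile,
    cycle_on_line: int = 0,
) -> float:
    """Drug acquisition cost for one cycle on ``line``.

    ``cycle_on_line`` is the 0-based cycle index since the line started and
    determines whether capped components are still administered.
    """
    total = 0.0
    for comp in line.regimen:
        if comp.max_cycles is not None and cycle_on_line >= comp.max_cycles:
            continue
        if comp.drug not in costs.drug_prices:
            raise ConfigurationError(f"no unit price configured for drug {comp.drug!r}")
        total += comp.units * costs.drug_prices[comp.drug] * _component_scale(comp, patient)
    return total


# ---------------------------------------------------------------------------
# transition probabilities
# ---------------------------------------------------------------------------


def _tp_table(curve: ParametricSurvival, n: int, step: float) -> np.ndarray:
    """Per-cycle conditional transition probabilities tp[k] on a grid of
    ``n + 2`` cycle-start times; evaluated in log space and clipped to [0, 1].
    """
    t = np.arange(n + 3, dtype=float) * step
    log_s = np.asarray(curve.log_survival(t))
    tp = -np.expm1(log_s[1:] - log_s[:-1])
    return np.clip(tp, 0.0, 1.0)


def build_cycle_transitions(
    strategy: StrategyDefinition,
    state: HealthState,
    age: int,
    cycle: int,
    config: ModelConfig,
) -> dict:
    """One-cycle transition row for a single state occupant.

    ``age`` is the occupant's state-clock (cycles since the governing clock
    started; which clock that is depends on ``config.convention``) and
    ``cycle`` the model cycle index.  Returns a dict mapping destination
    :class:`HealthState` to probability; entries sum to 1.

    This scalar routine is the reference semantics of the engine; the
    vectorized cohort loop in :func:`run_cohort` must agree with it.
    """
    step = config.curve_time_per_cycle
    conv = config.convention
    l1, l2, l3 = strategy.lines

    def tp(curve, k):
        log_s = curve.log_survival(np.array([k * step, (k + 1) * step]))
        return float(np.clip(-np.expm1(log_s[1] - log_s[0]), 0.0, 1.0))

    def death_time():
        # clock on which the mortality hazard is evaluated
        if conv == "stage-indexed":
            return cycle
        return age  # line clock (model clock for line 1 coincides with age)

    def prog_time():
        if conv == "sequential":
            return age
        return cycle  # anchored and stage-indexed: model clock

    if state in (HealthState.PFS, HealthState.DISC_L1):
        qd = tp(l1.os_curve, cycle)  # line-1 clock == model clock
        if state is HealthState.DISC_L1:
            return {HealthState.DEATH: qd, HealthState.FDP: 1.0 - qd}
        qpd = tp(l1.pfs_curve, prog_time())
        qp = max(0.0, qpd - qd)
        alive = max(0.0, 1.0 - qd - qp)
        qdisc = l1.disc_prob * alive
        return {
            HealthState.DEATH: qd,
            HealthState.FDP: qp,
            HealthState.DISC_L1: qdisc,
            HealthState.PFS: alive - qdisc,
        }

    if state in (HealthState.FDP, HealthState.DISC_L2):
        qd = tp(l2.os_curve, death_time())
        if state is HealthState.DISC_L2:
            return {HealthState.DEATH: qd, HealthState.SDP: 1.0 - qd}
        if conv == "sequential":
            qp = max(0.0, tp(l2.pfs_curve, age) - qd)
        else:
            qp = max(0.0, tp(l2.pfs_curve, cycle) - tp(l2.os_curve, cycle))
        qp = min(qp, max(0.0, 1.0 - qd))
        alive = max(0.0, 1.0 - qd - qp)
        qdisc = l2.disc_prob * alive
        return {
            HealthState.DEATH: qd,
            HealthState.SDP: qp,
            HealthState.DISC_L2: qdisc,
            HealthState.FDP: alive - qdisc,
        }

    if state in (HealthState.SDP, HealthState.DISC_L3, HealthState.END_STAGE):
        if conv == "anchored":
            qd = tp(l2.os_curve, age)  # line-2 OS carried through downstream states
        elif conv == "sequential":
            qd = tp(l3.os_curve, age)
        else:
            qd = tp(l3.os_curve, cycle)
        if state is HealthState.DISC_L3:
            return {HealthState.DEATH: qd, HealthState.END_STAGE: 1.0 - qd}
        if state is HealthState.END_STAGE:
            return {HealthState.DEATH: qd, HealthState.END_STAGE: 1.0 - qd}
        if conv == "sequential":
            qp = max(0.0, tp(l3.pfs_curve, age) - qd)
        else:
            qp = max(0.0, tp(l3.pfs_curve, cycle) - tp(l3.os_curve, cycle))
        qp = min(qp, max(0.0, 1.0 - qd))
        alive = max(0.0, 1.0 - qd - qp)
        qdisc = l3.disc_prob * alive
        return {
            HealthState.DEATH: qd,
            HealthState.END_STAGE: qp,
            HealthState.DISC_L3: qdisc,
            HealthState.SDP: alive - qdisc,
        }

    if state is HealthState.DEATH:
        return {HealthState.DEATH: 1.0}
    raise ConfigurationError(f"unknown state {state}")


# ---------------------------------------------------------------------------
# cohort trace
# ---------------------------------------------------------------------------


@dataclass
class CohortTrace:
    """Cycle-by-cycle state occupancy with line-clock bookkeeping.

    ``occupancy`` has one row per cycle *start* (``n_cycles + 1`` rows) and
    one column per :data:`STATE_ORDER` entry; rows sum to one.  ``new_deaths``
    holds the death inflow during each cycle.  ``drug_units[(line, i)]`` is
    the expected number of unit doses of regimen component ``i`` of treatment
    line ``line`` (0-based) consumed in each cycle per cohort member, with
    component caps already applied; prices and patient scaling are applied at
    accrual time.  ``mean_age`` tracks the mean governing-clock age of the
    occupants of each state (cycles).
    """

    strategy_name: str
    occupancy: np.ndarray
    new_deaths: np.ndarray
    drug_units: dict
    mean_age: np.ndarray
    config: ModelConfig

    def occupancy_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.occupancy, columns=[s.value for s in STATE_ORDER]
        ).rename_axis("cycle")


def run_cohort(strategy: StrategyDefinition, config: ModelConfig) -> CohortTrace:
    """Propagate the full cohort from PFS entry over the model horizon."""
    n = config.n_cycles
    step = config.curve_time_per_cycle
    conv = config.convention
    l1, l2, l3 = strategy.lines

    tp_os1 = _tp_table(l1.os_curve, n, step)
    tp_pfs1 = _tp_table(l1.pfs_curve, n, step)
    tp_os2 = _tp_table(l2.os_curve, n, step)
    tp_pfs2 = _tp_table(l2.pfs_curve, n, step)
    tp_os3 = _tp_table(l3.os_curve, n, step)
    tp_pfs3 = _tp_table(l3.pfs_curve, n, step)

    z = n + 2  # age-resolved vectors
    ages = np.arange(z)
    pfs = np.zeros(z)
    pfs[0] = 1.0
    d1 = np.zeros(z)
    fdp = np.zeros(z)
    d2 = np.zeros(z)
    sdp = np.zeros(z)
    d3 = np.zeros(z)
    end = np.zeros(z)
    dead = 0.0

    occupancy = np.zeros((n + 1, len(STATE_ORDER)))
    mean_age = np.full((n + 1, len(STATE_ORDER)), np.nan)
    new_deaths = np.zeros(n)
    drug_units = {
        (li, ci): np.zeros(n)
        for li, line in enumerate(strategy.lines)
        for ci in range(len(line.regimen))
    }

    def record(k):
        vals = {
            HealthState.PFS: pfs,
            HealthState.FDP: fdp,
            HealthState.SDP: sdp,
            HealthState.END_STAGE: end,
            HealthState.DISC_L1: d1,
            HealthState.DISC_L2: d2,
            HealthState.DISC_L3: d3,
        }
        for state, vec in vals.items():
            tot = vec.sum()
            occupancy[k, _COL[state]] = tot
            if tot > 0:
                mean_age[k, _COL[state]] = float(np.dot(vec, ages) / tot)
        occupancy[k, _COL[HealthState.DEATH]] = dead
        total = occupancy[k].sum()
        if abs(total - 1.0) > 1e-6:
            raise ConsistencyError(
                f"cohort mass {total!r} != 1 at cycle {k} ({strategy.name})"
            )

    def cap_mask(comp):
        if comp.max_cycles is None:
            return np.ones(z)
        return (ages < comp.max_cycles).astype(float)

    cap_masks = {
        (li, ci): cap_mask(comp)
        for li, line in enumerate(strategy.lines)
        for ci, comp in enumerate(line.regimen)
    }

    for k in range(n):
        record(k)
        # expected unit doses consumed this cycle (start-of-cycle occupants)
        for li, line_occ in ((0, pfs), (1, fdp), (2, sdp)):
            line = strategy.lines[li]
            for ci, comp in enumerate(line.regimen):
                drug_units[(li, ci)][k] = comp.units * float(
                    np.dot(line_occ, cap_masks[(li, ci)])
                )

        died = 0.0
        kk = min(k, n)

        # --- line 1 (clock == model time) ---
        qd1 = tp_os1[kk]
        qpd1 = tp_pfs1[kk]
        qp1 = max(0.0, qpd1 - qd1)
        alive1 = max(0.0, 1.0 - qd1 - qp1)
        qdisc1 = l1.disc_prob * alive1
        died += pfs.sum() * qd1 + d1.sum() * qd1
        fdp_in = pfs.sum() * qp1 + d1.sum() * (1.0 - qd1)
        new_pfs = np.zeros(z)
        new_pfs[1:] = (pfs * (alive1 - qdisc1))[:-1]
        new_d1 = np.zeros(z)
        new_d1[1:] = (pfs * qdisc1)[:-1]

        # --- line 2 ---
        if conv == "stage-indexed":
            qd2 = np.full(z, tp_os2[kk])
        else:
            qd2 = tp_os2[ages]
        if conv == "sequential":
            qp2 = np.maximum(0.0, tp_pfs2[ages] - qd2)
        else:
            qp2 = np.full(z, max(0.0, tp_pfs2[kk] - tp_os2[kk]))
        qp2 = np.minimum(qp2, np.maximum(0.0, 1.0 - qd2))
        alive2 = np.maximum(0.0, 1.0 - qd2 - qp2)
        qdisc2 = l2.disc_prob * alive2
        died += float(np.dot(fdp, qd2) + np.dot(d2, qd2))
        sdp_in_prog = fdp * qp2
        sdp_in_disc = d2 * (1.0 - qd2)
        new_fdp = np.zeros(z)
        new_fdp[1:] = (fdp * (alive2 - qdisc2))[:-1]
        new_fdp[0] = fdp_in
        new_d2 = np.zeros(z)
        new_d2[1:] = (fdp * qdisc2)[:-1]

        # --- line 3 and end-stage ---
        if conv == "anchored":
            qd3 = tp_os2[ages]
        elif conv == "sequential":
            qd3 = tp_os3[ages]
        else:
            qd3 = np.full(z, tp_os3[kk])
        if conv == "sequential":
            qp3 = np.maximum(0.0, tp_pfs3[ages] - qd3)
        else:
            qp3 = np.full(z, max(0.0, tp_pfs3[kk] - tp_os3[kk]))
        qp3 = np.minimum(qp3, np.maximum(0.0, 1.0 - qd3))
        alive3 = np.maximum(0.0, 1.0 - qd3 - qp3)
        qdisc3 = l3.disc_prob * alive3
        died += float(np.dot(sdp, qd3) + np.dot(d3, qd3) + np.dot(end, qd3))
        end_in = sdp * qp3 + d3 * (1.0 - qd3)
        new_sdp = np.zeros(z)
        new_sdp[1:] = (sdp * (alive3 - qdisc3))[:-1]
        new_d3 = np.zeros(z)
        new_d3[1:] = (sdp * qdisc3)[:-1]
        new_end = np.zeros(z)
        new_end[1:] = (end * (1.0 - qd3))[:-1] + end_in[:-1]

        # SDP entry: line-3 clock starts (sequential/stage), or the line-2
        # clock is carried through (anchored)
        if conv == "anchored":
            new_sdp[1:] += sdp_in_prog[:-1] + sdp_in_disc[:-1]
        else:
            new_sdp[0] += float(sdp_in_prog.sum() + sdp_in_disc.sum())

        pfs, d1, fdp, d2, sdp, d3, end = (
            new_pfs,
            new_d1,
            new_fdp,
            new_d2,
            new_sdp,
            new_d3,
            new_end,
        )
        dead += died
        new_deaths[k] = died

    record(n)
    return CohortTrace(
        strategy_name=strategy.name,
        occupancy=occupancy,
        new_deaths=new_deaths,
        drug_units=drug_units,
        mean_age=mean_age,
        config=config,
    )


# ---------------------------------------------------------------------------
# accrual and ICER
# ---------------------------------------------------------------------------


@dataclass
class Outcomes:
    strategy_name: str
    total_cost: float
    total_qalys: float
    qalys_by_state: dict
    costs_by_state: dict
    life_years: float


def accrue(
    trace: CohortTrace,
    costs: CostInputs,
    utilities: UtilityInputs,
    strategy: StrategyDefinition,
    config: ModelConfig,
) -> Outcomes:
    """Discounted cost and QALY accrual over a cohort trace.

    Utilities and per-cycle costs accrue on start-of-cycle occupancy (mean of
    cycle start/end when ``half_cycle_correction`` is set).  The one-off AE
    management cost and a one-cycle AE disutility decrement apply at model
    entry; palliative care is charged for ``death_cycle_fraction`` of a cycle
    on each death transition.  Tunnel states carry the utility and follow-up
    cost of the state the patient discontinued from and are folded into that
    state's row of the decomposition.
    """
    n = config.n_cycles
    cy = config.cycle_years
    disc = (1.0 + config.discount_rate) ** (-np.arange(n) * cy)
    occ = trace.occupancy

    def occ_of(state):
        col = occ[:, _COL[state]]
        if config.half_cycle_correction:
            return 0.5 * (col[:-1] + col[1:])
        return col[:-1]

    rows = {
        "PFS": (occ_of(HealthState.PFS) + occ_of(HealthState.DISC_L1), utilities.u_pfs),
        "FDP": (occ_of(HealthState.FDP) + occ_of(HealthState.DISC_L2), utilities.u_fdp),
        "SDP": (occ_of(HealthState.SDP) + occ_of(HealthState.DISC_L3), utilities.u_sdp),
        "END_STAGE": (occ_of(HealthState.END_STAGE), utilities.u_endstage),
    }

    qalys = {name: float(np.sum(o * u * cy * disc)) for name, (o, u) in rows.items()}
    qalys["DEATH"] = 0.0
    qalys["PFS"] -= utilities.ae_disutility[strategy.ae_key] * cy

    life_years = float(
        sum(np.sum(o * cy * disc) for o, _ in rows.values())
    )

    hcc = config.half_cycle_correction
    cost_rows = {}
    for name, (o, _) in rows.items():
        per_cycle = costs.bsc if name == "END_STAGE" else costs.routine_followup
        cost_rows[name] = float(np.sum(o * per_cycle * disc))
    # drug acquisition per line
    line_state = {0: "PFS", 1: "FDP", 2: "SDP"}
    patient = getattr(trace, "_patient", None)
    for (li, ci), units in trace.drug_units.items():
        comp = strategy.lines[li].regimen[ci]
        if comp.drug not in costs.drug_prices:
            raise ConfigurationError(f"no unit price configured for drug {comp.drug!r}")
        price = costs.drug_prices[comp.drug] * _component_scale(
            comp, patient if patient is not None else PatientProfile()
        )
        u = units
        if hcc:
            u = 0.5 * (units + np.append(units[1:], units[-1]))
        cost_rows[line_state[li]] += float(np.sum(u * price * disc))
    cost_rows["PFS"] += costs.ae_first_line[strategy.ae_key]
    cost_rows["DEATH"] = float(
        np.sum(trace.new_deaths * costs.palliative * config.death_cycle_fraction * disc)
    )

    return Outcomes(
        strategy_name=trace.strategy_name,
        total_cost=float(sum(cost_rows.values())),
        total_qalys=float(sum(qalys.values())),
        qalys_by_state=qalys,
        costs_by_state=cost_rows,
        life_years=life_years,
    )


@dataclass
class IcerResult:
    value: float  # NaN when flagged undefined / dominant / dominated
    delta_cost: float
    delta_qalys: float
    flag: str = ""  # "", "dominant", "dominated", "undefined"

    def cost_effective(self, wtp: float) -> bool:
        """Is the comparator preferred at the given willingness-to-pay?"""
        return wtp * self.delta_qalys - self.delta_cost > 0


def icer(reference: Outcomes, comparator: Outcomes) -> IcerResult:
    """Incremental cost-effectiveness ratio of ``comparator`` vs ``reference``."""
    dc = comparator.total_cost - reference.total_cost
    dq = comparator.total_qalys - reference.total_qalys
    if abs(dq) < 1e-9:
        return IcerResult(float("nan"), dc, dq, "undefined")
    if dq > 0 and dc <= 0:
        return IcerResult(float("nan"), dc, dq, "dominant")
    if dq < 0 and dc >= 0:
        return IcerResult(float("nan"), dc, dq, "dominated")
    return IcerResult(dc / dq, dc, dq, "")


# ---------------------------------------------------------------------------
# convenience drivers
# ---------------------------------------------------------------------------


def run_strategy(inputs: ModelInputs, key: str):
    """Run one strategy of an input bundle; returns (trace, outcomes)."""
    strategy = inputs.strategies[key]
    trace = run_cohort(strategy, inputs.config)
    trace._patient = inputs.patient  # used for price scaling at accrual
    outcomes = accrue(trace, inputs.costs, inputs.utilities, strategy, inputs.config)
    return trace, outcomes


def run_base_case(inputs: ModelInputs) -> dict:
    """Run both strategies and the ICER of reserving sintilimab until second
    line (comparator) versus first-line use (reference)."""
    keys = list(inputs.strategies)
    if len(keys) != 2:
        raise ConfigurationError("base case expects exactly two strategies")
    ref_key, cmp_key = keys
    _, ref = run_strategy(inputs, ref_key)
    _, cmp_ = run_strategy(inputs, cmp_key)
    return {
        "reference": ref,
        "comparator": cmp_,
        "icer": icer(ref, cmp_),
    }
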