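"""Synthetic trial data and the complete base-case input fixture.

Two jobs live here.  First, simulation of right-censored survival data from
any supported parametric family (inverse-CDF sampling, closed form wherever
one exists) together with Kaplan-Meier summaries, which exercises the
digitization -> reconstruction -> fitting chain on data with a known truth.
Second, :func:`make_fixture_config` builds the complete published input set
of the sintilimab sequencing analysis: ten fitted survival parameter sets,
five per-cycle adverse-event discontinuation probabilities, unit drug
prices, management costs, health-state utilities, discount rate, patient
characteristics and willingness-to-pay, along with every deterministic
sensitivity bound and probabilistic sampling family.

The fixture's survival curves are parameterized on the model-cycle time
scale (one unit = one 3-week cycle); under that reading the curves reproduce
the source trials' published medians (e.g. second-line sintilimab OS
median 17.3 cycles = 11.9 months).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from lifelines import KaplanMeierFitter

from .ipd_tools import KMDigitization, ReconstructedIPD
from .markov_model import (
    CostInputs,
    ModelConfig,
    ModelInputs,
    PatientProfile,
    RegimenComponent,
    StrategyDefinition,
    TreatmentLine,
    UtilityInputs,
)
from .sensitivity import ParameterSpec
from .survival_models import ParametricSurvival, ValidationError

__all__ = [
    "TrialSimSpec",
    "simulate_trial",
    "km_curve",
    "coarsen_km",
    "make_fixture_config",
]


@dataclass
class TrialSimSpec:
    """Specification of one simulated single-arm trial."""

    dist: ParametricSurvival
    n: int
    max_follow_up: Optional[float] = None  # uniform censoring upper bound
    admin_cutoff: Optional[float] = None  # administrative cutoff time
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("need at least one patient")
        if self.max_follow_up is not None and self.max_follow_up <= 0:
            raise ValidationError("follow-up bound must be positive")


def simulate_trial(spec: TrialSimSpec) -> ReconstructedIPD:
    """Draw right-censored records: event times by inverse CDF, censoring
    from a uniform follow-up model and/or an administrative cutoff."""
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(size=spec.n)
    event_times = np.asarray(spec.dist.quantile(u), dtype=float)
    censor = np.full(spec.n, np.inf)
    if spec.max_follow_up is not None:
        censor = np.minimum(censor, rng.uniform(0.0, spec.max_follow_up, size=spec.n))
    if spec.admin_cutoff is not None:
        censor = np.minimum(censor, spec.admin_cutoff)
    times = np.minimum(event_times, censor)
    events = (event_times <= censor).astype(int)
    if not np.all(np.isfinite(times)):
        # improper tails (negative Gompertz shape) need a finite cutoff
        raise ValidationError("infinite simulated times; set a censoring model")
    return ReconstructedIPD(times, events)


def km_curve(ipd: ReconstructedIPD, risk_times=None) -> KMDigitization:
    """Kaplan-Meier product-limit summary of patient-level records.

    Coordinates are the KM estimate at time zero and after each distinct event
    time; the number-at-risk table is evaluated at ``risk_times`` (default:
    six evenly spaced times across follow-up).
    """
    if len(ipd) == 0:
        raise ValidationError("cannot summarize an empty dataset")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, ipd.events)
    sf = kmf.survival_function_.iloc[:, 0]
    event_times = np.unique(ipd.times[ipd.events == 1])
    coords = [(0.0, 1.0)]
    for t in event_times:
        coords.append((float(t), float(sf.loc[:t].iloc[-1])))
    t_max = float(ipd.times.max())
    if risk_times is None:
        risk_times = np.linspace(0.0, t_max, 6)[:-1]
    risk_table = [
        (float(rt), int(np.sum(ipd.times >= rt) if rt > 0 else len(ipd)))
        for rt in risk_times
    ]
    return KMDigitization(coords, risk_table, total_events=int(ipd.events.sum()))


def coarsen_km(km: KMDigitization, n_points: int) -> KMDigitization:
    """Thin the coordinate list to about ``n_points``, emulating a sparsely
    digitized published curve.

    Points are spaced evenly in *survival* (a digitizer follows the curve, so
    vertical steps between clicks are roughly equal), keeping the first and
    last coordinates.
    """
    coords = km.coords
    if n_points >= len(coords):
        return KMDigitization(list(coords), list(km.risk_table), km.total_events)
    s = np.array([c[1] for c in coords])
    targets = np.linspace(s[0], s[-1], n_points)
    idx = sorted({int(np.argmax(s <= tgt)) for tgt in targets} | {0, len(s) - 1})
    return KMDigitization(
        [coords[i] for i in idx], list(km.risk_table), km.total_events
    )


# ---------------------------------------------------------------------------
# base-case fixture
# ---------------------------------------------------------------------------


def _ll(theta, kappa):
    return ParametricSurvival("loglogistic", (theta, kappa))


def _wb(lam, gamma):
    return ParametricSurvival("weibull", (lam, gamma))


def make_fixture_config() -> ModelInputs:
    """The complete published base-case input bundle (see module docstring)."""
    anlotinib_regimen = [RegimenComponent("anlotinib", 1.0, "flat")]
    chemo_backbone = [
        RegimenComponent("gemcitabine", 1.0, "per_bsa", max_cycles=6),
        RegimenComponent("cisplatin", 1.0, "per_bsa", max_cycles=6),
    ]

    def anlotinib_line(disc):
        return TreatmentLine(
            name="anlotinib",
            os_curve=_wb(0.043830, 1.041130),
            pfs_curve=_wb(0.062080, 1.228680),
            disc_prob=disc,
            regimen=[RegimenComponent(**vars(c)) for c in anlotinib_regimen],
        )

    first_line_sintilimab = StrategyDefinition(
        name="first-line sintilimab",
        line1=TreatmentLine(
            name="sintilimab + gemcitabine/platinum",
            os_curve=_ll(0.001495, 1.977611),
            pfs_curve=_ll(0.009008, 2.158257),
            disc_prob=0.003701,
            regimen=[RegimenComponent("sintilimab", 1.0, "flat")]
            + [RegimenComponent(**vars(c)) for c in chemo_backbone],
        ),
        line2=TreatmentLine(
            name="docetaxel",
            os_curve=_ll(0.022400, 1.520600),
            pfs_curve=_ll(0.090110, 1.843920),
            disc_prob=0.004685,
            regimen=[RegimenComponent("docetaxel", 1.0, "per_bsa")],
        ),
        line3=anlotinib_line(0.007211),
        ae_key="sintilimab_gp",
    )
    second_line_sintilimab = StrategyDefinition(
        name="second-line sintilimab",
        line1=TreatmentLine(
            name="gemcitabine/platinum",
            os_curve=_ll(0.012050, 1.388800),
            pfs_curve=_ll(0.000821, 3.689725),
            disc_prob=0.003472,
            regimen=[RegimenComponent(**vars(c)) for c in chemo_backbone],
        ),
        line2=TreatmentLine(
            name="sintilimab",
            os_curve=_ll(0.009967, 1.617333),
            pfs_curve=_ll(0.109400, 1.197400),
            disc_prob=0.007897,
            regimen=[RegimenComponent("sintilimab", 1.0, "flat")],
        ),
        line3=anlotinib_line(0.007211),
        ae_key="gp",
    )

    costs = CostInputs(
        drug_prices={
            "sintilimab": 334.82,
            "gemcitabine": 70.53,
            "cisplatin": 8.80,
            "carboplatin": 1.30,
            "docetaxel": 39.53,
            "anlotinib": 665.97,
        },
        routine_followup=55.60,
        bsc=337.50,
        palliative=2627.80,
        ae_first_line={"sintilimab_gp": 2564.35, "gp": 2412.56},
    )
    utilities = UtilityInputs(
        u_pfs=0.856,
        u_fdp=0.768,
        u_sdp=0.703,
        u_endstage=0.703,
        ae_disutility={"sintilimab_gp": 0.100, "gp": 0.097},
    )

    s1 = "strategies.first_line_sintilimab"
    s2 = "strategies.second_line_sintilimab"
    parameters = [
        ParameterSpec(
            "disc_first_line_sintilimab_gp", 0.003701, 0.001850, 0.005551, "beta",
            [f"{s1}.line1.disc_prob"],
        ),
        ParameterSpec(
            "disc_first_line_gp", 0.003472, 0.001736, 0.005207, "beta",
            [f"{s2}.line1.disc_prob"],
        ),
        ParameterSpec(
            "disc_second_line_sintilimab", 0.007897, 0.003948, 0.011845, "beta",
            [f"{s2}.line2.disc_prob"],
        ),
        ParameterSpec(
            "disc_second_line_docetaxel", 0.004685, 0.002343, 0.007028, "beta",
            [f"{s1}.line2.disc_prob"],
        ),
        ParameterSpec(
            "disc_third_line_anlotinib", 0.007211, 0.003606, 0.010817, "beta",
            [f"{s1}.line3.disc_prob", f"{s2}.line3.disc_prob"],
        ),
        ParameterSpec(
            "cost_sintilimab_200mg", 334.82, 167.41, 502.23, "gamma",
            ["costs.drug_prices.sintilimab"],
        ),
        ParameterSpec(
            "cost_gemcitabine_per_g_m2", 70.53, 35.26, 105.79, "gamma",
            ["costs.drug_prices.gemcitabine"],
        ),
        ParameterSpec(
            "cost_cisplatin_per_75mg_m2", 8.80, 4.40, 13.20, "gamma",
            ["costs.drug_prices.cisplatin"],
        ),
        ParameterSpec(
            "cost_carboplatin_per_auc5", 1.30, 0.65, 1.95, "gamma",
            ["costs.drug_prices.carboplatin"],
        ),
        ParameterSpec(
            "cost_docetaxel_per_75mg_m2", 39.53, 19.76, 59.29, "gamma",
            ["costs.drug_prices.docetaxel"],
        ),
        ParameterSpec(
            "cost_anlotinib_per_168mg", 665.97, 332.99, 998.96, "gamma",
            ["costs.drug_prices.anlotinib"],
        ),
        ParameterSpec(
            "cost_routine_followup_per_cycle", 55.60, 27.80, 83.40, "gamma",
            ["costs.routine_followup"],
        ),
        ParameterSpec(
            "cost_bsc_per_cycle", 337.50, 168.75, 506.25, "gamma", ["costs.bsc"]
        ),
        ParameterSpec(
            "cost_palliative_per_cycle", 2627.80, 1313.90, 3941.70, "gamma",
            ["costs.palliative"],
        ),
        ParameterSpec(
            "cost_ae_first_line_sintilimab_gp", 2564.35, 1282.18, 3846.53, "gamma",
            ["costs.ae_first_line.sintilimab_gp"],
        ),
        ParameterSpec(
            "cost_ae_first_line_gp", 2412.56, 1206.28, 3618.84, "gamma",
            ["costs.ae_first_line.gp"],
        ),
        ParameterSpec(
            "utility_pfs", 0.856, 0.718, 0.994, "beta", ["utilities.u_pfs"]
        ),
        ParameterSpec(
            "utility_fdp", 0.768, 0.595, 0.941, "beta", ["utilities.u_fdp"]
        ),
        ParameterSpec(
            "utility_sdp", 0.703, 0.545, 0.861, "beta", ["utilities.u_sdp"]
        ),
        ParameterSpec(
            "utility_end_stage", 0.703, 0.545, 0.861, "beta", ["utilities.u_endstage"]
        ),
        ParameterSpec(
            "disutility_ae_sintilimab_gp", 0.100, 0.050, 0.150, "beta",
            ["utilities.ae_disutility.sintilimab_gp"],
        ),
        ParameterSpec(
            "disutility_ae_gp", 0.097, 0.049, 0.146, "beta",
            ["utilities.ae_disutility.gp"],
        ),
        ParameterSpec(
            "discount_rate", 0.05, 0.0, 0.08, "fixed", ["config.discount_rate"]
        ),
        ParameterSpec(
            "body_surface_area", 1.72, 0.86, 2.58, "normal", ["patient.bsa"]
        ),
        ParameterSpec(
            "creatinine_clearance", 70.0, 35.0, 105.0, "normal", ["patient.crcl"]
        ),
    ]

    return ModelInputs(
        strategies={
            "first_line_sintilimab": first_line_sintilimab,
            "second_line_sintilimab": second_line_sintilimab,
        },
        costs=costs,
        utilities=utilities,
        patient=PatientProfile(bsa=1.72, crcl=70.0),
        config=ModelConfig(
            cycle_length_days=21.0,
            horizon_years=20.0,
            discount_rate=0.05,
            wtp=35663.0,
        ),
        parameters=parameters,
    )
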