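import dataclasses

import pytest

from sintcea.cli_io import load_fixture
from sintcea.markov_model import run_base_case
from sintcea.survival_models import ParametricSurvival


@pytest.fixture()
def fixture_inputs():
    """A fresh copy of the complete base-case input bundle."""
    return load_fixture()


@pytest.fixture(scope="session")
def base_case():
    """Base-case outcomes of both strategies under the default convention."""
    return run_base_case(load_fixture())


@pytest.fixture(scope="session")
def exponential_toy():
    """An all-exponential toy strategy: memoryless hazards make every clock
    convention coincide, so the trace has a closed-form matrix-power oracle."""
    from sintcea.markov_model import (
        RegimenComponent,
        StrategyDefinition,
        TreatmentLine,
    )

    def line(name, lam_os, lam_pfs, disc):
        return TreatmentLine(
            name=name,
            os_curve=ParametricSurvival("exponential", (lam_os,)),
            pfs_curve=ParametricSurvival("exponential", (lam_pfs,)),
            disc_prob=disc,
            regimen=[RegimenComponent("drug_" + name, 1.0, "flat")],
        )

    return StrategyDefinition(
        name="toy",
        line1=line("l1", 0.02, 0.10, 0.01),
        line2=line("l2", 0.05, 0.15, 0.02),
        line3=line("l3", 0.08, 0.20, 0.015),
        ae_key="sintilimab_gp",
    )


def short_config(n_cycles, **kw):
    """A ModelConfig whose horizon covers exactly ``n_cycles`` cycles."""
    from sintcea.markov_model import DAYS_PER_YEAR, ModelConfig

    cfg = ModelConfig(**kw)
    return dataclasses.replace(
        cfg, horizon_years=n_cycles * cfg.cycle_length_days / DAYS_PER_YEAR
    )
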