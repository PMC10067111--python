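"""Deterministic (one-way) and probabilistic sensitivity analysis.

One-way DSA re-runs the model with each Table-1 parameter at its lower and
upper bound (utilities at their 95% CIs, costs/probabilities/patient
characteristics at +/-50%, discount rate 0-8%) and records the resulting
ICERs for a tornado ordering.  PSA samples all non-fixed parameters jointly
(Beta for probabilities and utilities, Gamma for costs, Normal for patient
characteristics; survival parameters and the discount rate stay fixed) and
summarizes the draws as a cost-effectiveness acceptability curve.

Distribution moments are matched so that the mean equals the baseline value
and the Table-1 range is treated as a 95% interval, i.e.
``sd = (high - low) / (2 * 1.96)``.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov_model import (
    ConsistencyError,
    IcerResult,
    ModelInputs,
    icer,
    run_strategy,
)

__all__ = [
    "ParameterSpec",
    "DSAResult",
    "PSAResult",
    "dsa_bounds",
    "run_dsa",
    "sample_parameters",
    "run_psa",
    "ceac",
    "prob_cost_effective",
]

logger = logging.getLogger(__name__)

PSA_FAMILIES = ("beta", "gamma", "normal", "fixed")


@dataclass
class ParameterSpec:
    """One model input with its DSA bounds and PSA sampling family.

    ``paths`` locate the value inside a :class:`ModelInputs` bundle as dotted
    attribute/key chains; one spec may target several locations (e.g. the
    shared third-line discontinuation probability of both strategies).
    """

    name: str
    baseline: float
    low: float
    high: float
    psa_family: str
    paths: list

    def __post_init__(self):
        if not self.low <= self.baseline <= self.high:
            raise ValueError(
                f"{self.name}: bounds must satisfy low <= baseline <= high"
            )
        if self.psa_family not in PSA_FAMILIES:
            raise ValueError(f"{self.name}: unknown PSA family {self.psa_family!r}")
        if not self.paths:
            raise ValueError(f"{self.name}: at least one path required")

    @property
    def sd(self) -> float:
        """Moment-matched standard deviation (range read as a 95% interval)."""
        return (self.high - self.low) / (2.0 * 1.96)


def _set_path(obj, path: str, value) -> None:
    parts = path.split(".")
    for part in parts[:-1]:
        obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
    last = parts[-1]
    if isinstance(obj, dict):
        if last not in obj:
            raise KeyError(f"path key {last!r} not present")
        obj[last] = value
    else:
        if not hasattr(obj, last):
            raise AttributeError(f"path attribute {last!r} not present")
        setattr(obj, last, value)


def apply_value(inputs: ModelInputs, spec: ParameterSpec, value: float) -> ModelInputs:
    """Return a deep copy of ``inputs`` with ``spec`` set to ``value``."""
    out = copy.deepcopy(inputs)
    for path in spec.paths:
        _set_path(out, path, value)
    return out


def dsa_bounds(inputs: ModelInputs) -> list:
    """The one-way DSA parameter set: every configured spec (survival curves
    are fixed by construction and carry no spec)."""
    if not inputs.parameters:
        raise ValueError("model inputs carry no sensitivity parameter specs")
    return list(inputs.parameters)


def _base_icer(inputs: ModelInputs) -> IcerResult:
    keys = list(inputs.strategies)
    _, ref = run_strategy(inputs, keys[0])
    _, cmp_ = run_strategy(inputs, keys[1])
    return icer(ref, cmp_)


@dataclass
class DSAResult:
    baseline: IcerResult
    records: pd.DataFrame  # parameter, icer_low, icer_high, range, flags
    max_icer: float

    def top(self, n=10) -> pd.DataFrame:
        return self.records.head(n)


def run_dsa(inputs: ModelInputs, specs=None) -> DSAResult:
    """One-way sensitivity analysis over ``specs`` (default: all configured).

    Each parameter is set to its low and high bound in turn with everything
    else at baseline, and both strategies re-run.  ``max_icer`` is the
    largest ICER over all runs among trade-off quadrants (positive
    incremental QALYs); dominance is recorded as a flag, not a number.
    """
    if specs is None:
        specs = dsa_bounds(inputs)
    baseline = _base_icer(inputs)
    rows = []
    all_defined = [baseline.value] if not baseline.flag else []
    for spec in specs:
        results = {}
        for side, bound in (("low", spec.low), ("high", spec.high)):
            res = _base_icer(apply_value(inputs, spec, bound))
            results[side] = res
            if not res.flag:
                all_defined.append(res.value)
        lo, hi = results["low"], results["high"]
        span = abs(hi.value - lo.value) if not (lo.flag or hi.flag) else np.nan
        rows.append(
            {
                "parameter": spec.name,
                "icer_low": lo.value,
                "icer_high": hi.value,
                "flag_low": lo.flag,
                "flag_high": hi.flag,
                "range": span,
            }
        )
    frame = pd.DataFrame(rows).sort_values(
        ["range", "parameter"], ascending=[False, True], na_position="last"
    )
    frame = frame.reset_index(drop=True)
    max_icer = float(np.nanmax(all_defined)) if all_defined else float("nan")
    return DSAResult(baseline=baseline, records=frame, max_icer=max_icer)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


def _draw(spec: ParameterSpec, rng: np.random.Generator) -> float:
    m, sd = spec.baseline, spec.sd
    if spec.psa_family == "fixed" or sd == 0.0:
        return m
    if spec.psa_family == "beta":
        var = sd**2
        limit = m * (1.0 - m)
        if limit <= 0:
            return m
        while var >= limit:
            logger.warning(
                "beta moment-matching infeasible for %s; shrinking sd", spec.name
            )
            var /= 4.0
        nu = limit / var - 1.0
        return float(rng.beta(m * nu, (1.0 - m) * nu))
    if spec.psa_family == "gamma":
        if m <= 0:
            return m
        shape = (m / sd) ** 2
        scale = sd**2 / m
        return float(rng.gamma(shape, scale))
    # normal, truncated to stay physically meaningful
    return float(max(rng.normal(m, sd), 1e-6))


def sample_parameters(inputs: ModelInputs, rng: np.random.Generator) -> ModelInputs:
    """One PSA draw: a deep-copied input bundle with every non-fixed
    parameter replaced by a sample from its configured distribution."""
    out = copy.deepcopy(inputs)
    for spec in out.parameters:
        value = _draw(spec, rng)
        for path in spec.paths:
            _set_path(out, path, value)
    return out


@dataclass
class PSAResult:
    draws: pd.DataFrame  # cost_ref, qaly_ref, cost_cmp, qaly_cmp
    seed: int
    strategy_keys: tuple
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return len(self.draws)


def run_psa(inputs: ModelInputs, n: int, seed: int) -> PSAResult:
    """``n`` Monte-Carlo evaluations of both strategies under joint parameter
    uncertainty; reproducible for a fixed seed."""
    if n < 1:
        raise ValueError("need at least one PSA iteration")
    rng = np.random.default_rng(seed)
    keys = list(inputs.strategies)
    rows = []
    dropped = 0
    for _ in range(n):
        sampled = sample_parameters(inputs, rng)
        try:
            _, ref = run_strategy(sampled, keys[0])
            _, cmp_ = run_strategy(sampled, keys[1])
        except ConsistencyError as exc:  # pragma: no cover - defensive
            dropped += 1
            logger.warning("PSA iteration dropped: %s", exc)
            continue
        rows.append(
            {
                "cost_ref": ref.total_cost,
                "qaly_ref": ref.total_qalys,
                "cost_cmp": cmp_.total_cost,
                "qaly_cmp": cmp_.total_qalys,
            }
        )
    if dropped > 0.01 * n:
        raise RuntimeError(f"{dropped}/{n} PSA iterations failed; aborting")
    return PSAResult(pd.DataFrame(rows), seed, tuple(keys), dropped)


def prob_cost_effective(psa: PSAResult, wtp: float) -> float:
    """Fraction of draws in which the comparator (second strategy) has
    positive incremental net monetary benefit at ``wtp``."""
    d = psa.draws
    nmb = wtp * (d["qaly_cmp"] - d["qaly_ref"]) - (d["cost_cmp"] - d["cost_ref"])
    return float((nmb > 0).mean())


def ceac(psa: PSAResult, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid."""
    wtp_grid = list(wtp_grid)
    if not wtp_grid:
        raise ValueError("WTP grid must not be empty")
    return pd.DataFrame(
        {
            "wtp": wtp_grid,
            "probability": [prob_cost_effective(psa, w) for w in wtp_grid],
        }
    )
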