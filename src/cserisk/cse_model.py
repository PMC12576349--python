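"""The WHO dichotomous catastrophic-expenditure rule.

A household suffers a catastrophic surgical expenditure (CSE) under a
scenario when the out-of-pocket payment — the burden fraction times the
procedure cost — strictly exceeds the threshold share (default 40%) of the
household's annual non-subsistence expenditure (NSE).  Because the OOP
payment is positive, any household with non-positive NSE is at risk under
every scenario.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Scenario
from .errors import InputError

__all__ = [
    "oop_payment",
    "is_cse",
    "risk_threshold_nse",
    "scenario_scan",
    "adjust_for_uninsurance",
    "CSEResult",
]


def oop_payment(s: Scenario) -> float:
    """Out-of-pocket payment: burden fraction times procedure cost."""
    return s.burden * s.procedure_cost


def risk_threshold_nse(s: Scenario) -> float:
    """NSE level at which a household transitions out of risk.

    A household is flagged iff its NSE is strictly below
    burden * cost / threshold (the closed-form inverse of :func:`is_cse`).
    """
    return oop_payment(s) / s.threshold


def is_cse(nse, s: Scenario):
    """Dichotomous CSE indicator: OOP payment > threshold * NSE.

    Strict inequality — a payment exactly equal to the threshold share is
    not catastrophic.  ``nse`` may be a scalar or array and may be
    negative (negative NSE is always at risk).
    """
    arr = np.asarray(nse, dtype=float)
    flags = oop_payment(s) > s.threshold * arr
    if np.ndim(nse) == 0:
        return bool(flags)
    return flags


@dataclass
class CSEResult:
    """Per-scenario risk summary with household-level flags."""

    scenario: Scenario
    flags: np.ndarray
    n_at_risk: int
    pct_at_risk: float

    @property
    def n_households(self) -> int:
        return len(self.flags)


def scenario_scan(profiles: pd.DataFrame, scenarios: list[Scenario]) -> list[CSEResult]:
    """Apply every scenario to one shared set of income draws.

    All scenarios see the same NSE values, so differences between rows are
    attributable to the burden assumption alone.  ``pct_at_risk`` is
    100 * n_at_risk / n_households rounded to 2 decimals.
    """
    if len(profiles) == 0:
        raise InputError("profile table is empty")
    if not scenarios:
        raise InputError("no scenarios provided")
    nse = profiles["nse"].to_numpy(dtype=float)
    results = []
    for s in scenarios:
        flags = is_cse(nse, s)
        n = int(flags.sum())
        results.append(
            CSEResult(
                scenario=s,
                flags=flags,
                n_at_risk=n,
                pct_at_risk=round(100.0 * n / len(nse), 2),
            )
        )
    return results


def results_to_frame(results: list[CSEResult]) -> pd.DataFrame:
    """Scenario-level summary table (one row per burden assumption)."""
    return pd.DataFrame(
        {
            "scenario": [r.scenario.name for r in results],
            "burden": [r.scenario.burden for r in results],
            "procedure_cost": [r.scenario.procedure_cost for r in results],
            "oop_payment": [round(oop_payment(r.scenario), 2) for r in results],
            "n_households": [r.n_households for r in results],
            "n_at_risk": [r.n_at_risk for r in results],
            "pct_at_risk": [r.pct_at_risk for r in results],
        }
    )


def flags_to_frame(profiles: pd.DataFrame, results: list[CSEResult]) -> pd.DataFrame:
    """Household-level flag table: one boolean column per scenario."""
    out = profiles[["hh_id"]].copy()
    for r in results:
        out[f"cse_{r.scenario.name}"] = r.flags
    return out


def adjust_for_uninsurance(pct_at_risk: float, p_uninsured: float) -> float:
    """Scale a population risk percentage by the uninsured fraction.

    The simple product p_uninsured * pct, rounded to 1 decimal: a lower
    bound on risk under the assumption that only uninsured households face
    the uninsured burden.  See :func:`adjust_for_uninsurance_mixture` for
    the two-component variant.
    """
    if not 0.0 <= p_uninsured <= 1.0:
        raise InputError("p_uninsured must lie in [0, 1]")
    return round(p_uninsured * pct_at_risk, 1)


def adjust_for_uninsurance_mixture(
    pct_uninsured_scenario: float, pct_insured_scenario: float, p_uninsured: float
) -> float:
    """Two-component insured/uninsured mixture of scenario risks.

    p * pct(uninsured burden) + (1 - p) * pct(insured burden), rounded to
    1 decimal — the risk of a population in which the insured face the
    insured burden rather than zero risk.
    """
    if not 0.0 <= p_uninsured <= 1.0:
        raise InputError("p_uninsured must lie in [0, 1]")
    return round(
        p_uninsured * pct_uninsured_scenario + (1.0 - p_uninsured) * pct_insured_scenario, 1
    )
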