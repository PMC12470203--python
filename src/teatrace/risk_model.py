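"""Carcinogenic health-risk chain for Cd ingested through tea infusions.

The exposure model is the standard ingestion-pathway pair

    D = I * C * mu / W          daily dose, mg per kg body weight per day
    R = (1 - exp(-D * q)) / A   average individual annual excess cancer risk, 1/a

with I the average daily dry-tea intake (0.0114 kg/d), C the Cd
concentration of the dry tea (mg/kg), mu the leaching fraction into the
infusion actually drunk, W the body weight (70 kg), q the carcinogenic
intensity coefficient of Cd (6.1 (mg kg-1 d-1)-1) and A an averaging
constant (70).  W and A are numerically equal but physically distinct and
are kept as independent parameters.  R is bounded above by 1/A and is
linear in dose (hence in mu) to better than 1e-5 relative at the doses a
tea drinker can realistically reach.

Two scenarios are reported: ``measured_leaching`` (mu from the brewing
assay) and ``total_transfer`` (worst case, mu = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RiskParams", "ICRP_MAX_ACCEPTABLE_RISK", "daily_dose", "annual_risk",
           "tea_concentration_from_total_risk", "risk_table"]

#: Maximum acceptable annual risk level for heavy-metal pollutants (ICRP), 1/a.
ICRP_MAX_ACCEPTABLE_RISK = 5e-5


@dataclass(frozen=True)
class RiskParams:
    daily_intake: float = 0.0114  # kg dry tea per day
    body_weight: float = 70.0  # kg
    q_ig: float = 6.1  # carcinogenic intensity coefficient, (mg kg-1 d-1)-1
    averaging_constant: float = 70.0  # unitless divisor in the annual risk

    def __post_init__(self) -> None:
        for name in ("daily_intake", "body_weight", "q_ig", "averaging_constant"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


def daily_dose(tea_conc_mg_kg, mu, params: RiskParams = RiskParams()):
    """Daily Cd exposure dose per unit body weight, mg kg-1 d-1."""
    tea = np.asarray(tea_conc_mg_kg, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any((mu < 0) | (mu > 1)):
        raise ValueError("mu must be a fraction in [0, 1]")
    if np.any(tea < 0):
        raise ValueError("tea concentration must be >= 0")
    out = params.daily_intake * tea * mu / params.body_weight
    return out if out.ndim else float(out)


def annual_risk(dose_mg_kg_d, params: RiskParams = RiskParams()):
    """Average individual annual carcinogenic risk, 1/a; monotone in dose."""
    dose = np.asarray(dose_mg_kg_d, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0")
    out = -np.expm1(-dose * params.q_ig) / params.averaging_constant
    return out if out.ndim else float(out)


def tea_concentration_from_total_risk(total_risk, params: RiskParams = RiskParams()):
    """Invert the model: dry-tea Cd (mg/kg) implied by a total-transfer (mu=1) risk.

    Useful when a survey prints per-site risks but not the unrounded tea
    concentrations behind them.
    """
    r = np.asarray(total_risk, dtype=float)
    if np.any((r < 0) | (r >= 1.0 / params.averaging_constant)):
        raise ValueError("total_risk must lie in [0, 1/averaging_constant)")
    dose = -np.log1p(-r * params.averaging_constant) / params.q_ig
    out = dose * params.body_weight / params.daily_intake
    return out if out.ndim else float(out)


def risk_table(tea_concs: pd.Series, leach_fracs: pd.Series,
               params: RiskParams = RiskParams(),
               pooled_label: str = "Mean") -> pd.DataFrame:
    """Per-site doses and risks under measured leaching and total transfer.

    ``tea_concs`` (mg/kg) and ``leach_fracs`` (fractions in [0, 1]) are
    Series indexed by site; their indices must match.  A pooled mean row
    per scenario is appended.
    """
    tea = pd.Series(tea_concs, dtype=float)
    mu = pd.Series(leach_fracs, dtype=float)
    if set(tea.index) != set(mu.index):
        raise ValueError(
            f"site mismatch between tea concentrations {sorted(tea.index)} "
            f"and leaching rates {sorted(mu.index)}")
    mu = mu.reindex(tea.index)
    rows = []
    for scenario, frac in (("measured_leaching", mu),
                           ("total_transfer", pd.Series(1.0, index=tea.index))):
        dose = daily_dose(tea.to_numpy(), frac.to_numpy(), params)
        risk = annual_risk(dose, params)
        for site, d, r in zip(tea.index, np.atleast_1d(dose), np.atleast_1d(risk)):
            rows.append({"site_id": site, "scenario": scenario,
                         "dose_mg_kg_d": d, "annual_risk_per_a": r})
        rows.append({"site_id": pooled_label, "scenario": scenario,
                     "dose_mg_kg_d": float(np.nanmean(dose)),
                     "annual_risk_per_a": float(np.nanmean(risk))})
    return pd.DataFrame(rows)
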