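"""Ratio indices of the soil-tea-infusion transfer chain.

Implemented indices
-------------------
pollution index        Pi  = soil total / regulatory standard (0.300 mg/kg for Cd)
activation rate        AR  = available fraction / total x 100   (percent)
enrichment coefficient EC  = organ concentration / soil concentration
transport coefficient  TC  = distal organ / adjacent proximal organ
leaching rate          mu  = element mass in one infusion / mass in the dry tea x 100

Aggregation convention: indices are computed per replicate, averaged to a
site value, then averaged across sites (mean of ratios, not ratio of
means).  Division by zero or a missing input yields NaN with a warning,
so a below-LOQ zero in a field table cannot abort a pipeline run.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .core_data import ORGANS, BrewSpec, Study

__all__ = [
    "CD_SOIL_STANDARD",
    "TRANSPORT_PAIRS",
    "pollution_index",
    "classify_pollution",
    "activation_rate",
    "enrichment_coefficient",
    "transport_coefficient",
    "leaching_rate",
    "summarize",
    "site_organ_table",
    "ec_table",
    "tc_table",
    "leaching_table",
    "compute_indices",
]

#: Soil Cd evaluation standard for tea-garden environments, mg/kg.
CD_SOIL_STANDARD = 0.300

#: Sanctioned (distal, proximal) pairs of the transport chain.  Both leaf
#: classes attach to the lateral stem; the infusion attaches to young leaves.
TRANSPORT_PAIRS: tuple[tuple[str, str], ...] = (
    ("taproot", "fibrous_root"),
    ("main_stem", "taproot"),
    ("lateral_stem", "main_stem"),
    ("old_leaf", "lateral_stem"),
    ("young_leaf", "lateral_stem"),
    ("infusion", "young_leaf"),
)


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def _safe_ratio(num, den, what: str):
    """num/den with NaN (plus a warning) wherever den is 0 or either is NaN."""
    num, den = _as_array(num), _as_array(den)
    bad = (den == 0) & ~np.isnan(den)
    if np.any(bad):
        warnings.warn(f"{what}: zero denominator -> missing", stacklevel=3)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, num / np.where(den == 0, np.nan, den))
    return out if out.ndim else float(out)


def pollution_index(cd_total, standard: float = CD_SOIL_STANDARD):
    """Single-factor pollution index: soil total divided by the standard value."""
    if not standard > 0:
        raise ValueError(f"standard must be > 0, got {standard}")
    out = _as_array(cd_total) / standard
    return out if out.ndim else float(out)


def classify_pollution(pi: float) -> str:
    """Verbal class for a pollution index: safe / below_standard / slight_pollution."""
    if np.isnan(pi):
        return "missing"
    if pi < 0.7:
        return "safe"
    if pi <= 1.0:
        return "below_standard"
    return "slight_pollution"


def activation_rate(available_ug_kg, total_mg_kg):
    """Available fraction as percent of soil total.

    ``available`` is in ug/kg and ``total`` in mg/kg; the factor 1000
    converting the total to ug/kg is applied here and only here, so
    ``activation_rate(1000*x, x) == 100`` for any x > 0.
    """
    return _safe_ratio(available_ug_kg, _as_array(total_mg_kg) * 1000.0,
                       "activation_rate") * 100.0


def enrichment_coefficient(organ_conc_mg_kg, soil_conc_mg_kg):
    """Organ concentration over soil concentration (both mg/kg)."""
    return _safe_ratio(organ_conc_mg_kg, soil_conc_mg_kg, "enrichment_coefficient")


def transport_coefficient(child_conc, parent_conc,
                          pair: tuple[str, str] | None = None):
    """Distal-organ concentration over adjacent proximal-organ concentration.

    If ``pair=(child, parent)`` is given it must be one of
    :data:`TRANSPORT_PAIRS`; non-adjacent compartments are a contract error.
    """
    if pair is not None and tuple(pair) not in TRANSPORT_PAIRS:
        raise ValueError(
            f"{pair} is not an adjacent organ pair; allowed: {TRANSPORT_PAIRS}")
    return _safe_ratio(child_conc, parent_conc, "transport_coefficient")


def leaching_rate(infusion_ug_L, tea_conc_mg_kg, brew: BrewSpec | None = None):
    """Percent of the element in the dry tea that passed into one infusion.

    mass in infusion = conc [ug/L] x water volume [L]
    mass in dry tea  = conc [mg/kg] x tea mass [kg] x 1000 [ug/mg]
    """
    brew = brew or BrewSpec()
    num = _as_array(infusion_ug_L) * brew.water_volume
    den = _as_array(tea_conc_mg_kg) * brew.tea_mass * 1000.0
    return _safe_ratio(num, den, "leaching_rate") * 100.0


def summarize(values, groups, pooled_label: str = "Mean") -> pd.DataFrame:
    """Per-group mean and sample sd (ddof=1), plus a pooled row of group means.

    The pooled row mirrors the bottom line of a per-site survey table:
    the mean and sd *across group means*, n = number of groups.
    Single-member groups get sd = NaN.
    """
    df = pd.DataFrame({"group": np.asarray(groups), "value": _as_array(values)})
    if df.empty:
        raise ValueError("summarize requires at least one value")
    rows = []
    for g, sub in df.groupby("group", sort=False):
        v = sub["value"].dropna()
        rows.append({
            "group": g,
            "n": len(v),
            "mean": v.mean() if len(v) else np.nan,
            "sd": v.std(ddof=1) if len(v) >= 2 else np.nan,
        })
    out = pd.DataFrame(rows)
    gm = out["mean"].dropna()
    out.loc[len(out)] = {
        "group": pooled_label,
        "n": len(gm),
        "mean": gm.mean(),
        "sd": gm.std(ddof=1) if len(gm) >= 2 else np.nan,
    }
    return out


# ---------------------------------------------------------------------------
# Study-level tables


def site_organ_table(study: Study, element: str) -> pd.DataFrame:
    """Site x organ mean concentrations (over replicates) for one element."""
    sub = study.organs[study.organs["element"] == element]
    wide = (sub.pivot_table(index="site_id", columns="organ",
                            values="conc_mg_kg", aggfunc="mean")
            .reindex(columns=[o for o in ORGANS]))
    return wide


def ec_table(study: Study, element: str) -> pd.DataFrame:
    """Per-site enrichment coefficients, one column per organ.

    Computed per replicate against the site's soil total, then averaged
    to the site.
    """
    soil_col = "cd_total_mg_kg" if element == "Cd" else "se_total_mg_kg"
    soil = study.soil.set_index("site_id")[soil_col]
    sub = study.organs[study.organs["element"] == element].copy()
    sub["soil"] = sub["site_id"].map(soil)
    sub["ec"] = enrichment_coefficient(sub["conc_mg_kg"], sub["soil"])
    return (sub.pivot_table(index="site_id", columns="organ", values="ec",
                            aggfunc="mean")
            .reindex(columns=[o for o in ORGANS]))


def tc_table(study: Study, element: str, include_infusion: bool = False) -> pd.DataFrame:
    """Per-site transport coefficients along the sanctioned chain.

    Replicates are paired by replicate index; the per-replicate ratio is
    averaged to the site.  Columns are labelled ``child/parent``.  The
    ``infusion/young_leaf`` step (a percent, the leaching rate) is only
    included on request.
    """
    sub = study.organs[study.organs["element"] == element]
    wide = sub.pivot_table(index=["site_id", "replicate"], columns="organ",
                           values="conc_mg_kg", aggfunc="mean")
    cols = {}
    for child, parent in TRANSPORT_PAIRS:
        if child == "infusion":
            continue
        if child in wide.columns and parent in wide.columns:
            cols[f"{child}/{parent}"] = transport_coefficient(
                wide[child], wide[parent], pair=(child, parent))
    tc = pd.DataFrame(cols, index=wide.index).groupby("site_id").mean()
    if include_infusion:
        leach = leaching_table(study, element).set_index("site_id")["leaching_pct"]
        tc["infusion/young_leaf"] = leach
    return tc


def leaching_table(study: Study, element: str) -> pd.DataFrame:
    """Per-site leaching rate (%) from young-leaf tea into the infusion."""
    inf = study.infusion[study.infusion["element"] == element]
    tea = (study.organs[(study.organs["element"] == element)
                        & (study.organs["organ"] == "young_leaf")]
           .groupby("site_id")["conc_mg_kg"].mean())
    rows = []
    for _, r in inf.iterrows():
        brew = BrewSpec(tea_mass=r["tea_mass_kg"], water_volume=r["water_volume_L"])
        tea_conc = tea.get(r["site_id"], np.nan)
        rows.append({
            "site_id": r["site_id"],
            "infusion_ug_L": r["conc_ug_L"],
            "tea_mg_kg": tea_conc,
            "leaching_pct": leaching_rate(r["conc_ug_L"], tea_conc, brew),
        })
    return pd.DataFrame(rows)


def compute_indices(study: Study, element: str = "Cd") -> pd.DataFrame:
    """All indices for one element as a tidy table.

    Columns: ``site_id, index_name, qualifier, value``.  Pi is Cd-only
    (the standard is a Cd standard); AR uses the matching available
    fraction; EC/TC/leaching follow the organ chain.
    """
    soil = study.soil
    rows: list[dict] = []
    if element == "Cd":
        pi = pollution_index(soil["cd_total_mg_kg"])
        ar = activation_rate(soil["cd_avail_ug_kg"], soil["cd_total_mg_kg"])
        ar_name = "ARCd"
    else:
        pi = None
        ar = activation_rate(soil["se_avail_ug_kg"], soil["se_total_mg_kg"])
        ar_name = "ARSe"
    for i, site in enumerate(soil["site_id"]):
        if pi is not None:
            rows.append({"site_id": site, "index_name": "Pi",
                         "qualifier": "", "value": pi[i]})
        rows.append({"site_id": site, "index_name": ar_name,
                     "qualifier": "", "value": ar[i]})
    ec = ec_table(study, element)
    for organ in ec.columns:
        for site, v in ec[organ].items():
            rows.append({"site_id": site, "index_name": "EC",
                         "qualifier": organ, "value": v})
    tc = tc_table(study, element)
    for pair in tc.columns:
        for site, v in tc[pair].items():
            rows.append({"site_id": site, "index_name": "TC",
                         "qualifier": pair, "value": v})
    leach = leaching_table(study, element)
    for _, r in leach.iterrows():
        rows.append({"site_id": r["site_id"], "index_name": "leaching",
                     "qualifier": "infusion/young_leaf",
                     "value": r["leaching_pct"]})
    return pd.DataFrame(rows, columns=["site_id", "index_name", "qualifier", "value"])
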