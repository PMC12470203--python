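"""Synthetic multi-compartment study generator.

Emulates the sampling design the analysis assumes: 12 Se-enriched tea
gardens, 3 replicates per garden, six organs per tree, plus one brewed
infusion per garden.  The generative chain is multiplicative:

* soil totals drawn uniformly within the observed survey ranges;
* available fractions = total x activation rate, with lognormal site
  scatter tied (via a Gaussian copula) to soil covariates so that the
  configured correlation signs (pH negative, AK/TN positive) hold;
* fibrous-root Cd = soil Cd x (EC + piece(Se_fr)), where piece is an
  additive coupling on the enrichment-coefficient scale whose slope is
  positive below the Se breakpoint and negative above it — the
  threshold antagonism the two-phase regression is meant to recover;
* every downstream organ = its proximal parent x the configured
  transport coefficient, with lognormal replicate noise (CV = noise_cv);
* infusion concentration = young-leaf concentration x leaching rate,
  converted to ug/L through the brew's tea mass and water volume.

A single ``noise_cv`` knob drives all lognormal scatter (site and
replicate levels); the real study's quadrat/plant/assay variance layers
are not separable from published tables, so no attempt is made to model
them separately.  The realized latent values are emitted as
:class:`GroundTruth` next to the data and are never read by the pipeline
under test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core_data import (ELEMENTS, ORGANS, BrewSpec, Study, read_study,
                        write_study)

__all__ = ["GeneratorConfig", "GroundTruth", "simulate_study", "write_truth"]

logger = logging.getLogger(__name__)

#: transport-chain order as (child, parent) edges, root -> leaf
_CHAIN_EDGES = (
    ("taproot", "fibrous_root"),
    ("main_stem", "taproot"),
    ("lateral_stem", "main_stem"),
    ("old_leaf", "lateral_stem"),
    ("young_leaf", "lateral_stem"),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one simulated survey.

    Defaults reproduce the printed summary state of the reference
    12-garden survey: soil ranges, mean activation rates, the fibrous-root
    enrichment coefficient, the organ-chain transport coefficients, the
    Se-Cd breakpoint at 2.0 mg/kg in fibrous roots, and mean leaching
    rates.  The coupling slopes act on the fibrous-root EC scale.
    """

    seed: int
    n_sites: int = 12
    n_reps: int = 3
    soil_cd_range: tuple[float, float] = (0.18, 0.55)  # mg/kg
    soil_se_range: tuple[float, float] = (1.46, 5.50)  # mg/kg
    ar_cd_mean: float = 20.93  # percent
    ar_se_mean: float = 2.27  # percent
    ec_fibrous_cd: float = 3.49
    tc_chain_cd: tuple[float, ...] = (0.29, 0.97, 1.16, 0.26, 0.07)
    ec_fibrous_se: float = 0.66
    tc_chain_se: tuple[float, ...] = (0.51, 0.72, 0.63, 2.0, 0.95)
    se_cd_breakpoint: float = 2.0  # mg/kg Se in fibrous roots
    coupling_slopes: tuple[float, float] = (0.6, -0.6)  # (below, above), EC per mg/kg
    leach_mean_cd: float = 13.33  # percent
    leach_mean_se: float = 22.62  # percent
    noise_cv: float = 0.05
    #: correlation signs/magnitudes of soil covariates with the Cd
    #: activation scatter (Gaussian copula weights)
    ph_rho: float = -0.6
    ak_rho: float = 0.6
    tn_rho: float = 0.4
    brew: BrewSpec = field(default_factory=BrewSpec)

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_reps < 1:
            raise ValueError("n_sites and n_reps must be >= 1")
        for name in ("soil_cd_range", "soil_se_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive and ordered")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        w2 = self.ph_rho ** 2 + self.ak_rho ** 2 + self.tn_rho ** 2
        if w2 > 1:
            raise ValueError("copula weights imply correlation > 1")

    def chain(self, element: str) -> dict[tuple[str, str], float]:
        tcs = self.tc_chain_cd if element == "Cd" else self.tc_chain_se
        return dict(zip(_CHAIN_EDGES, tcs))


@dataclass
class GroundTruth:
    """Realized latent state of one simulated study (never read by the pipeline)."""

    config: GeneratorConfig
    site_latents: pd.DataFrame  # per site x element: latent organ concentrations
    leach_rates: pd.DataFrame  # per site x element: realized leaching percent


def _sigma(cv: float) -> float:
    """Lognormal sigma with unit mean for a given coefficient of variation."""
    return float(np.sqrt(np.log1p(cv ** 2)))


def _lognoise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    s = _sigma(cv)
    return np.exp(rng.normal(-0.5 * s * s, s, size=size))


def simulate_study(config: GeneratorConfig,
                   max_retries: int = 100) -> tuple[Study, GroundTruth]:
    """Draw one complete study bundle plus its ground truth.

    Identical config and seed give bit-identical tables.  A site whose
    realized fibrous-root EC would be nonpositive (possible only under
    extreme coupling slopes) is redrawn, with a log notice, up to
    ``max_retries`` times.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sites
    sites = [f"s{i + 1:02d}" for i in range(n)]
    cv = config.noise_cv
    s_lo, s_hi = config.coupling_slopes
    bp = config.se_cd_breakpoint

    # --- soil draws (with copula-linked covariates)
    soil_cd = rng.uniform(*config.soil_cd_range, size=n)
    soil_se = rng.uniform(*config.soil_se_range, size=n)
    u_ph = rng.normal(size=n)
    u_ak = rng.normal(size=n)
    u_tn = rng.normal(size=n)
    resid_w = np.sqrt(max(0.0, 1.0 - config.ph_rho ** 2 - config.ak_rho ** 2
                          - config.tn_rho ** 2))
    z_acd = (config.ph_rho * u_ph + config.ak_rho * u_ak + config.tn_rho * u_tn
             + resid_w * rng.normal(size=n))
    z_ase = 0.5 * z_acd + np.sqrt(0.75) * rng.normal(size=n)

    sig = _sigma(cv) if cv > 0 else 0.0
    acd = soil_cd * 1000.0 * config.ar_cd_mean / 100.0 * np.exp(sig * z_acd - 0.5 * sig ** 2)
    ase = soil_se * 1000.0 * config.ar_se_mean / 100.0 * np.exp(sig * z_ase - 0.5 * sig ** 2)

    soil = pd.DataFrame({
        "site_id": sites,
        "cd_total_mg_kg": soil_cd,
        "cd_avail_ug_kg": acd,
        "se_total_mg_kg": soil_se,
        "se_avail_ug_kg": ase,
        "ph": 4.0 + 2.5 * norm.cdf(u_ph),  # acidic tea-garden range
        "som_g_kg": 25.0 * np.exp(0.3 * rng.normal(size=n)),
        "tn_g_kg": 1.5 * np.exp(0.25 * u_tn),
        "tp_g_kg": 0.8 * np.exp(0.25 * rng.normal(size=n)),
        "ap_mg_kg": 30.0 * np.exp(0.4 * rng.normal(size=n)),
        "ak_mg_kg": 120.0 * np.exp(0.3 * u_ak),
    })

    # --- site-level latent organ chains
    latents: dict[str, dict[str, np.ndarray]] = {e: {} for e in ELEMENTS}
    latents["Se"]["fibrous_root"] = soil_se * config.ec_fibrous_se
    se_fr = latents["Se"]["fibrous_root"]
    piece = np.where(se_fr <= bp, s_lo * (se_fr - bp), s_hi * (se_fr - bp))
    ec_real = config.ec_fibrous_cd + piece
    for attempt in range(max_retries):
        bad = ec_real <= 0
        if not bad.any():
            break
        logger.warning("regenerating %d site(s) with nonpositive fibrous EC", bad.sum())
        soil_cd[bad] = rng.uniform(*config.soil_cd_range, size=int(bad.sum()))
        # coupling depends on Se only; redraw Se where EC is impossible
        soil_se[bad] = rng.uniform(*config.soil_se_range, size=int(bad.sum()))
        se_fr = soil_se * config.ec_fibrous_se
        piece = np.where(se_fr <= bp, s_lo * (se_fr - bp), s_hi * (se_fr - bp))
        ec_real = config.ec_fibrous_cd + piece
        latents["Se"]["fibrous_root"] = se_fr
    else:
        raise RuntimeError("could not realize positive fibrous-root EC; "
                           "check coupling slopes")
    latents["Cd"]["fibrous_root"] = soil_cd * ec_real
    for element in ELEMENTS:
        chain = config.chain(element)
        for (child, parent), tc in chain.items():
            latents[element][child] = latents[element][parent] * tc

    # --- replicate-level organ table
    rows = []
    for element in ELEMENTS:
        for organ in ORGANS:
            lat = latents[element][organ]
            noise = _lognoise(rng, cv, (n, config.n_reps))
            conc = lat[:, None] * noise
            for i, site in enumerate(sites):
                for r in range(config.n_reps):
                    rows.append({"site_id": site, "organ": organ,
                                 "element": element, "replicate": r + 1,
                                 "conc_mg_kg": conc[i, r]})
    organs = pd.DataFrame(rows)

    # --- infusion
    leach = {
        "Cd": config.leach_mean_cd * _lognoise(rng, cv, n),
        "Se": config.leach_mean_se * _lognoise(rng, cv, n),
    }
    inf_rows = []
    for element in ELEMENTS:
        young = latents[element]["young_leaf"]
        conc_ug_L = (young * leach[element] / 100.0
                     * config.brew.tea_mass * 1000.0 / config.brew.water_volume)
        for i, site in enumerate(sites):
            inf_rows.append({"site_id": site, "element": element,
                             "conc_ug_L": conc_ug_L[i],
                             "tea_mass_kg": config.brew.tea_mass,
                             "water_volume_L": config.brew.water_volume})
    infusion = pd.DataFrame(inf_rows)

    study = Study(soil=soil, organs=organs, infusion=infusion)
    lat_rows = []
    for element in ELEMENTS:
        for organ in ORGANS:
            for i, site in enumerate(sites):
                lat_rows.append({"site_id": site, "element": element,
                                 "organ": organ,
                                 "latent_mg_kg": latents[element][organ][i]})
    truth = GroundTruth(
        config=config,
        site_latents=pd.DataFrame(lat_rows),
        leach_rates=pd.DataFrame({
            "site_id": sites,
            "Cd": leach["Cd"],
            "Se": leach["Se"],
        }),
    )
    return study, truth


def write_truth(truth: GroundTruth, path: str | Path) -> Path:
    """Serialize a :class:`GroundTruth` to JSON next to the generated CSVs."""
    path = Path(path)
    cfg = asdict(truth.config)
    cfg["brew"] = asdict(truth.config.brew)
    payload = {
        "config": cfg,
        "site_latents": truth.site_latents.to_dict(orient="records"),
        "leach_rates": truth.leach_rates.to_dict(orient="records"),
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def simulate_to_dir(config: GeneratorConfig, out_dir: str | Path) -> Study:
    """Simulate and write soil/organs/infusion CSVs plus truth.json; re-reads
    the files through the validating readers before returning."""
    out = Path(out_dir)
    study, truth = simulate_study(config)
    paths = write_study(study, out)
    write_truth(truth, out / "truth.json")
    return read_study(paths["soil"], paths["organs"], paths["infusion"])
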