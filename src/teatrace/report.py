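"""End-to-end pipeline: one config in, survey-style report tables out.

``run_pipeline`` composes the stages in order — load/simulate, indices,
statistics, risk — and emits:

* ``indices.csv``      tidy per-site indices at full precision
* ``table1.csv``       soil chemistry + activation rates + pollution index
* ``table2.csv``       site x organ concentrations with LSD letters
* ``table3.csv``       infusion, leaching rate, and annual risks (Cd only)
* ``correlation.csv``  soil correlation matrix, long format
* ``segmented.csv``    two-phase fibrous-root Se-Cd regression
* ``run_config.yaml``  the resolved configuration, for provenance
* ``run.log``          stage-level log with record counts

Display rounding (2 d.p. for ratios and concentrations, 3 significant
digits for risks) is applied here and only here; every displayed cell is
a pure formatting of a full-precision pipeline value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_data import ORGANS, Study, read_study
from .risk_model import RiskParams, risk_table
from .stats_suite import anova_lsd, pearson_matrix, threshold_fit
from .synthetic import GeneratorConfig, simulate_study, write_truth
from .transfer_indices import (activation_rate, classify_pollution,
                               compute_indices, leaching_table,
                               pollution_index, site_organ_table)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("teatrace")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the offending detail."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {detail}")


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run.

    Exactly one of ``inputs`` (paths to soil/organs/infusion CSVs) or
    ``simulate`` (a :class:`~teatrace.synthetic.GeneratorConfig`) must be
    given.
    """

    out_dir: str | Path
    inputs: dict[str, str] | None = None
    simulate: GeneratorConfig | None = None
    element: str = "Cd"
    alpha: float = 0.05
    risk_params: RiskParams = field(default_factory=RiskParams)
    breakpoint: float | None = 2.0  # None => search
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("exactly one of 'inputs' or 'simulate' must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = GeneratorConfig(**sim)
        rp = raw.pop("risk_params", None)
        kwargs = dict(raw)
        if rp is not None:
            kwargs["risk_params"] = RiskParams(**rp)
        bp = kwargs.get("breakpoint", 2.0)
        kwargs["breakpoint"] = None if bp in (None, "search") else float(bp)
        return cls(simulate=sim, **kwargs)

    def resolved(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "out_dir": str(self.out_dir),
            "element": self.element,
            "alpha": self.alpha,
            "breakpoint": "search" if self.breakpoint is None else self.breakpoint,
            "risk_params": vars(self.risk_params).copy(),
            "version": __version__,
        }
        if self.inputs is not None:
            out["inputs"] = dict(self.inputs)
        if self.simulate is not None:
            sim = {k: v for k, v in vars(self.simulate).items() if k != "brew"}
            sim["brew"] = vars(self.simulate.brew).copy()
            for k, v in sim.items():
                if isinstance(v, tuple):
                    sim[k] = list(v)
            out["simulate"] = sim
        return out


def _round2(x):
    return np.round(np.asarray(x, dtype=float), 2)


def _sci3(x) -> str:
    return "" if pd.isna(x) else f"{x:.2e}"


def _organ_letters(study: Study, element: str, alpha: float) -> dict[str, dict[str, str]]:
    """Per-organ LSD letters across sites, when replicates allow (n >= 2)."""
    sub = study.organs[study.organs["element"] == element]
    counts = sub.groupby(["site_id", "organ"]).size()
    if counts.empty or counts.min() < 2:
        return {}
    out = {}
    for organ in ORGANS:
        o = sub[sub["organ"] == organ]
        res = anova_lsd(o["conc_mg_kg"], o["site_id"], alpha=alpha)
        out[organ] = res.letters
    return out


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns the output paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    paths: dict[str, Path] = {}
    try:
        # --- stage: load / simulate
        try:
            if config.simulate is not None:
                study, truth = simulate_study(config.simulate)
                write_truth(truth, out / "truth.json")
                logger.info("simulated study: seed=%s sites=%d",
                            config.simulate.seed, config.simulate.n_sites)
            else:
                study = read_study(config.inputs["soil"], config.inputs["organs"],
                                   config.inputs["infusion"])
                logger.info("loaded study from %s", config.inputs)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("load", str(e)) from e
        logger.info("records: soil=%d organs=%d infusion=%d",
                    len(study.soil), len(study.organs), len(study.infusion))

        element = config.element
        # --- stage: indices
        try:
            indices = compute_indices(study, element)
            paths["indices"] = out / "indices.csv"
            indices.to_csv(paths["indices"], index=False)
            logger.info("indices: %d rows", len(indices))
        except Exception as e:  # noqa: BLE001
            raise PipelineError("indices", str(e)) from e

        # --- stage: table1 (soil)
        try:
            soil = study.soil
            t1 = soil[["site_id", "cd_total_mg_kg", "cd_avail_ug_kg",
                       "se_total_mg_kg", "se_avail_ug_kg"]].copy()
            t1["arcd_pct"] = _round2(activation_rate(soil["cd_avail_ug_kg"],
                                                     soil["cd_total_mg_kg"]))
            t1["arse_pct"] = _round2(activation_rate(soil["se_avail_ug_kg"],
                                                     soil["se_total_mg_kg"]))
            pi = pollution_index(soil["cd_total_mg_kg"])
            t1["pollution_index"] = _round2(pi)
            t1["pollution_class"] = [classify_pollution(v) for v in pi]
            for col in ("cd_total_mg_kg", "cd_avail_ug_kg", "se_total_mg_kg",
                        "se_avail_ug_kg"):
                t1[col] = _round2(t1[col])
            mean_row = {"site_id": "Mean"}
            for col in t1.columns:
                if col not in ("site_id", "pollution_class"):
                    mean_row[col] = round(float(t1[col].mean()), 2)
            t1.loc[len(t1)] = mean_row
            paths["table1"] = out / "table1.csv"
            t1.to_csv(paths["table1"], index=False)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("table1", str(e)) from e

        # --- stage: table2 (organ concentrations + letters)
        try:
            letters = _organ_letters(study, element, config.alpha)
            t2 = site_organ_table(study, element)
            disp = t2.round(2).astype(object)
            for organ in disp.columns:
                if organ in letters:
                    disp[organ] = [f"{v:.2f} {letters[organ].get(s, '')}".strip()
                                   for s, v in t2[organ].items()]
            disp.loc["Mean"] = [f"{t2[c].mean():.2f}" for c in t2.columns]
            paths["table2"] = out / "table2.csv"
            disp.to_csv(paths["table2"])
        except Exception as e:  # noqa: BLE001
            raise PipelineError("table2", str(e)) from e

        # --- stage: table3 (infusion, leaching, risk)
        try:
            leach = leaching_table(study, element).set_index("site_id")
            t3 = pd.DataFrame({
                "infusion_ug_L": leach["infusion_ug_L"],
                "leaching_pct": _round2(leach["leaching_pct"]),
            })
            if element == "Cd":
                tea = leach["tea_mg_kg"]
                rt = risk_table(tea, leach["leaching_pct"].clip(upper=100.0) / 100.0,
                                config.risk_params)
                for scen, col in (("measured_leaching", "risk_measured_per_a"),
                                  ("total_transfer", "risk_total_per_a")):
                    s = (rt[rt["scenario"] == scen]
                         .set_index("site_id")["annual_risk_per_a"])
                    t3[col] = s.reindex(list(t3.index) + ["Mean"])[:-1]
                mean_row = {
                    "infusion_ug_L": round(float(t3["infusion_ug_L"].mean()), 3),
                    "leaching_pct": round(float(t3["leaching_pct"].mean()), 2),
                    "risk_measured_per_a": float(
                        rt[(rt["scenario"] == "measured_leaching")
                           & (rt["site_id"] == "Mean")]["annual_risk_per_a"].iloc[0]),
                    "risk_total_per_a": float(
                        rt[(rt["scenario"] == "total_transfer")
                           & (rt["site_id"] == "Mean")]["annual_risk_per_a"].iloc[0]),
                }
                t3.loc["Mean"] = mean_row
                for col in ("risk_measured_per_a", "risk_total_per_a"):
                    t3[col] = t3[col].map(_sci3)
            else:
                logger.info("element=%s: risk stage skipped (Cd-only model)", element)
                t3.loc["Mean"] = {
                    "infusion_ug_L": round(float(t3["infusion_ug_L"].mean()), 3),
                    "leaching_pct": round(float(t3["leaching_pct"].mean()), 2),
                }
            paths["table3"] = out / "table3.csv"
            t3.to_csv(paths["table3"], index_label="site_id")
        except Exception as e:  # noqa: BLE001
            raise PipelineError("table3", str(e)) from e

        # --- stage: correlation
        try:
            soil_num = study.soil.drop(columns=["site_id"]).dropna(axis=1, how="all")
            soil_num = soil_num.assign(
                arcd_pct=activation_rate(study.soil["cd_avail_ug_kg"],
                                         study.soil["cd_total_mg_kg"]))
            corr = pearson_matrix(soil_num)
            paths["correlation"] = out / "correlation.csv"
            corr.to_long().to_csv(paths["correlation"], index=False)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("correlation", str(e)) from e

        # --- stage: segmented (fibrous-root Se vs Cd threshold regression)
        try:
            org = study.organs
            fib = org[org["organ"] == "fibrous_root"].pivot_table(
                index=["site_id", "replicate"], columns="element",
                values="conc_mg_kg")
            seg = threshold_fit(fib["Se"], fib["Cd"], breakpoint=config.breakpoint)
            rows = []
            for name, line in (("below", seg.below), ("above", seg.above)):
                rows.append({"segment": name, "slope": line.slope,
                             "intercept": line.intercept, "r2": line.r2,
                             "p": line.p, "n": line.n,
                             "breakpoint": seg.breakpoint})
            paths["segmented"] = out / "segmented.csv"
            pd.DataFrame(rows).to_csv(paths["segmented"], index=False)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("segmented", str(e)) from e

        # --- provenance
        paths["config"] = out / "run_config.yaml"
        paths["config"].write_text(yaml.safe_dump(config.resolved(), sort_keys=True))
        logger.info("run complete: %s", sorted(paths))
        return paths
    finally:
        logger.removeHandler(handler)
        handler.close()
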